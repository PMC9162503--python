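"""Virtual-pinhole viewpoint synthesis, extended depth of field and stereo.

Once the in-focus layers are separated, the scene as seen by a pinhole
camera displaced a fraction β of the pupil radius is obtained by shifting
every layer proportionally to its focus current — the disparity of layer k
is  d_k = β·R0·j_k  pixels — and summing.  The shift is applied in the
Fourier domain as a linear phase ramp on each layer spectrum:

    S_β(u,v) = Σ_k exp(−i·2π·j_k·R0·(βx·u + βy·v)) · F_k(u,v),

with (u, v) in cycles/px, and the view is the inverse transform of S_β.
β = 0 gives the centred pinhole, i.e. the extended-depth-of-field
(all-in-focus) image; a stereo pair is the two views at βx = ±B/(2R) for a
baseline B between virtual pinholes, physically constrained to B ≤ 2R.

Phase-ramp shifting implies circular boundary conditions; the stack-level
helpers accept a zero-padding guard (``pad="auto"`` pads by the largest
expected disparity) so that content cannot wrap across the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import fft as spfft

from .forward import BlurModel
from .separation import DEFAULT_RCOND, LayerSpectra, solve_layer_spectra
from .stack import MultifocusStack

__all__ = [
    "ViewpointRequest",
    "StereoPair",
    "disparity_px",
    "synthesize_viewpoint",
    "extended_dof",
    "stereo_pair",
    "render_stereo",
    "sweep_viewpoints",
]


@dataclass(frozen=True)
class ViewpointRequest:
    """Virtual pinhole position as fractions of the pupil radius.

    Displacements beyond the pupil rim (|β| > 1) have no physical meaning
    and are rejected.
    """

    beta_x: float = 0.0
    beta_y: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.beta_x) > 1 or abs(self.beta_y) > 1:
            raise ValueError(
                f"viewpoint ({self.beta_x}, {self.beta_y}) outside the pupil: "
                "|beta_x| <= 1 and |beta_y| <= 1 required"
            )


@dataclass
class StereoPair:
    """Left/right virtual-pinhole views with their baseline fraction B/R."""

    left: np.ndarray
    right: np.ndarray
    baseline_fraction: float

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("left and right views must share dimensions")
        if not 0 <= self.baseline_fraction <= 2:
            raise ValueError(
                f"baseline fraction B/R = {self.baseline_fraction} violates B <= 2R"
            )


def disparity_px(beta_x: float, j_k_mA: float, blur: BlurModel) -> float:
    """Signed horizontal disparity (px) of the layer at current ``j_k``.

    d = βx·R0·j_k: linear in both the pupil displacement fraction and the
    focus current.
    """
    return beta_x * blur.R0 * j_k_mA


def synthesize_viewpoint(spectra: LayerSpectra, req: ViewpointRequest) -> np.ndarray:
    """Render the view from a virtual pinhole at (βx, βy).

    Applies the per-layer phase ramps to the layer spectra, sums over
    layers and inverse-transforms.  βx > 0 shifts far layers (large j) to
    the right; βy > 0 shifts them down the rows (camera moved up).
    """
    h, w = spectra.shape
    u = spfft.fftfreq(w)[None, :]
    v = spfft.fftfreq(h)[:, None]
    S = np.zeros(spectra.F.shape[1:], dtype=complex)
    for k in range(spectra.n_layers):
        phase = np.exp(
            -2j
            * np.pi
            * spectra.currents_mA[k]
            * spectra.R0
            * (req.beta_x * u + req.beta_y * v)
        )
        Fk = spectra.F[k]
        S += phase[..., None] * Fk if Fk.ndim == 3 else phase * Fk
    return spfft.ifft2(S, axes=(0, 1), workers=-1).real


def _auto_pad(blur: BlurModel, currents: np.ndarray, betas: Iterable[tuple[float, float]]) -> int:
    d = max(
        (max(abs(bx), abs(by)) * blur.R0 * np.max(np.abs(currents)) for bx, by in betas),
        default=0.0,
    )
    return int(np.ceil(d))


def _solve_padded(
    stack: MultifocusStack,
    blur: BlurModel,
    rcond: float,
    pad: int,
) -> tuple[LayerSpectra, int]:
    if pad > 0:
        width = [(0, 0), (pad, pad), (pad, pad)] + [(0, 0)] * (stack.slices.ndim - 3)
        stack = stack.with_slices(np.pad(np.asarray(stack.slices, dtype=float), width))
    return solve_layer_spectra(stack, blur, rcond=rcond), pad


def _crop(img: np.ndarray, pad: int) -> np.ndarray:
    return img[pad:-pad, pad:-pad] if pad > 0 else img


def extended_dof(
    stack: MultifocusStack, blur: BlurModel, rcond: float = DEFAULT_RCOND
) -> np.ndarray:
    """All-in-focus image: the β = 0 viewpoint (centred pinhole)."""
    spectra = solve_layer_spectra(stack, blur, rcond=rcond)
    return synthesize_viewpoint(spectra, ViewpointRequest(0.0, 0.0))


def stereo_pair(
    stack: MultifocusStack,
    blur: BlurModel,
    baseline_fraction: float,
    rcond: float = DEFAULT_RCOND,
    pad: int | str = "auto",
) -> StereoPair:
    """Stereo views at βx = ±B/(2R) for a baseline fraction B/R.

    The left view looks from a pinhole displaced left (βx = +B/(2R)), the
    right view from one displaced right (βx = −B/(2R)).
    """
    if not 0 <= baseline_fraction <= 2:
        raise ValueError(
            f"baseline fraction B/R = {baseline_fraction} violates B <= 2R"
        )
    bx = baseline_fraction / 2.0
    if pad == "auto":
        pad = _auto_pad(blur, stack.currents_mA, [(bx, 0.0)])
    spectra, pad = _solve_padded(stack, blur, rcond, int(pad))
    left = _crop(synthesize_viewpoint(spectra, ViewpointRequest(bx, 0.0)), pad)
    right = _crop(synthesize_viewpoint(spectra, ViewpointRequest(-bx, 0.0)), pad)
    return StereoPair(left=left, right=right, baseline_fraction=baseline_fraction)


def render_stereo(pair: StereoPair, mode: str = "cross_eye", gutter: int = 0) -> np.ndarray:
    """Compose a stereo pair for display.

    ``cross_eye`` puts the left-eye view on the RIGHT panel (fused by
    crossing the eyes), ``parallel`` the opposite, ``anaglyph`` encodes the
    left view in red and the right view in green+blue.
    """
    left, right = pair.left, pair.right
    if mode in ("cross_eye", "parallel"):
        panels = (right, left) if mode == "cross_eye" else (left, right)
        if gutter > 0:
            gap_shape = (left.shape[0], gutter) + left.shape[2:]
            panels = (panels[0], np.zeros(gap_shape), panels[1])
        return np.concatenate(panels, axis=1)
    if mode == "anaglyph":
        def lum(img: np.ndarray) -> np.ndarray:
            return img @ np.array([0.299, 0.587, 0.114]) if img.ndim == 3 else img

        l, r = lum(left), lum(right)
        return np.stack([l, r, r], axis=-1)
    raise ValueError(f"unknown stereo render mode {mode!r}")


def sweep_viewpoints(
    stack: MultifocusStack,
    blur: BlurModel,
    beta_grid: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    rcond: float = DEFAULT_RCOND,
    pad: int | str = "auto",
) -> list[np.ndarray]:
    """Render an ordered sequence of viewpoints from one spectral solve.

    ``beta_grid`` is either an explicit sequence of (βx, βy) pairs or a
    pair of 1-D arrays (βx values, βy values) expanded in row-major
    serpentine order (each βy row traverses βx in alternating direction,
    as one would scan for a smooth video).
    """
    if (
        isinstance(beta_grid, tuple)
        and len(beta_grid) == 2
        and isinstance(beta_grid[0], np.ndarray)
        and isinstance(beta_grid[1], np.ndarray)
    ):
        bxs, bys = (np.asarray(b, dtype=float) for b in beta_grid)
        pairs = []
        for i, by in enumerate(bys):
            row = bxs if i % 2 == 0 else bxs[::-1]
            pairs.extend((float(bx), float(by)) for bx in row)
    else:
        pairs = [(float(bx), float(by)) for bx, by in beta_grid]
    if pad == "auto":
        pad = _auto_pad(blur, stack.currents_mA, pairs)
    spectra, pad = _solve_padded(stack, blur, rcond, int(pad))
    return [
        _crop(synthesize_viewpoint(spectra, ViewpointRequest(bx, by)), pad)
        for bx, by in pairs
    ]
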