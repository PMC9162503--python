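"""Fourier-domain separation of the in-focus layers of a multifocus stack.

Taking 2-D Fourier transforms of the slice model

    i_k = f_k + Σ_{k'≠k} h_kk' * f_k'

turns the coupled convolutions into, at every spatial frequency (u, v), an
N×N linear system  I(u,v) = H(u,v) · F(u,v)  with a real symmetric system
matrix: unit diagonal, off-diagonal entries equal to the defocus transfer
value of the pillbox coupling the two slices.  Because the pillbox is
radially symmetric, H depends on (u, v) only through ρ = √(u² + v²), so
bins sharing a ρ share a pseudoinverse.

The layer spectra are recovered per frequency by the Moore–Penrose
pseudoinverse, F = H†·I — the minimal-norm least-squares solution.  At DC
(ρ = 0) every transfer value is 1, H is the singular all-ones matrix, and
H† = H/N² spreads the mean slice energy evenly over layers; singular
values below ``rcond·σ_max`` are truncated likewise at near-singular
low-frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from scipy.signal.windows import tukey

from .forward import BlurModel, blur_radius, defocus_transfer
from .stack import MultifocusStack

__all__ = [
    "LayerSpectra",
    "build_system_matrix",
    "solve_layer_spectra",
    "layers_to_images",
    "rho_grid",
]

#: default truncation of singular values relative to the largest
DEFAULT_RCOND = 1e-3


@dataclass
class LayerSpectra:
    """Per-layer complex spectra on the stack's DFT grid.

    ``F`` has shape (N, H, W) for grayscale input or (N, H, W, 3) for RGB,
    in standard (fftfreq) frequency ordering.  ``R0`` and ``currents_mA``
    are retained because viewpoint synthesis derives its per-layer phase
    ramps from them.
    """

    F: np.ndarray
    currents_mA: np.ndarray
    R0: float
    rcond: float = DEFAULT_RCOND

    @property
    def n_layers(self) -> int:
        return self.F.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.F.shape[1:3]


def rho_grid(shape: tuple[int, int]) -> np.ndarray:
    """Radial spatial frequency ρ (cycles/px) for an H×W DFT grid."""
    h, w = shape
    v = spfft.fftfreq(h)
    u = spfft.fftfreq(w)
    return np.hypot(v[:, None], u[None, :])


def build_system_matrix(rho: float, currents_mA: np.ndarray, blur: BlurModel) -> np.ndarray:
    """N×N defocus transfer matrix at radial frequency ``rho`` (cycles/px).

    Entry (k, k') is the transfer value of the pillbox of radius
    R0·|j_k − j_k'|; the diagonal is exactly 1.
    """
    currents = np.asarray(currents_mA, dtype=float)
    n = len(currents)
    H = np.eye(n)
    for k in range(n):
        for kp in range(k + 1, n):
            val = float(defocus_transfer(blur_radius(currents[k], currents[kp], blur), rho))
            H[k, kp] = H[kp, k] = val
    return H


def _group_matrices(
    rho_vals: np.ndarray, currents: np.ndarray, blur: BlurModel
) -> np.ndarray:
    """Stack of system matrices, one per value in ``rho_vals``."""
    n = len(currents)
    g = len(rho_vals)
    H = np.empty((g, n, n))
    H[:, np.arange(n), np.arange(n)] = 1.0
    cache: dict[float, np.ndarray] = {}
    for k in range(n):
        for kp in range(k + 1, n):
            r = blur_radius(currents[k], currents[kp], blur)
            if r not in cache:
                cache[r] = np.asarray(defocus_transfer(r, rho_vals))
            H[:, k, kp] = H[:, kp, k] = cache[r]
    return H


def _taper(slices: np.ndarray, alpha: float) -> np.ndarray:
    h, w = slices.shape[1:3]
    win = np.outer(tukey(h, alpha), tukey(w, alpha))
    if slices.ndim == 4:
        win = win[..., None]
    return slices * win


def solve_layer_spectra(
    stack: MultifocusStack,
    blur: BlurModel,
    rcond: float = DEFAULT_RCOND,
    method: str = "grouped",
    taper_alpha: float = 0.0,
    rho_decimals: int = 12,
) -> LayerSpectra:
    """Recover per-layer spectra by per-frequency pseudoinversion.

    Parameters
    ----------
    stack : MultifocusStack
        Registered stack (or a single slice, which needs no registration).
    blur : BlurModel
        Supplies the blur radii r_kk' = R0·|j_k − j_k'|.
    rcond : float
        Relative singular-value cutoff of the pseudoinverse.
    method : {"grouped", "naive"}
        "grouped" batches bins sharing a radial frequency (the matrices are
        identical); "naive" pseudoinverts every bin separately.  Both give
        the same result; "naive" exists as the brute-force reference.
    taper_alpha : float
        Tukey-window edge taper fraction applied to the slices before the
        transform (0 = off).  Reduces wrap-around ringing from the periodic
        convolution model at the cost of darkened borders; it is a
        deviation knob, not part of the inversion itself.
    rho_decimals : int
        Decimals ρ is rounded to when grouping bins.  At the default the
        grouping is exact (bins are merged only when their ρ coincide to
        machine precision), keeping "grouped" bit-compatible with "naive";
        coarser values trade accuracy for fewer pseudoinversions.
    """
    if method not in ("grouped", "naive"):
        raise ValueError(f"unknown method {method!r}")
    if not (stack.registered or stack.n_slices == 1):
        raise ValueError("stack must be registered before layer separation (or have N=1)")
    slices = np.asarray(stack.slices, dtype=float)
    if not np.all(np.isfinite(slices)):
        raise ValueError("stack contains non-finite intensities")
    if taper_alpha > 0:
        slices = _taper(slices, taper_alpha)

    n = stack.n_slices
    h, w = stack.shape
    currents = stack.currents_mA
    # channels last, then solve each channel on the (N, H*W) flattened grid
    chans = slices[..., None] if slices.ndim == 3 else slices
    I = spfft.fft2(chans, axes=(1, 2), workers=-1)
    rho = rho_grid((h, w)).ravel()

    F = np.empty_like(I)
    if method == "naive":
        I_flat = I.reshape(n, h * w, -1)
        F_flat = np.empty_like(I_flat)
        for b in range(h * w):
            Hp = np.linalg.pinv(build_system_matrix(rho[b], currents, blur), rcond=rcond)
            F_flat[:, b, :] = Hp @ I_flat[:, b, :]
        F = F_flat.reshape(I.shape)
    else:
        rho_q = np.round(rho, rho_decimals)
        uniq, inv = np.unique(rho_q, return_inverse=True)
        Hp = np.linalg.pinv(_group_matrices(uniq, currents, blur), rcond=rcond)
        I_flat = I.reshape(n, h * w, -1)
        F_flat = np.einsum("bij,jbc->ibc", Hp[inv], I_flat)
        F = F_flat.reshape(I.shape)

    if slices.ndim == 3:
        F = F[..., 0]
    return LayerSpectra(F=F, currents_mA=currents.copy(), R0=blur.R0, rcond=rcond)


def layers_to_images(spectra: LayerSpectra, imag_tol: float = 1e-3) -> np.ndarray:
    """Inverse-transform the layer spectra to real images.

    The imaginary residue of each inverse transform must be below
    ``imag_tol`` relative to the layer's peak magnitude (it is ~1e−13 for
    any spectra produced from real slices); a larger residue signals
    inconsistent input and raises.  Negative excursions are retained.
    """
    imgs = spfft.ifft2(spectra.F, axes=(1, 2), workers=-1)
    scale = np.max(np.abs(imgs))
    if scale > 0 and np.max(np.abs(imgs.imag)) > imag_tol * scale:
        raise ValueError(
            "inverse transform is not real: layer spectra violate Hermitian symmetry"
        )
    return imgs.real
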