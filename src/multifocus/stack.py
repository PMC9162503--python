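"""The multifocus stack container.

A multifocus (z-) stack is an ordered set of images of the same scene, each
acquired with a different EFTL control current and therefore focused on a
different plane.  Slices are stored as a single array of shape ``(N, H, W)``
for grayscale or ``(N, H, W, 3)`` for RGB, with one current per slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MultifocusStack"]


@dataclass
class MultifocusStack:
    """Ordered multifocus images with per-slice EFTL currents.

    Parameters
    ----------
    slices : ndarray, shape (N, H, W) or (N, H, W, 3)
        Non-negative intensity images sharing a pixel grid.
    currents_mA : array-like of float, length N
        EFTL control current of each slice, mA.
    pixel_pitch_um : float
        Sensor pixel pitch, µm.
    bit_depth : int
        Nominal bit depth of the acquisition (8 or 16); float pipelines keep
        it for export scaling only.
    registered : bool
        Whether field-of-view/energy registration has been applied.
    """

    slices: np.ndarray
    currents_mA: np.ndarray
    pixel_pitch_um: float = 5.5
    bit_depth: int = 8
    registered: bool = False

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        self.currents_mA = np.atleast_1d(np.asarray(self.currents_mA, dtype=float))
        if self.slices.ndim not in (3, 4):
            raise ValueError("slices must have shape (N, H, W) or (N, H, W, 3)")
        if self.slices.ndim == 4 and self.slices.shape[-1] != 3:
            raise ValueError("color stacks must have exactly 3 channels")
        if self.slices.shape[0] != self.currents_mA.shape[0]:
            raise ValueError(
                f"{self.slices.shape[0]} slices but {self.currents_mA.shape[0]} currents"
            )
        if self.n_slices < 1:
            raise ValueError("stack must contain at least one slice")
        if np.issubdtype(self.slices.dtype, np.floating) and not np.all(
            np.isfinite(self.slices)
        ):
            raise ValueError("slice intensities must be finite")
        if np.any(np.asarray(self.slices, dtype=float) < 0):
            raise ValueError("slice intensities must be non-negative")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of each slice."""
        return self.slices.shape[1:3]

    @property
    def is_rgb(self) -> bool:
        return self.slices.ndim == 4

    def slice_energies(self) -> np.ndarray:
        """Total intensity of each slice (channels summed for RGB)."""
        axes = tuple(range(1, self.slices.ndim))
        return np.asarray(self.slices, dtype=float).sum(axis=axes)

    def with_slices(self, slices: np.ndarray, *, registered: bool | None = None) -> "MultifocusStack":
        """Copy of the stack with new pixel data (and optionally a new flag)."""
        return replace(
            self,
            slices=slices,
            registered=self.registered if registered is None else registered,
        )
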