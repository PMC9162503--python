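"""Optics of a microscope with an electrically focus-tunable lens (EFTL).

An EFTL placed between the objective and the sensor shifts the conjugate
object plane without moving any mechanical part.  Driving the lens with a
control current ``j`` (mA) changes its optical power ``P`` (diopters)
approximately linearly; the combined objective+EFTL system then focuses at
an axial offset ``z`` from the objective's working-distance plane, with a
current-dependent lateral magnification ``M``.

All public functions accept the units stated in their docstrings
(mA, diopters, mm, cm, µm) and convert to SI internally.  The lateral
magnification is

    M(P) = P⁻¹·fMO⁻¹ + (D − P⁻¹)·feq⁻¹,

with ``feq⁻¹ = fMO⁻¹ + P − fMO⁻¹·P·d`` the equivalent focal power of the
objective/EFTL pair, and the focus shift is

    z(P) = −fMO·P·(D − P⁻¹) / M(P),

where ``fMO`` is the objective focal length, ``D`` the EFTL-to-sensor
distance and ``d`` the objective-to-EFTL distance.  ``P = 0`` makes
``P⁻¹`` singular and is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsConfig",
    "SingularPowerError",
    "current_to_power",
    "equivalent_power",
    "focus_shift",
    "lateral_magnification",
    "focusing_range",
    "current_sweep",
]


class SingularPowerError(ValueError):
    """Raised when the EFTL power makes the imaging geometry singular."""


@dataclass(frozen=True)
class OpticsConfig:
    """Constants of the objective + EFTL imaging geometry.

    Parameters
    ----------
    f_mo_mm : float
        Focal length of the microscope objective, mm.
    D_cm : float
        Distance from the EFTL to the camera sensor, cm.
    d_cm : float
        Distance from the objective's back principal plane to the EFTL, cm.
    power_calibration : ((float, float), (float, float))
        Two ``(current mA, power diopter)`` endpoint pairs; EFTL power is
        interpolated linearly through them.
    NA : float
        Numerical aperture of the objective.
    WD_mm : float
        Working distance of the objective, mm.
    pixel_pitch_um : float
        Sensor pixel pitch, µm.

    Defaults correspond to a 20×/0.5 NA water-immersion objective
    (fMO = 9 mm, WD = 3.5 mm), D ≈ 10 cm, d ≈ 5 cm and an EFTL spanning
    −2 to +3 diopters over −230 to +270 mA, on a 5.5 µm-pitch sensor.
    """

    f_mo_mm: float = 9.0
    D_cm: float = 10.0
    d_cm: float = 5.0
    power_calibration: tuple[tuple[float, float], tuple[float, float]] = (
        (270.0, 3.0),
        (-230.0, -2.0),
    )
    NA: float = 0.5
    WD_mm: float = 3.5
    pixel_pitch_um: float = 5.5

    def __post_init__(self) -> None:
        if not (self.f_mo_mm > 0 and self.D_cm > 0 and self.d_cm > 0):
            raise ValueError("f_mo_mm, D_cm and d_cm must all be positive")
        if not self.D_cm > self.d_cm:
            raise ValueError("EFTL-to-sensor distance D must exceed objective-to-EFTL distance d")
        (j1, _), (j2, _) = self.power_calibration
        if j1 == j2:
            raise ValueError("power calibration endpoints must have distinct currents")

    # SI accessors
    @property
    def f_mo(self) -> float:
        """Objective focal length in m."""
        return self.f_mo_mm * 1e-3

    @property
    def D(self) -> float:
        """EFTL-to-sensor distance in m."""
        return self.D_cm * 1e-2

    @property
    def d(self) -> float:
        """Objective-to-EFTL distance in m."""
        return self.d_cm * 1e-2


def current_to_power(j_mA: float, cfg: OpticsConfig = OpticsConfig()) -> float:
    """EFTL optical power (diopters) at control current ``j_mA`` (mA).

    Affine interpolation through the two calibration endpoints; currents
    outside the calibrated interval are extrapolated with a warning.
    """
    (j1, p1), (j2, p2) = cfg.power_calibration
    lo, hi = min(j1, j2), max(j1, j2)
    j_arr = np.asarray(j_mA, dtype=float)
    if np.any((j_arr < lo) | (j_arr > hi)):
        warnings.warn(
            f"current {j_mA} mA outside calibrated range [{lo}, {hi}] mA; extrapolating",
            stacklevel=2,
        )
    slope = (p2 - p1) / (j2 - j1)
    out = p1 + slope * (j_arr - j1)
    return float(out) if out.ndim == 0 else out


def equivalent_power(P: float, cfg: OpticsConfig = OpticsConfig()) -> float:
    """Equivalent focal power feq⁻¹ (m⁻¹) of the objective+EFTL doublet.

    feq⁻¹ = fMO⁻¹ + P − fMO⁻¹·P·d, with ``P`` the EFTL power in diopters.
    """
    inv_f = 1.0 / cfg.f_mo
    return inv_f + P - inv_f * P * cfg.d


def lateral_magnification(P: float, cfg: OpticsConfig = OpticsConfig()) -> float:
    """Lateral magnification M at EFTL power ``P`` (diopters).

    ``P = 0`` is singular (the EFTL degenerates to a flat plate in this
    parametrization) and raises :class:`SingularPowerError`.
    """
    if P == 0:
        raise SingularPowerError("P = 0 diopters is outside the valid domain (1/P singular)")
    inv_P = 1.0 / P
    return inv_P / cfg.f_mo + (cfg.D - inv_P) * equivalent_power(P, cfg)


def focus_shift(P: float, cfg: OpticsConfig = OpticsConfig()) -> float:
    """Axial focus shift z (µm) from the working-distance plane at power ``P``.

    z = −fMO·P·(D − P⁻¹) / M(P).  Raises :class:`SingularPowerError` at
    P = 0 or where M(P) vanishes.
    """
    M = lateral_magnification(P, cfg)
    if abs(M) < 1e-12:
        raise SingularPowerError(f"magnification vanishes at P = {P} diopters; z undefined")
    z_m = -cfg.f_mo * P * (cfg.D - 1.0 / P) / M
    return z_m * 1e6


def focusing_range(cfg: OpticsConfig = OpticsConfig()) -> tuple[float, float, float]:
    """Focus shifts (µm) at the two calibrated power endpoints and their span.

    Returns ``(z_min, z_max, range)`` with ``range = z_max − z_min``.
    """
    (_, p1), (_, p2) = cfg.power_calibration
    z1 = focus_shift(p1, cfg)
    z2 = focus_shift(p2, cfg)
    z_min, z_max = sorted((z1, z2))
    return z_min, z_max, z_max - z_min


def current_sweep(start_mA: float, stop_mA: float, step_mA: float) -> np.ndarray:
    """Inclusive arithmetic sweep of EFTL control currents (mA).

    ``current_sweep(265, 125, -10)`` yields the 15 currents
    265, 255, …, 125.
    """
    if step_mA == 0:
        raise ValueError("step must be nonzero")
    n = int(np.floor((stop_mA - start_mA) / step_mA + 1e-9)) + 1
    if n < 1:
        raise ValueError("step direction does not reach stop from start")
    return start_mA + step_mA * np.arange(n, dtype=float)
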