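"""Ratiometric fura-2 calibration and dye-loading tracking.

Implements the standard two-wavelength calibration

    [Ca2+]i = Kd_eff * (R - Rmin) / (Rmax - R)

where ``R = F340/F380`` is the background-corrected excitation ratio,
``Rmin``/``Rmax`` are the ratios at zero and saturating Ca2+, and
``Kd_eff = Kd_fura * F380,min/F380,max`` folds the indicator's dynamic
range at 380 nm into an effective, rig-specific dissociation constant.
``Kd_eff`` can equivalently be measured from a solution of defined free
Ca2+ (``effective_kd``), which avoids measuring the 380-nm dynamic range
directly.

The isosbestic excitation (360 nm) is Ca2+-independent, so F360 tracks the
intracellular dye concentration during whole-cell loading; the loading
curve is fit with a saturating mono-exponential ``c(t) =
c_inf * (1 - exp(-t/tau_fill))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RatioTrace",
    "CalibrationResult",
    "LoadingCurve",
    "CalibrationRangeError",
    "SaturationError",
    "effective_kd",
    "ratio_to_ca",
    "ca_to_ratio",
    "fura_from_isosbestic",
    "fit_loading_curve",
]


class CalibrationRangeError(ValueError):
    """A ratio lies outside the calibrated (Rmin, Rmax) interval."""


class SaturationError(CalibrationRangeError):
    """A ratio at or above Rmax: the indicator is saturated."""


@dataclass
class RatioTrace:
    """Background-corrected fluorescence time series for one cell.

    ``time_s`` must be strictly increasing; ``f340``/``f380`` (and the
    optional isosbestic ``f360``) are ADU arrays of equal length.  The
    ratio is defined only where F380 > 0 (NaN elsewhere).
    """

    time_s: np.ndarray
    f340: np.ndarray
    f380: np.ndarray
    f360: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f340 = np.asarray(self.f340, dtype=float)
        self.f380 = np.asarray(self.f380, dtype=float)
        if self.f360 is not None:
            self.f360 = np.asarray(self.f360, dtype=float)
        n = self.time_s.size
        lengths = {n, self.f340.size, self.f380.size}
        if self.f360 is not None:
            lengths.add(self.f360.size)
        if len(lengths) != 1:
            raise ValueError("time and fluorescence channels must have equal length")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def ratio(self) -> np.ndarray:
        """F340/F380, NaN where F380 <= 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.f380 > 0, self.f340 / self.f380, np.nan)
        return r

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class CalibrationResult:
    """Rig-specific fura-2 calibration.

    ``kd_fura_uM`` is the chemical dissociation constant of the dye (used
    for Ca2+-binding-ratio arithmetic); ``kd_eff_uM = kd_fura_uM *
    dynamic_range`` is the effective constant entering the ratio equation.
    """

    r_min: float
    r_max: float
    kd_fura_uM: float
    dynamic_range: float  # F380,min / F380,max

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("require r_min < r_max")
        if min(self.r_min, self.kd_fura_uM, self.dynamic_range) <= 0:
            raise ValueError("calibration parameters must be positive")

    @property
    def kd_eff_uM(self) -> float:
        return self.kd_fura_uM * self.dynamic_range

    @classmethod
    def from_kd_eff(
        cls, r_min: float, r_max: float, kd_fura_uM: float, kd_eff_uM: float
    ) -> "CalibrationResult":
        """Build from a directly measured effective Kd."""
        return cls(r_min, r_max, kd_fura_uM, kd_eff_uM / kd_fura_uM)


def effective_kd(r_def: float, r_min: float, r_max: float, ca_def_uM: float) -> float:
    """Effective dissociation constant (uM) from a defined-Ca2+ solution.

    ``Kd_eff = [Ca2+]_def * (Rmax - R_def) / (R_def - Rmin)`` — the ratio
    equation solved for its constant, using the ratio ``r_def`` measured in
    a solution of known free Ca2+ ``ca_def_uM``.  Independent of dye
    concentration and specific to each optical setup.
    """
    if ca_def_uM <= 0:
        raise ValueError("defined free Ca2+ must be positive")
    if not r_min < r_def < r_max:
        raise CalibrationRangeError(
            f"R_def={r_def} outside calibration interval ({r_min}, {r_max})"
        )
    return ca_def_uM * (r_max - r_def) / (r_def - r_min)


def ratio_to_ca(r, cal: CalibrationResult):
    """Convert fluorescence ratio(s) to free Ca2+ in nM.

    ``[Ca2+] = Kd_eff * (R - Rmin) / (Rmax - R)``.  Ratios slightly below
    Rmin (noise) are clipped to 0 nM with a warning so resting-level
    estimates stay robust; ratios at or above Rmax raise
    :class:`SaturationError`.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r >= cal.r_max):
        raise SaturationError(
            f"ratio >= Rmax={cal.r_max}: indicator saturated, Ca2+ undefined"
        )
    below = r < cal.r_min
    if np.any(below):
        warnings.warn(
            f"{int(np.count_nonzero(below))} ratio sample(s) below Rmin "
            f"clipped to 0 nM",
            stacklevel=2,
        )
    ca_uM = cal.kd_eff_uM * np.clip(r - cal.r_min, 0.0, None) / (cal.r_max - r)
    ca_nM = ca_uM * 1e3
    return float(ca_nM) if np.ndim(ca_nM) == 0 else ca_nM


def ca_to_ratio(ca_nM, cal: CalibrationResult):
    """Inverse of :func:`ratio_to_ca`: free Ca2+ (nM) to fluorescence ratio.

    ``R = (Rmin*Kd_eff + Ca*Rmax) / (Kd_eff + Ca)``; maps [0, inf) onto
    [Rmin, Rmax).
    """
    ca_uM = np.asarray(ca_nM, dtype=float) * 1e-3
    if np.any(ca_uM < 0):
        raise ValueError("Ca2+ concentration must be non-negative")
    r = (cal.r_min * cal.kd_eff_uM + ca_uM * cal.r_max) / (cal.kd_eff_uM + ca_uM)
    return float(r) if np.ndim(r) == 0 else r


def fura_from_isosbestic(f360, cell_scale: float):
    """Convert isosbestic-wavelength fluorescence (ADU) to fura-2 (uM).

    F360 is Ca2+-independent, so concentration = F360 / cell_scale, where
    ``cell_scale`` (ADU per uM) is obtained by imaging the pipette solution
    of known dye concentration under identical optics.
    """
    if cell_scale <= 0:
        raise ValueError("cell_scale must be positive (ADU per uM)")
    c = np.asarray(f360, dtype=float) / cell_scale
    return float(c) if np.ndim(c) == 0 else c


@dataclass
class LoadingCurve:
    """Whole-cell dye-loading curve and its saturating-exponential fit."""

    time_s: np.ndarray
    fura_uM: np.ndarray
    c_inf_uM: float = np.nan       # fitted asymptote
    tau_fill_s: float = np.nan     # fill time constant
    rms_uM: float = np.nan
    ok: bool = False
    flag: str = ""
    _pcov: np.ndarray | None = field(default=None, repr=False)

    def concentration_at(self, t) -> np.ndarray:
        """Fitted dye concentration at time(s) t (uM)."""
        if not self.ok:
            raise RuntimeError(f"loading-curve fit not available: {self.flag}")
        c = self.c_inf_uM * (1.0 - np.exp(-np.asarray(t, float) / self.tau_fill_s))
        return float(c) if np.ndim(c) == 0 else c


def fit_loading_curve(time_s, fura_uM) -> LoadingCurve:
    """Fit ``c(t) = c_inf * (1 - exp(-t/tau_fill))`` to loading samples.

    Requires at least 4 points.  Degenerate data (flat or non-saturating in
    a way the model cannot represent) is flagged and the raw points are
    preserved with ``ok=False``.
    """
    t = np.asarray(time_s, dtype=float)
    c = np.asarray(fura_uM, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 loading samples")
    if np.any(c < 0):
        raise ValueError("dye concentrations must be non-negative")

    out = LoadingCurve(time_s=t, fura_uM=c)
    spread = np.ptp(c)
    if spread <= 0 or np.isclose(spread, 0.0, atol=1e-12 * max(c.max(), 1.0)):
        out.flag = "degenerate: constant samples (tau_fill -> 0 branch)"
        return out

    def model(tt, c_inf, tau):
        return c_inf * (1.0 - np.exp(-tt / tau))

    t_span = t[-1] - t[0] if t.size > 1 else 1.0
    p0 = (max(c.max(), 1e-9), max(t_span / 3.0, 1e-6))
    try:
        popt, pcov = curve_fit(
            model, t, c, p0=p0, bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=10000
        )
    except RuntimeError:
        out.flag = "fit failure: no convergence"
        return out

    resid = c - model(t, *popt)
    out.c_inf_uM = float(popt[0])
    out.tau_fill_s = float(popt[1])
    out.rms_uM = float(np.sqrt(np.mean(resid ** 2)))
    out.ok = True
    out._pcov = pcov
    return out
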