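"""The added-buffer estimation of endogenous Ca2+ handling.

A neuron's cytosolic Ca2+ transients are shaped by its endogenous buffers
(incremental binding ratio ``kappa_S``) and a lumped linear extrusion rate
``gamma``.  Loading the cell with increasing amounts of a known exogenous
buffer — the indicator dye itself, with binding ratio

    kappa_B = [B_total] * Kd_B / ([Ca2+]_rest + Kd_B)^2

slows the decay of evoked transients according to the linear
single-compartment model

    tau_transient = (1 + kappa_B + kappa_S) / gamma .

An ordinary least-squares fit of ``tau_transient`` against ``kappa_B``
therefore yields the endogenous parameters by extrapolation to zero added
buffer: the negative x-intercept is ``1 + kappa_S``, the slope is
``1/gamma`` and the y-intercept is the endogenous decay time constant
``tau_endo = (1 + kappa_S)/gamma``.

Uncertainty is quantified by fixed-x (residual) bootstrap resampling of the
linear fit, and cohorts are compared by unpaired t-tests on the
log-transformed bootstrap distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import curve_fit

from .fura_calibration import CalibrationResult, RatioTrace, fura_from_isosbestic, ratio_to_ca

__all__ = [
    "TransientFit",
    "KappaTauPoint",
    "BufferFitResult",
    "BootstrapResult",
    "ComparisonResult",
    "LoadingExperiment",
    "DegenerateFitError",
    "MissingIsosbesticError",
    "kappa_b",
    "fit_transient_decay",
    "collect_kappa_tau",
    "fit_added_buffer",
    "bootstrap_added_buffer",
    "compare_parameter_distributions",
]

#: transient acceptance window for the decay time constant, seconds
TAU_BOUNDS = (0.05, 60.0)
#: accepted transients must have relative fit RMS below this fraction of amplitude
MAX_RELATIVE_RMS = 0.20
#: pre-stimulus window used for resting-level estimation, seconds
BASELINE_SPAN_S = 5.0


class DegenerateFitError(RuntimeError):
    """Non-physical added-buffer fit (slope <= 0); carries raw coefficients."""

    def __init__(self, message: str, beta0: float, beta1: float):
        super().__init__(message)
        self.beta0 = beta0
        self.beta1 = beta1


class MissingIsosbesticError(ValueError):
    """kappa_B cannot be computed without an isosbestic (F360) channel."""


def kappa_b(fura_total_uM: float, kd_fura_uM: float, ca_rest_uM: float) -> float:
    """Incremental Ca2+-binding ratio of the dye at rest (dimensionless).

    ``kappa_B = d[BCa]/d[Ca] = B_T * Kd / (Ca_rest + Kd)^2`` evaluated at
    the resting free Ca2+.  All concentrations in uM.
    """
    if fura_total_uM < 0:
        raise ValueError("total dye concentration must be non-negative")
    if kd_fura_uM <= 0 or ca_rest_uM < 0:
        raise ValueError("Kd must be positive and resting Ca2+ non-negative")
    return fura_total_uM * kd_fura_uM / (ca_rest_uM + kd_fura_uM) ** 2


# --------------------------------------------------------------------------
# transient decay fitting
# --------------------------------------------------------------------------

@dataclass
class TransientFit:
    """Mono-exponential decay fit of one evoked Ca2+ transient."""

    t_onset_s: float
    amplitude_nM: float = np.nan
    tau_s: float = np.nan
    baseline_nM: float = np.nan
    rms_nM: float = np.nan
    accepted: bool = False
    reason: str = ""


def fit_transient_decay(
    time_s: np.ndarray,
    ca_nM: np.ndarray,
    t_onset: float | None = None,
) -> TransientFit:
    """Fit ``Ca(t) = baseline + A * exp(-(t - t_peak)/tau)`` after the peak.

    The segment should contain the stimulus-aligned peak followed by enough
    decay (>= 2 expected tau).  Acceptance requires the relative fit RMS to
    stay below 20 % of the amplitude and tau within [0.05, 60] s; anything
    else is returned flagged and excluded downstream.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(ca_nM, dtype=float)
    if t.size != y.size or t.size < 5:
        raise ValueError("need matched time/Ca arrays with >= 5 samples")
    onset = float(t[0]) if t_onset is None else float(t_onset)
    fit = TransientFit(t_onset_s=onset)

    i_peak = int(np.argmax(y))
    baseline0 = float(np.median(y[-max(t.size // 5, 3):]))
    amp0 = float(y[i_peak] - baseline0)
    if amp0 <= 0 or not np.isfinite(amp0):
        fit.reason = "no peak above baseline (amplitude ~ 0)"
        return fit

    td = t[i_peak:] - t[i_peak]
    yd = y[i_peak:]
    if td.size < 4:
        fit.reason = "too few decay samples after peak"
        return fit

    span = max(td[-1], 1e-6)

    def model(tt, baseline, amp, tau):
        return baseline + amp * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model,
            td,
            yd,
            p0=(baseline0, amp0, max(span / 4.0, TAU_BOUNDS[0])),
            bounds=([-np.inf, 0.0, TAU_BOUNDS[0] / 10], [np.inf, np.inf, TAU_BOUNDS[1] * 10]),
            maxfev=10000,
        )
    except RuntimeError:
        fit.reason = "fit divergence"
        return fit

    baseline, amp, tau = (float(v) for v in popt)
    rms = float(np.sqrt(np.mean((yd - model(td, *popt)) ** 2)))
    fit.baseline_nM, fit.amplitude_nM, fit.tau_s, fit.rms_nM = baseline, amp, tau, rms

    if not TAU_BOUNDS[0] <= tau <= TAU_BOUNDS[1]:
        fit.reason = f"tau={tau:.3g} s outside {TAU_BOUNDS}"
    elif amp <= 0:
        fit.reason = "non-positive amplitude"
    elif rms > MAX_RELATIVE_RMS * amp:
        fit.reason = f"relative RMS {rms / amp:.2f} exceeds {MAX_RELATIVE_RMS}"
    else:
        fit.accepted = True
    return fit


# --------------------------------------------------------------------------
# assembling (kappa_B, tau) points from a loading experiment
# --------------------------------------------------------------------------

@dataclass
class KappaTauPoint:
    """One accepted transient: dye binding ratio vs decay time constant."""

    kappa_b: float
    tau_s: float
    cell_id: str = ""
    cohort: str = ""


@dataclass
class LoadingExperiment:
    """A whole-cell fura-2 loading experiment for one neuron.

    ``trace`` must carry the isosbestic channel (F360) so the dye
    concentration at each stimulus can be estimated; ``cell_scale`` converts
    F360 ADUs to uM (see :func:`cabuffer.fura_calibration.fura_from_isosbestic`).
    """

    trace: RatioTrace
    stim_times_s: np.ndarray
    cell_scale: float
    cell_id: str = ""
    cohort: str = ""

    def __post_init__(self) -> None:
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)


def collect_kappa_tau(
    cell: LoadingExperiment,
    cal: CalibrationResult,
    baseline_span_s: float = BASELINE_SPAN_S,
    fit_window_s: float | None = None,
) -> tuple[list[KappaTauPoint], list[TransientFit]]:
    """Extract one (kappa_B, tau_transient) point per accepted transient.

    For each stimulus the resting Ca2+ is taken from the mean ratio over
    the pre-stimulus baseline, the dye concentration from the mean F360
    over the same window, and the decay time constant from a
    mono-exponential fit of the post-stimulus Ca2+ segment.  kappa_B uses
    the chemical ``Kd_fura``, not the effective constant of the ratio
    equation.

    Returns the accepted points and the full list of per-transient fits
    (including rejected ones, flagged).
    """
    trace = cell.trace
    if trace.f360 is None:
        raise MissingIsosbesticError(
            "loading experiment lacks an isosbestic (F360) channel; "
            "kappa_B cannot be computed"
        )
    t = trace.time_s
    ratio = trace.ratio
    stims = np.sort(cell.stim_times_s)

    points: list[KappaTauPoint] = []
    fits: list[TransientFit] = []
    for i, t0 in enumerate(stims):
        base_mask = (t >= t0 - baseline_span_s) & (t < t0)
        if not np.any(base_mask):
            continue
        r_rest = float(np.nanmean(ratio[base_mask]))
        ca_rest_nM = ratio_to_ca(r_rest, cal)
        # dye keeps loading through the baseline window: extrapolate the
        # isosbestic signal linearly to the stimulus onset
        f360_base = fura_from_isosbestic(trace.f360[base_mask], cell.cell_scale)
        tb = t[base_mask] - t0
        if tb.size >= 2 and np.ptp(tb) > 0:
            fura_uM = float(np.polyval(np.polyfit(tb, f360_base, 1), 0.0))
        else:
            fura_uM = float(np.mean(f360_base))
        kb = kappa_b(fura_uM, cal.kd_fura_uM, ca_rest_nM * 1e-3)

        t_end = stims[i + 1] - baseline_span_s if i + 1 < stims.size else t[-1]
        if fit_window_s is not None:
            t_end = min(t_end, t0 + fit_window_s)
        seg = (t >= t0) & (t <= t_end)
        if np.count_nonzero(seg) < 5:
            continue
        ca_seg = ratio_to_ca(ratio[seg], cal)
        fit = fit_transient_decay(t[seg], ca_seg, t_onset=t0)
        fits.append(fit)
        if fit.accepted:
            points.append(
                KappaTauPoint(kappa_b=kb, tau_s=fit.tau_s, cell_id=cell.cell_id, cohort=cell.cohort)
            )
    return points, fits


# --------------------------------------------------------------------------
# the linear added-buffer fit
# --------------------------------------------------------------------------

@dataclass
class BufferFitResult:
    """OLS fit of tau_transient against kappa_B and the derived parameters.

    ``kappa_s = beta0/beta1 - 1`` (negative x-intercept minus one),
    ``gamma_per_s = 1/beta1`` and ``tau_endo_s = beta0``; the internal
    identity ``tau_endo = (1 + kappa_s)/gamma`` holds exactly by
    construction.
    """

    kappa_s: float
    gamma_per_s: float
    tau_endo_s: float
    beta0: float
    beta1: float
    n_points: int
    low_n: bool = False
    points: list[KappaTauPoint] = field(default_factory=list, repr=False)
    _sm_result: object | None = field(default=None, repr=False)

    @property
    def slope_s(self) -> float:
        return self.beta1

    @property
    def x_intercept(self) -> float:
        return -(1.0 + self.kappa_s)

    def confidence_band(self, kappa_grid, alpha: float = 0.05):
        """Pointwise 95 % (or 1-alpha) confidence band of the fitted line."""
        if self._sm_result is None:
            raise RuntimeError("confidence band unavailable (exact low-n fit)")
        x = np.asarray(kappa_grid, dtype=float)
        design = sm.add_constant(x, has_constant="add")
        pred = self._sm_result.get_prediction(design)
        ci = pred.conf_int(alpha=alpha)
        return ci[:, 0], ci[:, 1]


def fit_added_buffer(points: list[KappaTauPoint]) -> BufferFitResult:
    """Unweighted OLS of ``tau = beta0 + beta1 * kappa_B`` over the points.

    Requires at least 2 points with spread in kappa_B (2 points give the
    exact interpolating line, flagged ``low_n``; >= 3 are needed for any
    uncertainty statement).  A non-positive slope is non-physical and
    raises :class:`DegenerateFitError` carrying the raw coefficients.
    """
    if len(points) < 2:
        raise ValueError(f"need >= 2 (kappa_B, tau) points, got {len(points)}")
    x = np.array([p.kappa_b for p in points], dtype=float)
    y = np.array([p.tau_s for p in points], dtype=float)
    if np.ptp(x) <= 0:
        raise ValueError("kappa_B values have zero spread; line is unidentifiable")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    beta0, beta1 = (float(b) for b in res.params)

    if beta1 <= 0:
        raise DegenerateFitError(
            f"non-physical added-buffer fit: slope {beta1:.4g} <= 0", beta0, beta1
        )
    return BufferFitResult(
        kappa_s=beta0 / beta1 - 1.0,
        gamma_per_s=1.0 / beta1,
        tau_endo_s=beta0,
        beta0=beta0,
        beta1=beta1,
        n_points=len(points),
        low_n=len(points) < 3,
        points=list(points),
        _sm_result=res if len(points) >= 3 else None,
    )


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Fixed-x bootstrap distributions of the added-buffer parameters."""

    kappa_s: np.ndarray
    gamma_per_s: np.ndarray
    tau_endo_s: np.ndarray
    n_invalid: int
    n_boot: int
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "kappa_s_mean": float(np.mean(self.kappa_s)),
            "kappa_s_sd": float(np.std(self.kappa_s, ddof=1)) if self.kappa_s.size > 1 else 0.0,
            "gamma_mean": float(np.mean(self.gamma_per_s)),
            "gamma_sd": float(np.std(self.gamma_per_s, ddof=1)) if self.gamma_per_s.size > 1 else 0.0,
            "n_valid": int(self.kappa_s.size),
            "n_invalid": int(self.n_invalid),
        }


def bootstrap_added_buffer(
    points: list[KappaTauPoint],
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> BootstrapResult:
    """Fixed-x (residual) bootstrap of the added-buffer linear fit.

    The kappa_B design is kept fixed; fitted residuals are resampled with
    replacement onto the fitted values and the line refit, giving ``n_boot``
    parameter triples.  Replicates with non-positive slope are recorded as
    invalid and excluded.  Reproducible for a fixed seed.
    """
    base = fit_added_buffer(points)
    x = np.array([p.kappa_b for p in points], dtype=float)
    y = np.array([p.tau_s for p in points], dtype=float)
    design = np.column_stack([np.ones_like(x), x])
    fitted = design @ (base.beta0, base.beta1)
    resid = y - fitted

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, resid.size, size=(n_boot, resid.size))
    y_star = fitted[None, :] + resid[idx]

    # hat projector for the fixed design: beta* = P @ y*
    projector = np.linalg.pinv(design)          # (2, n)
    betas = y_star @ projector.T                # (n_boot, 2)
    beta0s, beta1s = betas[:, 0], betas[:, 1]

    valid = beta1s > 0
    n_invalid = int(np.count_nonzero(~valid))
    beta0s, beta1s = beta0s[valid], beta1s[valid]
    return BootstrapResult(
        kappa_s=beta0s / beta1s - 1.0,
        gamma_per_s=1.0 / beta1s,
        tau_endo_s=beta0s.copy(),
        n_invalid=n_invalid,
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
    )


# --------------------------------------------------------------------------
# cohort comparison on log-transformed bootstrap distributions
# --------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Unpaired t-test on natural-log-transformed parameter distributions."""

    t_statistic: float
    p_value: float
    log_mean_a: float
    log_mean_b: float
    log_sd_a: float
    log_sd_b: float

    @property
    def geometric_mean_a(self) -> float:
        return float(np.exp(self.log_mean_a))

    @property
    def geometric_mean_b(self) -> float:
        return float(np.exp(self.log_mean_b))


def compare_parameter_distributions(dist_a, dist_b) -> ComparisonResult:
    """Compare two positive parameter distributions on the log scale.

    Both samples are natural-log transformed (bringing bootstrap
    distributions closer to Gaussian) and compared with a two-sided
    unpaired t-test.  Back-transformed (geometric) means are reported.
    Scaling both distributions by a common factor shifts both log-means
    equally and leaves the t statistic unchanged.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    for name, arr in (("dist_a", a), ("dist_b", b)):
        bad = np.flatnonzero(~(arr > 0))
        if bad.size:
            raise ValueError(
                f"{name} contains non-positive values at indices {bad[:10].tolist()}"
                f"{'...' if bad.size > 10 else ''}; cannot log-transform"
            )
    la, lb = np.log(a), np.log(b)
    t_stat, p = stats.ttest_ind(la, lb, equal_var=False)
    if np.isnan(t_stat) and np.allclose(la.mean(), lb.mean()):
        t_stat, p = 0.0, 1.0  # two identical zero-variance samples
    return ComparisonResult(
        t_statistic=float(t_stat),
        p_value=float(p),
        log_mean_a=float(la.mean()),
        log_mean_b=float(lb.mean()),
        log_sd_a=float(la.std(ddof=1)) if la.size > 1 else 0.0,
        log_sd_b=float(lb.std(ddof=1)) if lb.size > 1 else 0.0,
    )
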