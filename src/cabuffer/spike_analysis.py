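"""Activity and excitability metrics from current-clamp recordings.

Covers spike detection from voltage traces, spontaneous-activity
classification (a neuron firing below 0.5 Hz counts as not spontaneously
active, NSAN), instantaneous-frequency series, spike-frequency-adaptation
(SFA) fitting with the mono-exponential

    Y(T) = (Y0 - Plateau) * exp(-K * T) + Plateau

where ``Y0`` is fixed to the first instantaneous frequency of the 10-s
depolarising stimulus, ``Plateau`` the asymptotic frequency and ``K`` the
inverse adaptation time constant.  The SFA ratio is defined as
``Y0/Plateau`` (1 means no adaptation; above 3 counts as strong
adaptation; the plateau of a cell that effectively stops firing maps the
ratio to +inf).  Threshold currents are read off ascending current ramps
and F-I curves from families of current steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SpikeTrain",
    "SFAFit",
    "ExcitabilityResult",
    "NSAN_RATE_HZ",
    "STRONG_SFA_RATIO",
    "detect_spikes",
    "classify_activity",
    "instantaneous_frequency",
    "fit_sfa",
    "threshold_current_from_ramp",
    "fi_curve",
]

#: spontaneous-activity cut-off: mean rate below this is NSAN (strict)
NSAN_RATE_HZ = 0.5
#: SFA ratio above this counts as strong adaptation
STRONG_SFA_RATIO = 3.0

DEFAULT_SPIKE_THRESHOLD_MV = -20.0
DEFAULT_REFRACTORY_S = 0.002


@dataclass
class SpikeTrain:
    """Spike times for one recording epoch.

    ``times_s`` strictly increasing within [0, duration); ``rate_hz`` is
    count/duration over the full epoch.
    """

    times_s: np.ndarray
    duration_s: float
    baseline_mV: float = np.nan

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.times_s.size:
            if np.any(np.diff(self.times_s) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times_s[0] < 0 or self.times_s[-1] >= self.duration_s:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    @property
    def rate_hz(self) -> float:
        return self.n_spikes / self.duration_s


def detect_spikes(
    time_s,
    voltage_mV,
    threshold_mV: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings with a refractory period.

    Deterministic: a spike is the first sample at or above threshold whose
    predecessor is below it; crossings within ``refractory_s`` of the
    previous accepted spike are discarded.  The membrane-potential baseline
    is the median of the subthreshold samples.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(voltage_mV, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("need matched time/voltage arrays with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")

    above = v >= threshold_mV
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spike_times: list[float] = []
    last = -np.inf
    for i in crossings:
        if t[i] - last >= refractory_s:
            spike_times.append(t[i])
            last = t[i]

    sub = v[v < threshold_mV]
    baseline = float(np.median(sub)) if sub.size else np.nan
    duration = float(t[-1] - t[0]) + float(np.median(np.diff(t)))
    return SpikeTrain(
        times_s=np.asarray(spike_times) - t[0], duration_s=duration, baseline_mV=baseline
    )


def classify_activity(train: SpikeTrain) -> str:
    """Classify a train as ``"NSAN"`` (mean rate < 0.5 Hz, strict) or ``"SAN"``."""
    return "NSAN" if train.rate_hz < NSAN_RATE_HZ else "SAN"


def instantaneous_frequency(train: SpikeTrain) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous frequency series ``f_i = 1/ISI_i``.

    Each frequency is timestamped at the second spike of its interval.
    Fewer than two spikes give an empty series.
    """
    if train.n_spikes < 2:
        return np.empty(0), np.empty(0)
    isi = np.diff(train.times_s)
    return train.times_s[1:].copy(), 1.0 / isi


@dataclass
class SFAFit:
    """Mono-exponential spike-frequency-adaptation fit for one 10-s train."""

    y0_hz: float
    plateau_hz: float
    k_per_s: float
    sfa_ratio: float
    n_spikes: int
    k_identifiable: bool = True
    ceased_firing: bool = False


#: plateau at or below this is treated as "cell effectively ceases firing"
_PLATEAU_FLOOR_HZ = 0.1


def fit_sfa(
    time_s,
    freq_hz,
    y0_hz: float | None = None,
    n_spikes: int | None = None,
) -> SFAFit:
    """Fit ``Y = (Y0 - Plateau)*exp(-K*T) + Plateau`` with Y0 held fixed.

    ``time_s``/``freq_hz`` is the instantaneous-frequency series measured
    from stimulus onset; ``y0_hz`` defaults to the first instantaneous
    frequency.  Because Y0 is the frequency *at* the first sample, the
    exponential is anchored there (T is shifted so the first sample sits at
    T = 0); otherwise a fixed Y0 is inconsistent with the decay law it is
    read from.  Least squares runs over (Plateau, K) only.  A flat series
    leaves K unidentifiable (flagged) with Plateau at the mean; a plateau
    below 0.1 Hz reports the SFA ratio as +inf with the ``ceased_firing``
    flag.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(freq_hz, dtype=float)
    if t.size != f.size or t.size < 3:
        raise ValueError("need matched time/frequency arrays with >= 3 samples")
    t = t - t[0]
    y0 = float(f[0]) if y0_hz is None else float(y0_hz)
    count = int(n_spikes) if n_spikes is not None else int(f.size + 1)

    if np.ptp(f) < 1e-9 * max(abs(y0), 1.0):
        plateau = float(np.mean(f))
        return SFAFit(
            y0_hz=y0,
            plateau_hz=plateau,
            k_per_s=np.nan,
            sfa_ratio=y0 / plateau if plateau > _PLATEAU_FLOOR_HZ else np.inf,
            n_spikes=count,
            k_identifiable=False,
            ceased_firing=plateau <= _PLATEAU_FLOOR_HZ,
        )

    def model(tt, plateau, k):
        return (y0 - plateau) * np.exp(-k * tt) + plateau

    span = max(t[-1] - t[0], 1e-6)
    p0 = (max(float(f[-1]), 1e-3), 1.0 / span)
    popt, _ = curve_fit(
        model, t, f, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000
    )
    plateau, k = float(popt[0]), float(popt[1])
    ceased = plateau <= _PLATEAU_FLOOR_HZ
    ratio = np.inf if ceased else y0 / plateau
    return SFAFit(
        y0_hz=y0,
        plateau_hz=plateau,
        k_per_s=k,
        sfa_ratio=ratio,
        n_spikes=count,
        ceased_firing=ceased,
    )


@dataclass
class ExcitabilityResult:
    """Ramp threshold current and F-I relation for one neuron."""

    i_threshold_pA: float | None = None
    fi_pairs: list[tuple[float, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def has_threshold(self) -> bool:
        return self.i_threshold_pA is not None

    def fi_slope(self) -> float:
        """Least-squares gain (spikes per pA) over the suprathreshold part."""
        pairs = [(i, n) for i, n in self.fi_pairs if n > 0]
        if len(pairs) < 2:
            return np.nan
        x = np.array([p[0] for p in pairs], float)
        y = np.array([p[1] for p in pairs], float)
        return float(np.polyfit(x, y, 1)[0])


def threshold_current_from_ramp(
    time_s,
    voltage_mV,
    current_pA,
    threshold_mV: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> float | None:
    """Injected current (pA) at the first spike of an ascending ramp.

    Returns None when the ramp elicits no spike (no-threshold flag).
    """
    t = np.asarray(time_s, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if np.any(np.diff(i) < 0):
        raise ValueError("ramp current must be monotonically increasing")
    train = detect_spikes(t, voltage_mV, threshold_mV, refractory_s)
    if train.n_spikes == 0:
        return None
    first = train.times_s[0] + t[0]
    return float(np.interp(first, t, i))


def fi_curve(
    step_responses: list[tuple[float, tuple[np.ndarray, np.ndarray]]],
    threshold_mV: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_s: float = DEFAULT_REFRACTORY_S,
) -> ExcitabilityResult:
    """AP count per current step, sorted by injected current.

    ``step_responses`` is a list of ``(current_pA, (time_s, voltage_mV))``
    with at least two distinct currents; responses at duplicated currents
    are averaged with a note.
    """
    if len({round(i, 9) for i, _ in step_responses}) < 2:
        raise ValueError("need >= 2 distinct step currents")
    counts: dict[float, list[int]] = {}
    for current, (t, v) in step_responses:
        train = detect_spikes(t, v, threshold_mV, refractory_s)
        counts.setdefault(float(current), []).append(train.n_spikes)

    result = ExcitabilityResult()
    for current in sorted(counts):
        vals = counts[current]
        if len(vals) > 1:
            result.notes.append(
                f"{len(vals)} repeats at {current} pA averaged (counts {vals})"
            )
        result.fi_pairs.append((current, int(round(float(np.mean(vals))))))
    return result
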