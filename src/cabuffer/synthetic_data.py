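"""Forward simulation of every input the analysis pipeline consumes.

The generator produces synthetic recordings with stored ground truth so the
whole pipeline is verifiable by parameter recovery:

* whole-cell fura-2 loading experiments: the dye fills the cell as
  ``B(t) = B_pipette * (1 - exp(-t/tau_fill))``; each depolarising stimulus
  injects a fixed total Ca2+ load which, under the rapid-buffering
  approximation, raises free Ca2+ by ``influx/(1 + kappa_S + kappa_B)`` and
  decays mono-exponentially with ``tau = (1 + kappa_S + kappa_B)/gamma`` —
  so transient amplitudes shrink and decays slow as the dye accumulates,
  and the stored (kappa_B, tau) truths are exactly collinear before noise;
* 10-s depolarising current steps whose instantaneous spike frequency
  follows the mono-exponential adaptation law exactly at the spike times;
* ascending current ramps and step families through a passive RC membrane
  with a stereotyped action-potential template (adequate to exercise the
  detector, not a biophysical model);
* FCCP application traces: a slow difference-of-exponentials bump of known
  amplitude on a stable baseline ratio.

Cohort presets ("control" and "DIO") carry the reference group means; the
per-cell dispersion of each parameter is lognormal with the reference
standard error as its standard deviation, and the silent /
strong-adaptation class counts are deterministic (rounded fractions), so
cohorts built at the reference group sizes reproduce the reference
percentages exactly.  All randomness
flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .added_buffer import LoadingExperiment, kappa_b
from .fura_calibration import CalibrationResult, RatioTrace, ca_to_ratio
from .spike_analysis import SpikeTrain

__all__ = [
    "SimulationParams",
    "SyntheticCell",
    "SimulatedTrain",
    "SyntheticNeuron",
    "CohortPreset",
    "PRESETS",
    "DEFAULT_CALIBRATION",
    "simulate_cell",
    "simulate_spike_train",
    "simulate_fccp_trace",
    "simulate_current_ramp",
    "simulate_current_step",
    "make_cohort",
]

#: rig calibration used throughout the simulator (Kd_eff = 0.24 * 10.4167 = 2.5 uM)
DEFAULT_CALIBRATION = CalibrationResult(
    r_min=0.3, r_max=6.0, kd_fura_uM=0.24, dynamic_range=2.5 / 0.24
)


# --------------------------------------------------------------------------
# single-cell loading experiment
# --------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Ground-truth parameter set for one simulated loading experiment.

    Defaults are the control-cohort values; see :data:`PRESETS` for the
    diet-induced-obesity (DIO) set.
    """

    kappa_s: float = 497.0            # endogenous Ca2+-binding ratio
    gamma_per_s: float = 150.0        # linear extrusion rate, 1/s
    ca_rest_nM: float = 19.3          # resting free Ca2+
    influx_uM_total: float = 100.0    # total Ca2+ added per stimulus
    pipette_fura_uM: float = 200.0    # dye concentration in the pipette
    tau_fill_s: float = 300.0         # loading time constant
    calibration: CalibrationResult = DEFAULT_CALIBRATION
    noise_cv: float = 0.02            # multiplicative noise per wavelength
    stim_times_s: np.ndarray = field(
        default_factory=lambda: np.arange(30.0, 600.0, 60.0)
    )
    duration_s: float = 600.0
    dt_s: float = 0.05                # 20 Hz imaging
    cell_scale: float = 2.0           # F360 ADU per uM dye
    f380_scale: float = 50.0          # F380 ADU per uM dye at zero Ca2+
    seed: int | None = None

    def __post_init__(self) -> None:
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)
        if min(self.kappa_s, self.gamma_per_s, self.ca_rest_nM) <= 0:
            raise ValueError("kappa_s, gamma and resting Ca2+ must be positive")
        if self.stim_times_s.size and (
            self.stim_times_s.min() <= 0 or self.stim_times_s.max() >= self.duration_s
        ):
            raise ValueError("stimulus schedule must lie inside the recording")


@dataclass
class SyntheticCell:
    """One simulated loading experiment with its stored ground truth.

    ``true_points`` holds one (kappa_B, tau, amplitude) triple per stimulus;
    the (kappa_B, tau) pairs satisfy ``tau = (1 + kappa_S + kappa_B)/gamma``
    exactly before noise.
    """

    trace: RatioTrace
    stim_times_s: np.ndarray
    loading_time_s: np.ndarray
    loading_fura_uM: np.ndarray
    true_points: list[tuple[float, float, float]]
    params: SimulationParams
    cell_id: str = ""
    cohort: str = ""

    def as_loading_experiment(self) -> LoadingExperiment:
        return LoadingExperiment(
            trace=self.trace,
            stim_times_s=self.stim_times_s,
            cell_scale=self.params.cell_scale,
            cell_id=self.cell_id,
            cohort=self.cohort,
        )


def simulate_cell(params: SimulationParams, rng: np.random.Generator | None = None) -> SyntheticCell:
    """Simulate a whole-cell fura-2 loading experiment.

    Reproducible per seed.  Raises if the stimulus schedule is so dense
    that a transient would overlap the next stimulus within 5 tau.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cal = params.calibration
    t = np.arange(params.dt_s, params.duration_s + params.dt_s / 2, params.dt_s)
    fura_uM = params.pipette_fura_uM * (1.0 - np.exp(-t / params.tau_fill_s))
    ca_rest_uM = params.ca_rest_nM * 1e-3

    stims = np.sort(params.stim_times_s)
    fura_at_stim = params.pipette_fura_uM * (1.0 - np.exp(-stims / params.tau_fill_s))
    kbs = np.array(
        [kappa_b(b, cal.kd_fura_uM, ca_rest_uM) for b in fura_at_stim]
    )
    taus = (1.0 + params.kappa_s + kbs) / params.gamma_per_s
    amps_nM = params.influx_uM_total / (1.0 + params.kappa_s + kbs) * 1e3

    # density check: each transient must have decayed (5 tau) before the next
    gaps = np.diff(stims)
    if np.any(gaps < 5.0 * taus[:-1]):
        raise ValueError(
            "stimulus schedule too dense: transients overlap within 5 tau"
        )

    ca_nM = np.full_like(t, params.ca_rest_nM)
    for t0, amp, tau in zip(stims, amps_nM, taus):
        after = t >= t0
        ca_nM[after] += amp * np.exp(-(t[after] - t0) / tau)

    ratio = ca_to_ratio(ca_nM, cal)
    # F380 tracks dye content and the free-dye fraction; F340 preserves the ratio
    f380 = params.f380_scale * fura_uM * (cal.r_max - ratio) / (cal.r_max - cal.r_min)
    f340 = ratio * f380
    f360 = params.cell_scale * fura_uM

    if params.noise_cv > 0:
        f340 = f340 * (1.0 + params.noise_cv * rng.standard_normal(t.size))
        f380 = f380 * (1.0 + params.noise_cv * rng.standard_normal(t.size))
        f360 = f360 * (1.0 + params.noise_cv * rng.standard_normal(t.size))

    trace = RatioTrace(time_s=t, f340=f340, f380=f380, f360=f360)
    return SyntheticCell(
        trace=trace,
        stim_times_s=stims,
        loading_time_s=t.copy(),
        loading_fura_uM=fura_uM,
        true_points=[(float(k), float(tau), float(a)) for k, tau, a in zip(kbs, taus, amps_nM)],
        params=params,
    )


# --------------------------------------------------------------------------
# adapting spike trains
# --------------------------------------------------------------------------

@dataclass
class SimulatedTrain:
    """A simulated adapting spike train with its generating parameters."""

    train: SpikeTrain
    y0_hz: float
    plateau_hz: float
    k_per_s: float
    time_s: np.ndarray | None = None
    voltage_mV: np.ndarray | None = None

    @property
    def sfa_ratio(self) -> float:
        return self.y0_hz / self.plateau_hz if self.plateau_hz > 0 else np.inf


def _ap_template(time_rel_s: np.ndarray) -> np.ndarray:
    """Stereotyped action-potential waveform (mV above baseline)."""
    return 95.0 * np.exp(-0.5 * (time_rel_s / 3e-4) ** 2)


def _voltage_from_times(
    spike_times: np.ndarray,
    duration_s: float,
    dt_s: float,
    v_base,
) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(0.0, duration_s, dt_s)
    v = np.broadcast_to(np.asarray(v_base, dtype=float), t.shape).copy()
    half = 0.002
    for ts in spike_times:
        lo = np.searchsorted(t, ts - half)
        hi = np.searchsorted(t, ts + half)
        v[lo:hi] += _ap_template(t[lo:hi] - ts)
    return t, v


def simulate_spike_train(
    y0_hz: float,
    plateau_hz: float,
    k_per_s: float,
    duration_s: float = 10.0,
    jitter: float = 0.0,
    seed: int | np.random.Generator | None = None,
    with_voltage: bool = True,
    dt_s: float = 1e-4,
    v_rest_mV: float = -60.0,
) -> SimulatedTrain:
    """Generate spikes whose instantaneous frequency follows the SFA law.

    Starting from a spike at stimulus onset (plus a short 5-ms latency so
    the waveform rises out of baseline), each interspike interval solves
    ``ISI = 1/Y(t + ISI)`` so that the measured instantaneous frequency
    (1/ISI timestamped at the second spike) equals ``Y`` there exactly;
    optional multiplicative lognormal jitter is applied to the ISIs.
    Deterministic per seed.
    """
    if plateau_hz < 0 or y0_hz < plateau_hz:
        raise ValueError("require Y0 >= Plateau >= 0 (growth is not modelled)")
    if y0_hz <= 0:
        raise ValueError("Y0 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def rate(tt: float) -> float:
        return (y0_hz - plateau_hz) * np.exp(-k_per_s * tt) + plateau_hz

    latency = 0.005
    times = [0.0]
    while True:
        t_prev = times[-1]
        isi = 1.0 / rate(t_prev)
        for _ in range(60):  # fixed point of isi = 1/Y(t_prev + isi)
            new = 1.0 / rate(t_prev + isi)
            if abs(new - isi) < 1e-14:
                isi = new
                break
            isi = new
        if jitter > 0:
            isi *= float(np.exp(rng.normal(0.0, jitter) - 0.5 * jitter ** 2))
        t_next = t_prev + isi
        if t_next + latency >= duration_s:
            break
        times.append(t_next)
        if len(times) > 100000:
            raise RuntimeError("runaway spike generation")

    train = SpikeTrain(times_s=np.asarray(times) + latency, duration_s=duration_s)
    out = SimulatedTrain(train=train, y0_hz=y0_hz, plateau_hz=plateau_hz, k_per_s=k_per_s)
    if with_voltage:
        out.time_s, out.voltage_mV = _voltage_from_times(
            train.times_s, duration_s, dt_s, v_rest_mV
        )
    return out


# --------------------------------------------------------------------------
# ramps and steps (excitability protocols)
# --------------------------------------------------------------------------

def simulate_current_ramp(
    i_threshold_pA: float = 20.0,
    slope_pA_per_s: float = 10.0,
    duration_s: float | None = None,
    tau_m_s: float = 0.02,
    gain_hz_per_pA: float = 1.0,
    dt_s: float = 1e-4,
    v_rest_mV: float = -60.0,
    v_spike_threshold_mV: float = -45.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ascending current ramp through a passive RC membrane.

    The subthreshold voltage integrates the ramp with membrane time
    constant ``tau_m`` (so a steeper ramp crosses the firing threshold at
    an equal or higher injected current — the charging lag).  Once
    suprathreshold, spikes are emitted at a rate proportional to the
    suprathreshold current.  Returns (time, voltage, current).
    """
    if duration_s is None:
        duration_s = 2.0 * i_threshold_pA / slope_pA_per_s
    t = np.arange(0.0, duration_s, dt_s)
    current = slope_pA_per_s * t
    # input resistance chosen so the static threshold current sits at
    # v_spike_threshold: R * i_threshold = (v_thresh - v_rest)
    r_in = (v_spike_threshold_mV - v_rest_mV) / i_threshold_pA  # mV per pA
    # RC response to a ramp: V = Vrest + R*s*(t - tau*(1-exp(-t/tau)))
    v_sub = v_rest_mV + r_in * slope_pA_per_s * (
        t - tau_m_s * (1.0 - np.exp(-t / tau_m_s))
    )
    above = v_sub >= v_spike_threshold_mV
    spike_times: list[float] = []
    if np.any(above):
        t_first = t[np.argmax(above)]
        # integrate-and-fire above threshold: rate = gain * (I - I_thresh)
        tt = t[t >= t_first]
        rate = np.clip(gain_hz_per_pA * (slope_pA_per_s * tt - i_threshold_pA), 0.05, None)
        phase = np.cumsum(rate) * dt_s
        n_spk = int(np.floor(phase[-1])) + 1
        spike_times = list(np.interp(np.arange(n_spk), np.concatenate([[0.0], phase]),
                                     np.concatenate([[tt[0]], tt])))
    _, v = _voltage_from_times(np.asarray(spike_times), duration_s, dt_s, v_sub)
    return t, v, current


def simulate_current_step(
    current_pA: float,
    i_threshold_pA: float = 20.0,
    gain_spikes_per_pA: float = 0.5,
    duration_s: float = 1.0,
    dt_s: float = 1e-4,
    v_rest_mV: float = -60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One rectangular current step; spike count = gain * (I - I_thresh).

    Subthreshold steps produce a passive depolarisation and no spikes.
    Returns (time, voltage).
    """
    n_spikes = int(max(0.0, np.floor(gain_spikes_per_pA * (current_pA - i_threshold_pA))))
    if n_spikes > 0:
        spike_times = (np.arange(n_spikes) + 0.5) * duration_s / n_spikes
    else:
        spike_times = np.empty(0)
    v_base = v_rest_mV + min(max(current_pA, 0.0), i_threshold_pA) * 0.5
    t, v = _voltage_from_times(spike_times, duration_s, dt_s, v_base)
    return t, v


# --------------------------------------------------------------------------
# FCCP release traces
# --------------------------------------------------------------------------

def simulate_fccp_trace(
    r0: float = 0.40,
    delta_r: float = 0.020,
    rise_s: float = 30.0,
    fall_s: float = 120.0,
    t_on_s: float = 120.0,
    duration_s: float = 900.0,
    dt_s: float = 2.0,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> RatioTrace:
    """AM-loaded FCCP response: a slow transient of known peak amplitude.

    The bump is a difference of exponentials starting at ``t_on``,
    normalised so its peak equals ``delta_r`` exactly; the peak always
    falls after application onset.  Per-wavelength multiplicative noise.
    """
    if delta_r < 0:
        raise ValueError("delta_r must be non-negative")
    if not 0 < rise_s < fall_s:
        raise ValueError("require 0 < rise < fall kinetics")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_s)
    rel = np.clip(t - t_on_s, 0.0, None)
    bump = np.exp(-rel / fall_s) - np.exp(-rel / rise_s)
    bump[t < t_on_s] = 0.0
    t_peak = np.log(fall_s / rise_s) / (1.0 / rise_s - 1.0 / fall_s)
    peak = np.exp(-t_peak / fall_s) - np.exp(-t_peak / rise_s)
    ratio = r0 + delta_r * bump / peak

    f380 = np.full_like(t, 1000.0)
    f340 = ratio * f380
    if noise_cv > 0:
        f340 = f340 * (1.0 + noise_cv * rng.standard_normal(t.size))
        f380 = f380 * (1.0 + noise_cv * rng.standard_normal(t.size))
    return RatioTrace(time_s=t, f340=f340, f380=f380)


# --------------------------------------------------------------------------
# cohort presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPreset:
    """Reference group means (with SEMs) used as simulator ground truth."""

    name: str
    kappa_s: float
    kappa_s_sem: float
    gamma_per_s: float
    gamma_sem: float
    ca_rest_nM: float
    ca_rest_sem: float
    vm_mV: float
    vm_sem: float
    rate_hz: float
    rate_sem: float
    silent_fraction: float
    strong_sfa_fraction: float
    sfa_firing: float
    sfa_firing_sem: float
    sfa_silent: float
    sfa_silent_sem: float
    fccp_delta_r: float
    fccp_delta_r_sem: float


PRESETS: dict[str, CohortPreset] = {
    "control": CohortPreset(
        name="control",
        kappa_s=497.0, kappa_s_sem=18.0,
        gamma_per_s=150.0, gamma_sem=3.0,
        ca_rest_nM=19.3, ca_rest_sem=2.3,
        vm_mV=-58.8, vm_sem=1.1,
        rate_hz=3.4, rate_sem=0.7,
        silent_fraction=8.0 / 26.0,
        strong_sfa_fraction=4.0 / 19.0,
        sfa_firing=2.0, sfa_firing_sem=0.1,
        sfa_silent=3.6, sfa_silent_sem=0.3,
        fccp_delta_r=0.020, fccp_delta_r_sem=0.003,
    ),
    "DIO": CohortPreset(
        name="DIO",
        kappa_s=240.0, kappa_s_sem=5.0,
        gamma_per_s=111.0, gamma_sem=1.0,
        ca_rest_nM=45.8, ca_rest_sem=7.3,
        vm_mV=-64.0, vm_sem=1.2,
        rate_hz=1.7, rate_sem=0.4,
        silent_fraction=19.0 / 37.0,
        strong_sfa_fraction=10.0 / 29.0,
        sfa_firing=2.0, sfa_firing_sem=0.1,
        sfa_silent=3.6, sfa_silent_sem=0.3,
        fccp_delta_r=0.012, fccp_delta_r_sem=0.001,
    ),
}


@dataclass
class SyntheticNeuron:
    """One simulated neuron of a cohort, with all modality ground truths."""

    cell_id: str
    cohort: str
    truth: dict
    imaging: SyntheticCell | None = None
    spont_train: SpikeTrain | None = None
    sfa: SimulatedTrain | None = None
    fccp_trace: RatioTrace | None = None
    fccp_t_on_s: float = 120.0
    fccp_t_off_s: float = 240.0

    @property
    def is_silent(self) -> bool:
        return bool(self.truth["silent"])


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draws with the requested arithmetic mean and SD."""
    if sd <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _truncated_lognormal(
    rng: np.random.Generator, mean: float, sd: float, lo=-np.inf, hi=np.inf
) -> float:
    for _ in range(1000):
        v = float(_lognormal(rng, mean, sd))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def _spont_train(rng: np.random.Generator, rate_hz: float, duration_s: float = 60.0) -> SpikeTrain:
    """Spontaneous train with a deterministic count = round(rate*duration)."""
    count = int(round(rate_hz * duration_s))
    if count == 0:
        return SpikeTrain(times_s=np.empty(0), duration_s=duration_s)
    isis = rng.lognormal(0.0, 0.1, count)
    cs = np.cumsum(isis)
    times = cs / (cs[-1] + isis.mean()) * duration_s
    return SpikeTrain(times_s=times, duration_s=duration_s)


def make_cohort(
    preset: str,
    n_cells: int,
    seed: int | None = None,
    with_imaging: bool = True,
    with_fccp: bool = True,
    with_spikes: bool = True,
    with_voltage: bool = False,
    noise_cv: float = 0.02,
    sfa_jitter: float = 0.03,
) -> list[SyntheticNeuron]:
    """Simulate a cohort of neurons from a named preset.

    Class memberships (silent, strong adaptation) are deterministic counts
    ``round(fraction * n_cells)``; continuous per-cell parameters are drawn
    lognormally around the preset means with the reference SEM as the
    dispersion.  Same seed, same cohort (byte-identical arrays).
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    p = PRESETS[preset]
    rng = np.random.default_rng(seed)

    n_silent = int(round(p.silent_fraction * n_cells))
    n_strong = int(round(p.strong_sfa_fraction * n_cells))
    silent = np.zeros(n_cells, dtype=bool)
    silent[:n_silent] = True
    # strong adapters sit preferentially among the silent cells
    strong = np.zeros(n_cells, dtype=bool)
    order = np.concatenate([np.flatnonzero(silent), np.flatnonzero(~silent)])
    strong[order[:n_strong]] = True
    perm = rng.permutation(n_cells)
    silent, strong = silent[perm], strong[perm]

    # mean rate of the firing subpopulation so the cohort mean matches
    silent_rate_mean = 0.2
    if n_silent < n_cells:
        firing_rate_mean = max(
            (p.rate_hz * n_cells - silent_rate_mean * n_silent) / (n_cells - n_silent),
            0.8,
        )
    else:
        firing_rate_mean = p.rate_hz

    neurons: list[SyntheticNeuron] = []
    for i in range(n_cells):
        truth = {
            "kappa_s": _truncated_lognormal(rng, p.kappa_s, p.kappa_s_sem, lo=1.0),
            "gamma_per_s": _truncated_lognormal(rng, p.gamma_per_s, p.gamma_sem, lo=1.0),
            "ca_rest_nM": _truncated_lognormal(rng, p.ca_rest_nM, p.ca_rest_sem, lo=1.0),
            "vm_mV": float(rng.normal(p.vm_mV, p.vm_sem)),
            "silent": bool(silent[i]),
            "strong_sfa": bool(strong[i]),
            "fccp_delta_r": _truncated_lognormal(
                rng, p.fccp_delta_r, p.fccp_delta_r_sem, lo=1e-4
            ),
        }
        if silent[i]:
            truth["rate_hz"] = float(rng.uniform(0.05, 0.40))
        else:
            truth["rate_hz"] = _truncated_lognormal(
                rng, firing_rate_mean, p.rate_sem, lo=0.6
            )
        if strong[i]:
            truth["sfa_ratio"] = _truncated_lognormal(
                rng, p.sfa_silent, p.sfa_silent_sem, lo=3.3
            )
        else:
            truth["sfa_ratio"] = _truncated_lognormal(
                rng, p.sfa_firing, p.sfa_firing_sem, hi=2.8
            )
        truth["sfa_y0_hz"] = float(rng.uniform(30.0, 40.0))
        truth["sfa_k_per_s"] = _truncated_lognormal(rng, 0.5, 0.1, lo=0.2, hi=1.0)

        neuron = SyntheticNeuron(cell_id=f"{preset}-{i:03d}", cohort=preset, truth=truth)

        if with_spikes:
            neuron.spont_train = _spont_train(rng, truth["rate_hz"])
            neuron.sfa = simulate_spike_train(
                truth["sfa_y0_hz"],
                truth["sfa_y0_hz"] / truth["sfa_ratio"],
                truth["sfa_k_per_s"],
                duration_s=10.0,
                jitter=sfa_jitter,
                seed=rng,
                with_voltage=with_voltage,
            )

        if with_imaging:
            params = SimulationParams(
                kappa_s=truth["kappa_s"],
                gamma_per_s=truth["gamma_per_s"],
                ca_rest_nM=truth["ca_rest_nM"],
                noise_cv=noise_cv,
            )
            cell = simulate_cell(params, rng=rng)
            cell.cell_id = neuron.cell_id
            cell.cohort = preset
            neuron.imaging = cell

        if with_fccp:
            neuron.fccp_trace = simulate_fccp_trace(
                delta_r=truth["fccp_delta_r"],
                t_on_s=neuron.fccp_t_on_s,
                noise_cv=noise_cv / 2.0,
                seed=rng,
            )
        neurons.append(neuron)
    return neurons
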