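"""Spike detection, activity classification, SFA fitting, excitability."""

import numpy as np
import pytest

from cabuffer import synthetic_data as sd
from cabuffer.spike_analysis import (
    SpikeTrain,
    classify_activity,
    detect_spikes,
    fi_curve,
    fit_sfa,
    instantaneous_frequency,
    threshold_current_from_ramp,
)


def _template_trace(spike_times, duration=2.0, dt=1e-4, v_rest=-60.0):
    t = np.arange(0, duration, dt)
    v = np.full(t.size, v_rest)
    for ts in spike_times:
        v += 95.0 * np.exp(-0.5 * ((t - ts) / 3e-4) ** 2)
    return t, v


class TestDetectSpikes:
    def test_recovers_template_onsets(self):
        truth = np.array([0.1, 0.35, 0.5, 0.9, 1.4])
        t, v = _template_trace(truth)
        train = detect_spikes(t, v)
        assert train.n_spikes == truth.size
        np.testing.assert_allclose(train.times_s, truth, atol=2e-3)
        assert train.baseline_mV == pytest.approx(-60.0, abs=0.5)

    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 1, 1e-4)
        train = detect_spikes(t, np.full(t.size, -60.0))
        assert train.n_spikes == 0

    @pytest.mark.parametrize("dt", [2e-4, 1e-4, 5e-5])
    def test_count_stable_under_sampling_rate(self, dt):
        truth = np.linspace(0.05, 1.9, 12)
        t, v = _template_trace(truth, dt=dt)
        assert detect_spikes(t, v).n_spikes == truth.size

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes([0.0, 0.2, 0.1], [-60.0, -60.0, -60.0])


class TestClassification:
    @pytest.mark.parametrize(
        "rate,label",
        [(0.4, "NSAN"), (0.5, "SAN"), (3.4, "SAN"), (0.0, "NSAN")],
    )
    def test_rate_cutoff_strict(self, rate, label):
        n = int(round(rate * 60))
        times = np.linspace(0.5, 59.5, n) if n else np.empty(0)
        train = SpikeTrain(times_s=times, duration_s=60.0)
        assert classify_activity(train) == label

    def test_invariant_to_segmentation(self):
        """Rate over the full duration, not per segment."""
        times = np.linspace(0.1, 20.0, 30)
        full = SpikeTrain(times_s=times, duration_s=60.0)
        assert full.rate_hz == pytest.approx(0.5)
        assert classify_activity(full) == "SAN"


class TestInstantaneousFrequency:
    def test_regular_train(self):
        train = SpikeTrain(times_s=np.array([0.0, 0.1, 0.2]), duration_s=1.0)
        t, f = instantaneous_frequency(train)
        np.testing.assert_allclose(t, [0.1, 0.2])
        np.testing.assert_allclose(f, [10.0, 10.0])

    def test_geometric_isis_monotone_decreasing(self):
        isis = 0.02 * 1.3 ** np.arange(10)
        train = SpikeTrain(times_s=np.cumsum(isis), duration_s=10.0)
        _, f = instantaneous_frequency(train)
        assert np.all(np.diff(f) < 0)

    def test_single_spike_empty(self):
        train = SpikeTrain(times_s=np.array([1.0]), duration_s=10.0)
        t, f = instantaneous_frequency(train)
        assert t.size == 0 and f.size == 0


class TestFitSFA:
    def test_exact_samples_recovered(self):
        t = np.linspace(0.0, 10.0, 200)
        f = (35.0 - 10.0) * np.exp(-0.5 * t) + 10.0
        fit = fit_sfa(t, f)
        assert fit.plateau_hz == pytest.approx(10.0, rel=1e-6)
        assert fit.k_per_s == pytest.approx(0.5, rel=1e-6)
        assert fit.sfa_ratio == pytest.approx(3.5, rel=1e-6)
        assert fit.sfa_ratio > 3.0  # strong adaptation

    def test_constant_series_ratio_one(self):
        t = np.linspace(0, 10, 100)
        fit = fit_sfa(t, np.full(100, 35.0))
        assert fit.plateau_hz == pytest.approx(35.0)
        assert fit.sfa_ratio == pytest.approx(1.0)
        assert not fit.k_identifiable

    def test_ceased_firing_maps_to_infinite_ratio(self):
        t = np.linspace(0, 10, 100)
        f = 35.0 * np.exp(-1.2 * t) + 0.01
        fit = fit_sfa(t, f)
        assert fit.ceased_firing and np.isinf(fit.sfa_ratio)

    def test_noisy_silent_cell_ratio_within_15pct(self):
        """Recover a silent-cohort cell's ratio (truth 3.6) with jitter."""
        errs = []
        for seed in range(30):
            sim = sd.simulate_spike_train(
                35.0, 35.0 / 3.6, 0.5, jitter=0.03, seed=seed, with_voltage=False
            )
            t, f = instantaneous_frequency(sim.train)
            fit = fit_sfa(t, f)
            errs.append(abs(fit.sfa_ratio - 3.6) / 3.6)
        assert np.median(errs) < 0.15


class TestExcitability:
    def test_ramp_threshold_recovery(self):
        t, v, i = sd.simulate_current_ramp(i_threshold_pA=20.0, slope_pA_per_s=10.0)
        thr = threshold_current_from_ramp(t, v, i)
        # charging lag adds ~ slope * tau_m = 0.2 pA
        assert thr == pytest.approx(20.0, abs=1.0)

    def test_ramp_without_spikes_flags(self):
        t = np.arange(0, 1, 1e-4)
        v = np.full(t.size, -60.0)
        i = 10.0 * t
        assert threshold_current_from_ramp(t, v, i) is None

    def test_steeper_ramp_equal_or_higher_threshold(self):
        thresholds = []
        for slope in (5.0, 20.0, 80.0):
            t, v, i = sd.simulate_current_ramp(
                i_threshold_pA=20.0, slope_pA_per_s=slope, duration_s=10.0
            )
            thresholds.append(threshold_current_from_ramp(t, v, i))
        assert np.all(np.diff(thresholds) >= 0)

    def test_fi_curve_monotone_with_gain(self):
        gain = 0.5
        steps = []
        for current in (0.0, 10.0, 30.0, 50.0, 70.0):
            steps.append((current, sd.simulate_current_step(current, gain_spikes_per_pA=gain)))
        res = fi_curve(steps)
        counts = [n for _, n in res.fi_pairs]
        assert np.all(np.diff(counts) >= 0)
        assert res.fi_slope() == pytest.approx(gain, rel=0.10)

    def test_all_subthreshold_zero_counts(self):
        steps = [(c, sd.simulate_current_step(c)) for c in (0.0, 5.0, 10.0)]
        res = fi_curve(steps)
        assert all(n == 0 for _, n in res.fi_pairs)

    def test_duplicate_currents_averaged_with_note(self):
        steps = [
            (30.0, sd.simulate_current_step(30.0)),
            (30.0, sd.simulate_current_step(30.0)),
            (50.0, sd.simulate_current_step(50.0)),
        ]
        res = fi_curve(steps)
        assert len(res.fi_pairs) == 2
        assert res.notes
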