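"""Forward simulator: stored truths, seeding, presets, round trips."""

import numpy as np
import pytest

from cabuffer import synthetic_data as sd
from cabuffer.added_buffer import KappaTauPoint, fit_added_buffer
from cabuffer.spike_analysis import fit_sfa, instantaneous_frequency


class TestSimulateCell:
    def test_truths_exactly_collinear(self):
        cell = sd.simulate_cell(sd.SimulationParams(noise_cv=0.0, seed=1))
        pts = [KappaTauPoint(k, tau) for k, tau, _ in cell.true_points]
        fit = fit_added_buffer(pts)
        assert fit.kappa_s == pytest.approx(497.0, rel=1e-12)
        assert fit.gamma_per_s == pytest.approx(150.0, rel=1e-12)

    def test_control_vs_dio_decay_ordering(self):
        """DIO transients decay faster at equal kappa_B below the crossover.

        (1+240+kb)/111 < (1+497+kb)/150 iff kb < 19128/39 ~ 490.5.
        """
        tau = lambda ks, g, kb: (1 + ks + kb) / g
        for kb in (0.0, 150.0, 300.0, 480.0):
            assert tau(240.0, 111.0, kb) < tau(497.0, 150.0, kb)
        for kb in (500.0, 600.0):
            assert tau(240.0, 111.0, kb) > tau(497.0, 150.0, kb)

    def test_zero_influx_flat_at_rest(self, cal):
        p = sd.SimulationParams(influx_uM_total=0.0, noise_cv=0.0, seed=1)
        cell = sd.simulate_cell(p)
        from cabuffer.fura_calibration import ratio_to_ca

        ca = ratio_to_ca(cell.trace.ratio, cal)
        np.testing.assert_allclose(ca, p.ca_rest_nM, rtol=1e-9)

    def test_dense_schedule_rejected(self):
        with pytest.raises(ValueError, match="dense"):
            sd.simulate_cell(
                sd.SimulationParams(stim_times_s=np.array([30.0, 32.0, 34.0]))
            )

    def test_seed_reproducibility(self):
        c1 = sd.simulate_cell(sd.SimulationParams(seed=9))
        c2 = sd.simulate_cell(sd.SimulationParams(seed=9))
        np.testing.assert_array_equal(c1.trace.f340, c2.trace.f340)
        np.testing.assert_array_equal(c1.trace.f360, c2.trace.f360)


class TestSimulateSpikeTrain:
    def test_ap_count_matches_rate_integral(self):
        # integral of (10 + 25 exp(-0.5 T)) over 10 s = 149.66
        sim = sd.simulate_spike_train(35.0, 10.0, 0.5, 10.0, jitter=0.0,
                                      with_voltage=False)
        assert abs(sim.train.n_spikes - 150) <= 2

    def test_constant_rate_when_plateau_equals_y0(self):
        sim = sd.simulate_spike_train(35.0, 35.0, 0.5, 2.0, with_voltage=False)
        _, f = instantaneous_frequency(sim.train)
        np.testing.assert_allclose(f, 35.0, rtol=1e-9)

    def test_jitter_free_round_trip_below_1pct(self):
        sim = sd.simulate_spike_train(35.0, 10.0, 0.5, 10.0, jitter=0.0,
                                      with_voltage=False)
        t, f = instantaneous_frequency(sim.train)
        fit = fit_sfa(t, f)
        assert fit.plateau_hz == pytest.approx(10.0, rel=0.01)
        assert fit.k_per_s == pytest.approx(0.5, rel=0.01)

    def test_growth_not_modelled(self):
        with pytest.raises(ValueError):
            sd.simulate_spike_train(10.0, 20.0, 0.5)

    def test_voltage_exercises_detector(self):
        from cabuffer.spike_analysis import detect_spikes

        sim = sd.simulate_spike_train(35.0, 10.0, 0.5, 2.0, jitter=0.0)
        train = detect_spikes(sim.time_s, sim.voltage_mV)
        assert train.n_spikes == sim.train.n_spikes


class TestSimulateFccp:
    def test_zero_amplitude_flat(self):
        tr = sd.simulate_fccp_trace(delta_r=0.0, noise_cv=0.0)
        np.testing.assert_allclose(tr.ratio, tr.ratio[0], rtol=1e-12)

    def test_peak_after_onset(self):
        tr = sd.simulate_fccp_trace(delta_r=0.02, noise_cv=0.0, t_on_s=120.0)
        assert tr.time_s[np.argmax(tr.ratio)] > 120.0


class TestMakeCohort:
    def test_deterministic_class_counts(self):
        neurons = sd.make_cohort("control", 26, seed=1, with_imaging=False,
                                 with_fccp=False)
        assert sum(n.truth["silent"] for n in neurons) == 8
        neurons = sd.make_cohort("DIO", 37, seed=1, with_imaging=False,
                                 with_fccp=False)
        assert sum(n.truth["silent"] for n in neurons) == 19

    def test_same_seed_identical_cohort(self):
        a = sd.make_cohort("control", 4, seed=5)
        b = sd.make_cohort("control", 4, seed=5)
        for na, nb in zip(a, b):
            assert na.truth == nb.truth
            np.testing.assert_array_equal(na.imaging.trace.f340, nb.imaging.trace.f340)
            np.testing.assert_array_equal(na.spont_train.times_s, nb.spont_train.times_s)
            np.testing.assert_array_equal(na.fccp_trace.f340, nb.fccp_trace.f340)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            sd.make_cohort("lean", 5)

    def test_per_cell_dispersion_around_preset(self):
        neurons = sd.make_cohort("control", 40, seed=2, with_imaging=False,
                                 with_fccp=False)
        ks = np.array([n.truth["kappa_s"] for n in neurons])
        assert np.mean(ks) == pytest.approx(497.0, rel=0.05)
        assert 2.0 < np.std(ks, ddof=1) < 60.0  # SEM-scale dispersion

    def test_truth_satisfies_linear_law(self):
        neurons = sd.make_cohort("DIO", 2, seed=3, with_fccp=False)
        for n in neurons:
            ks, g = n.truth["kappa_s"], n.truth["gamma_per_s"]
            for kb, tau, _ in n.imaging.true_points:
                assert tau == pytest.approx((1 + ks + kb) / g, rel=1e-12)

    def test_nsan_fraction_tracks_mixture(self):
        """NSAN fraction on a large mixed cohort equals the preset fraction."""
        from cabuffer.spike_analysis import classify_activity

        neurons = sd.make_cohort("control", 130, seed=7, with_imaging=False,
                                 with_fccp=False)
        frac = np.mean([classify_activity(n.spont_train) == "NSAN" for n in neurons])
        assert frac == pytest.approx(8.0 / 26.0, abs=0.01)
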