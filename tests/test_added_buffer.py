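"""Added-buffer estimation: binding ratios, decay fits, OLS, bootstrap."""

import numpy as np
import pytest

from cabuffer import synthetic_data as sd
from cabuffer.added_buffer import (
    DegenerateFitError,
    KappaTauPoint,
    MissingIsosbesticError,
    bootstrap_added_buffer,
    collect_kappa_tau,
    compare_parameter_distributions,
    fit_added_buffer,
    fit_transient_decay,
    kappa_b,
)
from cabuffer.fura_calibration import RatioTrace


def _line_points(kappa_s, gamma, kbs):
    return [KappaTauPoint(kb, (1.0 + kappa_s + kb) / gamma) for kb in kbs]


class TestKappaB:
    def test_worked_example(self):
        # 100 * 0.24 / (0.02 + 0.24)^2 = 355.03
        assert kappa_b(100.0, 0.24, 0.02) == pytest.approx(355.03, abs=0.01)

    def test_no_dye_no_buffering(self):
        assert kappa_b(0.0, 0.24, 0.02) == 0.0

    def test_decreasing_in_resting_ca(self):
        cas = np.linspace(0.01, 1.0, 30)
        vals = [kappa_b(100.0, 0.24, c) for c in cas]
        assert np.all(np.diff(vals) < 0)


class TestTransientDecay:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0, 10, 0.05)
        ca = 20.0 + 200.0 * np.exp(-t / 1.5)
        fit = fit_transient_decay(t, ca)
        assert fit.accepted
        assert fit.amplitude_nM == pytest.approx(200.0, rel=1e-6)
        assert fit.tau_s == pytest.approx(1.5, rel=1e-6)
        assert fit.baseline_nM == pytest.approx(20.0, rel=1e-6)

    def test_flat_segment_rejected(self):
        t = np.arange(0, 10, 0.05)
        fit = fit_transient_decay(t, np.full(t.size, 20.0))
        assert not fit.accepted

    def test_monte_carlo_tau_recovery(self):
        """tau within 10 % for >= 90 % of seeded runs at default noise."""
        t = np.arange(0, 20, 0.05)
        truth = 20.0 + 150.0 * np.exp(-t / 3.0)
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ca = truth + 4.0 * rng.standard_normal(t.size)  # ~2 % ratio noise
            fit = fit_transient_decay(t, ca)
            ok += fit.accepted and abs(fit.tau_s - 3.0) / 3.0 < 0.10
        assert ok >= 90


class TestCollectKappaTau:
    def test_points_strictly_increasing_kappa(self, cal):
        cell = sd.simulate_cell(sd.SimulationParams(noise_cv=0.0, seed=1))
        points, fits = collect_kappa_tau(cell.as_loading_experiment(), cal)
        assert len(points) == len(cell.stim_times_s)
        kbs = [p.kappa_b for p in points]
        assert np.all(np.diff(kbs) > 0)
        assert len(points) <= len(fits)  # conservation: never more than stimuli

    def test_missing_isosbestic_raises(self, cal):
        cell = sd.simulate_cell(sd.SimulationParams(noise_cv=0.0, seed=1))
        trace = cell.trace
        bare = RatioTrace(trace.time_s, trace.f340, trace.f380, None)
        exp = cell.as_loading_experiment()
        exp.trace = bare
        with pytest.raises(MissingIsosbesticError):
            collect_kappa_tau(exp, cal)


class TestAddedBufferFit:
    @pytest.mark.parametrize(
        "kappa_s,gamma", [(497.0, 150.0), (240.0, 111.0)]
    )
    def test_collinear_oracle_machine_precision(self, kappa_s, gamma):
        points = _line_points(kappa_s, gamma, [0.0, 150.0, 300.0, 600.0])
        fit = fit_added_buffer(points)
        assert fit.kappa_s == pytest.approx(kappa_s, rel=1e-12)
        assert fit.gamma_per_s == pytest.approx(gamma, rel=1e-12)
        assert fit.tau_endo_s == pytest.approx((1 + kappa_s) / gamma, rel=1e-12)
        assert fit.x_intercept == pytest.approx(-(1 + kappa_s), rel=1e-12)
        # internal identity holds by construction
        assert fit.tau_endo_s == pytest.approx(
            (1 + fit.kappa_s) / fit.gamma_per_s, rel=1e-12
        )

    def test_two_points_exact_interpolation_flagged(self):
        points = _line_points(497.0, 150.0, [100.0, 400.0])
        fit = fit_added_buffer(points)
        assert fit.low_n
        assert fit.kappa_s == pytest.approx(497.0, rel=1e-9)

    def test_negative_slope_degenerate(self):
        points = [KappaTauPoint(0, 5.0), KappaTauPoint(300, 3.0), KappaTauPoint(600, 1.0)]
        with pytest.raises(DegenerateFitError) as err:
            fit_added_buffer(points)
        assert err.value.beta1 < 0

    def test_confidence_band_contains_line(self):
        rng = np.random.default_rng(7)
        kbs = np.linspace(0, 600, 30)
        points = [
            KappaTauPoint(kb, (1 + 497 + kb) / 150.0 + rng.normal(0, 0.1))
            for kb in kbs
        ]
        fit = fit_added_buffer(points)
        lo, hi = fit.confidence_band(kbs)
        line = fit.beta0 + fit.beta1 * kbs
        assert np.all(lo < line) and np.all(line < hi)


class TestBootstrap:
    def test_zero_noise_point_mass(self):
        points = _line_points(497.0, 150.0, [0.0, 150.0, 300.0, 600.0])
        boot = bootstrap_added_buffer(points, n_boot=200, seed=1)
        assert np.allclose(boot.kappa_s, 497.0)
        assert np.allclose(boot.gamma_per_s, 150.0)
        assert boot.n_invalid == 0

    def test_seed_contract(self, cal):
        cell = sd.simulate_cell(sd.SimulationParams(seed=4))
        points, _ = collect_kappa_tau(cell.as_loading_experiment(), cal)
        b1 = bootstrap_added_buffer(points, n_boot=300, seed=42)
        b2 = bootstrap_added_buffer(points, n_boot=300, seed=42)
        np.testing.assert_array_equal(b1.kappa_s, b2.kappa_s)
        b3 = bootstrap_added_buffer(points, n_boot=300, seed=43)
        assert not np.array_equal(b1.kappa_s, b3.kappa_s)
        # means agree within Monte-Carlo error across seeds
        sd_ks = np.std(b1.kappa_s, ddof=1)
        assert abs(np.mean(b1.kappa_s) - np.mean(b3.kappa_s)) < 5 * sd_ks / np.sqrt(300)

    def test_bootstrap_sd_shrinks_with_point_count(self):
        """Bootstrap SD of kappa_S scales roughly as 1/sqrt(n points)."""
        rng = np.random.default_rng(3)

        def boot_sd(n_points, seed):
            kbs = np.linspace(0, 600, n_points)
            pts = [
                KappaTauPoint(kb, (1 + 497 + kb) / 150.0 + rng.normal(0, 0.15))
                for kb in kbs
            ]
            return np.std(bootstrap_added_buffer(pts, 400, seed=seed).kappa_s, ddof=1)

        small = np.median([boot_sd(10, s) for s in range(8)])
        large = np.median([boot_sd(40, s) for s in range(8)])
        assert large < small  # more points, tighter distribution
        assert large / small == pytest.approx(0.5, abs=0.3)  # ~ 1/sqrt(4)


class TestLogComparison:
    def test_identical_distributions_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_parameter_distributions(a, a.copy())
        assert res.p_value == pytest.approx(1.0)
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_of_t(self, rng):
        a = rng.lognormal(6.0, 0.1, 500)
        b = rng.lognormal(5.5, 0.1, 500)
        r1 = compare_parameter_distributions(a, b)
        r2 = compare_parameter_distributions(10.0 * a, 10.0 * b)
        assert r1.t_statistic == pytest.approx(r2.t_statistic, rel=1e-9)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compare_parameter_distributions([1.0, -2.0], [1.0, 2.0])

    def test_geometric_means_back_transformed(self, rng):
        a = rng.lognormal(np.log(497.0), 0.05, 1000)
        res = compare_parameter_distributions(a, a * 0.5)
        assert res.geometric_mean_a == pytest.approx(497.0, rel=0.02)
        assert res.geometric_mean_b == pytest.approx(248.5, rel=0.02)
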