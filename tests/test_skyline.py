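import numpy as np
import pytest

import ydemos as yd
from ydemos.genealogy import CoalescentInterval, Genealogy
from ydemos.skyline import (
    ClockModel,
    ConvergenceWarning,
    DetectionRule,
    SkylineEstimate,
    calibrate_tree,
    classical_skyline,
    clock_rate,
    constant_size_mle,
    detect_change,
    ess,
    generalized_skyline,
)


class TestClock:
    def test_printed_clade1_rate(self):
        assert clock_rate(0.74e-9, 14_494_268, 7_834) == pytest.approx(
            1.369e-6, rel=1e-3
        )

    def test_printed_clade3_rate(self):
        assert clock_rate(0.74e-9, 14_494_268, 7_252) == pytest.approx(
            1.479e-6, rel=1e-3
        )

    def test_all_sites_observed_gives_mu(self):
        assert clock_rate(0.74e-9, 1000, 1000) == pytest.approx(0.74e-9)

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            clock_rate(0.74e-9, 1000, 0)

    def test_calibration_divides_by_rate(self):
        gen = Genealogy.from_newick("(A:0.001369,B:0.001369);")
        cal = calibrate_tree(gen, 1.369e-6)
        assert cal.tmrca == pytest.approx(1000.0, rel=1e-6)

    def test_clock_model_rate(self):
        clock = ClockModel(n_snps=7_834)
        gen = Genealogy.from_newick("(A:0.001369,B:0.001369);")
        cal = calibrate_tree(gen, clock)
        assert cal.tmrca == pytest.approx(1000.0, rel=1e-3)

    def test_degenerate_tree_rejected(self):
        gen = Genealogy.from_newick("(A:1,B:1);").scale_times(1e-300)
        gen.time[:] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_tree(gen, 1e-6)


class TestClassicalSkyline:
    def test_pair_interval(self):
        est = classical_skyline([CoalescentInterval(2, 3.5)])
        assert est.point.tolist() == [3.5]

    def test_three_lineage_interval(self):
        est = classical_skyline([CoalescentInterval(3, 1.0)])
        assert est.point.tolist() == [3.0]

    def test_time_unit_equivariance(self, rng):
        gen = yd.simulate_genealogy(yd.DemographicModel(n0=100.0), 10, rng)
        est1 = classical_skyline(gen.coalescent_intervals())
        est2 = classical_skyline(gen.scale_times(7.0).coalescent_intervals())
        assert np.allclose(est2.point, 7.0 * est1.point)
        assert np.allclose(est2.times, 7.0 * est1.times)

    def test_constant_size_recovery(self):
        """The skyline's time-weighted harmonic mean, which reduces to
        TMRCA/(2(1-1/n)), has median within 15% of the true size."""
        rng = np.random.default_rng(31)
        N, n = 1000.0, 200
        hmeans = []
        for _ in range(3000):
            gen = yd.simulate_genealogy(yd.DemographicModel(n0=N), n, rng)
            est = classical_skyline(gen.coalescent_intervals())
            w = np.diff(est.times)
            keep = est.point > 0
            hmeans.append(w[keep].sum() / (w[keep] / est.point[keep]).sum())
        assert np.median(hmeans) == pytest.approx(N, rel=0.15)


class TestGeneralizedSkyline:
    def test_single_group_equals_constant_mle(self, rng):
        gen = yd.simulate_genealogy(yd.DemographicModel(n0=500.0), 30, rng)
        iv = gen.coalescent_intervals()
        est = generalized_skyline(iv, max_groups=1)
        assert est.n_groups == 1
        assert est.point[0] == pytest.approx(constant_size_mle(iv))

    def test_selects_one_group_on_constant_size(self):
        rng = np.random.default_rng(41)
        one = 0
        for _ in range(100):
            gen = yd.simulate_genealogy(yd.DemographicModel(n0=1000.0), 100, rng)
            est = generalized_skyline(gen.coalescent_intervals())
            one += est.n_groups == 1
        assert one >= 80

    def test_detects_strong_two_epoch_change(self):
        rng = np.random.default_rng(42)
        model = yd.DemographicModel(
            n0=1000.0, events=(yd.HistoricalEvent(100.0, 10.0),)
        )
        multi = 0
        for _ in range(100):
            gen = yd.simulate_genealogy(model, 100, rng)
            est = generalized_skyline(gen.coalescent_intervals())
            multi += est.n_groups >= 2
        assert multi >= 80

    def test_needs_two_intervals(self):
        with pytest.raises(ValueError):
            generalized_skyline([CoalescentInterval(2, 1.0)])


class TestESS:
    def test_iid_trace(self):
        rng = np.random.default_rng(51)
        x = rng.normal(size=10_000)
        assert ess(x) == pytest.approx(10_000, rel=0.10)

    def test_ar1_trace(self):
        rng = np.random.default_rng(52)
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        expect = n * (1 - rho) / (1 + rho)
        assert ess(x) == pytest.approx(expect, rel=0.25)

    def test_constant_trace_is_zero_with_warning(self):
        with pytest.warns(ConvergenceWarning):
            assert ess(np.ones(100)) == 0.0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            ess(np.arange(5))


class TestDetectChange:
    def model_trajectory(self, scale=1.0):
        # true model trajectory in years: 10,000/1,120/4,009.6/689.65
        times = np.array([0.0, 2000.0, 3000.0, 14500.0, 50000.0])
        point = scale * np.array([10_000.0, 1_120.0, 4_009.6, 689.65])
        return SkylineEstimate(times, point)

    def test_true_trajectory_detected(self):
        assert detect_change(self.model_trajectory(), DetectionRule())
        assert detect_change(self.model_trajectory(scale=25.0), DetectionRule())

    def test_constant_trajectory_not_detected(self):
        est = SkylineEstimate(
            np.array([0.0, 50_000.0]), np.array([10_000.0])
        )
        assert not detect_change(est, DetectionRule())

    def test_decrease_without_recovery_not_detected(self):
        times = np.array([0.0, 2900.0, 14500.0, 50_000.0])
        point = np.array([1_000.0, 1_000.0, 10_000.0])
        est = SkylineEstimate(times, point)
        assert not detect_change(est, DetectionRule())

    def test_window_outside_span_raises(self):
        est = SkylineEstimate(np.array([0.0, 5000.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="span"):
            detect_change(est, DetectionRule())

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            DetectionRule(fold=1.0)
        with pytest.raises(ValueError):
            DetectionRule(post=(0, 2500.0))


class TestWindowMean:
    def test_time_weighting(self):
        est = SkylineEstimate(
            np.array([0.0, 1.0, 3.0]), np.array([10.0, 40.0])
        )
        assert est.window_mean(0.0, 3.0) == pytest.approx(30.0)
        assert est.window_mean(0.0, 1.0) == pytest.approx(10.0)

    def test_zero_width_steps_excluded(self):
        est = SkylineEstimate(
            np.array([0.0, 1.0, 1.0, 2.0]), np.array([10.0, 0.0, 20.0])
        )
        assert est.window_mean(0.0, 2.0) == pytest.approx(15.0)


def test_hpd_matches_arviz():
    az = pytest.importorskip("arviz")
    from ydemos.skyline import _hpd

    rng = np.random.default_rng(61)
    x = rng.gamma(2.0, 3.0, size=20_000)
    lo, hi = _hpd(x, 0.95)
    ref = az.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(ref[0], abs=0.15)
    assert hi == pytest.approx(ref[1], abs=0.3)
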