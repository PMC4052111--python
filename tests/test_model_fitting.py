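"""Trimmed means, slice handling and kinetic-parameter estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paslquant import (AcquisitionParams, KineticParams, RoiSignalCurve,
                       average_adjacent_slices, delta_m, fit_kinetic,
                       simulate_ladder_curves, trimmed_mean)

LADDER = np.r_[50.0, np.arange(300.0, 3301.0, 300.0)]  # 12-point TI2 ladder, ms


def oracle_trimmed_mean(values, frac):
    """Brute-force sort-and-slice reference."""
    s = sorted(values)
    k = int(np.floor(frac * len(s)))
    core = s[k:len(s) - k] if k else s
    return sum(core) / len(core)


class TestTrimmedMean:
    def test_constant_vector(self):
        assert trimmed_mean([7.0] * 13, 0.05) == 7.0

    def test_twenty_values_drop_one_per_tail(self):
        assert trimmed_mean(np.arange(1.0, 21.0), 0.05) == 10.5

    def test_floor_rule_keeps_all_below_twenty(self):
        # floor(0.05 * 19) = 0: nothing removed, plain mean
        assert trimmed_mean(np.arange(1.0, 20.0), 0.05) == 10.0

    def test_zero_trim_is_plain_mean(self, rng):
        v = rng.normal(size=37)
        assert trimmed_mean(v, 0.0) == pytest.approx(v.mean(), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_mean([], 0.05)

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
           st.floats(0.0, 0.49))
    def test_matches_sort_and_slice_oracle(self, values, frac):
        assert trimmed_mean(values, frac) == pytest.approx(
            oracle_trimmed_mean(values, frac), rel=1e-9, abs=1e-9)


class TestAdjacentSliceAveraging:
    def test_twelve_slices_make_six_pairs(self, acq):
        ti2 = acq.ti2_base + np.arange(12) * acq.slice_dt
        t, d, n, groups = average_adjacent_slices(ti2, np.arange(12.0))
        assert len(t) == 6 and groups[0] == (0, 1) and groups[-1] == (10, 11)

    def test_identical_signals_unchanged(self, acq):
        ti2 = acq.ti2_base + np.arange(4) * acq.slice_dt
        _, d, _, _ = average_adjacent_slices(ti2, np.full(4, 5.0))
        np.testing.assert_allclose(d, 5.0)

    def test_linear_signal_pairs_to_midpoints(self, acq):
        ti2 = acq.ti2_base + np.arange(6) * acq.slice_dt
        sig = 2.0 * np.arange(6) + 1.0
        t, d, _, _ = average_adjacent_slices(ti2, sig)
        np.testing.assert_allclose(d, [2.0, 6.0, 10.0])
        np.testing.assert_allclose(t, acq.ti2_base + acq.slice_dt *
                                   np.array([0.5, 2.5, 4.5]))

    def test_odd_trailing_slice_kept(self, acq):
        ti2 = acq.ti2_base + np.arange(5) * acq.slice_dt
        t, _, _, groups = average_adjacent_slices(ti2, np.arange(5.0))
        assert groups[-1] == (4,)
        assert t[-1] == ti2[-1]


def ladder_curve(kp, acq, noise=None):
    dm = delta_m(LADDER, kp, acq)
    if noise is not None:
        dm = dm + noise
    return RoiSignalCurve(ti2=LADDER, dm=dm, n_voxels=np.full(12, 100))


class TestFitKinetic:
    def test_noiseless_recovery(self, acq):
        truth = KineticParams(cbf=50.0, att=700.0, tau=900.0, m0b=1111.0)
        res = fit_kinetic(ladder_curve(truth, acq), acq,
                          init=KineticParams(40.0, 500.0, 1200.0, 1111.0))
        assert res.converged and not res.degenerate
        assert res.params.cbf == pytest.approx(50.0, rel=1e-6)
        assert res.params.att == pytest.approx(700.0, rel=1e-6)
        assert res.params.tau == pytest.approx(900.0, rel=1e-6)
        assert res.offset == pytest.approx(0.0, abs=1e-8)

    def test_zero_curve_degenerate(self, acq):
        curve = RoiSignalCurve(ti2=LADDER, dm=np.zeros(12),
                               n_voxels=np.full(12, 10))
        res = fit_kinetic(curve, acq)
        assert res.degenerate and res.params.cbf == 0.0

    def test_deterministic(self, acq):
        truth = KineticParams(cbf=45.0, att=600.0, tau=1000.0, m0b=1000.0)
        rng = np.random.default_rng(5)
        curve = ladder_curve(truth, acq, noise=rng.normal(0, 0.2, 12))
        r1 = fit_kinetic(curve, acq)
        r2 = fit_kinetic(curve, acq)
        assert r1.params == r2.params and r1.rss == r2.rss

    def test_too_few_points_rejected(self, acq):
        curve = RoiSignalCurve(ti2=LADDER[:4], dm=np.ones(4),
                               n_voxels=np.full(4, 10))
        with pytest.raises(ValueError):
            fit_kinetic(curve, acq)

    def test_estimates_within_bounds(self, acq, rng):
        truth = KineticParams(cbf=50.0, att=700.0, tau=900.0, m0b=1111.0)
        curve = ladder_curve(truth, acq, noise=rng.normal(0, 0.5, 12))
        res = fit_kinetic(curve, acq, init=truth)
        assert 0.0 <= res.params.cbf <= 300.0
        assert 0.0 <= res.params.att <= 3000.0
        assert 100.0 <= res.params.tau <= 3000.0

    def test_monte_carlo_recovery_at_default_snr(self, acq):
        """Median errors across noisy ladder fits stay inside tight bands.

        cbf within 5%, transit time and bolus duration within 10% of truth
        at the simulator's default noise propagation (voxel sd 10, 30 pairs,
        250-voxel ROI), and the estimate distribution stays inside the
        physiological windows the transit-time literature reports for
        cerebellum (transit 550-1000 ms, bolus 800-1500 ms).
        """
        truth = KineticParams(cbf=50.0, att=700.0, tau=900.0, m0b=1111.0)
        init = KineticParams(cbf=50.0, att=700.0, tau=1000.0, m0b=1111.0)
        curves = simulate_ladder_curves(truth, acq, n_curves=60, seed=901)
        fits = [fit_kinetic(c, acq, init=init) for c in curves]
        cbf = np.array([f.params.cbf for f in fits])
        att = np.array([f.params.att for f in fits])
        tau = np.array([f.params.tau for f in fits])
        assert np.median(np.abs(cbf - 50.0)) / 50.0 < 0.05
        assert np.median(np.abs(att - 700.0)) / 700.0 < 0.10
        assert np.median(np.abs(tau - 900.0)) / 900.0 < 0.10
        assert 550.0 <= np.median(att) <= 1000.0
        assert 800.0 <= np.median(tau) <= 1500.0
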