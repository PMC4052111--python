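"""ROI statistics, variability metrics and the published reference table."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from paslquant import (cerebellum_cbf_table, cv_percent, gm_wm_ratio,
                       group_stats, interslice_cv, paired_ttest,
                       perfusion_report, roi_cbf, spatial_cv, temporal_cv)

FAIR_GM = [42.58, 45.07, 37.89, 41.82, 51.57]
PICORE_WM = [33.50, 28.89, 19.04, 14.71, 22.51]


class TestRoiCbf:
    def test_uniform_map(self):
        m = np.full((5, 5, 3), 42.0)
        mask = np.ones_like(m, bool)
        assert roi_cbf(m, mask) == 42.0

    def test_trim_zero_equals_plain_mean(self, rng):
        m = rng.normal(45, 5, (6, 6, 4))
        mask = rng.uniform(size=m.shape) > 0.3
        assert roi_cbf(m, mask, 0.0) == pytest.approx(m[mask].mean())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            roi_cbf(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))

    def test_nan_voxels_ignored(self):
        m = np.array([[[40.0, np.nan, 50.0]]])
        assert roi_cbf(m, np.ones_like(m, bool)) == 45.0


class TestRatioAndCv:
    @pytest.mark.parametrize("gm,wm,expected", [
        (42.58, 29.56, 1.44), (51.57, 32.53, 1.59), (30.0, 30.0, 1.0),
    ])
    def test_gm_wm_ratio(self, gm, wm, expected):
        assert gm_wm_ratio(gm, wm) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_wm_rejected(self):
        with pytest.raises(ValueError):
            gm_wm_ratio(40.0, 0.0)

    def test_cv_hand_computed(self):
        assert cv_percent([40.0, 50.0, 60.0]) == pytest.approx(20.0)

    def test_cv_constant_is_zero(self):
        assert cv_percent([5.0] * 4) == 0.0

    def test_cv_reference_gm_column(self):
        assert cv_percent(FAIR_GM) == pytest.approx(11.6, abs=0.05)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1.0, 1e3), min_size=2, max_size=30),
           st.floats(0.01, 100.0))
    def test_cv_scale_invariant(self, values, c):
        v = np.asarray(values)
        assert cv_percent(c * v) == pytest.approx(cv_percent(v),
                                                  rel=1e-9, abs=1e-9)


class TestVariabilityMetrics:
    def test_interslice_uniform_is_zero(self):
        m = np.full((4, 4, 5), 30.0)
        assert interslice_cv(m, np.ones_like(m, bool)) == 0.0

    def test_interslice_known_slice_means(self):
        m = np.empty((4, 4, 3))
        for k, v in enumerate((40.0, 50.0, 60.0)):
            m[:, :, k] = v
        assert interslice_cv(m, np.ones_like(m, bool)) == pytest.approx(20.0)

    def test_interslice_needs_two_slices(self):
        m = np.ones((4, 4, 3))
        mask = np.zeros_like(m, bool)
        mask[:, :, 1] = True
        with pytest.raises(ValueError):
            interslice_cv(m, mask)

    def test_interslice_shrinks_with_voxels_per_slice(self, rng):
        """Noise-driven interslice C.V. scales roughly as 1/sqrt(voxels)."""
        cvs = []
        for n in (4, 64):
            m = 50.0 + rng.normal(0, 5, (n, n, 6))
            cvs.append(interslice_cv(m, np.ones_like(m, bool)))
        assert cvs[1] < cvs[0]

    def test_spatial_two_voxels(self):
        m = np.array([[[40.0, 60.0]]])
        assert spatial_cv(m, np.ones_like(m, bool)) == pytest.approx(
            100.0 * np.sqrt(200.0) / 50.0)

    def test_spatial_matches_brute_force(self, rng):
        m = rng.normal(45, 7, (6, 6, 4))
        mask = rng.uniform(size=m.shape) > 0.4
        vals = m[mask]
        expected = 100.0 * vals.std(ddof=1) / vals.mean()
        assert spatial_cv(m, mask) == pytest.approx(expected, rel=1e-12)

    def test_temporal_constant_series_is_zero(self):
        series = np.full((4, 4, 6, 10), 3.0)
        assert temporal_cv(series, (0, 1, 2, 3),
                           np.ones((4, 4, 6), bool)) == 0.0

    def test_temporal_two_point_alternation(self):
        a = 2.0
        series = np.empty((3, 3, 4, 2))
        series[..., 0], series[..., 1] = a, 3 * a
        # mean 2a, sample sd sqrt(2)*a -> C.V. = 70.71%
        assert temporal_cv(series, (0, 1), np.ones((3, 3, 4), bool)) == \
            pytest.approx(100.0 / np.sqrt(2.0))

    def test_temporal_white_noise_matches_snr(self, rng):
        """Pure-noise series: C.V. approaches 100*sigma/(mu*sqrt(voxels))."""
        mu, sigma, n_t = 10.0, 2.0, 400
        mask = np.ones((12, 12, 4), bool)
        series = mu + rng.normal(0, sigma, mask.shape + (n_t,))
        expected = 100.0 * sigma / (mu * np.sqrt(mask.sum()))
        assert temporal_cv(series, range(4), mask) == pytest.approx(
            expected, rel=0.15)

    def test_temporal_empty_region_rejected(self):
        series = np.ones((3, 3, 4, 5))
        with pytest.raises(ValueError):
            temporal_cv(series, (0,), np.zeros((3, 3, 4), bool))


class TestGroupStats:
    def test_reference_fair_gm_column(self):
        gs = group_stats(FAIR_GM)
        assert gs.mean == pytest.approx(43.78, abs=0.011)
        assert gs.sd == pytest.approx(5.06, abs=0.011)

    def test_reference_picore_wm_column(self):
        gs = group_stats(PICORE_WM)
        assert gs.mean == pytest.approx(23.73, abs=0.011)
        assert gs.sd == pytest.approx(7.53, abs=0.011)

    def test_constant_column(self):
        gs = group_stats([30.0, 30.0, 30.0])
        assert gs.sd == 0.0

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError):
            group_stats([1.0])


class TestPairedTTest:
    def test_closed_form_oracle(self, rng):
        """Matches t = mean(d) / (sd(d)/sqrt(n)) with the t CDF."""
        a = rng.normal(40, 5, 8)
        b = a + rng.normal(1, 2, 8)
        res = paired_ttest(a, b)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        p = 2.0 * sps.t.sf(abs(t), df=d.size - 1)
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.df == 7

    def test_identical_inputs_degenerate(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.t)


class TestPerfusionReport:
    def test_reference_table_reconstruction(self):
        """Every derived row of the bundled two-method table is reproduced."""
        report = perfusion_report(cerebellum_cbf_table())
        fair = report[report.method == "FAIR_ASST"].set_index("row")
        pic = report[report.method == "PICORE"].set_index("row")
        assert fair.loc["Mean", "cbf_gm"] == pytest.approx(43.79, abs=0.011)
        assert fair.loc["S.D.", "cbf_gm"] == pytest.approx(5.06, abs=0.011)
        assert fair.loc["C.V.(%)", "cbf_gm"] == pytest.approx(11.6, abs=0.055)
        assert fair.loc["1", "ratio"] == pytest.approx(1.44, abs=0.011)
        assert fair.loc["Mean", "ratio"] == pytest.approx(1.60, abs=0.011)
        assert pic.loc["Mean", "ratio"] == pytest.approx(1.79, abs=0.011)
        assert pic.loc["C.V.(%)", "cbf_wm"] == pytest.approx(31.7, abs=0.055)

    def test_missing_columns_rejected(self):
        import pandas as pd
        with pytest.raises(ValueError):
            perfusion_report(pd.DataFrame({"subject": [1], "cbf_gm": [40.0]}))
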