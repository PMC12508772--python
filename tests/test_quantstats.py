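"""Repeatability/reproducibility statistics: CV, RC, Bland-Altman,
relaxivity, ANOVA/Tukey, paired t, histogram shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from t1map.quantstats import (bland_altman, compute_cv, compute_rc,
                              histogram_shape, one_way_anova, paired_t_test,
                              relaxivity_fit, repeatability_summary,
                              roi_stats, tukey_hsd)
from t1map.t1fit import QuantMaps

# printed longitudinal summary rows: (mean, temporal SD, CV %, RC ms)
PHANTOM_ROWS = [
    ("sphere_wm", 252.8, 1.9, 0.75, 5.3),
    ("sphere_cortex", 354.4, 3.9, 1.10, 10.8),
]


class TestCVandRC:
    @pytest.mark.parametrize("_, mean, sd, cv, rc", PHANTOM_ROWS)
    def test_phantom_sphere_rows_round_trip(self, _, mean, sd, cv, rc):
        assert round(compute_cv(mean, sd), 2) == pytest.approx(cv)
        assert round(compute_rc(sd), 1) == pytest.approx(rc)

    def test_in_vivo_wm_rc_rounds_to_2ms(self):
        assert round(compute_rc(0.7)) == 2

    def test_zero_sd(self):
        assert compute_cv(300.0, 0.0) == 0.0
        assert compute_rc(0.0) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compute_cv(0.0, 1.0)
        with pytest.raises(ValueError):
            compute_rc(-1.0)

    @settings(max_examples=100, deadline=None)
    @given(mean=st.floats(1, 1e4), sd=st.floats(0, 1e3))
    def test_identities_hold_for_all_inputs(self, mean, sd):
        cv = compute_cv(mean, sd)
        rc = compute_rc(sd)
        assert cv * mean / 100.0 == pytest.approx(sd, abs=1e-9 * max(sd, 1))
        if sd > 1e-9:
            assert rc / sd == pytest.approx(1.96 * np.sqrt(2))


class TestRepeatabilitySummary:
    def test_identical_sessions_zero_variability(self):
        r = repeatability_summary([300.0] * 6)
        assert r.cv == 0.0 and r.rc == 0.0 and r.n_sessions == 6

    def test_reconstructed_phantom_row(self):
        """Six session means engineered to the printed mean/SD reproduce
        the printed CV and RC after rounding."""
        base = np.array([-1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        means = 252.8 + base / np.std(base, ddof=1) * 1.9
        r = repeatability_summary(means)
        assert round(r.cv, 2) == 0.75
        assert round(r.rc, 1) == 5.3

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(100, 500), min_size=2, max_size=10))
    def test_composition_matches_direct_formulas(self, means):
        r = repeatability_summary(means)
        m = np.asarray(means)
        assert r.temporal_sd == pytest.approx(np.std(m, ddof=1))
        assert r.rc == pytest.approx(1.96 * np.sqrt(2) * r.temporal_sd)

    def test_single_session_refused(self):
        with pytest.raises(ValueError):
            repeatability_summary([300.0])


class TestBlandAltman:
    def test_identical_arrays(self):
        r = bland_altman([300.0, 310.0], [300.0, 310.0])
        assert r.mean_diff == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_hand_computed_pairs(self):
        r = bland_altman([300.0, 310.0], [298.0, 312.0])
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(2 * np.sqrt(2))
        assert r.loa_high == pytest.approx(1.96 * 2 * np.sqrt(2))
        assert r.loa_low == pytest.approx(-1.96 * 2 * np.sqrt(2))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=20),
           st.floats(-50, 50))
    def test_translation_and_loa_width(self, b, c):
        a = [v + 1.3 for v in b]
        r0 = bland_altman(a, b)
        r1 = bland_altman([v + c for v in a], b)
        assert r1.mean_diff == pytest.approx(r0.mean_diff + c, abs=1e-8)
        assert r1.sd_diff == pytest.approx(r0.sd_diff, abs=1e-8)
        assert r1.loa_high - r1.loa_low == pytest.approx(3.92 * r1.sd_diff)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRelaxivity:
    def test_exact_line_recovered(self):
        c = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        r1 = 0.8 * c + 0.3                      # s^-1
        t1_ms = 1000.0 / r1                     # all within 100-1000 ms
        fit = relaxivity_fit(c, t1_ms)
        assert fit.r1_slope == pytest.approx(0.8, abs=1e-10)
        assert fit.intercept_r1_c0 == pytest.approx(0.3, abs=1e-10)
        assert fit.n_points_used == 5

    def test_out_of_range_points_excluded(self):
        c = np.array([0.0, 0.5, 1.0, 2.0, 5.0])
        t1 = np.array([2000.0, 500.0, 300.0, 150.0, 50.0])
        fit = relaxivity_fit(c, t1)
        assert fit.n_points_used == 3  # 2000 and 50 ms fall outside

    def test_matches_grid_search_oracle_on_noisy_line(self):
        rng = np.random.default_rng(0)
        c = np.linspace(0.1, 2.0, 12)
        r1 = 0.7 * c + 0.4 + 0.02 * rng.standard_normal(12)
        t1 = 1000.0 / r1
        keep = (t1 >= 100) & (t1 <= 1000)
        fit = relaxivity_fit(c, t1)
        slopes = np.linspace(0.5, 0.9, 401)
        inters = np.linspace(0.2, 0.6, 401)
        sse = np.array([[np.sum((r1[keep] - s * c[keep] - b) ** 2)
                         for b in inters] for s in slopes])
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.r1_slope == pytest.approx(slopes[i], abs=1e-3)
        assert fit.intercept_r1_c0 == pytest.approx(inters[j], abs=1e-3)

    def test_too_few_in_range_rejected(self):
        with pytest.raises(ValueError):
            relaxivity_fit([0.1, 1.0], [2000.0, 300.0])


class TestAnova:
    def test_two_groups_f_equals_t_squared(self):
        a = [290.0, 292.0, 287.0, 294.0]
        b = [330.0, 334.0, 328.0, 333.0]
        res = one_way_anova([a, b])
        t, _ = sps.ttest_ind(a, b)
        assert res.f_stat == pytest.approx(t ** 2)
        assert res.df_between == 1 and res.df_within == 6

    def test_textbook_sums_of_squares(self):
        groups = [[1.0, 2, 3], [2.0, 3, 4], [3.0, 4, 5]]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        gm = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - gm) ** 2 for g in groups)
        ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
        f = (ssb / 2) / (ssw / 6)
        assert res.f_stat == pytest.approx(f)
        assert res.p_value == pytest.approx(sps.f.sf(f, 2, 6))

    def test_invariance_and_scaling(self):
        rng = np.random.default_rng(1)
        groups = [list(rng.normal(300, 5, 8)) for _ in range(3)]
        f0 = one_way_anova(groups).f_stat
        shifted = [[v + 17.0 for v in g] for g in groups]
        scaled = [[3.0 * v for v in g] for g in groups]
        permuted = [list(np.random.default_rng(2).permutation(g)) for g in groups]
        for other in (shifted, scaled, permuted):
            assert one_way_anova(other).f_stat == pytest.approx(f0)

    def test_degenerate_identical_data_flagged(self):
        res = one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        assert res.degenerate and not res.significant


class TestTukey:
    def test_identical_groups_not_significant(self):
        rows = tukey_hsd([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert rows[0]["mean_diff"] == 0.0
        assert rows[0]["adjusted_p"] > 0.99

    def test_two_groups_reduce_to_pooled_t(self):
        a = [290.0, 292.0, 287.0, 294.0, 291.0]
        b = [296.0, 295.0, 299.0, 293.0, 297.0]
        rows = tukey_hsd([a, b])
        _, p = sps.ttest_ind(a, b)
        assert rows[0]["adjusted_p"] == pytest.approx(p, rel=1e-6)

    def test_well_separated_groups_all_significant(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(mu, 0.1, 10)) for mu in (0.0, 10.0, 20.0)]
        rows = tukey_hsd(groups)
        assert len(rows) == 3
        assert all(r["adjusted_p"] < 0.05 for r in rows)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 2.0, 8) for mu in (300, 303, 310)]
        rows = tukey_hsd(groups)
        data = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 8)
        sm = statsmodels.pairwise_tukeyhsd(data, labels)
        np.testing.assert_allclose([r["adjusted_p"] for r in rows],
                                   sm.pvalues, atol=1e-4)


class TestPairedT:
    def test_equal_inputs(self):
        t, p, degen = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and degen

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(5)
        b = rng.normal(300, 5, 10)
        a = b + 1.0 + rng.normal(0, 0.1, 10)
        _, p, _ = paired_t_test(a, b)
        assert p < 1e-3

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        t_ab, _, _ = paired_t_test(a, b)
        t_ba, _, _ = paired_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba)


class TestHistogramShape:
    def test_gaussian_fwhm_closed_form(self):
        rng = np.random.default_rng(7)
        sigma = 30.0
        v = rng.normal(250.0, sigma, 200_000)
        fwhm_s, skew, flag = histogram_shape(v)
        assert fwhm_s == pytest.approx(2.3548 * sigma / 1000.0, rel=0.05)
        assert skew == pytest.approx(0.0, abs=0.05)

    def test_single_bin_fwhm_is_bin_width(self):
        v = np.full(100, 250.3)
        fwhm_s, _, _ = histogram_shape(v)
        assert fwhm_s == pytest.approx((499.0 / 200) / 1000.0)

    def test_skewed_sample_positive_g1(self):
        rng = np.random.default_rng(8)
        v = rng.gamma(2.0, 40.0, 100_000) + 50
        _, skew, _ = histogram_shape(v)
        assert skew > 0.5

    def test_multimodal_flagged_outermost_crossings(self):
        v = np.concatenate([np.full(100, 100.0), np.full(100, 400.0)])
        fwhm_s, _, flag = histogram_shape(v)
        assert flag
        assert fwhm_s > 0.29  # spans both modes

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_shape([])


class TestRoiStats:
    @staticmethod
    def _maps(t1_vol, fit_mask=None):
        shape = t1_vol.shape
        if fit_mask is None:
            fit_mask = np.ones(shape, bool)
        return QuantMaps(t1=t1_vol, pd=np.ones(shape), rmse=np.zeros(shape),
                         fit_mask=fit_mask, at_bound=np.zeros(shape, bool))

    def test_uniform_region(self):
        labels = np.ones((4, 4, 4), int)
        res = roi_stats(self._maps(np.full((4, 4, 4), 300.0)), labels)
        assert res[0].mean_t1 == 300.0 and res[0].sd_t1 == 0.0
        assert res[0].n_voxels == 64

    def test_two_half_regions_average(self):
        t1 = np.full((4, 4, 4), 200.0)
        t1[2:] = 400.0
        res = roi_stats(self._maps(t1), np.ones((4, 4, 4), int))
        assert res[0].mean_t1 == pytest.approx(300.0)

    def test_flagged_voxels_excluded(self):
        t1 = np.full((4, 4, 4), 300.0)
        fit_mask = np.ones((4, 4, 4), bool)
        fit_mask[2:] = False
        res = roi_stats(self._maps(t1, fit_mask), np.ones((4, 4, 4), int))
        assert res[0].n_voxels == 32

    def test_empty_label_omitted_with_warning(self):
        labels = np.ones((2, 2, 2), int)
        with pytest.warns(UserWarning):
            res = roi_stats(self._maps(np.full((2, 2, 2), 300.0),
                                       np.zeros((2, 2, 2), bool)), labels)
        assert res == []
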