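import itertools

import numpy as np
import pytest
from scipy import stats
from hypothesis import given, settings, strategies as st

import tremorkit as tk
from tremorkit.exceptions import InputError
from tremorkit.onset_stats import (
    baseline_median,
    bh_adjust,
    ci_segment_median,
    detect_onset,
    fit_drift,
    normalize_mpr,
    signed_rank_test,
)
from tremorkit.types import BandDefinition, MPRSeries, SegmentStat


def make_series(times, mprs, seg_ids=None):
    n = len(times)
    return MPRSeries(
        window_times=np.asarray(times, float),
        mpr=np.asarray(mprs, float),
        bands=BandDefinition(),
        segment_ids=np.asarray(seg_ids or ["s"] * n, dtype=object),
    )


def signed_rank_enumeration_p(values, null=1.0):
    """Brute-force two-sided signed-rank p over all sign assignments."""
    d = np.asarray(values, float) - null
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ])
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestBaseline:
    def test_constant_baseline(self):
        s = make_series([100, 200, 300], [2.0, 2.0, 2.0])
        assert baseline_median(s).baseline_median_mpr == 2.0

    def test_only_windows_before_cutoff_contribute(self):
        # segments at -5, 10, 20 min: the 20-min one is past the 900-s cutoff
        s = make_series([-300, 600, 1200], [1.0, 3.0, 100.0])
        b = baseline_median(s)
        assert b.baseline_median_mpr == 2.0
        assert b.n_baseline_windows == 2

    def test_even_n_median(self):
        s = make_series([1, 2, 3, 4], [1.0, 3.0, 2.0, 100.0])
        assert baseline_median(s).baseline_median_mpr == 2.5

    def test_no_baseline_windows_is_error(self):
        with pytest.raises(InputError):
            baseline_median(make_series([1000.0], [1.0]))

    def test_normalized_baseline_median_is_one(self):
        # odd window count: the median is an element, so exactly 1.0
        s = make_series([10, 20, 30, 1000, 2000],
                        [0.8, 1.7, 2.9, 5.0, 6.0])
        b = baseline_median(s)
        s = normalize_mpr(s, b)
        base = s.normalized_mpr[s.window_times <= 900]
        assert np.median(base) == 1.0


class TestSignedRank:
    def test_all_above_exact_p(self):
        # 6 untied values above the null: exact two-sided p = 2/2^6
        p, direction = signed_rank_test(
            np.array([1.1, 1.2, 1.3, 1.4, 1.5, 1.6]))
        assert p == 0.03125
        assert direction == "above"

    def test_symmetric_values_not_significant(self):
        # offsets exactly representable in binary so the +/- pairs tie
        vals = 1.0 + np.array([-0.25, 0.25, -0.5, 0.5, -0.75, 0.75])
        p, direction = signed_rank_test(vals)
        assert p == 1.0
        assert direction == "none"

    def test_all_zero_differences(self):
        p, direction = signed_rank_test(np.ones(5))
        assert p == 1.0 and direction == "none"

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            vals = 1 + rng.normal(0, 0.5, n)
            p, _ = signed_rank_test(vals)
            assert p == pytest.approx(signed_rank_enumeration_p(vals),
                                      abs=1e-12)

    def test_direction_below(self):
        p, direction = signed_rank_test(np.array([0.2, 0.3, 0.1, 0.25, 0.4]))
        assert direction == "below"


class TestBenjaminiHochberg:
    def test_all_ones_no_rejections(self):
        assert not bh_adjust(np.ones(10)).any()

    def test_hand_computed_step_up(self):
        # p=[1e-5, 0.5] at fdr 1e-4: reject first only (1e-5 <= 0.5e-4)
        flags = bh_adjust(np.array([1e-5, 0.5]), fdr=1e-4)
        assert flags.tolist() == [True, False]

    def test_empty_input(self):
        assert bh_adjust(np.array([])).size == 0

    def test_bonferroni_subset_of_bh(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 13))
            p = rng.random(m) ** 3
            alpha = 0.05
            bonf = p <= alpha / m
            bh = bh_adjust(p, fdr=alpha)
            assert (bh | ~bonf).all()  # bonferroni rejections are in BH

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 20))) ** 4
            ours = bh_adjust(p, fdr=0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert np.array_equal(ours, ref)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.sampled_from([1e-4, 0.01, 0.05, 0.25]))
    def test_matches_brute_force_oracle(self, p_list, fdr):
        p = np.asarray(p_list)
        ps = np.sort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if ps[k - 1] <= k / m * fdr:
                k_star = k
        expected = p <= ps[k_star - 1] if k_star else np.zeros(m, bool)
        assert np.array_equal(bh_adjust(p, fdr=fdr), expected)


class TestMedianCI:
    def test_constant_values_zero_width(self):
        lo, hi = ci_segment_median(np.full(20, 3.3))
        assert lo == hi == 3.3

    def test_contains_sample_median(self, rng):
        for _ in range(20):
            vals = rng.normal(size=int(rng.integers(5, 50)))
            lo, hi = ci_segment_median(vals, rng=rng)
            assert lo <= np.median(vals) <= hi

    def test_coverage_near_nominal(self, rng):
        # N(0,1), n=100: 95% bootstrap CI should cover the true median 0
        # at about the nominal rate (+/- 3 points) over 500 replicates
        covered = 0
        for _ in range(500):
            vals = rng.normal(size=100)
            lo, hi = ci_segment_median(vals, n_boot=500, rng=rng)
            covered += lo <= 0.0 <= hi
        assert 0.92 <= covered / 500 <= 0.98

    def test_single_value_degenerate(self):
        assert ci_segment_median(np.array([4.0])) == (4.0, 4.0)


class TestDetectOnset:
    def _stat(self, t_min, reject, direction="above"):
        return SegmentStat(
            segment_id=f"t{t_min}", midpoint_time=t_min * 60.0, n_windows=60,
            median_normalized_mpr=2.0, ci_low=1.5, ci_high=2.5,
            p_value=0.001, direction=direction, bh_reject=reject)

    def test_earliest_rejected_segment(self):
        stats_ = [self._stat(5, False), self._stat(18, False),
                  self._stat(21, True), self._stat(30, True)]
        res = detect_onset(stats_)
        assert res.onset_time == pytest.approx(21.0)

    def test_no_rejections_gives_none(self):
        res = detect_onset([self._stat(20, False), self._stat(25, False)])
        assert res.onset_time is None

    def test_below_baseline_segment_ignored(self):
        res = detect_onset([self._stat(20, True, direction="below")])
        assert res.onset_time is None

    def test_baseline_period_segment_ignored(self):
        # a rejected segment inside the baseline window is not an onset
        res = detect_onset([self._stat(10, True), self._stat(25, True)])
        assert res.onset_time == pytest.approx(25.0)


class TestDriftFit:
    def test_exact_line(self):
        t = np.arange(16, 60, 1.0)
        fit = fit_drift(t, 14.0 - 0.02 * t)
        assert fit.slope == pytest.approx(-0.02, abs=1e-12)
        assert fit.slope_ci_high - fit.slope_ci_low < 1e-9

    def test_cutoff_excludes_early_points(self):
        t = np.array([5.0, 10.0, 20.0, 30.0, 40.0, 50.0])
        f = 14.0 - 0.02 * t
        f[:2] = 99.0  # garbage before the wash-in cutoff must not matter
        fit = fit_drift(t, f)
        assert fit.slope == pytest.approx(-0.02, abs=1e-9)
        assert fit.n_points == 4

    def test_band_edge_peaks_dropped(self):
        t = np.arange(16, 46, 1.0)
        f = 12.5 - 0.02 * (t - 16)
        f[5] = 10.0  # saturated at the lower search-band edge
        fit = fit_drift(t, f, band=(10.0, 14.0))
        assert 5 in fit.excluded_points
        assert fit.slope == pytest.approx(-0.02, abs=1e-9)

    def test_gross_outlier_screened(self):
        t = np.arange(16, 66, 1.0)
        f = 13.0 - 0.0241 * (t - 16)
        clean = fit_drift(t, f.copy()).slope
        f[20] += 3.0
        robust = fit_drift(t, f).slope
        assert robust == pytest.approx(clean, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_drift(np.array([20.0, 25.0]), np.array([12.0, 11.9]))

    def test_ci_coverage_and_unbiasedness(self):
        # slopes in the observed tremor range with tracking noise:
        # nominal-ish coverage and no detectable bias over 200 replicates
        cov = tk.drift_ci_coverage(n_replicates=200, seed=5)
        assert cov.coverage >= 0.90
        assert abs(cov.mean_slope_error) <= 2 * cov.se_slope_error
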