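"""Paired/Welch tests, group summaries, splits and the dropout table."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from nutricohort.endpoints import make_endpoints
from nutricohort.model import ClientProfile
from nutricohort.stats import (
    dropout_analysis,
    paired_test,
    split_analyses,
    summarize_group,
    two_sample_test,
)

from .conftest import make_client


class TestPairedTest:
    def test_closed_form_hand_example(self):
        """Differences {2,4,6,8}: mean 5, sd sqrt(20/3), d = 5/sd, t = 2d."""
        res = paired_test([12, 14, 16, 18], [10, 10, 10, 10])
        assert res.mean_diff == pytest.approx(5.0)
        assert res.sd_diff == pytest.approx(math.sqrt(20 / 3))
        assert res.effect_size_d == pytest.approx(5 / math.sqrt(20 / 3))
        assert res.t_statistic == pytest.approx(2 * res.effect_size_d)
        assert res.degrees_of_freedom == 3

    def test_zero_variance_flagged_degenerate(self):
        res = paired_test([5, 6, 7], [4, 5, 6])  # all diffs 1
        assert res.degenerate
        assert math.isnan(res.t_statistic) and math.isnan(res.p_value)

    def test_requires_paired_vectors(self):
        with pytest.raises(ValueError):
            paired_test([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            paired_test([1], [2])

    @given(
        n=st.integers(min_value=3, max_value=40),
        seed=st.integers(min_value=0, max_value=99_999),
    )
    def test_t_equals_d_root_n(self, n, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(10, 3, n)
        l = rng.normal(8, 3, n)
        res = paired_test(b, l)
        if not res.degenerate:
            assert res.t_statistic == pytest.approx(
                res.effect_size_d * math.sqrt(n), rel=1e-12
            )

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 50))
            b, l = rng.normal(size=n), rng.normal(size=n)
            res = paired_test(b, l)
            ref = sps.ttest_rel(b, l)
            assert res.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestTwoSampleTest:
    def test_identical_groups(self):
        res = two_sample_test([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_welch_formula(self):
        """{1,2,3} vs {4,5,6}: equal variances 1, se = sqrt(2/3), df = 4."""
        res = two_sample_test([1, 2, 3], [4, 5, 6])
        assert res.t_statistic == pytest.approx(-3.0 / math.sqrt(2 / 3))
        assert res.degrees_of_freedom == pytest.approx(4.0)

    def test_agrees_with_reference_implementation(self, rng):
        for _ in range(25):
            na, nb = int(rng.integers(3, 40)), int(rng.integers(3, 40))
            a, b = rng.normal(0, 1, na), rng.normal(0.3, 2, nb)
            res = two_sample_test(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert res.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            pooled = two_sample_test(a, b, welch=False)
            ref_p = sps.ttest_ind(a, b, equal_var=True)
            assert pooled.t_statistic == pytest.approx(ref_p.statistic, abs=1e-10)

    def test_double_zero_variance_degenerate(self):
        res = two_sample_test([2, 2, 2], [3, 3])
        assert res.degenerate and math.isnan(res.t_statistic)


def _ep(cid, base, locf, month=6, scale="bipolar"):
    return make_endpoints(cid, scale, base, locf, month)


class TestSummarizeGroup:
    def test_hand_built_five_clients(self):
        """Every summary field checked against direct arithmetic."""
        eps = [
            _ep("a", 20.0, 8.0),   # -60%: responder at both thresholds
            _ep("b", 10.0, 6.0),   # -40%: >30 only
            _ep("c", 30.0, 0.0),   # symptom-free
            _ep("d", 8.0, 10.0),   # worsened
            _ep("e", 12.0, 12.0),  # unchanged
        ]
        s = summarize_group(eps, "hand")
        base, locf = [20, 10, 30, 8, 12], [8, 6, 0, 10, 12]
        assert s.n == 5
        assert s.baseline_mean == pytest.approx(np.mean(base))
        assert s.baseline_median == 12.0 and s.locf_median == 8.0
        assert s.baseline_sd == pytest.approx(np.std(base, ddof=1))
        assert s.pct_change_of_means == pytest.approx(100 * (7.2 - 16.0) / 16.0)
        assert s.pct_change_of_medians == pytest.approx(100 * (8 - 12) / 12)
        assert s.frac_reduction_gt_30 == pytest.approx(3 / 5)
        assert s.frac_reduction_gt_50 == pytest.approx(2 / 5)
        assert s.frac_symptom_free == pytest.approx(1 / 5)
        assert s.frac_worsened == pytest.approx(1 / 5)
        assert s.median_pct_change == pytest.approx(-40.0)
        ref = sps.ttest_rel(base, locf)
        assert s.t_statistic == pytest.approx(ref.statistic)
        assert s.n_pct_undefined == 0

    def test_exact_fifty_percent_is_not_a_50_responder(self):
        eps = [_ep(c, 20.0, 10.0) for c in "abc"]
        s = summarize_group(eps, "edge")
        assert s.frac_reduction_gt_50 == 0.0
        assert s.frac_reduction_gt_30 == 1.0

    def test_zero_baseline_clients_counted_separately(self):
        eps = [_ep("a", 20.0, 5.0), _ep("b", 16.0, 4.0), _ep("z", 0.0, 2.0)]
        s = summarize_group(eps, "zb")
        assert s.n == 3 and s.n_pct_undefined == 1
        assert s.frac_reduction_gt_50 == pytest.approx(1.0)  # over the 2 defined

    def test_permutation_invariance(self, rng):
        eps = [_ep(f"c{i}", float(b), float(l)) for i, (b, l) in
               enumerate(rng.integers(1, 40, size=(12, 2)))]
        s1 = summarize_group(eps, "x")
        s2 = summarize_group([eps[i] for i in rng.permutation(12)], "x")
        assert s1 == s2

    def test_small_group_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_group([_ep("a", 10, 5)], "tiny")

    @given(seed=st.integers(min_value=0, max_value=9_999))
    def test_responder_fraction_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        eps = [_ep(f"c{i}", float(b), float(l)) for i, (b, l) in
               enumerate(rng.integers(0, 40, size=(10, 2)))]
        s = summarize_group(eps, "mono")
        assert s.frac_reduction_gt_50 <= s.frac_reduction_gt_30


def _profiles(eps, ages=None, sexes=None):
    out = {}
    for i, e in enumerate(eps):
        out[e.client_id] = ClientProfile(
            e.client_id,
            (ages or {}).get(e.client_id, 12),
            (sexes or {}).get(e.client_id, "male"),
            True,
            False,
        )
    return out


class TestSplits:
    def test_even_median_split_sizes(self):
        eps = [_ep(f"c{i:03d}", float(i + 1), float(i)) for i in range(120)]
        res = split_analyses(eps, _profiles(eps))
        sides = res["baseline_median"]["sides"]
        assert sides["above"].n == 60 and sides["below"].n == 60
        assert sides["below"].baseline_mean < sides["above"].baseline_mean
        assert res["baseline_median"]["tests"]["baseline"].p_value < 0.05

    def test_odd_n_median_client_goes_below(self):
        eps = [_ep(f"c{i}", float(10 + i), 5.0) for i in range(5)]
        sides = split_analyses(eps, _profiles(eps))["baseline_median"]["sides"]
        assert sides["below"].n == 3 and sides["above"].n == 2

    def test_tied_baselines_split_by_id_order(self):
        eps = [_ep(f"c{i}", 10.0, 5.0) for i in range(4)]
        sides = split_analyses(eps, _profiles(eps))["baseline_median"]["sides"]
        assert sides["below"].n == 2  # deterministic despite all-equal baselines

    def test_age_boundary_at_twelve(self):
        eps = [_ep("young", 10, 5), _ep("old", 10, 5),
               _ep("young2", 12, 6), _ep("old2", 12, 6)]
        ages = {"young": 11, "old": 12, "young2": 11, "old2": 17}
        res = split_analyses(eps, _profiles(eps, ages=ages))["age"]["sides"]
        assert res["older"].n == 2 and res["younger"].n == 2

    def test_sex_split_and_small_side_flagged(self):
        eps = [_ep(f"m{i}", 10 + i, 5) for i in range(4)] + [_ep("f0", 12, 6)]
        sexes = {"f0": "female"}
        res = split_analyses(eps, _profiles(eps, sexes=sexes))["sex"]
        assert res["sides"]["male"].n == 4
        assert res["sides"]["female"] is None  # one member: no summary
        assert res["tests"]["baseline"] is None


class TestDropout:
    def test_hand_built_table(self):
        """Eight clients spread over months 3-6, checked against hand sums."""
        eps = [
            _ep("a", 20, 10, month=3), _ep("b", 10, 8, month=3),   # -50, -20
            _ep("c", 30, 15, month=4), _ep("d", 10, 2, month=4),   # -50, -80
            _ep("e", 16, 4, month=5), _ep("f", 20, 16, month=5),   # -75, -20
            _ep("g", 10, 4, month=6), _ep("h", 20, 8, month=6),    # -60, -60
        ]
        res = dropout_analysis(eps)
        table = res["table"].set_index("last_month")
        assert list(table["n"]) == [2, 2, 2, 2]
        assert table.loc[3, "median_pct_reduction"] == pytest.approx(35.0)
        assert table.loc[4, "median_pct_reduction"] == pytest.approx(65.0)
        assert table.loc[6, "median_pct_reduction"] == pytest.approx(60.0)
        ref = sps.ttest_rel([20, 10], [10, 8])
        assert res["paired_tests"][3].t_statistic == pytest.approx(ref.statistic)
        # stop-at-3 baselines {20,10} vs continuing {30,10,16,20,10,20}
        svc = res["stop_vs_continue"][3]
        ref2 = sps.ttest_ind([20, 10], [30, 10, 16, 20, 10, 20], equal_var=False)
        assert svc.t_statistic == pytest.approx(ref2.statistic)

    def test_uniform_improvement_month_six(self):
        eps = [_ep(f"c{i}", 10.0 * (i + 1), 4.0 * (i + 1), month=6) for i in range(5)]
        table = dropout_analysis(eps)["table"].set_index("last_month")
        assert table.loc[6, "median_pct_reduction"] == pytest.approx(60.0)

    def test_empty_month_flagged_unavailable(self):
        eps = [_ep("a", 20, 10, month=3), _ep("b", 10, 5, month=3),
               _ep("c", 20, 10, month=6), _ep("d", 10, 5, month=6)]
        res = dropout_analysis(eps)
        table = res["table"].set_index("last_month")
        assert table.loc[5, "n"] == 0
        assert pd.isna(table.loc[5, "median_pct_reduction"])
        assert res["paired_tests"][5] is None
        assert res["stop_vs_continue"][5] is None
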