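"""Horizon 2x2, accuracy metrics, ROC/AUC, odds ratios, group tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from premicc.diagnostics import (
    ConfusionMatrix,
    compare_baseline,
    confusion_at_horizon,
    diagnostic_metrics,
    odds_ratio,
    roc_auc,
    wilson_interval,
)
from premicc.scoring import RiskClass

from conftest import tte
from test_scoring import make_record

MILD = RiskClass.MILD_PREDICTED
SEVERE = RiskClass.SEVERE_PREDICTED


class TestConfusionAtHorizon:
    def test_cell_assignment_rules(self):
        records = [
            tte("tp", 40.0, False, MILD),     # mild pred, mild course
            tte("fp", 10.0, True, MILD),      # mild pred, escalated
            tte("fn", 36.0, False, SEVERE),   # severe pred, mild course
            tte("tn", 10.0, True, SEVERE),    # severe pred, escalated
            tte("ex", 20.0, False, MILD),     # censored early: excluded
        ]
        cm = confusion_at_horizon(records, 36.0)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_event_after_horizon_counts_as_mild(self):
        cm = confusion_at_horizon([tte("a", 40.0, True, MILD)], 36.0)
        assert cm.tp == 1 and cm.total == 1

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_horizon([], 0.0)

    def test_missing_risk_class_rejected(self):
        with pytest.raises(ValueError, match="risk class"):
            confusion_at_horizon([tte("a", 10.0, True)], 36.0)


class TestDiagnosticMetrics:
    def test_published_triple_from_constructed_table(self):
        """tp=20, fn=2, fp=5, tn=18 reproduces sens 90.9%, spec 78.3%,
        PPV 80.0% (20/22, 18/23, 20/25)."""
        m = diagnostic_metrics(ConfusionMatrix(tp=20, fp=5, fn=2, tn=18))
        assert round(100 * m.sensitivity, 1) == 90.9
        assert round(100 * m.specificity, 1) == 78.3
        assert round(100 * m.ppv, 1) == 80.0

    def test_undefined_metric_is_none_not_zero(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=7))
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(0.7)

    def test_perfect_matrix(self):
        m = diagnostic_metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=9))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_ppv_prevalence_identity(self, tp, fp, fn, tn):
        """ppv = sens*P / (sens*P + (1-spec)(1-P)), P = prevalence."""
        m = diagnostic_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        total = tp + fp + fn + tn
        if total == 0 or m.sensitivity is None or m.specificity is None:
            return
        prev = (tp + fn) / total
        num = m.sensitivity * prev
        den = num + (1 - m.specificity) * (1 - prev)
        if den > 0 and m.ppv is not None:
            assert m.ppv == pytest.approx(num / den)


def auc_pairwise_oracle(pairs):
    """O(n^2) concordance count: mild scoring lower is concordant."""
    pos = [s for s, m in pairs if m]
    neg = [s for s, m in pairs if not m]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p < n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        pairs = [(0, True), (1, True), (5, False), (6, False)]
        assert roc_auc(pairs).auc == 1.0

    def test_all_ties(self):
        pairs = [(3, True), (3, False), (3, True), (3, False)]
        assert roc_auc(pairs).auc == 0.5

    def test_toy_set_matches_oracle(self):
        pairs = [(1, True), (1, False), (4, False), (0, True)]
        assert roc_auc(pairs).auc == pytest.approx(auc_pairwise_oracle(pairs))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([(1, True), (2, True)])

    def test_points_monotone_from_origin_to_one(self):
        pairs = [(s % 7, s % 3 == 0) for s in range(20)]
        res = roc_auc(pairs)
        xs = [p[0] for p in res.points]
        ys = [p[1] for p in res.points]
        assert res.points[0] == (0.0, 0.0)
        assert res.points[-1] == (1.0, 1.0)
        assert all(a <= b + 1e-12 for a, b in zip(xs, xs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(ys, ys[1:]))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 6), st.booleans()),
            min_size=2, max_size=30,
        )
    )
    def test_sweep_auc_equals_pairwise_concordance(self, pairs):
        classes = {m for _, m in pairs}
        if len(classes) < 2:
            return
        res = roc_auc(pairs)
        assert res.auc == pytest.approx(auc_pairwise_oracle(pairs))
        # and equals trapezoidal area under the sweep points
        xs = np.array([p[0] for p in res.points])
        ys = np.array([p[1] for p in res.points])
        assert res.auc == pytest.approx(float(np.trapezoid(ys, xs)))

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        totals = rng.integers(0, 7, size=80)
        mild = rng.random(80) < 0.4
        if mild.all() or not mild.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        ours = roc_auc(list(zip(totals.tolist(), mild.tolist()))).auc
        # negate the score so that low totals rank the positive class first
        ref = sk.roc_auc_score(mild, -totals)
        assert ours == pytest.approx(ref)


class TestOddsRatio:
    def test_symmetric_groups_give_one(self):
        assert odds_ratio(10, 20, 10, 20).odds_ratio == pytest.approx(1.0)

    def test_published_rates_counts(self):
        """70.2% of 113 vs 24.2% of 88 -> 79/113 vs 21/88 -> OR 7.41."""
        res = odds_ratio(79, 113, 21, 88)
        assert res.odds_ratio == pytest.approx((79 / 34) / (21 / 67))
        assert res.odds_ratio == pytest.approx(7.41, abs=0.01)
        assert res.ci_lower < res.odds_ratio < res.ci_upper

    def test_zero_cell_correction_is_finite(self):
        res = odds_ratio(5, 5, 0, 10)
        assert res.corrected
        assert math.isfinite(res.odds_ratio) and res.odds_ratio > 0

    def test_reciprocal_property(self):
        r1 = odds_ratio(30, 50, 10, 40)
        r2 = odds_ratio(10, 40, 30, 50)
        assert r1.odds_ratio == pytest.approx(1 / r2.odds_ratio)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio(0, 0, 5, 10)


class TestWilson:
    def test_contains_point_estimate(self):
        lo, hi = wilson_interval(18, 23)
        assert lo < 18 / 23 < hi
        assert 0 <= lo and hi <= 1


def group(n, **kw):
    return [make_record(pid=f"g{i}", **kw) for i in range(n)]


class TestCompareBaseline:
    def test_identical_groups_p_one(self):
        g = group(10, age=30, stenosis=True) + group(10, age=50)
        for var in ("age_years", "stenosis"):
            res = compare_baseline(g, list(g), var)
            assert res.p_value == pytest.approx(1.0)
            assert not res.significant

    def test_fisher_matches_hypergeometric_enumeration(self):
        """2x2 (1,9 / 5,2): two-sided Fisher p by exhaustive tail sum."""
        a = group(1, stenosis=True) + group(9)
        b = group(5, stenosis=True) + group(2)
        res = compare_baseline(a, b, "stenosis")
        assert res.test_name == "fisher_exact"
        # enumerate all tables with the same margins via hypergeom pmf
        rv = stats.hypergeom(17, 6, 10)  # N, successes, draws
        p0 = rv.pmf(1)
        exact = sum(rv.pmf(k) for k in range(7) if rv.pmf(k) <= p0 + 1e-12)
        assert res.p_value == pytest.approx(exact, rel=1e-6)

    def test_boundary_expected_cell_of_five_uses_chi_square(self):
        a = group(1, stenosis=True) + group(9)
        b = group(9, stenosis=True) + group(1)
        assert compare_baseline(a, b, "stenosis").test_name == "chi_square"

    def test_wilcoxon_matches_direct_rank_computation(self):
        a = [make_record(pid=f"a{i}", age=age) for i, age in enumerate((20, 25, 30))]
        b = [make_record(pid=f"b{i}", age=age) for i, age in enumerate((40, 45, 50))]
        res = compare_baseline(a, b, "age_years")
        assert res.test_name == "wilcoxon_rank_sum"
        # complete separation: U = 0 for group a over group b
        assert res.statistic == pytest.approx(0.0)

    def test_chi_square_used_for_large_expected_cells(self):
        a = group(40, stenosis=True) + group(40)
        b = group(15, stenosis=True) + group(65)
        res = compare_baseline(a, b, "stenosis")
        assert res.test_name == "chi_square"
        # cross-check statistic against an independent chi-square CDF
        table = np.array([[40, 40], [15, 65]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(chi2, 1)))

    def test_endoscopic_score_compared_as_dichotomy(self):
        a = group(10, endo=3)
        b = group(10, endo=1)
        res = compare_baseline(a, b, "endoscopic_score")
        assert res.p_value < 0.05 and res.significant

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_baseline([], group(3), "age_years")

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            compare_baseline(group(3), group(3), "height")
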