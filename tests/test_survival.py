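"""Product-limit estimator, Greenwood bands and log-rank test.

Checked against closed forms, a hand-computed product-limit table,
the no-censoring 1 - ECDF identity, and lifelines as an independent
reference implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premicc.survival import greenwood_ci, km_fit, logrank_test, survival_at

from conftest import tte


class TestKaplanMeier:
    def test_two_events_closed_form(self):
        curve = km_fit([tte("a", 1, True), tte("b", 2, True)])
        assert survival_at(curve, 1) == pytest.approx(0.5)
        assert survival_at(curve, 2) == pytest.approx(0.0)

    def test_hand_computed_toy_curve(self, toy_curve_records):
        # events at 2 and 4, censored at 3, 5, 5:
        # S(2) = 1 - 1/5 = 0.8 ; S(4) = 0.8 * (1 - 1/3) = 0.5333
        curve = km_fit(toy_curve_records)
        assert curve.event_times.tolist() == [2.0, 4.0]
        assert curve.at_risk.tolist() == [5, 3]
        assert curve.survival == pytest.approx([0.8, 0.8 * 2 / 3])

    def test_all_censored_survival_is_one(self):
        curve = km_fit([tte(str(i), i + 1.0, False) for i in range(4)])
        assert curve.event_times.size == 0
        assert survival_at(curve, 100.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_fit([])

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_fit([tte("a", 0.0, True)])

    def test_tied_event_and_censoring(self):
        # censored subject at t is still at risk at t
        curve = km_fit([tte("a", 2, True), tte("b", 2, False), tte("c", 5, False)])
        assert curve.at_risk.tolist() == [3]
        assert curve.survival == pytest.approx([2 / 3])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        times=st.lists(
            st.floats(min_value=0.1, max_value=100, allow_nan=False),
            min_size=1, max_size=30,
        )
    )
    def test_no_censoring_equals_one_minus_ecdf(self, times):
        records = [tte(str(i), t, True) for i, t in enumerate(times)]
        curve = km_fit(records)
        arr = np.asarray(times)
        for q in [0.0, 0.5, 1.0, 1.5]:
            t_eval = q * arr.max()
            ecdf = np.mean(arr <= t_eval)
            assert survival_at(curve, t_eval) == pytest.approx(1 - ecdf)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=60, allow_nan=False),
                st.booleans(),
            ),
            min_size=1, max_size=40,
        )
    )
    def test_matches_lifelines(self, data):
        lifelines = pytest.importorskip("lifelines")
        records = [tte(str(i), t, e) for i, (t, e) in enumerate(data)]
        curve = km_fit(records)
        kmf = lifelines.KaplanMeierFitter().fit(
            [t for t, _ in data], [e for _, e in data]
        )
        for t in {t for t, _ in data} | {0.0}:
            assert survival_at(curve, t) == pytest.approx(
                float(kmf.predict(t)), abs=1e-9
            )

    def test_survival_non_increasing(self, toy_curve_records):
        curve = km_fit(toy_curve_records)
        assert np.all(np.diff(curve.survival) <= 0)
        assert np.all(np.diff(curve.at_risk) < 0)

    def test_negative_time_lookup_rejected(self, toy_curve_records):
        with pytest.raises(ValueError):
            survival_at(km_fit(toy_curve_records), -1.0)

    def test_step_lookup_between_events(self, toy_curve_records):
        curve = km_fit(toy_curve_records)
        assert survival_at(curve, 3.0) == pytest.approx(0.8)
        assert survival_at(curve, 0.0) == 1.0


class TestGreenwood:
    def test_single_event_closed_form(self):
        n = 6
        records = [tte("e", 1.0, True)] + [
            tte(str(i), 2.0, False) for i in range(n - 1)
        ]
        curve = km_fit(records)
        s = 1 - 1 / n
        var = s**2 * (1 / (n * (n - 1)))
        assert curve.greenwood_se[0] == pytest.approx(np.sqrt(var))

    def test_toy_curve_matches_direct_formula(self, toy_curve_records):
        curve = km_fit(toy_curve_records)
        # cumulative Greenwood terms: 1/(5*4), then + 1/(3*2)
        v1 = 0.8**2 * (1 / 20)
        v2 = (0.8 * 2 / 3) ** 2 * (1 / 20 + 1 / 6)
        assert curve.greenwood_se == pytest.approx(np.sqrt([v1, v2]))

    def test_bands_contain_estimate_and_stay_in_unit_interval(
        self, toy_curve_records
    ):
        curve = greenwood_ci(km_fit(toy_curve_records), 0.95)
        assert np.all(curve.ci_lower <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_upper + 1e-12)
        assert np.all((curve.ci_lower >= 0) & (curve.ci_upper <= 1))

    def test_invalid_level_rejected(self, toy_curve_records):
        with pytest.raises(ValueError):
            greenwood_ci(km_fit(toy_curve_records), 1.5)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        g = [tte(str(i), t, True) for i, t in enumerate([1.0, 2.0, 3.0])]
        res = logrank_test(g, g)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_toy_hand_computation(self):
        """Group A events at 1,2 (n=2); B events at 3,4 (n=2).

        Hand O-E/V sums: E_A = 2/4 + 1/3 + 0 + 0 = 5/6, O_A = 2;
        V = (2*2*1*3)/(16*3) + (1*2*1*2)/(9*2) = 1/4 + 2/9 = 17/36.
        """
        a = [tte("a1", 1, True), tte("a2", 2, True)]
        b = [tte("b1", 3, True), tte("b2", 4, True)]
        res = logrank_test(a, b)
        expected_chi2 = (2 - 5 / 6) ** 2 / (17 / 36)
        assert res.chi_square == pytest.approx(expected_chi2)
        assert res.observed[0] == pytest.approx(2)
        assert res.expected[0] == pytest.approx(5 / 6)

    def test_symmetry(self, toy_curve_records):
        other = [tte("x", 1.0, True), tte("y", 6.0, False)]
        r1 = logrank_test(toy_curve_records, other)
        r2 = logrank_test(other, toy_curve_records)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_observed_minus_expected_sums_to_zero(self, toy_curve_records):
        other = [tte("x", 1.0, True), tte("y", 6.0, False)]
        res = logrank_test(toy_curve_records, other)
        assert (res.observed[0] - res.expected[0]) + (
            res.observed[1] - res.expected[1]
        ) == pytest.approx(0.0, abs=1e-10)

    def test_empty_group_rejected(self, toy_curve_records):
        with pytest.raises(ValueError):
            logrank_test([], toy_curve_records)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(
            st.tuples(st.floats(0.1, 50, allow_nan=False), st.booleans()),
            min_size=2, max_size=25,
        ),
        b=st.lists(
            st.tuples(st.floats(0.1, 50, allow_nan=False), st.booleans()),
            min_size=2, max_size=25,
        ),
    )
    def test_matches_lifelines_logrank(self, a, b):
        stats_mod = pytest.importorskip("lifelines.statistics")
        ga = [tte(f"a{i}", t, e) for i, (t, e) in enumerate(a)]
        gb = [tte(f"b{i}", t, e) for i, (t, e) in enumerate(b)]
        res = logrank_test(ga, gb)
        ref = stats_mod.logrank_test(
            [t for t, _ in a], [t for t, _ in b],
            event_observed_A=[e for _, e in a],
            event_observed_B=[e for _, e in b],
        )
        assert res.chi_square == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)


def test_km_consistency_under_exponential_censoring():
    """Mean KM estimate at t recovers exp(-lambda t) under
    administrative censoring (simulation consistency)."""
    rng = np.random.default_rng(42)
    lam, t_eval, admin = 0.0337, 36.0, 48.0
    estimates = []
    for _ in range(300):
        raw = rng.exponential(1 / lam, size=150)
        records = [
            tte(str(i), min(t, admin), t <= admin) for i, t in enumerate(raw)
        ]
        estimates.append(survival_at(km_fit(records), t_eval))
    truth = np.exp(-lam * t_eval)
    mc_se = np.std(estimates) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - truth) < 3 * mc_se + 1e-3
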