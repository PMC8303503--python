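"""Tertile split, log-rank test, two-group Cox fit and the screen itself.

The Cox fit is checked against an independent grid-search maximizer of the
naively written partial likelihood, and against lifelines; the log-rank
statistic against hand-tallied hypergeometric tables and its identity with
the Cox score test at beta = 0.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_survival
from gbmscreen.io_formats import GeneExpressionMatrix, SurvivalTable, ValidationError
from gbmscreen.survival_stats import (
    SKIP_DEGENERATE,
    GeneSurvivalResult,
    ScreenConfig,
    _cox_score_info,
    _risk_tables,
    cox_binary_fit,
    km_estimate,
    logrank_test,
    screen_features,
    select_differential,
    tertile_split,
)


# --- independent oracle: naive partial likelihood + grid search ------------


def naive_log_partial_likelihood(beta, t, e, x):
    """Direct product-form Cox partial likelihood (valid without ties)."""
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            denom = sum(np.exp(beta * x[j]) for j in range(len(t)) if t[j] >= t[i])
            ll += beta * x[i] - np.log(denom)
    return ll


def grid_search_beta(t, e, x, lo=-6.0, hi=6.0):
    coarse = np.linspace(lo, hi, 2401)
    lls = [naive_log_partial_likelihood(b, t, e, x) for b in coarse]
    b0 = coarse[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 801)
    lls = [naive_log_partial_likelihood(b, t, e, x) for b in fine]
    return fine[int(np.argmax(lls))]


def random_no_tie_instance(rng, n):
    """A small survival instance with distinct times, both groups and >= 1 event."""
    while True:
        t = np.round(rng.uniform(1, 100, n), 3)
        if len(np.unique(t)) < n:
            continue
        e = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n)
        if e.sum() == 0 or x.min() == x.max():
            continue
        return t, e, x


def as_survival(t, e):
    return make_survival([f"s{i}" for i in range(len(t))], t, e)


def as_labels(x):
    return {f"s{i}": int(v) for i, v in enumerate(x)}


# --- tertile split ---------------------------------------------------------


class TestTertileSplit:
    def test_one_to_nine(self):
        split = tertile_split({str(v): float(v) for v in range(1, 10)})
        assert split.low_samples == {"1", "2", "3"}
        assert split.high_samples == {"7", "8", "9"}
        assert split.p33 == pytest.approx(3.64)
        assert split.p66 == pytest.approx(6.28)

    def test_three_values(self):
        split = tertile_split({"a": 1.0, "b": 2.0, "c": 3.0})
        assert split.low_samples == {"a"}
        assert split.high_samples == {"c"}
        assert split.p33 == pytest.approx(1.66)
        assert split.p66 == pytest.approx(2.32)

    def test_constant_vector_degenerate(self):
        split = tertile_split({c: 5.0 for c in "abcd"})
        assert split.degenerate
        assert not split.high_samples and not split.low_samples

    def test_groups_disjoint_and_thresholds_ordered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = {f"s{i}": v for i, v in enumerate(rng.normal(0, 1, 30))}
            split = tertile_split(vals)
            assert not (split.high_samples & split.low_samples)
            assert split.p33 <= split.p66


# --- log-rank test ---------------------------------------------------------


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 1.0, 2.0]
        e = [1, 1, 1, 1]
        chi2, p = logrank_test({"s0": 1, "s1": 1, "s2": 0, "s3": 0}, as_survival(t, e))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_interleaved_events_hand_tally(self):
        # group A events at 1 and 3, group B at 2 and 4, no censoring
        sv = as_survival([1, 3, 2, 4], [1, 1, 1, 1])
        chi2, p = logrank_test({"s0": 1, "s1": 1, "s2": 0, "s3": 0}, sv)
        assert chi2 == pytest.approx(8 / 13)
        assert p == pytest.approx(stats.chi2.sf(8 / 13, 1))

    def test_single_risk_set(self):
        sv = as_survival([1, 2], [1, 0])
        chi2, p = logrank_test({"s0": 1, "s1": 0}, sv)
        assert chi2 == pytest.approx(1.0)
        assert p == pytest.approx(stats.chi2.sf(1.0, 1))

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            t, e, x = random_no_tie_instance(rng, 10)
            sv = as_survival(t, e)
            a = logrank_test(as_labels(x), sv)
            b = logrank_test(as_labels(1 - x), sv)
            assert a[0] == pytest.approx(b[0], abs=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test({"s0": 1, "s1": 0}, as_survival([1, 2], [0, 0]))

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        for _ in range(10):
            t, e, x = random_no_tie_instance(rng, 25)
            chi2, p = logrank_test(as_labels(x), as_survival(t, e))
            ref = ll_logrank(t[x == 1], t[x == 0], e[x == 1], e[x == 0])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_equals_cox_score_test_without_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t, e, x = random_no_tie_instance(rng, rng.integers(5, 30))
            order = np.argsort(t)
            ts, es, xs = t[order], e[order], x[order].astype(float)
            chi2, _ = logrank_test(as_labels(x), as_survival(t, e))
            d, d1, n_risk, n1_risk = _risk_tables(ts, es, xs)
            _, score, info = _cox_score_info(0.0, d, d1, n_risk, n1_risk, efron=True)
            if info > 0:
                assert abs(chi2 - score**2 / info) < 1e-8


# --- Cox binary fit --------------------------------------------------------


class TestCoxBinaryFit:
    def test_identical_groups_beta_zero(self):
        sv = as_survival([1, 2, 1, 2], [1, 1, 1, 1])
        beta, se, p = cox_binary_fit({"s0": 1, "s1": 1, "s2": 0, "s3": 0}, sv)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_interleaved_events_hand_maximum(self):
        sv = as_survival([1, 3, 2, 4], [1, 1, 1, 1])
        beta, _, _ = cox_binary_fit({"s0": 1, "s1": 1, "s2": 0, "s3": 0}, sv)
        ref = grid_search_beta(np.array([1, 3, 2, 4.0]), np.array([1, 1, 1, 1]), np.array([1, 1, 0, 0]))
        assert beta == pytest.approx(0.94, abs=0.005)
        assert abs(beta - ref) < 1e-4

    def test_label_swap_negates_beta(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            t, e, x = random_no_tie_instance(rng, 12)
            sv = as_survival(t, e)
            b1, _, p1 = cox_binary_fit(as_labels(x), sv)
            b2, _, p2 = cox_binary_fit(as_labels(1 - x), sv)
            if np.isnan(b1):
                assert np.isnan(b2)
                continue
            assert b1 == pytest.approx(-b2, abs=1e-7)
            assert p1 == pytest.approx(p2, abs=1e-9)

    def test_grid_search_oracle_small_no_tie_instances(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(120):
            t, e, x = random_no_tie_instance(rng, int(rng.integers(4, 9)))
            beta, _, _ = cox_binary_fit(as_labels(x), as_survival(t, e))
            if np.isnan(beta):  # monotone likelihood flagged, oracle diverges too
                continue
            ref = grid_search_beta(t, e, x)
            assert abs(beta - ref) < 1e-4
            checked += 1
        assert checked >= 30

    def test_monotone_likelihood_flagged_not_infinite(self):
        # every event in group 1, with group-1 members leaving the risk set first
        sv = as_survival([1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0])
        beta, se, p = cox_binary_fit(
            {"s0": 1, "s1": 1, "s2": 1, "s3": 0, "s4": 0, "s5": 0}, sv
        )
        assert np.isnan(beta) and np.isnan(p)

    def test_zero_events_rejected(self):
        with pytest.raises(ValidationError):
            cox_binary_fit({"s0": 1, "s1": 0}, as_survival([1, 2], [0, 0]))

    def test_efron_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(29)
        for _ in range(8):
            n = 30
            t = rng.integers(1, 10, n).astype(float)  # heavy ties
            e = rng.integers(0, 2, n)
            x = rng.integers(0, 2, n)
            if e.sum() < 2 or x.min() == x.max():
                continue
            beta, se, p = cox_binary_fit(as_labels(x), as_survival(t, e))
            if np.isnan(beta):
                continue
            cph = CoxPHFitter()
            cph.fit(pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
            assert beta == pytest.approx(cph.params_["x"], abs=5e-3)
            assert se == pytest.approx(cph.standard_errors_["x"], abs=5e-3)

    def test_breslow_equals_efron_without_ties(self):
        rng = np.random.default_rng(31)
        t, e, x = random_no_tie_instance(rng, 15)
        sv = as_survival(t, e)
        b_e, _, _ = cox_binary_fit(as_labels(x), sv, tie_method="efron")
        b_b, _, _ = cox_binary_fit(as_labels(x), sv, tie_method="breslow")
        assert b_e == pytest.approx(b_b, abs=1e-8)


# --- Kaplan-Meier ----------------------------------------------------------


class TestKMEstimate:
    def test_all_censored_flat_at_one(self):
        curve = km_estimate(as_survival([3, 7, 9], [0, 0, 0]))
        assert curve.event_times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_two_events_product_limit(self):
        curve = km_estimate(as_survival([1, 2], [1, 1]))
        assert curve.survival_at(1.0) == pytest.approx(0.5)
        assert curve.survival_at(2.0) == pytest.approx(0.0)

    def test_censoring_between_events(self):
        curve = km_estimate(as_survival([1, 2, 3], [1, 0, 1]))
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(37)
        t = np.round(rng.uniform(1, 50, 12), 2)
        curve = km_estimate(as_survival(t, np.ones(12, dtype=int)))
        for v in np.unique(t):
            assert curve.survival_at(v) == pytest.approx(np.mean(t > v))

    def test_survival_non_increasing_in_unit_interval(self):
        rng = np.random.default_rng(41)
        curve = km_estimate(as_survival(rng.exponential(5, 30) + 0.1, rng.integers(0, 2, 30)))
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))


# --- the screen and differential selection ---------------------------------


def expression_matrix(values):
    values = np.asarray(values, dtype=float)
    return GeneExpressionMatrix(
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
        "toy",
        scale="log_transformed",
    )


class TestScreen:
    def test_constant_feature_skipped_degenerate(self):
        rng = np.random.default_rng(43)
        vals = np.vstack([np.full(12, 3.0), rng.normal(0, 1, 12)])
        sv = make_survival([f"s{j}" for j in range(12)], rng.exponential(10, 12) + 1, np.ones(12))
        results = screen_features(expression_matrix(vals), sv)
        assert results[0].skip_reason == SKIP_DEGENERATE
        assert results[1].skip_reason is None

    def test_small_group_skipped(self):
        rng = np.random.default_rng(47)
        vals = rng.normal(0, 1, (1, 4))
        sv = make_survival([f"s{j}" for j in range(4)], [1, 2, 3, 4], [1, 1, 1, 1])
        results = screen_features(expression_matrix(vals), sv, ScreenConfig(min_group_size=2))
        assert results[0].skip_reason == "group too small"

    def test_no_overlap_errors(self):
        sv = make_survival(["x1", "x2", "x3"], [1, 2, 3], [1, 1, 1])
        with pytest.raises(ValidationError):
            screen_features(expression_matrix(np.ones((1, 3))), sv)

    def test_strong_marker_detected(self):
        rng = np.random.default_rng(53)
        n = 90
        expr = rng.normal(0, 1, n)
        # hazard increases with expression -> high group dies sooner
        t = rng.exponential(1.0 / (0.05 * np.exp(1.5 * expr)))
        sv = make_survival([f"s{j}" for j in range(n)], t, np.ones(n))
        results = screen_features(expression_matrix(expr.reshape(1, -1)), sv)
        r = results[0]
        assert r.beta > 0 and r.wald_p < 0.05 and r.logrank_p < 0.05
        plus, minus = select_differential(results)
        assert plus == {"g0"} and minus == set()


class TestSelectDifferential:
    def result(self, **kw):
        base = dict(
            feature_id="f", beta=0.5, se=0.1, wald_p=0.01, logrank_p=0.01,
            n_high=5, n_low=5, n_events=8, converged=True, skip_reason=None,
        )
        base.update(kw)
        return GeneSurvivalResult(**base)

    def test_requires_both_pvalues_below_alpha(self):
        plus, minus = select_differential([self.result(logrank_p=0.04, wald_p=0.06)])
        assert plus == set() and minus == set()

    def test_plus_assignment(self):
        plus, minus = select_differential([self.result(wald_p=0.01, logrank_p=0.01, beta=0.5)])
        assert plus == {"f"} and minus == set()

    def test_minus_assignment_and_disjoint(self):
        results = [
            self.result(feature_id="up", beta=1.0),
            self.result(feature_id="down", beta=-1.0),
        ]
        plus, minus = select_differential(results)
        assert plus == {"up"} and minus == {"down"}
        assert not plus & minus

    def test_beta_exactly_zero_in_neither(self):
        plus, minus = select_differential([self.result(beta=0.0)])
        assert plus == set() and minus == set()

    def test_skipped_and_nonconverged_excluded(self):
        results = [
            self.result(feature_id="skipped", skip_reason="degenerate split"),
            self.result(feature_id="diverged", converged=False),
        ]
        plus, minus = select_differential(results)
        assert plus == set() and minus == set()
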