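"""Per-feature survival screen: tertile split, log-rank test, two-group Cox fit.

For each feature (gene or pathway activation level) the screen compares the
samples above the 66th percentile against those below the 33rd percentile —
the middle tertile is discarded — with a two-group Cox proportional hazards
fit (Wald p-value on the log hazard ratio) and a log-rank test. A feature is
"differential" when BOTH p-values fall below alpha; differential features
are split into *plus* (log HR > 0, higher expression -> higher hazard) and
*minus* (log HR < 0) sets by the sign of the coefficient.

The Cox partial likelihood for a single binary covariate is maximized by
Newton-Raphson with Efron tie handling by default (Breslow available). The
log-rank statistic uses the standard hypergeometric variance at each
distinct event time. Both are written against numpy primitives so the
screen stays fast across tens of thousands of features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .io_formats import SurvivalTable, ValidationError

logger = logging.getLogger(__name__)

MAX_ABS_BETA = 20.0  # beyond this the likelihood is monotone for all purposes
_NEWTON_TOL = 1e-10
_NEWTON_MAXITER = 50

SKIP_DEGENERATE = "degenerate split"
SKIP_SMALL_GROUP = "group too small"
SKIP_NO_EVENTS = "no events"


@dataclass
class ScreenConfig:
    """Settings of the dual-threshold tertile screen."""

    alpha: float = 0.05
    low_pct: float = 33.0
    high_pct: float = 66.0
    min_group_size: int = 2
    tie_method: Literal["efron", "breslow"] = "efron"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if not 0 <= self.low_pct < self.high_pct <= 100:
            raise ValidationError("need 0 <= low_pct < high_pct <= 100")
        if self.tie_method not in ("efron", "breslow"):
            raise ValidationError(f"unknown tie method {self.tie_method!r}")


@dataclass
class TertileSplit:
    """High/low expression groups of one feature.

    Membership uses strict inequalities against the percentile thresholds,
    so a constant feature yields two empty groups (``degenerate``).
    """

    high_samples: set[str]
    low_samples: set[str]
    p33: float
    p66: float

    @property
    def degenerate(self) -> bool:
        return not self.high_samples or not self.low_samples


@dataclass
class GeneSurvivalResult:
    """Screen output for one feature (high-vs-low two-group comparison)."""

    feature_id: str
    beta: float = np.nan  # log hazard ratio, high vs low
    se: float = np.nan
    wald_p: float = np.nan
    logrank_p: float = np.nan
    n_high: int = 0
    n_low: int = 0
    n_events: int = 0
    converged: bool = False
    skip_reason: str | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""

    event_times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk at each event time
    censor_times: np.ndarray  # times of censored records

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


# ---------------------------------------------------------------------------
# Tertile split
# ---------------------------------------------------------------------------


def tertile_split(
    values: dict[str, float] | "Sequence[float]",
    config: ScreenConfig | None = None,
    sample_ids: Sequence[str] | None = None,
) -> TertileSplit:
    """Split samples into high (> 66th pct) and low (< 33rd pct) groups.

    Percentiles are computed by linear interpolation of order statistics
    (index ``(n - 1) * q / 100``).
    """
    config = config or ScreenConfig()
    if isinstance(values, dict):
        sample_ids = list(values.keys())
        arr = np.asarray(list(values.values()), dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if sample_ids is None:
            sample_ids = [str(i) for i in range(len(arr))]
    if len(arr) < 3 or not np.all(np.isfinite(arr)):
        raise ValidationError("tertile split needs >= 3 finite values")
    p33, p66 = np.percentile(arr, [config.low_pct, config.high_pct])
    ids = np.asarray(sample_ids, dtype=object)
    return TertileSplit(
        high_samples=set(ids[arr > p66]),
        low_samples=set(ids[arr < p33]),
        p33=float(p33),
        p66=float(p66),
    )


# ---------------------------------------------------------------------------
# Log-rank test and Cox fit on pre-sorted arrays (internal hot path)
# ---------------------------------------------------------------------------


def _risk_tables(t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Per-distinct-event-time counts; ``t`` must be ascending.

    Returns (d, d1, n_risk, n1_risk): total deaths, group-1 deaths, total
    at risk and group-1 at risk at each distinct event time.
    """
    ev = e == 1
    te = t[ev]
    xe = x[ev]
    ut = np.unique(te)
    idx = np.searchsorted(t, ut, side="left")
    n = len(t)
    suffix_x = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
    n_risk = (n - idx).astype(float)
    n1_risk = suffix_x[idx]
    lo = np.searchsorted(te, ut, side="left")
    hi = np.searchsorted(te, ut, side="right")
    d = (hi - lo).astype(float)
    cxe = np.concatenate([[0.0], np.cumsum(xe)])
    d1 = cxe[hi] - cxe[lo]
    return d, d1, n_risk, n1_risk


def _logrank_sorted(t: np.ndarray, e: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    d, d1, n_risk, n1_risk = _risk_tables(t, e, x)
    frac = n1_risk / n_risk
    observed = d1.sum()
    expected = (d * frac).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    variance = np.nansum(np.where(n_risk > 1, var_terms, 0.0))
    if variance <= 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_score_info(
    beta: float,
    d: np.ndarray,
    d1: np.ndarray,
    n_risk: np.ndarray,
    n1_risk: np.ndarray,
    efron: bool,
) -> tuple[float, float, float]:
    """Log partial likelihood, score and information at ``beta`` (binary x)."""
    w = np.exp(beta)
    n0_risk = n_risk - n1_risk
    if not efron:
        # Breslow: one denominator per event time, weighted by death count.
        S0 = n0_risk + n1_risk * w
        p = n1_risk * w / S0
        ll = float((d1 * beta).sum() - (d * np.log(S0)).sum())
        score = float(d1.sum() - (d * p).sum())
        info = float((d * p * (1.0 - p)).sum())
        return ll, score, info
    # Efron correction subtracts a graded share of the tied deaths from
    # the risk-set sums: l/d for l = 0..d-1.
    dmax = int(d.max())
    frac = np.arange(dmax) / d[:, None]  # shape (times, dmax)
    valid = np.arange(dmax) < d[:, None]
    S0 = n0_risk[:, None] + n1_risk[:, None] * w - frac * ((d - d1)[:, None] + d1[:, None] * w)
    S1 = n1_risk[:, None] * w - frac * (d1[:, None] * w)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, S1 / S0, 0.0)
        logS0 = np.where(valid, np.log(np.where(valid, S0, 1.0)), 0.0)
    ll = float((d1 * beta).sum() - logS0.sum())
    score = float(d1.sum() - p.sum())
    info = float((p * (1.0 - p)).sum())
    return ll, score, info


def _cox_sorted(
    t: np.ndarray, e: np.ndarray, x: np.ndarray, tie_method: str = "efron"
) -> tuple[float, float, float, bool]:
    """Newton-Raphson fit of the two-group Cox model on sorted arrays.

    Returns (beta, se, wald_p, converged). Monotone-likelihood instances
    (|beta| runs away) are flagged not converged with NaN statistics.
    """
    d, d1, n_risk, n1_risk = _risk_tables(t, e, x)
    efron = tie_method == "efron"
    beta = 0.0
    for _ in range(_NEWTON_MAXITER):
        _, score, info = _cox_score_info(beta, d, d1, n_risk, n1_risk, efron)
        if info <= 0:
            return np.nan, np.nan, np.nan, False
        step = score / info
        beta += np.clip(step, -2.0, 2.0)  # damped step; full Newton near optimum
        if abs(beta) > MAX_ABS_BETA:
            return np.nan, np.nan, np.nan, False
        if abs(step) < _NEWTON_TOL:
            break
    else:
        return np.nan, np.nan, np.nan, False
    _, _, info = _cox_score_info(beta, d, d1, n_risk, n1_risk, efron)
    if info <= 0:
        return np.nan, np.nan, np.nan, False
    se = 1.0 / np.sqrt(info)
    z = beta / se
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), float(se), wald_p, True


def _aligned_sorted_arrays(group_labels: dict[str, int], survival: SurvivalTable):
    ids = [s for s in survival.sample_ids if s in group_labels]
    if not ids:
        raise ValidationError("no overlap between group labels and survival records")
    t, e = survival.arrays_for(ids)
    x = np.asarray([group_labels[s] for s in ids], dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValidationError("group labels must be binary 0/1")
    if x.min() == x.max():
        raise ValidationError("both groups must be non-empty")
    order = np.argsort(t, kind="mergesort")
    return t[order], e[order], x[order]


# ---------------------------------------------------------------------------
# Public single-feature operations
# ---------------------------------------------------------------------------


def logrank_test(group_labels: dict[str, int], survival: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t, e, x = _aligned_sorted_arrays(group_labels, survival)
    if e.sum() == 0:
        raise ValidationError("log-rank test undefined with zero events")
    return _logrank_sorted(t, e, x)


def cox_binary_fit(
    group_labels: dict[str, int],
    survival: SurvivalTable,
    tie_method: str = "efron",
) -> tuple[float, float, float]:
    """Cox PH fit of a single binary covariate; returns (beta, se, wald_p).

    Raises on zero events; monotone-likelihood / non-converged fits return
    NaNs (checked via ``np.isnan``).
    """
    if tie_method not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie method {tie_method!r}")
    t, e, x = _aligned_sorted_arrays(group_labels, survival)
    if e.sum() == 0:
        raise ValidationError("Cox fit undefined with zero events")
    beta, se, wald_p, _ = _cox_sorted(t, e, x, tie_method)
    return beta, se, wald_p


def km_estimate(survival: SurvivalTable) -> KMCurve:
    """Kaplan-Meier product-limit estimator (lifelines-backed).

    Records censored at an event time are counted at risk for that time
    (the standard convention).
    """
    from lifelines import KaplanMeierFitter

    if len(survival) == 0:
        raise ValidationError("empty survival table")
    t = survival.data["time"].to_numpy()
    e = survival.data["event"].to_numpy()
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    ev_times = np.unique(t[e == 1])
    surv = np.asarray([float(kmf.predict(v)) for v in ev_times])
    order = np.argsort(t, kind="mergesort")
    ts = t[order]
    at_risk = np.asarray([np.sum(ts >= v) for v in ev_times], dtype=int)
    return KMCurve(
        event_times=ev_times,
        survival=surv,
        at_risk=at_risk,
        censor_times=np.sort(t[e == 0]),
    )


# ---------------------------------------------------------------------------
# The screen
# ---------------------------------------------------------------------------


def screen_features(matrix, survival: SurvivalTable, config: ScreenConfig | None = None) -> list[GeneSurvivalResult]:
    """Run the tertile high-vs-low Cox + log-rank screen over every feature.

    ``matrix`` is any feature x sample container exposing ``feature_ids``,
    ``sample_ids`` and ``values`` (log-transformed expression or pathway
    activation levels). Percentiles are computed over the samples that
    carry survival records for the endpoint being screened. Features with
    a degenerate split, an undersized group or zero usable events are
    returned with an explicit ``skip_reason`` instead of statistics.
    """
    config = config or ScreenConfig()
    have = set(matrix.sample_ids)
    ids = [s for s in survival.sample_ids if s in have]
    if not ids:
        raise ValidationError("no samples shared between matrix and survival table")
    col_of = {s: j for j, s in enumerate(matrix.sample_ids)}
    cols = np.asarray([col_of[s] for s in ids])
    t, e = survival.arrays_for(ids)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    values = np.asarray(matrix.values, dtype=float)[:, cols][:, order]

    p_lo, p_hi = np.percentile(values, [config.low_pct, config.high_pct], axis=1)
    results: list[GeneSurvivalResult] = []
    for i, fid in enumerate(matrix.feature_ids):
        row = values[i]
        high = row > p_hi[i]
        low = row < p_lo[i]
        n_high, n_low = int(high.sum()), int(low.sum())
        res = GeneSurvivalResult(feature_id=fid, n_high=n_high, n_low=n_low)
        if n_high == 0 or n_low == 0:
            res.skip_reason = SKIP_DEGENERATE
            results.append(res)
            continue
        if min(n_high, n_low) < config.min_group_size:
            res.skip_reason = SKIP_SMALL_GROUP
            results.append(res)
            continue
        sel = high | low
        ts, es, xs = t[sel], e[sel], high[sel].astype(float)
        n_events = int(es.sum())
        res.n_events = n_events
        if n_events == 0:
            res.skip_reason = SKIP_NO_EVENTS
            results.append(res)
            continue
        chi2, lr_p = _logrank_sorted(ts, es, xs)
        beta, se, wald_p, conv = _cox_sorted(ts, es, xs, config.tie_method)
        res.logrank_p = lr_p
        res.beta, res.se, res.wald_p, res.converged = beta, se, wald_p, conv
        results.append(res)
    return results


def select_differential(
    results: Sequence[GeneSurvivalResult], config: ScreenConfig | None = None
) -> tuple[set[str], set[str]]:
    """Partition differential features into (plus_set, minus_set).

    A feature is differential when both the Wald and the log-rank p-value
    are below alpha; plus/minus by the strict sign of the log hazard ratio.
    """
    config = config or ScreenConfig()
    plus: set[str] = set()
    minus: set[str] = set()
    for r in results:
        if r.skip_reason is not None or not r.converged:
            continue
        if np.isnan(r.wald_p) or np.isnan(r.logrank_p):
            continue
        if r.wald_p < config.alpha and r.logrank_p < config.alpha:
            if r.beta > 0:
                plus.add(r.feature_id)
            elif r.beta < 0:
                minus.add(r.feature_id)
    return plus, minus


def screened_universe(results: Sequence[GeneSurvivalResult]) -> set[str]:
    """Features that actually entered the tests (not skipped)."""
    return {r.feature_id for r in results if r.skip_reason is None}


def results_to_frame(results: Sequence[GeneSurvivalResult]):
    """Tabulate screen results (one row per feature) for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "feature": [r.feature_id for r in results],
            "beta": [r.beta for r in results],
            "hr": [r.hr for r in results],
            "wald_p": [r.wald_p for r in results],
            "logrank_p": [r.logrank_p for r in results],
            "n_high": [r.n_high for r in results],
            "n_low": [r.n_low for r in results],
            "n_events": [r.n_events for r in results],
            "skip_reason": [r.skip_reason or "" for r in results],
        }
    )
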