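"""Product-limit survival estimation and the two-sample log-rank test.

Both are implemented from first principles (they are the analytic core
of the validation, so the arithmetic is explicit and unit-tested
against independent oracles rather than delegated):

* Kaplan-Meier product-limit estimator
      S(t) = prod_{t_i <= t} (1 - d_i / n_i)
  over the distinct event times t_i, with d_i events among n_i at
  risk.  Ties are resolved with events preceding censorings at equal
  times, so a patient censored at t_i is still at risk at t_i.

* Greenwood variance
      Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
  with confidence bands on the log(-log S) scale, clipped to [0, 1].

* Unweighted two-sample log-rank test: at every distinct event time
  the observed events in group 1 are compared with the expectation
  d * n_1/n under the hypergeometric model, with variance
  d (n_1/n)(n_2/n)(n - d)/(n - 1); the statistic
  (O_1 - E_1)^2 / V is referred to chi-square with 1 df
  (upper tail, no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .events import TimeToEventRecord

__all__ = [
    "SurvivalCurve",
    "LogRankResult",
    "km_fit",
    "survival_at",
    "greenwood_ci",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate tabulated at the distinct event times.

    ``n_initial`` is the number of subjects entering follow-up;
    ``survival[i]`` is S(event_times[i]); S(t) = 1 for t before the
    first event time.  ``greenwood_se`` is the Greenwood standard
    error of S at each event time; the confidence bands are computed
    on the log(-log) scale at ``ci_level``.
    """

    event_times: np.ndarray  # ascending, d_i > 0 at each
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_initial: int
    ci_level: float = 0.95


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def _as_arrays(records: Sequence[TimeToEventRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray([r.time_months for r in records], dtype=float)
    events = np.asarray([r.event for r in records], dtype=bool)
    if times.size and times.min() <= 0:
        raise ValueError("all event/censoring times must be > 0")
    return times, events


def _risk_table(
    times: np.ndarray, events: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distinct event times with at-risk and event counts.

    A subject with time t is at risk at t (events precede censorings
    at tied times).
    """
    etimes = np.unique(times[events])
    # at risk at t: everyone whose time is >= t
    order = np.sort(times)
    n_at_risk = len(times) - np.searchsorted(order, etimes, side="left")
    d = np.array([np.sum((times == t) & events) for t in etimes])
    return etimes, n_at_risk.astype(int), d.astype(int)


def km_fit(
    records: Sequence[TimeToEventRecord], ci_level: float = 0.95
) -> SurvivalCurve:
    """Fit the Kaplan-Meier product-limit estimator.

    Parameters
    ----------
    records : sequence of TimeToEventRecord
        Nonempty; all times strictly positive.
    ci_level : float
        Confidence level for the Greenwood log(-log) bands.
    """
    if len(records) == 0:
        raise ValueError("km_fit requires at least one record")
    times, events = _as_arrays(records)
    etimes, n_at_risk, d = _risk_table(times, events)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / n_at_risk)
    curve = SurvivalCurve(
        event_times=etimes,
        at_risk=n_at_risk,
        events=d,
        survival=surv,
        greenwood_se=np.zeros_like(surv),
        ci_lower=surv.copy(),
        ci_upper=surv.copy(),
        n_initial=len(records),
        ci_level=ci_level,
    )
    return greenwood_ci(curve, ci_level)


def greenwood_ci(curve: SurvivalCurve, level: float = 0.95) -> SurvivalCurve:
    """Attach Greenwood standard errors and log(-log) confidence bands.

    Var[S(t)] = S(t)^2 * sum d_i / (n_i (n_i - d_i)); at times where
    S has dropped to 0 the variance terms are degenerate and the band
    collapses to [0, 0].
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    n, d, surv = curve.at_risk, curve.events, curve.survival
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d.astype(float))), np.inf)
        cum = np.cumsum(terms)
        se = np.where(surv > 0, surv * np.sqrt(cum), 0.0)
    z = stats.norm.ppf(0.5 + level / 2.0)
    lower = np.zeros_like(surv)
    upper = np.zeros_like(surv)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, s in enumerate(surv):
            if s <= 0.0:
                lower[i] = upper[i] = 0.0
            elif s >= 1.0:
                lower[i] = upper[i] = 1.0
            else:
                # log(-log) transform preserves the [0, 1] range
                sd_loglog = np.sqrt(cum[i]) / abs(np.log(s))
                lower[i] = s ** np.exp(z * sd_loglog)
                upper[i] = s ** np.exp(-z * sd_loglog)
    return replace(
        curve,
        greenwood_se=se,
        ci_lower=np.clip(lower, 0.0, 1.0),
        ci_upper=np.clip(upper, 0.0, 1.0),
        ci_level=level,
    )


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Right-continuous step evaluation of S at time ``t``.

    Before the first event time S = 1; between event times the value
    at the earlier event time carries forward.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    idx = np.searchsorted(curve.event_times, t, side="right")
    if idx == 0:
        return 1.0
    return float(curve.survival[idx - 1])


def logrank_test(
    a: Sequence[TimeToEventRecord], b: Sequence[TimeToEventRecord]
) -> LogRankResult:
    """Unweighted two-sample log-rank test.

    At each distinct pooled event time the events in group ``a`` are
    compared with their hypergeometric expectation; the summed
    O - E over its variance gives a chi-square statistic with 1 df.
    Symmetric in its arguments.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("logrank_test requires two nonempty groups")
    ta, ea = _as_arrays(a)
    tb, eb = _as_arrays(b)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    etimes = np.unique(times[events])

    sa, sb = np.sort(ta), np.sort(tb)
    o1 = e1 = o2 = e2 = v = 0.0
    for t in etimes:
        n1 = len(sa) - np.searchsorted(sa, t, side="left")
        n2 = len(sb) - np.searchsorted(sb, t, side="left")
        n = n1 + n2
        d1 = float(np.sum((ta == t) & ea))
        d2 = float(np.sum((tb == t) & eb))
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        o1 += d1
        o2 += d2
        e1 += d * n1 / n
        e2 += d * n2 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi_square=float(chi2),
        p_value=p,
        observed=(o1, o2),
        expected=(e1, e2),
    )
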