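"""Kaplan-Meier progression-free-survival curves and the log-rank test.

Times are months from surgery; an event is documented haematogenous
metastasis (progression), and patients without one are right-censored at
last follow-up. The product-limit estimator uses the standard tie
convention: at equal times, events precede censorings, so censored subjects
at an event time are still in the risk set for that event. The two-group
log-rank statistic accumulates observed-minus-expected events with the
hypergeometric variance at each distinct event time and is referred to a
chi-square distribution with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "KmCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "pfs_by_biomarker",
]


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) evaluated at the distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray  # events at each time
    survival: np.ndarray  # S(t) just after each event time
    n: int

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("nan")


@dataclass
class LogRankResult:
    observed: np.ndarray  # events per group
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


def _check_times(times: np.ndarray) -> None:
    if len(times) == 0:
        raise ValidationError("need at least one record")
    if np.any(times < 0) or not np.isfinite(times).all():
        raise ValidationError("times must be finite and non-negative")


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is a boolean/0-1 vector (True = progression observed). With no
    censoring the curve equals the empirical survival function; with all
    subjects censored, S is identically 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    _check_times(t)
    if len(e) != len(t):
        raise ValidationError("times and events differ in length")
    event_times = np.unique(t[e])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    d = np.array([((t == u) & e).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(event_times, at_risk, d, surv, n=len(t))


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time j with d_j total events, n_j subjects at
    risk and n_1j of them in group 1, the group-1 expectation is
    d_j * n_1j / n_j with hypergeometric variance; the statistic
    (O_1 - E_1)^2 / V is chi-square with 1 df. Group observed and expected
    event counts sum to the same total, and the statistic is invariant under
    relabeling.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    _check_times(t)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    in1 = g == labels[0]

    event_times = np.unique(t[e])
    o1 = e1 = v = 0.0
    for u in event_times:
        at_risk = t >= u
        n_j = at_risk.sum()
        n1_j = (at_risk & in1).sum()
        d_j = ((t == u) & e).sum()
        d1_j = ((t == u) & e & in1).sum()
        o1 += d1_j
        e1 += d_j * n1_j / n_j
        if n_j > 1:
            v += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    total = float(e.sum())
    if v == 0.0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - e1) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        observed=np.array([o1, total - o1]),
        expected=np.array([e1, total - e1]),
        statistic=float(chi2),
        df=1,
        p_value=p,
    )


def logrank_permutation_p(
    times, events, groups, n_permutations: int = 2000, seed: int = 0
) -> float:
    """Permutation p-value for the log-rank statistic (label reshuffling);
    used to validate the chi-square reference distribution."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    obs = logrank_test(t, e, g).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(g)
        if logrank_test(t, e, perm).statistic >= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def pfs_by_biomarker(
    sample_table: pd.DataFrame,
    labels: dict[str, bool] | pd.Series,
) -> tuple[KmCurve, KmCurve, LogRankResult]:
    """Progression-free survival stratified by biomarker positivity.

    ``labels`` maps sample ids (all patients with survival data) to
    positivity from :func:`exomir.biomarker_performance.dichotomize`.
    Returns (positive-group curve, negative-group curve, log-rank result).
    """
    labels = pd.Series(labels, dtype=bool)
    df = sample_table.set_index("sample_id")
    missing = [s for s in labels.index if s not in df.index]
    if missing:
        raise ValidationError(f"labels for unknown samples: {missing}")
    sub = df.loc[labels.index]
    bad = sub.index[sub["pfs_months"].isna()].tolist()
    if bad:
        raise ValidationError(f"samples missing survival fields: {bad}")
    t = sub["pfs_months"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=bool)
    pos = labels.to_numpy()
    km_pos = km_estimate(t[pos], e[pos])
    km_neg = km_estimate(t[~pos], e[~pos])
    lr = logrank_test(t, e, np.where(pos, "positive", "negative"))
    return km_pos, km_neg, lr
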