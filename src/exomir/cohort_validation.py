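"""Validation-cohort expression comparison and clinical statistics.

Group comparisons of relative expression (2^-dCt) use the Mann-Whitney U
test; paired tumour/adjacent tissue uses the Wilcoxon signed-rank test;
contingency tables of clinico-pathological parameters use Pearson chi-square
(no continuity correction) or Fisher's exact test; mean +/- SD readouts use
Student's t test.

Exact (permutation) p-values for the rank tests are computed here from the
full permutation distribution of the midrank sum, via a subset-sum dynamic
program that is exact under ties; the two-sided exact p is
min(1, 2*min(lower tail, upper tail)). Large-sample modes delegate to
scipy.stats (tie-corrected normal approximation, no continuity correction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CensoredInputError,
    InsufficientDataError,
    ValidationError,
)
from .discovery_screen import relative_expression
from .qpcr_io import CtMatrix

__all__ = [
    "ExpressionVector",
    "GroupComparison",
    "ContingencyTable",
    "cohort_expression",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "paired_direction_count",
    "chi_square",
    "fisher_exact",
    "student_t",
    "adjust_pvalues",
]


@dataclass
class ExpressionVector:
    """Per-sample relative expression 2^-(Ct_assay - Ct_reference)."""

    assay_id: str
    reference_id: str
    values: pd.Series  # indexed by sample id, uncensored samples only
    n_censored: int
    groups: pd.Series | None = None  # optional group label per retained sample

    def split(self, group_a: str, group_b: str) -> tuple[np.ndarray, np.ndarray]:
        if self.groups is None:
            raise ValidationError("no group labels attached")
        a = self.values[self.groups == group_a].to_numpy()
        b = self.values[self.groups == group_b].to_numpy()
        return a, b


@dataclass
class GroupComparison:
    method: str  # mann_whitney | wilcoxon | student_t
    mode: str  # exact | normal | pooled | welch
    statistic: float
    n1: int
    n2: int
    p_value: float
    summary1: float = math.nan  # median (rank tests) or mean (t test)
    summary2: float = math.nan


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("contingency table must be 2-dimensional")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)) or np.any(
                self.counts < 0
            ):
                raise ValidationError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)


def _as_counts(t) -> np.ndarray:
    if isinstance(t, ContingencyTable):
        return t.counts
    return ContingencyTable(np.asarray(t)).counts


def cohort_expression(m: CtMatrix, assay: str, reference: str) -> ExpressionVector:
    """Per-sample relative expression of ``assay`` against ``reference``.

    Samples where the assay is censored are omitted and counted; a censored
    reference anywhere is an error (references must be fully detected).
    """
    for a in (assay, reference):
        if a not in m.ct.index:
            raise ValidationError(f"assay {a!r} not in matrix")
    if m.censored.loc[reference].any():
        bad = list(m.censored.loc[reference][m.censored.loc[reference]].index)
        raise CensoredInputError(f"reference {reference!r} censored in samples {bad}")
    keep = ~m.censored.loc[assay]
    vals = pd.Series(
        {
            s: relative_expression(m.value(assay, s), m.value(reference, s))
            for s in m.sample_ids
            if keep[s]
        },
        dtype=float,
    )
    return ExpressionVector(
        assay_id=assay,
        reference_id=reference,
        values=vals,
        n_censored=int((~keep).sum()),
    )


# ---------------------------------------------------------------------------
# exact permutation machinery (midrank subset-sum dynamic program)


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    return np.rint(2.0 * stats.rankdata(values)).astype(np.int64)


def _subset_sum_counts(items: np.ndarray, k: int) -> np.ndarray:
    """counts[s] = number of size-k subsets of ``items`` with sum s (integers)."""
    total = int(items.sum())
    dp = np.zeros((k + 1, total + 1))
    dp[0, 0] = 1.0
    for idx, r in enumerate(items):
        r = int(r)
        kmax = min(k, idx + 1)
        for kk in range(kmax, 0, -1):
            dp[kk, r:] += dp[kk - 1, : total + 1 - r]
    return dp[k]


def _two_sided_from_counts(counts: np.ndarray, obs: int, n_total: float) -> float:
    p_le = counts[: obs + 1].sum() / n_total
    p_ge = counts[obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(
    x,
    y,
    mode: str = "auto",
    exact_limit: int = 25,
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    ``mode='exact'`` enumerates the permutation distribution of the midrank
    sum (valid under ties) and requires n1 + n2 <= ``exact_limit``;
    ``mode='normal'`` uses the tie-corrected normal approximation without
    continuity correction; ``'auto'`` picks exact when it is affordable.
    The reported U counts tied cross-pairs as 1/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise InsufficientDataError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    med1, med2 = float(np.median(x)), float(np.median(y))
    if np.all(combined == combined[0]):
        warnings.warn("all values identical across both groups", stacklevel=2)
        return GroupComparison(
            "mann_whitney", "degenerate", n1 * n2 / 2.0, n1, n2, 1.0, med1, med2
        )
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if mode == "auto":
        mode = "exact" if n1 + n2 <= exact_limit else "normal"
    if mode == "exact":
        if n1 + n2 > exact_limit:
            raise InsufficientDataError(
                f"exact mode limited to n1+n2 <= {exact_limit}, got {n1 + n2}"
            )
        r2 = _doubled_midranks(combined)
        counts = _subset_sum_counts(r2, n1)
        obs = int(np.rint(2.0 * ranks[:n1].sum()))
        p = _two_sided_from_counts(counts, obs, math.comb(n1 + n2, n1))
    elif mode == "normal":
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=False, method="asymptotic"
        )
        p = float(res.pvalue)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return GroupComparison("mann_whitney", mode, u1, n1, n2, p, med1, med2)


def wilcoxon_signed_rank(
    pairs,
    mode: str = "auto",
    exact_limit: int = 20,
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired values.

    ``pairs`` is an (n, 2) array of (tumour, adjacent) values or a sequence
    of such 2-tuples. Zero differences are dropped (Wilcoxon convention).
    Exact mode enumerates all sign assignments of the |difference| midranks
    (up to ``exact_limit`` non-zero pairs); normal mode delegates to the
    tie-corrected normal approximation without continuity correction. The
    statistic is min(W+, W-).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array of value pairs")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", stacklevel=2)
        return GroupComparison("wilcoxon", "degenerate", 0.0, len(arr), len(arr), 1.0)
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    stat = min(w_pos, w_neg)

    if mode == "auto":
        mode = "exact" if n <= exact_limit else "normal"
    if mode == "exact":
        if n > exact_limit:
            raise InsufficientDataError(
                f"exact mode limited to {exact_limit} non-zero pairs, got {n}"
            )
        r2 = np.rint(2.0 * ranks).astype(np.int64)
        total = int(r2.sum())
        dp = np.zeros(total + 1)
        dp[0] = 1.0
        for r in r2:
            r = int(r)
            dp[r:] += dp[: total + 1 - r]
        obs = int(np.rint(2.0 * w_pos))
        p = _two_sided_from_counts(dp, obs, 2.0**n)
    elif mode == "normal":
        res = stats.wilcoxon(
            d, correction=False, alternative="two-sided", method="approx"
        )
        p = float(res.pvalue)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return GroupComparison("wilcoxon", mode, stat, n, n, p)


def paired_direction_count(pairs) -> tuple[int, int]:
    """Count pairs whose tumour/adjacent ratio is below 1 (down-regulated in
    tumour). Ratios of exactly 1 are not counted as down."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValidationError("pairs must be a non-empty (n, 2) array")
    if np.any(arr <= 0):
        raise ValidationError("expression values must be positive")
    ratios = arr[:, 0] / arr[:, 1]
    return int((ratios < 1.0).sum()), len(ratios)


def chi_square(t) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table, no continuity correction.

    Returns (statistic, df, upper-tail p). All expected counts must be
    positive (no zero margin).
    """
    counts = _as_counts(t)
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValidationError("contingency table has a zero margin")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(t) -> float:
    """Two-sided Fisher exact p for a 2x2 table, summing hypergeometric
    probabilities not exceeding the observed table's. A zero margin gives
    p = 1 (only one table is possible)."""
    counts = _as_counts(t)
    if counts.shape != (2, 2):
        raise ValidationError(f"Fisher exact supports 2x2 tables, got {counts.shape}")
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def student_t(x, y, equal_var: bool = True) -> GroupComparison:
    """Two-sided two-sample t test: pooled-variance (classic Student) by
    default, Welch with ``equal_var=False``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("t test needs >= 2 values per group")
    mode = "pooled" if equal_var else "welch"
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        warnings.warn("zero variance in both groups", stacklevel=2)
        equal_means = x.mean() == y.mean()
        return GroupComparison(
            "student_t",
            "degenerate",
            0.0 if equal_means else math.inf,
            len(x),
            len(y),
            1.0 if equal_means else 0.0,
            float(x.mean()),
            float(y.mean()),
        )
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        "student_t",
        mode,
        float(res.statistic),
        len(x),
        len(y),
        float(res.pvalue),
        float(x.mean()),
        float(y.mean()),
    )


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; no adjustment is
    applied anywhere by default)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float))
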