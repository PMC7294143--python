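"""ROC analysis, optimal cut-off selection, dichotomization and
metastatic-site association for candidate biomarkers.

The ROC curve is built over thresholds at the unique observed scores (plus
-inf), with positivity defined as score strictly greater than the threshold;
a score equal to the cut-off is negative. AUC is computed by the
Mann-Whitney identity U / (n_pos * n_neg), counting ties as 1/2, which
coincides with trapezoidal integration of the empirical curve. The optimal
cut-off maximizes Youden's J = sensitivity + specificity - 1, with ties
broken toward higher specificity, then the higher cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .qpcr_io import MET_SITES

__all__ = [
    "RocCurve",
    "CutoffResult",
    "roc_curve",
    "optimal_cutoff",
    "dichotomize",
    "site_association",
]


@dataclass
class RocCurve:
    thresholds: np.ndarray  # -inf followed by the unique observed scores, ascending
    sensitivity: np.ndarray  # P(pos > t) per threshold
    specificity: np.ndarray  # P(neg <= t) per threshold
    auc: float
    scores_pos: np.ndarray
    scores_neg: np.ndarray

    @property
    def n_pos(self) -> int:
        return len(self.scores_pos)

    @property
    def n_neg(self) -> int:
        return len(self.scores_neg)


@dataclass
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    tp: int  # positives among cases
    fn: int
    fp: int  # positives among controls
    tn: int


def roc_curve(scores_pos, scores_neg) -> RocCurve:
    """Empirical ROC of case scores against control scores.

    AUC is the probability that a random case outranks a random control
    (ties counted 1/2), computed from the rank sum.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both score groups must be non-empty")
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([pos, neg]))])
    sens = np.array([(pos > t).mean() for t in thresholds])
    spec = np.array([(neg <= t).mean() for t in thresholds])
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))
    return RocCurve(thresholds, sens, spec, auc, pos, neg)


def optimal_cutoff(roc: RocCurve, criterion: str = "youden") -> CutoffResult:
    """Pick the cut-off maximizing Youden's J (default) or minimizing the
    distance to the perfect corner (0, 1) in (1-specificity, sensitivity)
    space (``criterion='closest'``). Ties break toward higher specificity,
    then the higher cut-off. Positivity is score > cutoff."""
    if criterion == "youden":
        objective = roc.sensitivity + roc.specificity - 1.0
    elif criterion == "closest":
        objective = -np.hypot(1.0 - roc.sensitivity, 1.0 - roc.specificity)
    else:
        raise ValidationError(f"unknown cutoff criterion {criterion!r}")
    order = sorted(
        range(len(roc.thresholds)),
        key=lambda i: (objective[i], roc.specificity[i], roc.thresholds[i]),
    )
    best = order[-1]
    cut = float(roc.thresholds[best])
    tp = int((roc.scores_pos > cut).sum())
    fp = int((roc.scores_neg > cut).sum())
    sens = float(roc.sensitivity[best])
    spec = float(roc.specificity[best])
    return CutoffResult(
        cutoff=cut,
        sensitivity=sens,
        specificity=spec,
        youden_j=sens + spec - 1.0,
        tp=tp,
        fn=roc.n_pos - tp,
        fp=fp,
        tn=roc.n_neg - fp,
    )


def dichotomize(scores, cutoff: float) -> np.ndarray:
    """Positivity labels: True iff score is strictly greater than the cut-off."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    return np.asarray(scores, dtype=float) > cutoff


def site_association(
    labels: dict[str, bool] | pd.Series,
    met_sites: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-site counts of biomarker-positive/-negative metastatic patients.

    ``labels`` maps metastatic patients to positivity; ``met_sites`` maps
    each of them to their documented metastatic sites. A patient with
    several sites contributes to every one of their site rows, so row sums
    can exceed the patient count.
    """
    labels = pd.Series(labels, dtype=bool)
    site_order = ["liver", "lung", "bone", "brain", "skin_soft_tissue"]
    counts = {s: [0, 0] for s in site_order}
    for patient, label in labels.items():
        sites = met_sites.get(patient, [])
        bad = set(sites) - MET_SITES
        if bad:
            raise ValidationError(f"patient {patient!r}: unknown sites {sorted(bad)}")
        for s in sites:
            counts[s][0 if label else 1] += 1
    return pd.DataFrame(
        [[s, counts[s][0], counts[s][1]] for s in site_order],
        columns=["site", "positive", "negative"],
    ).set_index("site")
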