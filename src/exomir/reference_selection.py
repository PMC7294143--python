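"""Internal-control (reference assay) selection by detectability and
coefficient of variation.

Exosomal miRNA qPCR has no standard endogenous control, so candidate
reference assays are ranked by how stably they are expressed across the
cohort: a candidate must be detected (uncensored) in every sample, abundant
enough (mean Ct at or below a ceiling), and have the lowest coefficient of
variation CV% = 100 * SD / mean on the Ct scale. SD uses the sample (n-1)
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InsufficientDataError, SelectionError, ValidationError
from .qpcr_io import CtMatrix

__all__ = [
    "ReferenceCandidate",
    "compute_cv",
    "cv_percent",
    "evaluate_candidates",
    "select_references",
]


@dataclass
class ReferenceCandidate:
    assay_id: str
    n_samples: int
    detect_fraction: float
    mean_ct: float
    sd_ct: float
    cv_percent: float


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, 100 * sd / mean (mean must be > 0)."""
    if not mean > 0:
        raise DomainError(f"CV undefined for non-positive mean {mean!r}")
    if sd < 0:
        raise DomainError(f"negative SD {sd!r}")
    return 100.0 * sd / mean


def compute_cv(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and CV% of a vector of Ct values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError(f"need >= 2 values for a CV, got {v.size}")
    if not np.isfinite(v).all():
        raise InsufficientDataError("non-finite value in CV input")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return mean, sd, cv_percent(mean, sd)


def evaluate_candidates(m: CtMatrix, candidates: list[str]) -> list[ReferenceCandidate]:
    """Summarize each candidate reference over all cohort samples.

    Mean/SD/CV are computed over uncensored values only; ``detect_fraction``
    is the proportion of samples where the candidate was detected. Result is
    sorted ascending by CV%.
    """
    out: list[ReferenceCandidate] = []
    n = len(m.sample_ids)
    for a in candidates:
        if a not in m.ct.index:
            raise ValidationError(f"candidate assay {a!r} not in matrix")
        cen = m.censored.loc[a]
        vals = m.ct.loc[a][~cen].to_numpy(dtype=float)
        detect = len(vals) / n if n else 0.0
        if len(vals) >= 2:
            mean, sd, cv = compute_cv(vals)
        elif len(vals) == 1:
            mean, sd, cv = float(vals[0]), float("nan"), float("nan")
        else:
            mean = sd = cv = float("nan")
        out.append(ReferenceCandidate(a, n, detect, mean, sd, cv))
    return sorted(out, key=lambda c: (np.isnan(c.cv_percent), c.cv_percent))


def select_references(
    cands: list[ReferenceCandidate],
    k: int = 2,
    max_mean_ct: float = 35.0,
    require_full_detection: bool = True,
) -> list[str]:
    """Pick the ``k`` most stable eligible candidates.

    Eligible: detected in every sample (a single undetermined reading
    disqualifies, unless ``require_full_detection`` is off) and mean Ct at or
    below ``max_mean_ct`` (abundance). Among eligible candidates the smallest
    CV% wins; ties break toward the lower mean Ct (more abundant), then
    lexicographic assay id. Output is independent of input order.
    """
    if k < 1:
        raise SelectionError(f"k must be >= 1, got {k}")
    eligible = [
        c
        for c in cands
        if (c.detect_fraction >= 1.0 or not require_full_detection)
        and np.isfinite(c.cv_percent)
        and c.mean_ct <= max_mean_ct
    ]
    if len(eligible) < k:
        raise SelectionError(
            f"only {len(eligible)} of {len(cands)} candidates eligible, need {k}"
        )
    eligible.sort(key=lambda c: (c.cv_percent, c.mean_ct, c.assay_id))
    return [c.assay_id for c in eligible[:k]]
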