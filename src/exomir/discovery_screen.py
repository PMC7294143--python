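"""Paired discovery screen on the profiling panel.

Three matched case/control serum pairs are profiled on the full miRNA panel.
Per pair, an assay censored ("undetermined", Ct > 40) in *both* members is
excluded; the assays surviving every pair form the common detected set. For
each retained assay, pair and reference, the fold change of the case over
the control is the comparative-Ct quantity

    FC = 2^-(dCt_case - dCt_control),   dCt = Ct_target - Ct_reference,

so one cycle less than the reference doubles relative expression (lower Ct
means more template). Cross-pair averages are called up-/down-regulated
against configurable ratio thresholds, and the consensus is the intersection
of the calls under each reference normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CensoredInputError, ValidationError
from .qpcr_io import CtMatrix

__all__ = [
    "PairDesign",
    "FoldChangeRecord",
    "ConsensusResult",
    "read_pairs",
    "filter_pair_detected",
    "common_detected",
    "relative_expression",
    "pair_fold_change",
    "average_fold_change",
    "call_directions",
    "consensus_overlap",
    "run_discovery",
]

DEFAULT_UP_THRESHOLD = 1.5
DEFAULT_DOWN_THRESHOLD = 1.0 / 1.5


@dataclass(frozen=True)
class PairDesign:
    pair_id: str
    case_sample: str
    control_sample: str

    def __post_init__(self):
        if self.case_sample == self.control_sample:
            raise ValidationError(
                f"pair {self.pair_id!r}: case and control are the same sample"
            )


@dataclass
class FoldChangeRecord:
    assay_id: str
    pair_id: str  # or "average"
    reference_id: str
    delta_ct_case: float
    delta_ct_control: float
    fold_change: float
    imputed: bool = False


@dataclass
class ConsensusResult:
    """Per-reference direction calls and their intersection."""

    up_by_reference: dict[str, list[str]]
    down_by_reference: dict[str, list[str]]
    consensus_up: list[str]
    consensus_down: list[str]
    up_threshold: float
    down_threshold: float


def read_pairs(path: str | Path) -> list[PairDesign]:
    """Read a pair design CSV with columns pair_id, case_sample, control_sample."""
    df = pd.read_csv(path, dtype=str)
    for col in ("pair_id", "case_sample", "control_sample"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return [
        PairDesign(r.pair_id, r.case_sample, r.control_sample)
        for r in df.itertuples(index=False)
    ]


def _check_pair(m: CtMatrix, pair: PairDesign) -> None:
    for s in (pair.case_sample, pair.control_sample):
        if s not in m.ct.columns:
            raise ValidationError(f"pair {pair.pair_id!r}: sample {s!r} not in matrix")


def filter_pair_detected(m: CtMatrix, pair: PairDesign) -> list[str]:
    """Target assays detected in at least one member of the pair.

    An assay censored in both the case and the control is excluded (its
    expression is too low to analyse); censored in only one member it is
    retained. Spike-ins are never returned.
    """
    _check_pair(m, pair)
    both = m.censored[pair.case_sample] & m.censored[pair.control_sample]
    targets = set(m.target_assays)
    return [a for a in m.assay_ids if a in targets and not both[a]]


def common_detected(m: CtMatrix, pairs: list[PairDesign]) -> list[str]:
    """Intersection of the per-pair detected sets, in matrix assay order."""
    if not pairs:
        raise ValidationError("need at least one pair")
    keep = None
    for p in pairs:
        s = set(filter_pair_detected(m, p))
        keep = s if keep is None else keep & s
    if not keep:
        warnings.warn("no assay detected in every pair", stacklevel=2)
        return []
    return [a for a in m.assay_ids if a in keep]


def relative_expression(ct_target: float, ct_reference: float) -> float:
    """2^-(Ct_target - Ct_reference): relative abundance of the target vs the
    reference within one sample."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise CensoredInputError("relative_expression requires finite Ct values")
    return float(2.0 ** -(ct_target - ct_reference))


def pair_fold_change(
    m: CtMatrix,
    assay: str,
    pair: PairDesign,
    reference: str,
    impute_ct: float = 40.0,
) -> FoldChangeRecord:
    """Case/control fold change for one assay, pair and reference.

    A censored target reading (in at most one pair member, by the detection
    filter) is imputed at ``impute_ct`` and the record flagged; a censored
    reference is a hard error since references must be fully detected.
    """
    _check_pair(m, pair)
    for a in (assay, reference):
        if a not in m.ct.index:
            raise ValidationError(f"assay {a!r} not in matrix")
    imputed = False
    cts = {}
    for role, s in (("case", pair.case_sample), ("control", pair.control_sample)):
        if m.is_censored(reference, s):
            raise CensoredInputError(
                f"reference {reference!r} censored in sample {s!r}"
            )
        if m.is_censored(assay, s):
            t = impute_ct
            imputed = True
        else:
            t = m.value(assay, s)
        cts[role] = t - m.value(reference, s)
    fc = float(2.0 ** -(cts["case"] - cts["control"]))
    return FoldChangeRecord(
        assay_id=assay,
        pair_id=pair.pair_id,
        reference_id=reference,
        delta_ct_case=cts["case"],
        delta_ct_control=cts["control"],
        fold_change=fc,
        imputed=imputed,
    )


def average_fold_change(
    records: list[FoldChangeRecord], geometric: bool = False
) -> FoldChangeRecord:
    """Cross-pair average fold change for one assay under one reference.

    Arithmetic mean of the per-pair ratios by default (the scale on which
    screen tables are usually reported); geometric mean optionally.
    """
    if not records:
        raise ValidationError("no records to average")
    assays = {r.assay_id for r in records}
    refs = {r.reference_id for r in records}
    if len(assays) != 1 or len(refs) != 1:
        raise ValidationError(
            f"records mix assays {sorted(assays)} / references {sorted(refs)}"
        )
    fcs = np.array([r.fold_change for r in records], dtype=float)
    fc = float(np.exp(np.mean(np.log(fcs)))) if geometric else float(fcs.mean())
    return FoldChangeRecord(
        assay_id=records[0].assay_id,
        pair_id="average",
        reference_id=records[0].reference_id,
        delta_ct_case=float(np.mean([r.delta_ct_case for r in records])),
        delta_ct_control=float(np.mean([r.delta_ct_control for r in records])),
        fold_change=fc,
        imputed=any(r.imputed for r in records),
    )


def call_directions(
    avg_records: list[FoldChangeRecord],
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Partition cross-pair averages into up (FC >= up_threshold), down
    (FC <= down_threshold) and uncalled."""
    if not (up_threshold > 1.0 > down_threshold > 0.0):
        raise ValidationError(
            f"need up_threshold > 1 > down_threshold > 0, got "
            f"({up_threshold}, {down_threshold})"
        )
    up = [r.assay_id for r in avg_records if r.fold_change >= up_threshold]
    down = [r.assay_id for r in avg_records if r.fold_change <= down_threshold]
    return up, down


def consensus_overlap(
    calls_by_reference: dict[str, tuple[list[str], list[str]]],
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> ConsensusResult:
    """Intersect the up/down calls across reference normalizations.

    An assay is a consensus biomarker only if every reference agrees on its
    direction; the consensus lists are therefore disjoint.
    """
    if len(calls_by_reference) < 2:
        raise ValidationError("consensus needs >= 2 reference normalizations")
    refs = list(calls_by_reference)
    up_sets = [set(calls_by_reference[r][0]) for r in refs]
    down_sets = [set(calls_by_reference[r][1]) for r in refs]
    first_up = calls_by_reference[refs[0]][0]
    first_down = calls_by_reference[refs[0]][1]
    cons_up = [a for a in first_up if all(a in s for s in up_sets)]
    cons_down = [a for a in first_down if all(a in s for s in down_sets)]
    return ConsensusResult(
        up_by_reference={r: list(calls_by_reference[r][0]) for r in refs},
        down_by_reference={r: list(calls_by_reference[r][1]) for r in refs},
        consensus_up=cons_up,
        consensus_down=cons_down,
        up_threshold=up_threshold,
        down_threshold=down_threshold,
    )


def run_discovery(
    m: CtMatrix,
    pairs: list[PairDesign],
    references: list[str],
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    impute_ct: float = 40.0,
    geometric: bool = False,
) -> dict:
    """Full screen: detection filter, per-pair and average fold changes under
    every reference, direction calls, and the cross-reference consensus.

    Returns a dict with ``detected_per_pair`` (pair_id -> assay list),
    ``common`` (assay list), ``records`` (all per-pair and average
    FoldChangeRecords), ``averages`` (reference -> assay -> record),
    ``calls`` (reference -> (up, down)) and ``consensus``.
    """
    detected = {p.pair_id: filter_pair_detected(m, p) for p in pairs}
    common = common_detected(m, pairs)
    records: list[FoldChangeRecord] = []
    averages: dict[str, dict[str, FoldChangeRecord]] = {}
    calls: dict[str, tuple[list[str], list[str]]] = {}
    common_nonref = [a for a in common if a not in references]
    for ref in references:
        averages[ref] = {}
        avg_records = []
        for assay in common_nonref:
            per_pair = [pair_fold_change(m, assay, p, ref, impute_ct) for p in pairs]
            records.extend(per_pair)
            avg = average_fold_change(per_pair, geometric=geometric)
            records.append(avg)
            averages[ref][assay] = avg
            avg_records.append(avg)
        calls[ref] = call_directions(avg_records, up_threshold, down_threshold)
    consensus = consensus_overlap(calls, up_threshold, down_threshold)
    return {
        "detected_per_pair": detected,
        "common": common,
        "records": records,
        "averages": averages,
        "calls": calls,
        "consensus": consensus,
    }


def records_to_frame(records: list[FoldChangeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "assay_id": r.assay_id,
                "reference_id": r.reference_id,
                "pair_id": r.pair_id,
                "delta_ct_case": r.delta_ct_case,
                "delta_ct_control": r.delta_ct_control,
                "fold_change": r.fold_change,
                "imputed": r.imputed,
            }
            for r in records
        ],
        columns=[
            "assay_id",
            "reference_id",
            "pair_id",
            "delta_ct_case",
            "delta_ct_control",
            "fold_change",
            "imputed",
        ],
    )
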