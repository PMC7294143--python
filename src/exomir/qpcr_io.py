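"""Reading, validation, censoring, spike-in QC and inter-plate calibration of
qPCR-panel Ct matrices.

The central object is :class:`CtMatrix`: an assay x sample grid of
quantification-cycle (Ct) values with a parallel boolean censoring grid.
Panels report an assay that fails to cross the fluorescence threshold by the
final cycle as "Undetermined"; here any cell equal to that token, empty, or
with Ct above ``ct_max`` (default 40, strict inequality) is flagged censored.

Spike-in assays monitor the wet-lab steps: UniSp2/4/5 the RNA extraction,
UniSp6 and cel-miR-39-5p the reverse transcription, and UniSp3 serves as the
inter-plate calibrator (IPC). Classification is by assay name; a panel layout
YAML can override it and assign samples to plates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    CalibrationError,
    FormatError,
    ParseError,
    QcError,
    ValidationError,
)

__all__ = [
    "CtMatrix",
    "QcFlag",
    "QcReport",
    "classify_assay",
    "read_ct_matrix",
    "write_ct_matrix",
    "interplate_calibrate",
    "spikein_qc",
    "read_sample_table",
    "validate_sample_table",
    "read_panel_layout",
    "GROUP_METASTASIS",
    "GROUP_NON_METASTASIS",
    "MET_SITES",
    "SPIKEIN_CLASSES",
]

GROUP_METASTASIS = "metastasis"
GROUP_NON_METASTASIS = "non_metastasis"
MET_SITES = frozenset({"liver", "lung", "bone", "brain", "skin_soft_tissue"})

#: assay-name -> class for the standard panel spike-ins; everything else is a target
SPIKEIN_CLASSES: dict[str, str] = {
    "unisp2": "extraction_spikein",
    "unisp4": "extraction_spikein",
    "unisp5": "extraction_spikein",
    "unisp6": "rt_spikein",
    "cel-mir-39-5p": "rt_spikein",
    "unisp3": "ipc",
}

ASSAY_CLASSES = ("target", "extraction_spikein", "rt_spikein", "ipc")


def classify_assay(assay_id: str) -> str:
    """Classify an assay by name: spike-in classes for UniSp2..6 / cel-miR-39-5p
    (case-insensitive, IPC triplicates like ``UniSp3_2`` included), else target."""
    name = assay_id.strip().lower()
    base = name.split("_")[0] if name.startswith("unisp") else name
    return SPIKEIN_CLASSES.get(base, "target")


@dataclass
class CtMatrix:
    """Assay x sample grid of Ct values with censoring flags.

    ``ct`` holds the numeric value where one was reported, including values
    above the censoring threshold; cells censored without a numeric reading
    (the "Undetermined" token or an empty cell) are NaN. ``censored`` is a
    parallel boolean grid with identical index/columns.
    """

    ct: pd.DataFrame
    censored: pd.DataFrame
    plate_of_sample: dict[str, str] = field(default_factory=dict)
    assay_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.plate_of_sample:
            self.plate_of_sample = {s: "plate1" for s in self.ct.columns}
        if not self.assay_class:
            self.assay_class = {a: classify_assay(a) for a in self.ct.index}

    @property
    def assay_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def target_assays(self) -> list[str]:
        return [a for a in self.ct.index if self.assay_class.get(a) == "target"]

    def assays_of_class(self, cls: str) -> list[str]:
        return [a for a in self.ct.index if self.assay_class.get(a) == cls]

    def value(self, assay: str, sample: str) -> float:
        return float(self.ct.at[assay, sample])

    def is_censored(self, assay: str, sample: str) -> bool:
        return bool(self.censored.at[assay, sample])

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            ct=self.ct.copy(),
            censored=self.censored.copy(),
            plate_of_sample=dict(self.plate_of_sample),
            assay_class=dict(self.assay_class),
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on violation."""
        if not self.ct.index.equals(self.censored.index) or not self.ct.columns.equals(
            self.censored.columns
        ):
            raise ValidationError("ct and censored grids have mismatched dimensions")
        if self.ct.index.has_duplicates:
            dups = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate assay ids: {dups}")
        if self.ct.columns.has_duplicates:
            dups = self.ct.columns[self.ct.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        uncensored = ~self.censored.to_numpy()
        vals = self.ct.to_numpy()
        bad = uncensored & ~(np.isfinite(vals) & (vals > 0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"uncensored cell ({self.ct.index[i]}, {self.ct.columns[j]}) "
                f"is not a finite positive Ct: {vals[i, j]!r}"
            )
        missing = set(self.ct.columns) - set(self.plate_of_sample)
        if missing:
            raise ValidationError(f"samples without a plate assignment: {sorted(missing)}")
        for a, c in self.assay_class.items():
            if c not in ASSAY_CLASSES:
                raise ValidationError(f"unknown assay class {c!r} for assay {a!r}")


def _is_undetermined(cell: str, token: str) -> bool:
    s = cell.strip()
    return s == "" or s.lower() == token.strip().lower() or s.lower() == "undetermined"


def read_ct_matrix(
    path: str | Path,
    undetermined_token: str = "Undetermined",
    ct_max: float = 40.0,
    layout: str | Path | None = None,
) -> CtMatrix:
    """Read a delimited Ct matrix (rows = assays, columns = samples).

    The delimiter is chosen by extension (``.tsv`` -> tab, else comma). Cells
    equal to the undetermined token (case-insensitive), empty, or with a
    numeric Ct strictly greater than ``ct_max`` are marked censored; a Ct of
    exactly ``ct_max`` is kept. Any other non-numeric cell raises
    :class:`ParseError` naming the cell.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows) < 2:
        raise FormatError(f"{path}: no data rows")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged row {i + 1} (expected {width} fields, got {len(row)})"
            )
    sample_ids = [c.strip() for c in rows[0][1:]]
    assay_ids = [r[0].strip() for r in rows[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    if len(set(assay_ids)) != len(assay_ids):
        dups = sorted({a for a in assay_ids if assay_ids.count(a) > 1})
        raise ValidationError(f"{path}: duplicate assay ids {dups}")

    n, m = len(assay_ids), len(sample_ids)
    ct = np.full((n, m), np.nan)
    cen = np.zeros((n, m), dtype=bool)
    for i, row in enumerate(rows[1:]):
        for j, cell in enumerate(row[1:]):
            if _is_undetermined(cell, undetermined_token):
                cen[i, j] = True
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: cell ({assay_ids[i]}, {sample_ids[j]}) is neither a "
                    f"Ct value nor {undetermined_token!r}: {cell!r}"
                ) from None
            ct[i, j] = v
            if v > ct_max:
                cen[i, j] = True

    plate_of_sample: dict[str, str] = {}
    assay_class: dict[str, str] = {}
    if layout is not None:
        assay_class, plate_of_sample = read_panel_layout(layout)
        assay_class = {a: assay_class.get(a, classify_assay(a)) for a in assay_ids}
        plate_of_sample = {s: plate_of_sample.get(s, "plate1") for s in sample_ids}
    m_out = CtMatrix(
        ct=pd.DataFrame(ct, index=assay_ids, columns=sample_ids),
        censored=pd.DataFrame(cen, index=assay_ids, columns=sample_ids),
        plate_of_sample=plate_of_sample,
        assay_class=assay_class,
    )
    m_out.validate()
    return m_out


def write_ct_matrix(
    m: CtMatrix, path: str | Path, undetermined_token: str = "Undetermined"
) -> None:
    """Write a Ct matrix back to delimited text (inverse of :func:`read_ct_matrix`).

    Censored cells with a recorded numeric Ct (above the threshold) keep the
    number; censored cells without one are written as the token. Values
    round-trip to better than 1e-9.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["assay_id"] + m.sample_ids)
        vals = m.ct.to_numpy()
        cen = m.censored.to_numpy()
        for i, assay in enumerate(m.assay_ids):
            row: list[str] = [assay]
            for j in range(vals.shape[1]):
                v = vals[i, j]
                if cen[i, j] and not math.isfinite(v):
                    row.append(undetermined_token)
                else:
                    row.append(f"{v:.12g}")
            w.writerow(row)


def read_panel_layout(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read an optional panel layout YAML with ``assay_classes`` (assay -> class)
    and ``plates`` (sample -> plate id) mappings."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    assay_class = {str(k): str(v) for k, v in (doc.get("assay_classes") or {}).items()}
    for a, c in assay_class.items():
        if c not in ASSAY_CLASSES:
            raise ValidationError(f"layout {path}: unknown assay class {c!r} for {a!r}")
    plates = {str(k): str(v) for k, v in (doc.get("plates") or {}).items()}
    return assay_class, plates


# ---------------------------------------------------------------------------
# inter-plate calibration


def interplate_calibrate(m: CtMatrix, ipc_assay: str | None = None) -> CtMatrix:
    """Additively align plates on the inter-plate calibrator (IPC).

    For each plate, the offset (plate mean IPC Ct - global mean IPC Ct) is
    subtracted from every Ct value of the samples on that plate, so per-plate
    IPC means coincide afterwards. Within-plate Ct differences are preserved
    exactly and censoring flags are untouched. Multiple IPC rows (triplicated
    calibrator) are averaged arithmetically.
    """
    if ipc_assay is not None:
        ipc_rows = [ipc_assay]
        if ipc_assay not in m.ct.index:
            raise CalibrationError(f"IPC assay {ipc_assay!r} not in matrix")
    else:
        ipc_rows = m.assays_of_class("ipc")
        if not ipc_rows:
            raise CalibrationError("no IPC assay in matrix")

    bad_plates = sorted(
        {
            m.plate_of_sample[s]
            for s in m.sample_ids
            if m.censored.loc[ipc_rows, s].any()
        }
    )
    if bad_plates:
        raise CalibrationError(f"IPC censored on plates: {bad_plates}")

    ipc = m.ct.loc[ipc_rows]  # rows x samples
    per_sample = ipc.mean(axis=0)  # triplicate mean per sample
    global_mean = per_sample.mean()
    plates = pd.Series({s: m.plate_of_sample[s] for s in m.sample_ids})
    plate_means = per_sample.groupby(plates).mean()

    out = m.copy()
    for plate, pmean in plate_means.items():
        cols = [s for s in m.sample_ids if m.plate_of_sample[s] == plate]
        out.ct[cols] = out.ct[cols] - (pmean - global_mean)
    return out


# ---------------------------------------------------------------------------
# spike-in QC


@dataclass
class QcFlag:
    sample_id: str
    reason: str  # spike-in class
    assay_id: str
    deviation: float  # |Ct - cohort median|, cycles; inf when censored


@dataclass
class QcReport:
    """Advisory spike-in QC: per-sample deviations from the cohort median of
    each spike-in assay, per-plate IPC means, and flags beyond ``max_dev``.
    No sample is dropped automatically."""

    deviations: pd.DataFrame  # spike-in assays x samples, |Ct - median|
    ipc_plate_means: dict[str, float]
    flags: list[QcFlag]
    max_dev: float

    @property
    def flagged_samples(self) -> list[str]:
        return sorted({f.sample_id for f in self.flags})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": f.sample_id,
                    "reason": f.reason,
                    "assay_id": f.assay_id,
                    "deviation": f.deviation,
                }
                for f in self.flags
            ],
            columns=["sample_id", "reason", "assay_id", "deviation"],
        )


def spikein_qc(m: CtMatrix, max_dev: float = 2.0) -> QcReport:
    """Flag samples whose spike-in Ct deviates from the cohort median by more
    than ``max_dev`` cycles (default 2.0). Censored spike-in readings are
    flagged with infinite deviation; a spike-in censored in every sample
    raises :class:`QcError`."""
    spike_assays = [a for a in m.assay_ids if m.assay_class[a] != "target"]
    if not spike_assays:
        raise QcError("no spike-in assays present")
    dev_rows = {}
    flags: list[QcFlag] = []
    for a in spike_assays:
        cen = m.censored.loc[a]
        vals = m.ct.loc[a][~cen]
        if vals.empty:
            raise QcError(f"spike-in {a!r} censored in every sample")
        med = vals.median()
        dev = (m.ct.loc[a] - med).abs()
        dev[cen] = np.inf
        dev_rows[a] = dev
        cls = m.assay_class[a]
        for s in m.sample_ids:
            if dev[s] > max_dev:
                flags.append(QcFlag(s, cls, a, float(dev[s])))

    ipc_rows = m.assays_of_class("ipc")
    ipc_plate_means: dict[str, float] = {}
    if ipc_rows:
        per_sample = m.ct.loc[ipc_rows].mean(axis=0)
        plates = pd.Series({s: m.plate_of_sample[s] for s in m.sample_ids})
        ipc_plate_means = per_sample.groupby(plates).mean().to_dict()

    return QcReport(
        deviations=pd.DataFrame(dev_rows).T.reindex(spike_assays),
        ipc_plate_means=ipc_plate_means,
        flags=flags,
        max_dev=max_dev,
    )


# ---------------------------------------------------------------------------
# sample metadata

_SAMPLE_COLUMNS = [
    "sample_id",
    "group",
    "pair_id",
    "stage",
    "gender",
    "age",
    "pfs_months",
    "event",
    "met_sites",
]

_STAGES = {"II", "IIIA", "IIIB"}


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample clinical metadata.

    Expected columns: sample_id, group (metastasis/non_metastasis), pair_id
    (optional matched-pair label), stage (II/IIIA/IIIB), gender, age,
    pfs_months, event (0/1), met_sites (semicolon-separated subset of
    liver;lung;bone;brain;skin_soft_tissue).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "pair_id": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["event"] = df["event"].astype(bool)
    df["met_sites"] = [
        [] if (pd.isna(x) or str(x).strip() == "") else str(x).split(";")
        for x in df["met_sites"]
    ]
    df["pair_id"] = df["pair_id"].where(df["pair_id"].notna(), None)
    validate_sample_table(df)
    return df


def validate_sample_table(df: pd.DataFrame, require_pairs: bool = False) -> None:
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in sample table")
    bad_group = set(df["group"]) - {GROUP_METASTASIS, GROUP_NON_METASTASIS}
    if bad_group:
        raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
    bad_stage = set(df["stage"]) - _STAGES
    if bad_stage:
        raise ValidationError(f"unknown stages: {sorted(bad_stage)}")
    if (df["pfs_months"] < 0).any():
        raise ValidationError("negative pfs_months")
    for sites in df["met_sites"]:
        bad = set(sites) - MET_SITES
        if bad:
            raise ValidationError(f"unknown metastatic sites: {sorted(bad)}")
    paired = df[df["pair_id"].notna()] if "pair_id" in df else df.iloc[0:0]
    for pid, sub in paired.groupby("pair_id"):
        if len(sub) != 2 or set(sub["group"]) != {GROUP_METASTASIS, GROUP_NON_METASTASIS}:
            raise ValidationError(
                f"pair {pid!r} must have exactly one sample per group"
            )
    if require_pairs and paired.empty:
        raise ValidationError("no matched pairs in sample table")


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["met_sites"] = [";".join(s) for s in out["met_sites"]]
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index=False)
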