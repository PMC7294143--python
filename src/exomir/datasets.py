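"""Small published summary tables shipped with the package.

These are reported cohort-level summaries (not raw per-sample data) from an
89-patient stage II/III gastric-cancer serum-exosome study design that this
pipeline emulates: a stage-by-metastasis contingency table and the consensus
screen's 19 average fold changes under two reference normalizations. They
serve as fixtures for the clinical statistics and the direction-calling
logic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_stage_table", "load_foldchange_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("exomir.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_stage_table() -> tuple[np.ndarray, list[str], list[str]]:
    """Stage (II/IIIA/IIIB) by metastasis-status counts for the emulated
    cohort: returns (3x2 count array, stage labels, group labels)."""
    df = _read("stage_by_metastasis.csv")
    counts = df[["metastasis", "no_metastasis"]].to_numpy(dtype=int)
    return counts, df["stage"].tolist(), ["metastasis", "no_metastasis"]


def load_foldchange_table() -> pd.DataFrame:
    """The 19 consensus-screen average case/control fold changes under the
    miR-16-5p and miR-93-5p normalizations, with the reported direction.
    Columns: assay_id, direction, avg_fc_miR16, avg_fc_miR93."""
    return _read("discovery_foldchange_averages.csv")
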