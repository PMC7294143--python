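"""Validation-cohort comparisons and clinical statistics.

Relative expression (2^-dCt) of each shortlisted miRNA is compared between
the metastasis (n=31) and non-metastasis (n=52) groups with the
Mann-Whitney test under both internal controls; the clinical stage and
gender margins are tested with Pearson chi-square. The paired
tumour/adjacent tissue samples are summarized by down-regulation counts and
the Wilcoxon signed-rank test on log2 expression.
"""

import pandas as pd

from exomir.pipeline import RunConfig, stage_tissue, stage_validation

cfg = RunConfig(
    samples="results/inputs/samples.csv",
    tissue="results/inputs/tissue_pairs.csv",
    outdir="results",
)
stats = stage_validation(cfg, ["hsa-miR-16-5p", "hsa-miR-93-5p"])
print(stats.to_string(index=False))
print()
tissue = stage_tissue(cfg)
print(tissue.to_string(index=False))
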