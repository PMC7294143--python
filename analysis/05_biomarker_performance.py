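"""ROC analysis and dichotomization of the validated biomarkers.

For miR-379-5p and miR-410-3p under each internal control: the empirical
ROC and its AUC (rank/U identity), the Youden-optimal cut-off with its
sensitivity and specificity, positivity labels (expression strictly above
the cut-off), and the per-site positive/negative counts among metastatic
patients.
"""

import pandas as pd

from exomir.pipeline import RunConfig, stage_performance

cfg = RunConfig(
    samples="results/inputs/samples.csv",
    outdir="results",
)
perf = stage_performance(cfg, ["hsa-miR-16-5p", "hsa-miR-93-5p"])
print(perf.to_string(index=False))
print()
print(pd.read_csv("results/sites.tsv", sep="\t").to_string(index=False))
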