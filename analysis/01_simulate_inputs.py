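"""Generate the full synthetic input set for the downstream analyses.

Emulates the study design: a 752-assay profiling panel on 3 matched
case/control serum pairs (about half the assays censoring at Ct 40), a
validation cohort of 31 metastasis vs 52 non-metastasis patients with the
two designated biomarkers calibrated to AUC 0.70, survival times driven by
true biomarker positivity (HR 3), and 43 paired tumour/adjacent tissue
samples. Writes everything plus the ground-truth manifest under
results/inputs/.
"""

import sys
from pathlib import Path

from exomir.synthetic_data import SimulationConfig, write_all_inputs

seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
outdir = Path("results/inputs")
paths = write_all_inputs(SimulationConfig(seed=seed), outdir)
print(f"seed {seed}; wrote:")
for name, p in paths.items():
    print(f"  {name}: {p}")
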