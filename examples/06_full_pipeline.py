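"""The full study in one call: build -> RE-DMD -> WHAM -> ensembles -> PCA.

Equivalent to `gofold run --out scratch/pipeline_demo` from the shell.
Run:  python examples/06_full_pipeline.py   (about two minutes)
"""

import json

from gofold.pipeline import DEFAULT_CONFIG, run_pipeline

cfg = json.loads(json.dumps(DEFAULT_CONFIG))
report = run_pipeline(cfg, "scratch/pipeline_demo")

print(json.dumps(report, indent=2, default=float))
# n_contacts / native_energy      : size of the Gō model
# melting_temperature             : Cv-peak location (reduced units)
# basins                          : energy windows of the F(E) minima at Tm
# populations / cluster_populations : basin occupancies at Tm, via energy
#                                   windows and via structural clusters
# pca.msf_fraction_top_k          : collectivity of the transition ensemble
# Tables for every stage are under scratch/pipeline_demo/ (TSV + JSON).
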