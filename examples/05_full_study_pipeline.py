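"""End-to-end synthetic study: simulate, measure every surface, run statistics.

Equivalent to the CLI sequence:

    plaquemetry simulate study_dir --subjects 2 --teeth 2 --seed 7
    plaquemetry run study_dir --out results --seed 7
"""

import json
from pathlib import Path

from plaquemetry import RunConfig
from plaquemetry.pipeline import run_study, simulate_study

study = Path("example_study")
simulate_study(study, n_subjects=2, teeth_per_subject=2, seed=7, edge_length=0.3)

cfg = RunConfig(study_dir=study, output_dir=Path("example_results"), seed=7)
records, report = run_study(cfg)

ok = records[records["status"] == "ok"]
print(ok[["subject_id", "tooth_id", "vpi", "avpi", "plani_volmap",
          "plani_tot", "plani_dark", "tmqhpli_tdp_mean"]].round(3).to_string(index=False))
print("\nFriedman across planimetric measures:",
      json.dumps(report.get("friedman", {}), indent=None))
print("outputs: example_results/{records.csv, stats.json, manifest.json, *_boolmap.png}")
# Each row joins the volumetric (VPI/AVPI), map-based (PLANIvolmap),
# image-based (PLANItot/dark) and clinical (TMQHPlI) measures for one
# tooth surface - the table every statistic in stats.json is built from.
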