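#!/usr/bin/env python
"""Quick validation battery: a scaled-down tour of the experiments that
scripts/acceptance.py runs in full.

Prints the published-table overlap p-values, one null-W recovery run, the
top-candidate calibration numbers, one structure-correction run and the
BLUP recovery summary; writes results/08_validation/summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import out_dir
from clinescan.experiments import (
    blup_recovery_experiment,
    parallelism_experiment,
    reference_overlap_table,
    structure_correction_experiment,
    topcandidate_calibration,
)

OUT = out_dir("08_validation")
summary = {}

table = reference_overlap_table()
print("published-count overlap p-values:")
print(table.to_string(index=False))
summary["overlap"] = table.to_dict(orient="records")

r = parallelism_experiment(seed=1)
print(f"\nnull-W (1 seed): shared {r['shared_parallel']}/{r['shared_tested']} "
      f"parallel, specific {r['specific_parallel']}/{r['specific_tested']}")
summary["nullw_seed1"] = r

cal = topcandidate_calibration(seed=1)
print(f"top-candidate: null fraction {cal['null_candidate_fraction']:.2e}, "
      f"p_bar {cal['p_bar_null']:.3f}, sensitivity {cal['sensitivity']:.2f}")
summary["topcandidate"] = cal

sc = structure_correction_experiment(seed=1)
print(f"structure: lambda(simple)={sc['lambdas']['simple']:.2f} -> "
      f"{sc['selected']} (lambda={sc['selected_lambda']:.3f})")
summary["structure_seed1"] = sc

b = blup_recovery_experiment(seed=1)
print(f"BLUP recovery: corr={b['corr_blup_truth']:.3f}, "
      f"variance ratio {b['variance_ratio_hat']:.2f}")
summary["blup_seed1"] = b

(OUT / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
print(f"\nwrote {OUT / 'summary.json'}")
print("full-scale versions: python scripts/acceptance.py --seed 1 "
      "--out results/acceptance.json")
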