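#!/usr/bin/env python
"""Screen every DSC study for signal loss and apply the accrual filters.

Computes the nCBV map of all 71 phantoms, measures the nil fraction inside
each lesion (all should be uninterpretable — that is the cohort's premise),
then filters on DWI/DCE interpretability, steroid use and follow-up to
reach the analyzable subset. Writes the accrual report and per-patient
screening table under results/.
"""

import argparse
from pathlib import Path

from gbmalt import PipelineConfig, run_pipeline
from gbmalt.io import save_json

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1234)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

result = run_pipeline(PipelineConfig(seed=args.seed))
args.out.mkdir(parents=True, exist_ok=True)
save_json(result.accrual.to_dict(), args.out / "accrual.json")
result.screen_table.to_csv(args.out / "dsc_screen.csv", index=False)

print(result.accrual.to_text())
n_flagged = int((~result.screen_table["dsc_interpretable"]).sum())
print(f"\nmap-based DSC screening flagged {n_flagged}/71 studies "
      "uninterpretable")
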