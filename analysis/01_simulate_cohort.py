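#!/usr/bin/env python
"""Generate the default synthetic accrual cohort and tabulate its records.

71 post-treatment glioblastoma patients, all with uninterpretable DSC
perfusion (54 hemorrhage / 17 skull-base); writes the per-patient record
table and the stage-by-stage accrual table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from gbmalt import CohortConfig, generate_cohort

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1234)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

config = CohortConfig()
records, accrual = generate_cohort(config, seed=args.seed)

table = pd.DataFrame([r.__dict__ for r in records])
args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "cohort_records.csv", index=False)
accrual.to_csv(args.out / "accrual_table.csv", index=False)

print(accrual.to_string(index=False))
print(f"\nwrote {args.out / 'cohort_records.csv'} "
      f"({len(records)} patients, seed {args.seed})")
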