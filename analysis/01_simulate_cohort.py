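#!/usr/bin/env python
"""Generate the synthetic study cohort.

Simulates urgency-gating agents through full 320-trial sessions in both
penalty contexts and draws their single-trial MEP amplitudes from the
configured excitability model.  Writes the behavior table, the tidy MEP
table, and the ground truth to results/.
"""

import argparse
from pathlib import Path

from satmep import io
from satmep.cohort import CohortConfig, generate_mep_table

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--participants", type=int, default=12)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

config = CohortConfig(n_participants=args.participants, master_seed=args.seed)
behavior, meps, truth = generate_mep_table(config)

args.out.mkdir(parents=True, exist_ok=True)
io.save_table(behavior, args.out / "behavior.csv")
io.save_table(meps, args.out / "mep_table.csv")
io.save_config(config, args.out / "cohort_config.json")
truth.to_json(args.out / "ground_truth.json")

log = io.RunLog(args.out / "run_log.jsonl")
log.record(
    "simulate",
    seed=args.seed,
    participants=args.participants,
    trials=len(behavior),
    mep_observations=len(meps),
)

resp = behavior[~behavior["no_response"]]
print(f"{args.participants} agents x 2 contexts, {len(behavior)} trials")
print(f"no-response rate: {behavior['no_response'].mean():.3%}")
print(resp.groupby('context')[['rt_ms']].median().round(0))
print(f"wrote behavior.csv, mep_table.csv, ground_truth.json to {args.out}/")
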