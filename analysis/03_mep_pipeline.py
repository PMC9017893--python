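#!/usr/bin/env python
"""Motor excitability: inclusion rules, RT matching, normalization, maps.

Runs the full MEP quantification chain on the synthetic cohort's tidy
amplitude table: trial inclusion (ambiguous, RT in [1,350, 2,800] ms),
iterated RT matching with median-of-medians aggregation, normalization
to baseline (and baseline to rest), the Jump_7 context contrast per
representation, and the somatotopic spatiotemporal difference map.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from satmep import io, mep
from satmep.task_model import DELIBERATION_EVENTS

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--iterations", type=int, default=100)
args = parser.parse_args()
rng = np.random.default_rng(args.seed)
log = io.RunLog(args.results / "run_log.jsonl")

meps = io.load_table(args.results / "mep_table.csv")
delib = meps[meps["tms_event"].isin(DELIBERATION_EVENTS)]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    outlier_mask = mep.reject_outlier_meps(delib)
    delib = delib[~outlier_mask]
    retained, excluded = mep.filter_inclusion(delib)
    log.record(
        "mep_inclusion",
        seed=args.seed,
        input_rows=len(meps),
        outliers_removed=int(outlier_mask.sum()),
        retained_rows=len(retained),
        excluded_participants=list(map(int, excluded)),
    )
    agg = mep.aggregate_iterations(retained, rng, n_iter=args.iterations)

    groupers = ["participant", "muscle", "body_side", "context"]
    base = (
        meps[meps["tms_event"] == "baseline"]
        .groupby(groupers, observed=True)["amplitude_uv"].median().reset_index()
    )
    rest = (
        meps[meps["tms_event"] == "rest"]
        .groupby(groupers, observed=True)["amplitude_uv"].median().reset_index()
    )
    baseline_pct = mep.normalize_baseline(base, rest)
    excitability = mep.normalize_deliberation(agg, base)

io.save_table(baseline_pct, args.results / "baseline_excitability.csv")
io.save_table(excitability, args.results / "excitability.csv")

j7 = (
    excitability[excitability["tms_event"] == "jump7"]
    .groupby(["muscle", "side_class", "context"])["percent"].mean().unstack("context")
)
j7["hasty_minus_cautious"] = j7["hasty"] - j7["cautious"]
io.save_table(j7.reset_index(), args.results / "jump7_contrast.csv")
print("Jump_7 excitability (% of baseline, participant mean):")
print(j7.round(1))

# leg slots are absent in the finger cohort: map the finger-only subset
have = set(zip(excitability["muscle"], excitability["side_class"]))
order = [slot for slot in mep.SOMATOTOPIC_ORDER if slot in have]
grids = mep.spatiotemporal_map(excitability, somatotopic_order=order)
for name in ("hasty", "cautious", "difference"):
    io.save_table(
        pd.DataFrame(
            grids[name], index=grids["space_axis"], columns=grids["time_axis"]
        ).reset_index(names="somatotopic_position"),
        args.results / f"map_{name}.csv",
    )
print(f"wrote excitability.csv, jump7_contrast.csv, map_*.csv ({len(order)} slots)")
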