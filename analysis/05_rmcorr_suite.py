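#!/usr/bin/env python
"""Seed-based single-trial correlations between finger representations.

Normalizes the Jump_7 single-trial MEPs to baseline, then correlates the
chosen index finger with each of the five other finger representations
per context (repeated-measures correlation over iterated RT-matched
draws, with within-participant permutation p-values).  The context
contrast per pair uses 95% CI overlap.  Writes the 10 correlation
results, the 5 contrasts, and a network-plot edge list.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from satmep import io, rmcorr as rc

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--iterations", type=int, default=100)
parser.add_argument("--permutations", type=int, default=1000)
args = parser.parse_args()
rng = np.random.default_rng(args.seed)

meps = io.load_table(args.results / "mep_table.csv")
j7 = meps[(meps["tms_event"] == "jump7") & ~meps["no_response"]]
j7 = j7[(j7["rt_ms"] >= 1350) & (j7["rt_ms"] <= 2800)]
base = (
    meps[meps["tms_event"] == "baseline"]
    .groupby(["participant", "muscle", "body_side", "context"], observed=True)[
        "amplitude_uv"
    ]
    .median()
    .rename("base")
    .reset_index()
)
j7 = j7.merge(base, on=["participant", "muscle", "body_side", "context"])
j7["percent"] = 100.0 * j7["amplitude_uv"] / j7["base"]
wide = j7.pivot_table(
    index=["participant", "context", "trial", "rt_ms"],
    columns=["muscle", "side_class"],
    values="percent",
)
wide.columns = [f"{m}_{s}" for m, s in wide.columns]
wide = wide.reset_index().dropna()

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    results, contrasts = rc.seed_correlation_suite(
        wide, rng, n_iterations=args.iterations, n_perm=args.permutations
    )
io.save_table(results, args.results / "rmcorr_results.csv")
io.save_table(contrasts, args.results / "rmcorr_contrasts.csv")
edges = results.rename(columns={"pair": "edge"})[
    ["edge", "context", "r", "significant"]
]
io.save_table(edges, args.results / "rmcorr_edges.csv")
io.RunLog(args.results / "run_log.jsonl").record(
    "rmcorr", seed=args.seed, n_points=int(results["n_points"].median()),
    iterations=args.iterations, permutations=args.permutations,
)

print(f"single-trial pool: {len(wide)} trials")
print(results[["pair", "context", "r", "p", "significant"]].round(3).to_string(index=False))
print(contrasts.round(3).to_string(index=False))
print("wrote rmcorr_results.csv, rmcorr_contrasts.csv, rmcorr_edges.csv")
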