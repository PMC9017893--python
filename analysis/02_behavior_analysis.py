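#!/usr/bin/env python
"""Decision behavior: the speed-accuracy shift and the urgency functions.

From the simulated behavior table: per-participant median decision time
and accuracy per context, the between-context paired contrasts, the
permutation-based DT-accuracy correlation within each context, and the
urgency-function fits (slope and intercept) from SumLogLR at DT.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from satmep import behavior as bh
from satmep import io

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
rng = np.random.default_rng(args.seed)

beh = io.load_table(
    args.results / "behavior.csv",
    required_columns=["participant", "context", "rt_ms", "jumps", "chosen_side"],
)
cfg = io.load_config(
    __import__("satmep.cohort", fromlist=["CohortConfig"]).CohortConfig,
    args.results / "cohort_config.json",
)
beh["dt_ms"] = bh.compute_dt(beh["rt_ms"].to_numpy(), cfg.srt_median_ms)

rows, fits = [], []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for (p, ctx), grp in beh.groupby(["participant", "context"]):
        resp = grp[~grp["no_response"]]
        fit = bh.estimate_urgency_function(grp)
        rows.append(
            {
                "participant": p,
                "context": ctx,
                "median_dt_ms": resp["dt_ms"].median(),
                "accuracy": resp["correct"].mean(),
                "urgency_slope": fit.slope,
                "urgency_intercept": fit.intercept,
            }
        )
        fits.append(fit.bin_summaries.assign(participant=p, context=ctx))
summary = pd.DataFrame(rows)
io.save_table(summary, args.results / "behavior_summary.csv")
io.save_table(pd.concat(fits, ignore_index=True), args.results / "urgency_bins.csv")

wide = summary.pivot(index="participant", columns="context")
contrasts = []
for var in ("median_dt_ms", "accuracy", "urgency_intercept", "urgency_slope"):
    t, d = bh.paired_stats(wide[(var, "hasty")], wide[(var, "cautious")])
    contrasts.append({"variable": var, "t": t, "cohens_d": d, "n": len(wide)})
    print(f"{var:18s} hasty-cautious: t = {t:+.2f}, d = {d:.3f}")
io.save_table(pd.DataFrame(contrasts), args.results / "behavior_contrasts.csv")

for ctx, grp in summary.groupby("context"):
    r, p = bh.permutation_correlation(
        grp["median_dt_ms"], grp["accuracy"], n_perm=1000, rng=rng
    )
    print(f"DT-accuracy correlation ({ctx}): R = {r:.2f}, permutation p = {p:.4f}")
print(f"wrote behavior_summary.csv, urgency_bins.csv, behavior_contrasts.csv")
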