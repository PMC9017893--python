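#!/usr/bin/env python
"""Movement vigor from pre-press EMG bursts.

Synthesizes raw EMG for the cohort's responded trials (pulse artifacts,
MEP waveforms, voluntary bursts in background noise), epochs the 300 ms
before each key press, median-splits trials into short/long RT classes
with cross-context RT matching, and extracts the conditioned-signal peak
amplitude and time to peak per muscle x RT class x context.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from satmep import io, vigor
from satmep.cohort import CohortConfig, synthesize_trial_emg
from satmep.task_model import TMS_EVENT_JUMP

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--results", type=Path, default=Path("results"))
parser.add_argument("--participants", type=int, default=6)
args = parser.parse_args()
rng = np.random.default_rng(args.seed)

beh = io.load_table(args.results / "behavior.csv")
cfg = io.load_config(CohortConfig, args.results / "cohort_config.json")
pulse_by_event = {"baseline": -1300.0} | {
    e: 200.0 * (j - 1) for e, j in TMS_EVENT_JUMP.items()
}

trials = beh[
    (~beh["no_response"])
    & (beh["participant"] < args.participants)
    & (beh["rt_ms"] >= -1400.0)  # enough pre-press history in the trace
    & (beh["rt_ms"] <= 2150.0)  # press inside the recording window
].copy()

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    matched, excluded = vigor.split_and_match(trials, rng)

epochs: dict[tuple, list] = {}
n_pulse_rejected = 0
for r in matched.itertuples():
    pulses = (
        [pulse_by_event[r.tms_event]] if r.tms_event in pulse_by_event else []
    )
    trace = synthesize_trial_emg(cfg, rng, {}, pulses[0] if pulses else None,
                                 float(r.rt_ms), r.chosen_side)
    for muscle in cfg.muscles:
        for hand in ("chosen", "unchosen"):
            side = r.chosen_side if hand == "chosen" else (
                "left" if r.chosen_side == "right" else "right"
            )
            epoch = vigor.epoch_and_clean(
                trace, f"{muscle}_{side}", float(r.rt_ms), pulses
            )
            if epoch is None:
                n_pulse_rejected += 1
                continue
            key = (r.participant, muscle, hand, r.rt_class, r.context)
            epochs.setdefault(key, []).append(epoch)

rows = []
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for (p, muscle, hand, rt_class, ctx), eps in sorted(epochs.items()):
        m = vigor.vigor_metrics(vigor.condition_signal(np.array(eps)))
        rows.append(
            {
                "participant": p, "muscle": muscle, "hand": hand,
                "rt_class": rt_class, "context": ctx, "n_epochs": len(eps),
                "peak_amplitude_uv": m.peak_amplitude_uv,
                "onset_ms": m.onset_ms, "time_to_peak_ms": m.time_to_peak_ms,
            }
        )
metrics = pd.DataFrame(rows)
io.save_table(metrics, args.results / "vigor_metrics.csv")
io.RunLog(args.results / "run_log.jsonl").record(
    "vigor", seed=args.seed, participants=args.participants,
    matched_trials=len(matched), pulse_rejected_epochs=n_pulse_rejected,
    excluded_participants=list(map(int, excluded)),
)

chosen = metrics[metrics["hand"] == "chosen"]
print("chosen-hand peak EMG amplitude (uV) by RT class and context:")
print(
    chosen.pivot_table(
        index="muscle", columns=["rt_class", "context"],
        values="peak_amplitude_uv",
    ).round(1)
)
print(f"wrote vigor_metrics.csv ({len(metrics)} condition signals)")
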