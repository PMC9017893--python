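"""Movement-vigor quantification from pre-key-press EMG bursts.

The voluntary EMG burst immediately preceding the key press indexes the
vigor of the response movement.  Epochs of 300 ms (600 samples at
2,000 Hz) before the press are offset-corrected and rectified, grouped
by muscle x RT class (median split) x context with RT matching across
contexts, reduced to a pointwise-median conditioned signal (baseline
corrected, first-order 5-Hz low-pass applied zero-phase), and summarised
by peak amplitude and time to peak from the 3-SD onset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .mep import EmgTrace, rt_match

__all__ = [
    "EPOCH_SAMPLES",
    "epoch_and_clean",
    "condition_signal",
    "VigorMetrics",
    "vigor_metrics",
    "median_split",
    "split_and_match",
]

SAMPLING_RATE_HZ = 2000.0
EPOCH_MS = 300.0
EPOCH_SAMPLES = int(EPOCH_MS * SAMPLING_RATE_HZ / 1000.0)  # 600
OFFSET_WINDOW_MS = 50.0
PULSE_EXCLUSION_MS = (-400.0, 0.0)
BASELINE_WINDOW_MS = (-300.0, -200.0)


def epoch_and_clean(
    trace: EmgTrace,
    channel: str,
    press_ms: float,
    pulse_times_ms=(),
) -> np.ndarray | None:
    """Extract one rectified vigor epoch, or ``None`` if rejected.

    Trials with any TMS pulse in [-400, 0] ms of the press are rejected
    (the pulse artifact and MEP would contaminate the burst).  The epoch
    spans [-300, 0) ms before the press; the mean of its first 50 ms is
    subtracted from every sample (offset removal) before full-wave
    rectification.
    """
    for p in np.atleast_1d(np.asarray(pulse_times_ms, dtype=float)):
        if press_ms + PULSE_EXCLUSION_MS[0] <= p <= press_ms + PULSE_EXCLUSION_MS[1]:
            return None
    seg = trace.segment(channel, press_ms - EPOCH_MS, press_ms)
    if len(seg) != EPOCH_SAMPLES:
        raise IndexError(f"epoch has {len(seg)} samples, expected {EPOCH_SAMPLES}")
    n_offset = int(OFFSET_WINDOW_MS * SAMPLING_RATE_HZ / 1000.0)
    return np.abs(seg - seg[:n_offset].mean())


def _baseline_slice() -> slice:
    i0 = int((BASELINE_WINDOW_MS[0] + EPOCH_MS) * SAMPLING_RATE_HZ / 1000.0)
    i1 = int((BASELINE_WINDOW_MS[1] + EPOCH_MS) * SAMPLING_RATE_HZ / 1000.0)
    return slice(i0, i1)


def condition_signal(epochs, cutoff_hz: float = 5.0) -> np.ndarray:
    """Condition one muscle x RT-class x context set of epochs.

    Pointwise median across epochs, baseline correction (mean over
    [-300, -200] ms), then a first-order Butterworth low-pass applied
    forward-backward (zero-phase) so peak latencies are not biased.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] == 0 or epochs.shape[1] != EPOCH_SAMPLES:
        raise ValueError(f"need >= 1 epoch of {EPOCH_SAMPLES} samples")
    med = np.median(epochs, axis=0)
    med = med - med[_baseline_slice()].mean()
    b, a = signal.butter(1, cutoff_hz, fs=SAMPLING_RATE_HZ, btype="low")
    return signal.filtfilt(b, a, med)


@dataclass(frozen=True)
class VigorMetrics:
    peak_amplitude_uv: float
    peak_ms: float  # relative to key press
    onset_ms: float | None
    time_to_peak_ms: float | None


def vigor_metrics(conditioned: np.ndarray) -> VigorMetrics:
    """Peak amplitude, EMG onset, and time to peak of a conditioned trace.

    Onset is the first sample after the baseline window exceeding the
    baseline mean + 3 SD; with no crossing the onset is undefined and a
    warning is issued.
    """
    x = np.asarray(conditioned, dtype=float)
    if len(x) != EPOCH_SAMPLES:
        raise ValueError(f"expected {EPOCH_SAMPLES} samples")
    base = x[_baseline_slice()]
    thresh = base.mean() + 3 * base.std(ddof=1)
    start = _baseline_slice().stop  # onset search begins after -200 ms
    peak_idx = int(np.argmax(x))
    peak_ms = -EPOCH_MS + peak_idx * 1000.0 / SAMPLING_RATE_HZ
    crossing = np.flatnonzero(x[start:] > thresh)
    if len(crossing) == 0:
        warnings.warn("no EMG onset detected (flat or sub-threshold trace)")
        return VigorMetrics(float(x.max()), peak_ms, None, None)
    onset_ms = -EPOCH_MS + (start + crossing[0]) * 1000.0 / SAMPLING_RATE_HZ
    return VigorMetrics(float(x.max()), peak_ms, onset_ms, peak_ms - onset_ms)


def median_split(rt_ms) -> np.ndarray:
    """'short'/'long' labels by median split; ties at the median go short."""
    rt = np.asarray(rt_ms, dtype=float)
    med = np.median(rt)
    return np.where(rt <= med, "short", "long")


def split_and_match(
    records: pd.DataFrame,
    rng: np.random.Generator,
    bin_width_ms: float = 200.0,
) -> tuple[pd.DataFrame, list]:
    """RT-class labelling and cross-context RT matching for vigor trials.

    Within each participant x context the responded trials are median-split
    into short/long RT classes, then RTs are matched across contexts
    within each class (200-ms bins).  Participants left with an empty
    RT-class x context cell are flagged for exclusion.  Returns the
    matched rows and the excluded participants.
    """
    df = records
    if "no_response" in df.columns:
        df = df[~df["no_response"].astype(bool)]
    df = df.dropna(subset=["rt_ms"]).copy()
    df["rt_class"] = ""
    for (_, _), idx in df.groupby(["participant", "context"]).groups.items():
        df.loc[idx, "rt_class"] = median_split(df.loc[idx, "rt_ms"].to_numpy())

    kept, excluded = [], []
    contexts = sorted(df["context"].unique())
    for p, grp in df.groupby("participant"):
        parts = []
        ok = True
        for rt_class in ("short", "long"):
            sub = grp[grp["rt_class"] == rt_class]
            by_ctx = [sub[sub["context"] == c].reset_index(drop=True) for c in contexts]
            if any(len(s) == 0 for s in by_ctx):
                ok = False
                break
            if len(by_ctx) == 2:
                ia, ib = rt_match(
                    by_ctx[0]["rt_ms"].to_numpy(),
                    by_ctx[1]["rt_ms"].to_numpy(),
                    rng,
                    bin_width_ms,
                )
                if len(ia) == 0 or len(ib) == 0:
                    ok = False
                    break
                parts.extend([by_ctx[0].iloc[ia], by_ctx[1].iloc[ib]])
            else:
                parts.extend(by_ctx)
        if ok:
            kept.extend(parts)
        else:
            excluded.append(p)
    matched = (
        pd.concat(kept, ignore_index=True)
        if kept
        else df.iloc[0:0].copy()
    )
    return matched, excluded
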