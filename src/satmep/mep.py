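"""Corticospinal excitability pipeline: from EMG traces to normalized MEP maps.

Single-pulse TMS over the motor cortex elicits a motor-evoked potential
(MEP) in target muscles; its peak-to-peak amplitude indexes the
excitability of the corresponding motor representation at the pulse
time.  This module covers the full quantification chain: pre-activation
screening (RMS before the pulse), peak-to-peak extraction, +/-3 SD
amplitude outlier rejection, trial-inclusion rules (ambiguous trials
with RT in [1,350, 2,800] ms), reaction-time distribution matching
across contexts (200-ms bins, resampled over iterations with median
aggregation), normalization (baseline as % of rest; deliberation
timings as % of baseline, per hand before pooling into chosen/unchosen
classes), and the somatotopically arranged spatiotemporal maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_model import DELIBERATION_EVENTS

__all__ = [
    "EmgTrace",
    "preactivation_rms",
    "flag_preactivated",
    "extract_mep_amplitude",
    "flag_amplitude_outliers",
    "reject_outlier_meps",
    "filter_inclusion",
    "rt_match",
    "aggregate_iterations",
    "normalize_baseline",
    "normalize_deliberation",
    "SOMATOTOPIC_ORDER",
    "spatiotemporal_map",
    "NormalizationError",
    "MapError",
]

RT_BOUNDS_MS = (1350.0, 2800.0)  # closed interval, >=150 ms after Jump_7
MIN_MEAN_TRIALS = 8.0
#: default peak-to-peak search windows after the pulse (ms)
SEARCH_WINDOW_FINGER = (10.0, 60.0)
SEARCH_WINDOW_LEG = (20.0, 80.0)


class NormalizationError(ValueError):
    pass


class MapError(ValueError):
    pass


@dataclass
class EmgTrace:
    """Multi-channel EMG of one trial.

    ``samples`` is (n_channels, n_samples) in microvolts; ``start_ms`` is
    the time of the first sample relative to Jump_1 (the recording spans
    4,000 ms, -1,800 to +2,200 ms by default, covering 500 ms before the
    baseline pulse through 1,000 ms after Jump_7).  ``markers`` carries
    event times in the same clock (``pulse_ms``, ``press_ms``...).
    """

    channels: list[str]
    samples: np.ndarray
    start_ms: float = -1800.0
    sampling_rate_hz: float = 2000.0
    markers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("one sample row per channel required")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.n_samples * 1000.0 / self.sampling_rate_hz

    def _index(self, t_ms: float) -> int:
        return int(round((t_ms - self.start_ms) * self.sampling_rate_hz / 1000.0))

    def segment(self, channel: str, t0_ms: float, t1_ms: float) -> np.ndarray:
        """Samples of ``channel`` in [t0, t1) ms relative to Jump_1."""
        if t0_ms < self.start_ms or t1_ms > self.end_ms or t1_ms <= t0_ms:
            raise IndexError(
                f"window [{t0_ms}, {t1_ms}) outside trace "
                f"[{self.start_ms}, {self.end_ms})"
            )
        row = self.channels.index(channel)
        return self.samples[row, self._index(t0_ms) : self._index(t1_ms)]


def preactivation_rms(
    trace: EmgTrace,
    channel: str,
    pulse_ms: float,
    window_ms: tuple[float, float] = (-250.0, -50.0),
) -> float:
    """RMS of the pre-pulse EMG in ``window_ms`` relative to the pulse."""
    seg = trace.segment(channel, pulse_ms + window_ms[0], pulse_ms + window_ms[1])
    return float(np.sqrt(np.mean(seg**2)))


def flag_preactivated(rms_values) -> np.ndarray:
    """Flag trials whose pre-pulse RMS exceeds mean + 3 SD of the group.

    The group is the participant x muscle x session distribution of RMS
    values.  Strict inequality: identical values are never flagged.
    """
    v = np.asarray(rms_values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("rms_values must be a non-empty 1-d array")
    return v > v.mean() + 3 * v.std(ddof=1 if len(v) > 1 else 0)


def extract_mep_amplitude(
    trace: EmgTrace,
    channel: str,
    pulse_ms: float,
    search_window_ms: tuple[float, float] = SEARCH_WINDOW_FINGER,
) -> float:
    """Peak-to-peak amplitude (max - min, microvolts) after the pulse."""
    seg = trace.segment(
        channel, pulse_ms + search_window_ms[0], pulse_ms + search_window_ms[1]
    )
    if seg.size == 0:
        raise IndexError("empty MEP search window")
    return float(seg.max() - seg.min())


def flag_amplitude_outliers(values) -> np.ndarray:
    """Flag amplitudes outside mean +/- 3 SD of their group (single pass).

    Groups smaller than 3 are skipped with a warning (nothing flagged).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        warnings.warn("group of < 3 MEPs: outlier rejection skipped")
        return np.zeros(len(v), dtype=bool)
    sd = v.std(ddof=1)
    return np.abs(v - v.mean()) > 3 * sd


def reject_outlier_meps(
    df: pd.DataFrame,
    group_cols=("participant", "muscle", "context"),
    value_col: str = "amplitude_uv",
) -> pd.Series:
    """Apply the +/-3 SD rule per group; returns a boolean exclusion mask
    aligned with ``df``.  Each session holds one context, so grouping by
    context groups by session."""
    mask = pd.Series(False, index=df.index)
    for _, idx in df.groupby(list(group_cols)).groups.items():
        mask.loc[idx] = flag_amplitude_outliers(df.loc[idx, value_col].to_numpy())
    return mask


def filter_inclusion(
    df: pd.DataFrame,
    rt_bounds_ms: tuple[float, float] = RT_BOUNDS_MS,
    min_mean_trials: float = MIN_MEAN_TRIALS,
) -> tuple[pd.DataFrame, list]:
    """Deliberation-trial inclusion rules.

    Keeps ambiguous trials stimulated at Jump_1/4/7 whose RT lies in the
    closed ``rt_bounds_ms`` interval (responses at least 150 ms after
    Jump_7 and before Jump_15); no-response trials are dropped.  Returns
    the retained rows and the participants whose mean retained trial
    count per timing x context falls below ``min_mean_trials`` (they are
    excluded from downstream excitability analyses).
    """
    lo, hi = rt_bounds_ms
    keep = (
        (df["trial_type"] == "ambiguous")
        & df["tms_event"].isin(DELIBERATION_EVENTS)
        & ~df["rt_ms"].isna()
        & (df["rt_ms"] >= lo)
        & (df["rt_ms"] <= hi)
    )
    if "no_response" in df.columns:
        keep &= ~df["no_response"].astype(bool)
    retained = df[keep]
    excluded = []
    n_cells = len(DELIBERATION_EVENTS) * df["context"].nunique()
    for p, grp in retained.groupby("participant"):
        n_trials = grp[["context", "tms_event", "trial"]].drop_duplicates().shape[0]
        if n_trials / n_cells < min_mean_trials:
            excluded.append(p)
    for p in df["participant"].unique():  # participants losing every trial
        if p not in retained["participant"].values and p not in excluded:
            excluded.append(p)
    return retained, excluded


def rt_match(
    rt_a,
    rt_b,
    rng: np.random.Generator,
    bin_width_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Match two RT distributions bin by bin.

    RTs are discretized into ``bin_width_ms`` bins anchored at 0 ms.  In
    every bin present on both sides, all trials of the smaller side are
    kept together with a uniform random subset of equal size from the
    larger side; bins present on one side only are dropped.  Returns
    index arrays into ``rt_a`` and ``rt_b``.
    """
    rt_a = np.asarray(rt_a, dtype=float)
    rt_b = np.asarray(rt_b, dtype=float)
    bins_a = np.floor(rt_a / bin_width_ms).astype(int)
    bins_b = np.floor(rt_b / bin_width_ms).astype(int)
    shared = sorted(set(bins_a) & set(bins_b))
    if not shared:
        warnings.warn("RT distributions do not overlap: empty match")
        return np.array([], dtype=int), np.array([], dtype=int)
    sel_a, sel_b = [], []
    for b in shared:
        ia = np.flatnonzero(bins_a == b)
        ib = np.flatnonzero(bins_b == b)
        n = min(len(ia), len(ib))
        sel_a.append(ia if len(ia) == n else rng.choice(ia, n, replace=False))
        sel_b.append(ib if len(ib) == n else rng.choice(ib, n, replace=False))
    return np.sort(np.concatenate(sel_a)), np.sort(np.concatenate(sel_b))


def _matched_trials(
    trials: pd.DataFrame, rng: np.random.Generator, bin_width_ms: float
) -> pd.DataFrame:
    """One RT-matching draw over a participant x timing trial table with
    exactly two contexts; returns the retained trial keys."""
    contexts = sorted(trials["context"].unique())
    if len(contexts) != 2:
        return trials
    a = trials[trials["context"] == contexts[0]].reset_index(drop=True)
    b = trials[trials["context"] == contexts[1]].reset_index(drop=True)
    ia, ib = rt_match(
        a["rt_ms"].to_numpy(), b["rt_ms"].to_numpy(), rng, bin_width_ms
    )
    return pd.concat([a.iloc[ia], b.iloc[ib]], ignore_index=True)


def aggregate_iterations(
    df: pd.DataFrame,
    rng: np.random.Generator,
    n_iter: int = 100,
    bin_width_ms: float = 200.0,
    condition_cols=("participant", "muscle", "body_side", "side_class",
                    "tms_event", "context"),
    value_col: str = "amplitude_uv",
) -> pd.DataFrame:
    """Iterated RT matching with median-of-medians aggregation.

    ``df`` is a tidy MEP table (one row per muscle observation) with
    ``participant``, ``context``, ``tms_event``, ``trial`` and ``rt_ms``
    columns.  Each iteration redraws the RT match between contexts
    (per participant and TMS timing), computes the per-condition median
    amplitude, and the final table is the median across iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    trial_cols = ["participant", "context", "tms_event", "trial", "rt_ms"]
    trials = df[trial_cols].drop_duplicates()
    per_iter = []
    for _ in range(n_iter):
        kept = []
        for _, grp in trials.groupby(["participant", "tms_event"], sort=True):
            kept.append(_matched_trials(grp, rng, bin_width_ms))
        keys = pd.concat(kept, ignore_index=True)[
            ["participant", "context", "tms_event", "trial"]
        ]
        sub = df.merge(keys, on=list(keys.columns), how="inner")
        med = sub.groupby(list(condition_cols), observed=True)[value_col].median()
        per_iter.append(med)
    stacked = pd.concat(per_iter, axis=1)
    out = stacked.median(axis=1).rename(value_col).reset_index()
    return out


def normalize_baseline(
    baseline: pd.DataFrame,
    rest: pd.DataFrame,
    on=("participant", "muscle", "body_side", "context"),
    value_col: str = "amplitude_uv",
) -> pd.DataFrame:
    """Baseline-timing MEP medians as a percentage of resting-state medians."""
    merged = baseline.merge(
        rest.rename(columns={value_col: "_rest"}), on=list(on), how="left"
    )
    if merged["_rest"].isna().any() or (merged["_rest"] <= 0).any():
        raise NormalizationError("missing or non-positive resting-state median")
    merged["percent"] = 100.0 * merged[value_col] / merged["_rest"]
    return merged.drop(columns=["_rest", value_col])


def normalize_deliberation(
    deliberation: pd.DataFrame,
    baseline: pd.DataFrame,
    on=("participant", "muscle", "body_side", "context"),
    value_col: str = "amplitude_uv",
    pool_body_sides: bool = True,
) -> pd.DataFrame:
    """Deliberation-timing MEP medians as a percentage of baseline medians.

    Normalization happens per hand (``body_side``) so that left and right
    MEPs are each scaled by their own baseline, and only then are values
    pooled (averaged) into chosen/unchosen classes.  Muscles recorded on
    one side only (leg) pool trivially.
    """
    merged = deliberation.merge(
        baseline.rename(columns={value_col: "_base"}), on=list(on), how="left"
    )
    if merged["_base"].isna().any() or (merged["_base"] <= 0).any():
        raise NormalizationError("missing or non-positive baseline median")
    merged["percent"] = 100.0 * merged[value_col] / merged["_base"]
    merged = merged.drop(columns=["_base", value_col])
    if not pool_body_sides:
        return merged
    keys = ["participant", "muscle", "side_class", "tms_event", "context"]
    return merged.groupby(keys, observed=True)["percent"].mean().reset_index()


#: Somatotopic arrangement of the 8 representation slots, lateral to
#: medial on the chosen hemisphere then medial to lateral on the
#: unchosen one (the two leg slots sit side by side at the midline).
SOMATOTOPIC_ORDER = (
    ("thumb", "chosen"),
    ("index", "chosen"),
    ("pinky", "chosen"),
    ("leg", "chosen"),
    ("leg", "unchosen"),
    ("pinky", "unchosen"),
    ("index", "unchosen"),
    ("thumb", "unchosen"),
)


def _interp_axis(n_nodes: int, n_interp: int) -> np.ndarray:
    """Fractional node coordinates with ``n_interp`` points inserted
    between consecutive nodes (nodes included)."""
    pts = [0.0]
    for i in range(n_nodes - 1):
        pts.extend(np.linspace(i, i + 1, n_interp + 2)[1:])
    return np.array(pts)


def spatiotemporal_map(
    table: pd.DataFrame,
    somatotopic_order=SOMATOTOPIC_ORDER,
    timings=DELIBERATION_EVENTS,
    n_interp: int = 100,
    value_col: str = "percent",
) -> dict:
    """Participant-averaged excitability maps and their context difference.

    ``table`` holds normalized excitability per participant x muscle x
    side_class x tms_event x context.  Values are averaged across
    participants, linearly interpolated along time (``n_interp`` points
    between consecutive timings) and then along the somatotopic axis
    (``n_interp`` points between adjacent representation slots).
    Returns ``{"hasty": grid, "cautious": grid, "difference": grid,
    "space_axis": ..., "time_axis": ...}`` with grids shaped
    (space, time) and difference = hasty - cautious.
    """
    mean = table.groupby(
        ["muscle", "side_class", "tms_event", "context"], observed=True
    )[value_col].mean()
    grids = {}
    for context in ("hasty", "cautious"):
        node = np.empty((len(somatotopic_order), len(timings)))
        for i, (muscle, side) in enumerate(somatotopic_order):
            for j, timing in enumerate(timings):
                key = (muscle, side, timing, context)
                if key not in mean.index:
                    raise MapError(
                        f"missing cell muscle={muscle} side={side} "
                        f"timing={timing} context={context}"
                    )
                node[i, j] = mean.loc[key]
        t_axis = _interp_axis(len(timings), n_interp)
        tgrid = np.vstack(
            [np.interp(t_axis, np.arange(len(timings)), row) for row in node]
        )
        s_axis = _interp_axis(len(somatotopic_order), n_interp)
        grid = np.vstack(
            [
                np.interp(s_axis, np.arange(len(somatotopic_order)), col)
                for col in tgrid.T
            ]
        ).T
        grids[context] = grid
    grids["difference"] = grids["hasty"] - grids["cautious"]
    grids["space_axis"] = _interp_axis(len(somatotopic_order), n_interp)
    grids["time_axis"] = _interp_axis(len(timings), n_interp)
    return grids
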