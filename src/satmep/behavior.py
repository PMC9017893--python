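"""Decision-behavior quantification: DTs, accuracy, evidence, urgency fits.

Decision time (DT) is the reaction time minus the participant's median
simple reaction time, removing sensory and motor conduction delays.  The
evidence at commitment is summarised by the sum of per-token
log-likelihood ratios (SumLogLR), proportional to the token-count
difference favouring the chosen circle.  Urgency at a given DT is
estimated as U = T / SumLogLR-at-DT: committing on weak evidence implies
high urgency.  Binning trials into DT deciles and regressing U on the
bin-mean DT yields each participant's urgency slope and intercept per
context.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .task_model import N_TOKENS, TokenTrial

__all__ = [
    "compute_dt",
    "jumps_elapsed",
    "sum_log_lr",
    "permutation_correlation",
    "UrgencyFit",
    "estimate_urgency_function",
    "paired_stats",
    "cohens_d_from_t",
]


def compute_dt(rt_ms, median_srt_ms):
    """DT = RT - median SRT (ms).  Negative DTs are legal but suspicious
    (a press faster than the participant's simple RT) and trigger a warning."""
    rt = np.asarray(rt_ms, dtype=float)
    if np.any(rt[~np.isnan(rt)] < 0) or median_srt_ms < 0:
        raise ValueError("RTs and median SRT must be non-negative")
    dt = rt - median_srt_ms
    if np.any(dt[~np.isnan(dt)] < 0):
        warnings.warn("negative decision time(s): RT below median SRT")
    return dt if dt.ndim else float(dt)


def jumps_elapsed(dt_ms: float) -> int:
    """Number of token jumps at or before time ``dt_ms`` (Jump_1 at 0 ms)."""
    return int(np.clip(dt_ms // 200 + 1, 1, N_TOKENS))


def sum_log_lr(
    jumps,
    n_jumps: int,
    chosen_side: str,
    per_token_log_lr: float = 1.0,
) -> float:
    """SumLogLR after ``n_jumps``: lambda * (tokens toward chosen - away).

    ``jumps`` is a :class:`TokenTrial` or a 15-character 'L'/'R' string.
    Each token carries a constant log-likelihood ratio ``per_token_log_lr``
    (lambda), signed by whether it favoured the chosen circle, so the sum
    is proportional to the token-count difference.
    """
    if isinstance(jumps, TokenTrial):
        jumps = jumps.jumps
    if not 1 <= n_jumps <= N_TOKENS:
        raise ValueError("n_jumps must be in 1..15")
    c = chosen_side[0].upper()
    n_chosen = jumps[:n_jumps].count(c)
    return per_token_log_lr * (2 * n_chosen - n_jumps)


def permutation_correlation(
    x,
    y,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson r with a two-sided permutation p-value.

    y is permuted across observations; p = (1 + #{|r_perm| >= |r_obs|})
    / (n_perm + 1), so the smallest attainable p is 1/(n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d arrays, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if rng is None:
        rng = np.random.default_rng()
    xc = x - x.mean()
    denom_x = np.sqrt(np.sum(xc**2))
    yc = y - y.mean()
    r_obs = float(np.sum(xc * yc) / (denom_x * np.sqrt(np.sum(yc**2))))
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    pc = perms - perms.mean(axis=1, keepdims=True)
    r_perm = pc @ xc / (denom_x * np.sqrt(np.sum(pc**2, axis=1)))
    p = (1 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (n_perm + 1)
    return r_obs, float(p)


@dataclass
class UrgencyFit:
    participant: object
    context: object
    bin_summaries: pd.DataFrame  # columns: mean_dt_s, mean_slr, urgency
    slope: float  # 1/s
    intercept: float


def estimate_urgency_function(
    records: pd.DataFrame,
    per_token_log_lr: float = 1.0,
    threshold: float = 1.0,
    n_bins: int = 10,
) -> UrgencyFit:
    """Fit one participant x context urgency function from behavior records.

    ``records`` needs columns ``jumps``, ``chosen_side``, ``dt_ms`` (plus
    optional ``no_response``).  Responded trials with positive DT and
    nonzero SumLogLR at DT are sorted by DT (stable) into ``n_bins``
    consecutive bins -- remainders go to the earliest bins -- then per
    bin U = threshold / mean SumLogLR, and OLS of U on the bin-mean DT
    (in seconds) gives the slope and intercept.  Bins whose mean SumLogLR
    is <= 0 are excluded with a warning; fewer than 3 usable bins is an
    error.
    """
    df = records
    if "no_response" in df.columns:
        df = df[~df["no_response"].astype(bool)]
    df = df.dropna(subset=["dt_ms", "chosen_side"])
    df = df[df["dt_ms"] > 0]
    slr = np.array(
        [
            sum_log_lr(j, jumps_elapsed(dt), side, per_token_log_lr)
            for j, dt, side in zip(df["jumps"], df["dt_ms"], df["chosen_side"])
        ]
    )
    keep = slr != 0
    df, slr = df[keep], slr[keep]
    if len(df) < n_bins:
        raise ValueError(
            f"need >= {n_bins} usable trials, got {len(df)}"
        )
    order = np.argsort(df["dt_ms"].to_numpy(), kind="stable")
    dt_s = df["dt_ms"].to_numpy()[order] / 1000.0
    slr = slr[order]

    n = len(dt_s)
    base, extra = divmod(n, n_bins)
    sizes = [base + (1 if i < extra else 0) for i in range(n_bins)]
    rows = []
    start = 0
    for i, size in enumerate(sizes):
        sl = slice(start, start + size)
        start += size
        mean_slr = float(np.mean(slr[sl]))
        rows.append(
            {
                "bin": i,
                "n_trials": size,
                "mean_dt_s": float(np.mean(dt_s[sl])),
                "mean_slr": mean_slr,
                "urgency": threshold / mean_slr if mean_slr > 0 else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    usable = bins.dropna(subset=["urgency"])
    if len(usable) < len(bins):
        warnings.warn(
            f"excluded {len(bins) - len(usable)} bin(s) with mean SumLogLR <= 0"
        )
    if len(usable) < 3:
        raise ValueError("fewer than 3 usable DT bins; cannot fit urgency")
    slope, intercept = np.polyfit(usable["mean_dt_s"], usable["urgency"], 1)
    participant = records["participant"].iloc[0] if "participant" in records else None
    context = records["context"].iloc[0] if "context" in records else None
    return UrgencyFit(participant, context, bins, float(slope), float(intercept))


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-samples effect size d = |t| / sqrt(n)."""
    return abs(t) / np.sqrt(n)


def paired_stats(values_a, values_b) -> tuple[float, float]:
    """Two-tailed paired t statistic and Cohen's d = |t|/sqrt(n)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("paired samples must be equal-length 1-d arrays, n >= 3")
    if np.ptp(a - b) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    t = float(stats.ttest_rel(a, b).statistic)
    return t, float(cohens_d_from_t(t, len(a)))
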