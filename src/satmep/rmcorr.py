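"""Repeated-measures correlation (rmCorr) and the seed-based MEP suite.

rmCorr estimates the common within-participant association between two
repeatedly measured variables: an ANCOVA with one intercept per
participant and a single shared slope.  Removing the between-participant
variance, the correlation coefficient is the signed square root of the
partial eta-squared of the covariate, with N - k - 1 error degrees of
freedom for N points and k participants.  Statistical significance is
assessed both parametrically and by permuting the response within each
participant, which preserves the intercept structure under the null.

The seed suite applies this machinery to single-trial normalized MEP
amplitudes at the late deliberation pulse: the chosen index finger is
the seed and is correlated with each of the five other finger
representations, separately per context, over iterated RT-matched
draws; context contrasts use 95% confidence-interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mep import rt_match

__all__ = [
    "RmCorrResult",
    "sqrt_transform",
    "rmcorr_fit",
    "permutation_p",
    "FINGER_TARGETS",
    "seed_correlation_suite",
]

SEED_COLUMN = "index_chosen"
FINGER_TARGETS = (
    "thumb_chosen",
    "pinky_chosen",
    "index_unchosen",
    "thumb_unchosen",
    "pinky_unchosen",
)


def sqrt_transform(values):
    """Elementwise square root (normalizes right-skewed MEP amplitudes)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("square-root transform requires non-negative values")
    return np.sqrt(v)


@dataclass(frozen=True)
class RmCorrResult:
    pair: str
    context: str | None
    r: float
    df: int
    p: float
    ci95: tuple[float, float]
    n_points: int
    n_participants: int


def _within_center(x: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    sums = np.bincount(codes, weights=x, minlength=k)
    counts = np.bincount(codes, minlength=k)
    return x - (sums / counts)[codes]


def _fisher_ci(r: float, df: int, level: float = 0.95) -> tuple[float, float]:
    if df <= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    se = 1.0 / np.sqrt(df - 1)
    zcrit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def rmcorr_fit(x, y, participants) -> RmCorrResult:
    """Common within-participant correlation of ``x`` and ``y``.

    Both variables are centered within participant (equivalent to
    projecting out the participant-intercept dummies); the correlation of
    the residuals is the rmCorr r, whose sign is the sign of the common
    slope.  df = N - k - 1; the parametric p comes from the t
    distribution and the CI from the Fisher z transform with standard
    error 1/sqrt(df - 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(participants))
    k = len(uniques)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1 or n != len(codes):
        raise ValueError("x, y and participants must be equal-length 1-d arrays")
    df = n - k - 1
    if df < 1:
        raise ValueError("not enough points for the ANCOVA error term")
    xc = _within_center(x, codes, k)
    yc = _within_center(y, codes, k)
    ssx = float(np.sum(xc**2))
    ssy = float(np.sum(yc**2))
    if ssx == 0:
        raise ValueError("no within-participant variance in x")
    if ssy == 0:
        raise ValueError("no within-participant variance in y")
    r = float(np.sum(xc * yc) / np.sqrt(ssx * ssy))
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return RmCorrResult("", None, r, df, p, _fisher_ci(r, df), n, k)


def permutation_p(
    x,
    y,
    participants,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation p-value for rmCorr.

    ``y`` is shuffled independently within each participant, holding the
    participant structure fixed; p = (1 + #{|r_perm| >= |r_obs|}) /
    (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    codes, uniques = pd.factorize(np.asarray(participants))
    k = len(uniques)
    xc = _within_center(x, codes, k)
    yc = _within_center(y, codes, k)
    ssx = np.sum(xc**2)
    if ssx == 0 or np.sum(yc**2) == 0:
        raise ValueError("degenerate rmCorr input")
    r_obs = abs(np.sum(xc * yc) / np.sqrt(ssx * np.sum(yc**2)))
    groups = [np.flatnonzero(codes == g) for g in range(k)]
    count = 0
    yp = y.copy()
    for _ in range(n_perm):
        for idx in groups:
            yp[idx] = y[idx][rng.permutation(len(idx))]
        ypc = _within_center(yp, codes, k)
        r = abs(np.sum(xc * ypc) / np.sqrt(ssx * np.sum(ypc**2)))
        if r >= r_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def seed_correlation_suite(
    table: pd.DataFrame,
    rng: np.random.Generator,
    n_iterations: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.005,
    bin_width_ms: float = 200.0,
    apply_sqrt: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed-based single-trial correlation analysis at the late pulse.

    ``table`` holds one row per trial with columns ``participant``,
    ``context``, ``rt_ms`` and the six normalized finger amplitudes
    (``index_chosen`` ... ``pinky_unchosen``).  Each iteration redraws
    the per-participant RT match between contexts, square-root-transforms
    the amplitudes, and computes rmCorr r and its within-participant
    permutation p for the 5 seed-target pairs in both contexts.  Medians
    across iterations are reported; significance uses the
    Bonferroni-corrected ``alpha``; the context contrast per pair is
    significant when the 95% CIs do not overlap.

    Returns (results, contrasts): 10 result rows (5 pairs x 2 contexts)
    and 5 contrast rows.
    """
    contexts = sorted(table["context"].unique())
    if len(contexts) != 2:
        raise ValueError("expected exactly two contexts")
    missing = [
        c for c in (SEED_COLUMN,) + FINGER_TARGETS if c not in table.columns
    ]
    if missing:
        raise KeyError(f"missing muscle column(s): {missing}")

    acc: dict[tuple[str, str], dict[str, list]] = {
        (t, c): {"r": [], "p": [], "df": [], "n": []}
        for t in FINGER_TARGETS
        for c in contexts
    }
    for _ in range(n_iterations):
        parts = []
        for _, grp in table.groupby("participant", sort=True):
            a = grp[grp["context"] == contexts[0]].reset_index(drop=True)
            b = grp[grp["context"] == contexts[1]].reset_index(drop=True)
            ia, ib = rt_match(
                a["rt_ms"].to_numpy(), b["rt_ms"].to_numpy(), rng, bin_width_ms
            )
            parts.extend([a.iloc[ia], b.iloc[ib]])
        matched = pd.concat(parts, ignore_index=True)
        for context in contexts:
            sub = matched[matched["context"] == context]
            seed = sub[SEED_COLUMN].to_numpy()
            if apply_sqrt:
                seed = sqrt_transform(seed)
            for target in FINGER_TARGETS:
                yv = sub[target].to_numpy()
                if apply_sqrt:
                    yv = sqrt_transform(yv)
                res = rmcorr_fit(seed, yv, sub["participant"].to_numpy())
                p = permutation_p(
                    seed, yv, sub["participant"].to_numpy(), n_perm, rng
                )
                cell = acc[(target, context)]
                cell["r"].append(res.r)
                cell["p"].append(p)
                cell["df"].append(res.df)
                cell["n"].append(res.n_points)

    rows = []
    for (target, context), cell in acc.items():
        r_med = float(np.median(cell["r"]))
        df_med = int(np.median(cell["df"]))
        lo, hi = _fisher_ci(r_med, df_med)
        rows.append(
            {
                "pair": f"{SEED_COLUMN}~{target}",
                "context": context,
                "r": r_med,
                "p": float(np.median(cell["p"])),
                "df": df_med,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_points": int(np.median(cell["n"])),
                "significant": float(np.median(cell["p"])) < alpha,
            }
        )
    results = pd.DataFrame(rows)

    contrasts = []
    for target in FINGER_TARGETS:
        pair = f"{SEED_COLUMN}~{target}"
        a = results[(results["pair"] == pair) & (results["context"] == contexts[0])]
        b = results[(results["pair"] == pair) & (results["context"] == contexts[1])]
        a, b = a.iloc[0], b.iloc[0]
        overlap = (a["ci_lo"] <= b["ci_hi"]) and (b["ci_lo"] <= a["ci_hi"])
        contrasts.append(
            {
                "pair": pair,
                f"r_{contexts[0]}": a["r"],
                f"r_{contexts[1]}": b["r"],
                "ci_overlap": overlap,
                "significant_difference": not overlap,
            }
        )
    return results, pd.DataFrame(contrasts)
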