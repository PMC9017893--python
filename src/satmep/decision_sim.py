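"""Urgency-gating simulation of choices and response times in the tokens task.

The urgency-gating model evaluates, at each token jump, the product of
the current evidence (the signed token-count difference) and a linearly
growing, half-wave-rectified urgency signal:

    y_i = (N_i - N_j) * [a*t + b]+        (commit when y_i >= T)

where ``t`` is the time in seconds since deliberation onset (Jump_1),
``a`` and ``b`` are the urgency slope and intercept, and ``T`` is a fixed
threshold.  A larger intercept ``b`` makes the agent hastier: it commits
earlier, on weaker evidence.  Response time adds a simple-RT motor delay
(sensory + motor conduction) to the commitment time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_model import N_TOKENS, SessionSchedule, TokenTrial

__all__ = [
    "UrgencyGatingParams",
    "SimulatedResponse",
    "simulate_choice",
    "simulate_session",
    "draw_motor_delay",
]


@dataclass(frozen=True)
class UrgencyGatingParams:
    """Parameters of one urgency-gating agent.

    a : urgency slope (1/s).
    b : urgency intercept (dimensionless); the hastiness knob.
    threshold : fixed decision bound T (default 1).
    evidence_unit : contribution of one net token to the evidence term.
    noise_sd : SD of zero-mean Gaussian noise drawn per side at each
        evaluation (0 = deterministic).
    noise_on : where the noise enters -- 'evidence' perturbs the token
        count difference before the urgency gain (so hasty agents, who
        commit on weak evidence under a high gain, err more), while
        'activation' adds it to y after the gain.
    t_offset_s : offset added to the elapsed time entering the urgency
        signal (0 anchors t at Jump_1).
    """

    a: float
    b: float
    threshold: float = 1.0
    evidence_unit: float = 1.0
    noise_sd: float = 0.0
    noise_on: str = "evidence"
    t_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_on not in ("evidence", "activation"):
            raise ValueError("noise_on must be 'evidence' or 'activation'")


@dataclass(frozen=True)
class SimulatedResponse:
    chosen_side: str | None  # None = no response before Jump_15
    commitment_ms: int | None
    correct: bool | None

    @property
    def responded(self) -> bool:
        return self.chosen_side is not None


def simulate_choice(
    trial: TokenTrial,
    params: UrgencyGatingParams,
    rng: np.random.Generator | None = None,
) -> SimulatedResponse:
    """Run the urgency-gating race on one trial.

    Evidence changes only at token jumps, so y is evaluated at each jump
    time t_k = (k - 1) * 0.2 s; the first side whose y reaches the
    threshold wins and evaluation stops.  With noise both sides can cross
    at the same evaluation; such ties break uniformly at random.  If no
    crossing occurs by Jump_15 the trial ends without a response.
    """
    if params.noise_sd > 0 and rng is None:
        raise ValueError("noisy simulation requires an rng")
    n_left = n_right = 0
    for k in range(1, N_TOKENS + 1):
        n_left, n_right = (
            (n_left + 1, n_right)
            if trial.jumps[k - 1] == "L"
            else (n_left, n_right + 1)
        )
        t = (k - 1) * 0.2 + params.t_offset_s
        urgency = max(params.a * t + params.b, 0.0)
        diff = (n_left - n_right) * params.evidence_unit
        if params.noise_sd > 0:
            eps_l, eps_r = rng.normal(0.0, params.noise_sd, size=2)
        else:
            eps_l = eps_r = 0.0
        if params.noise_on == "evidence":
            y_left = (diff + eps_l) * urgency
            y_right = (-diff + eps_r) * urgency
        else:
            y_left = diff * urgency + eps_l
            y_right = -diff * urgency + eps_r
        left_hit = y_left >= params.threshold
        right_hit = y_right >= params.threshold
        if left_hit and right_hit:
            side = "left" if rng.random() < 0.5 else "right"
        elif left_hit:
            side = "left"
        elif right_hit:
            side = "right"
        else:
            continue
        return SimulatedResponse(side, (k - 1) * 200, side == trial.correct_side)
    return SimulatedResponse(None, None, None)


def draw_motor_delay(
    median_ms: float,
    sigma: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Log-normal simple-RT delay with the given median (ms)."""
    if median_ms < 0:
        raise ValueError("median delay must be non-negative")
    return rng.lognormal(np.log(median_ms), sigma, size=size)


def simulate_session(
    schedule: SessionSchedule,
    params: UrgencyGatingParams,
    context: str,
    rng: np.random.Generator,
    participant: str | int = 0,
    srt_median_ms: float = 250.0,
    srt_sigma: float = 0.15,
) -> pd.DataFrame:
    """Simulate one session; returns one behavior record per trial.

    RT = commitment time + a log-normal motor delay drawn per trial; the
    delay draw is consumed on every trial (responded or not) so the
    random stream does not depend on the agent's choices.
    """
    rows = []
    for entry in schedule:
        resp = simulate_choice(entry.trial, params, rng)
        delay = float(draw_motor_delay(srt_median_ms, srt_sigma, rng))
        rows.append(
            {
                "participant": participant,
                "context": context,
                "trial": entry.index,
                "trial_type": entry.trial.trial_type,
                "tms_event": entry.tms_event,
                "correct_side": entry.trial.correct_side,
                "jumps": entry.trial.jumps,
                "chosen_side": resp.chosen_side,
                "correct": resp.correct,
                "commitment_ms": resp.commitment_ms,
                "rt_ms": (
                    resp.commitment_ms + delay if resp.responded else np.nan
                ),
                "no_response": not resp.responded,
            }
        )
    return pd.DataFrame(rows)
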