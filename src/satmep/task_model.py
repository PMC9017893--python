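"""Tokens decision task: success probability, trial generation, and session scheduling.

The task presents 15 tokens that jump one by one, every 200 ms, from a
central circle to one of two lateral circles.  The participant predicts
which lateral circle will ultimately hold the majority (>= 8 of 15) of
the tokens.  This module implements the task's probabilistic machinery
(the exact success probability of a choice given the current token
counts), generators for the four trial types used in the experiment
(ambiguous, obvious, misleading, random), the reward/penalty schedule of
the two speed-accuracy contexts, the within-trial timeline, and the
320-trial session schedule with its TMS-timing assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "TRIAL_TYPES",
    "TMS_EVENTS",
    "DELIBERATION_EVENTS",
    "TokenTrial",
    "TaskClock",
    "PayoffScheme",
    "ScheduledTrial",
    "SessionSchedule",
    "DEFAULT_COMPOSITION",
    "success_probability",
    "success_trajectory",
    "generate_trial",
    "build_session_schedule",
    "outcome_score",
    "trial_timeline",
    "GenerationError",
    "ConfigError",
]

N_TOKENS = 15
MAJORITY = 8  # tokens needed to win (8 of 15)

TRIAL_TYPES = ("ambiguous", "obvious", "misleading", "random")
TMS_EVENTS = ("none", "baseline", "jump1", "jump4", "jump7")
DELIBERATION_EVENTS = ("jump1", "jump4", "jump7")

#: Jump index probed by each deliberation TMS event (1-based).
TMS_EVENT_JUMP = {"jump1": 1, "jump4": 4, "jump7": 7}


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


class ConfigError(ValueError):
    """Inconsistent session/schedule configuration."""


def success_probability(n_left: int, n_right: int, n_center: int) -> float:
    """Probability that the *left* circle ends up with the token majority.

    Given ``n_left``/``n_right`` tokens already in the lateral circles and
    ``n_center`` still in the centre (each of which will jump to either
    side with probability 1/2), the left response is ultimately correct
    iff at most ``7 - n_right`` of the remaining tokens go right:

        p(L) = sum_{k=0}^{min(n_center, 7 - n_right)} C(n_center, k) / 2**n_center

    Computed with exact integer binomials; the single final division
    keeps the error well below 1e-12.
    """
    if n_left < 0 or n_right < 0 or n_center < 0:
        raise ValueError("token counts must be non-negative")
    if n_left + n_right + n_center > N_TOKENS:
        raise ValueError("token counts exceed the 15 tokens of a trial")
    upper = min(n_center, (MAJORITY - 1) - n_right)
    if upper < 0:
        return 0.0
    return sum(comb(n_center, k) for k in range(upper + 1)) / 2**n_center


@dataclass(frozen=True)
class TokenTrial:
    """One trial's token-jump sequence.

    ``jumps`` is a 15-character string of ``'L'``/``'R'`` destinations;
    jump *k* occurs at ``(k - 1) * 200`` ms from deliberation onset
    (Jump_1 = 0 ms).
    """

    trial_type: str
    correct_side: str  # 'left' | 'right'
    jumps: str

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.correct_side not in ("left", "right"):
            raise ValueError(f"invalid side {self.correct_side!r}")
        if len(self.jumps) != N_TOKENS or set(self.jumps) - {"L", "R"}:
            raise ValueError("jumps must be 15 characters of 'L'/'R'")
        if self.jumps.count(self.correct_side[0].upper()) < MAJORITY:
            raise ValueError("correct side must receive >= 8 tokens")

    @property
    def jump_times_ms(self) -> tuple[int, ...]:
        return tuple(200 * k for k in range(N_TOKENS))

    def counts_after(self, n_jumps: int) -> tuple[int, int, int]:
        """(n_correct, n_incorrect, n_center) after the first ``n_jumps``."""
        if not 0 <= n_jumps <= N_TOKENS:
            raise ValueError("n_jumps must be in 0..15")
        c = self.correct_side[0].upper()
        n_corr = self.jumps[:n_jumps].count(c)
        return n_corr, n_jumps - n_corr, N_TOKENS - n_jumps


def success_trajectory(trial: TokenTrial) -> np.ndarray:
    """Success probability of the *correct* side after each of the 15 jumps."""
    out = np.empty(N_TOKENS)
    for k in range(1, N_TOKENS + 1):
        n_corr, n_inc, n_cen = trial.counts_after(k)
        out[k - 1] = success_probability(n_corr, n_inc, n_cen)
    return out


# Valid completions of an ambiguous trial after the 10 alternating jumps:
# the correct side holds 5 of 10 and needs >= 3 of the last 5 tokens.
_AMBIGUOUS_TAILS = [
    tail
    for tail in itertools.product((1, 0), repeat=5)
    if sum(tail) >= MAJORITY - 5
]


def _sides_to_string(toward_correct: Sequence[int], correct_side: str) -> str:
    c = correct_side[0].upper()
    o = "R" if c == "L" else "L"
    return "".join(c if x else o for x in toward_correct)


def generate_trial(
    trial_type: str,
    rng: np.random.Generator,
    correct_side: str | None = None,
    max_attempts: int = 10_000,
) -> TokenTrial:
    """Sample one trial of the requested type.

    * ambiguous  -- strict alternation through Jump_10 starting toward the
      correct circle (counts equal after even jumps, correct side leads by
      one after odd jumps), then a uniform draw among the 16 tails that
      give the correct side >= 8 tokens.  Keeps the success probability
      within [0.5, 0.66] up to Jump_10.
    * obvious    -- rejection sampling until the correct-side trajectory
      exceeds 0.7 after Jump_3 and 0.8 after Jump_5.
    * misleading -- rejection sampling until the trajectory falls below
      0.4 after Jump_3 while the correct side still ends with >= 8.
    * random     -- 15 fair coin flips; the majority side (always defined
      with 15 tokens) is labelled correct post hoc.
    """
    if trial_type not in TRIAL_TYPES:
        raise ValueError(f"unknown trial type {trial_type!r}")
    if correct_side is None and trial_type != "random":
        correct_side = "left" if rng.random() < 0.5 else "right"

    if trial_type == "ambiguous":
        head = [1, 0] * 5  # toward-correct flags, jumps 1..10
        tail = _AMBIGUOUS_TAILS[rng.integers(len(_AMBIGUOUS_TAILS))]
        jumps = _sides_to_string(head + list(tail), correct_side)
        return TokenTrial(trial_type, correct_side, jumps)

    if trial_type == "random":
        flips = rng.integers(0, 2, size=N_TOKENS)
        jumps = "".join("L" if x else "R" for x in flips)
        majority = "left" if jumps.count("L") >= MAJORITY else "right"
        if correct_side is not None and majority != correct_side:
            # mirror the sequence so the requested side wins
            jumps = jumps.translate(str.maketrans("LR", "RL"))
            majority = correct_side
        return TokenTrial(trial_type, majority, jumps)

    for _ in range(max_attempts):
        toward = rng.integers(0, 2, size=N_TOKENS)
        if toward.sum() < MAJORITY:
            continue
        trial = TokenTrial(
            trial_type, correct_side, _sides_to_string(toward, correct_side)
        )
        p = success_trajectory(trial)
        if trial_type == "obvious" and p[2] > 0.7 and p[4] > 0.8:
            return trial
        if trial_type == "misleading" and p[2] < 0.4:
            return trial
    raise GenerationError(
        f"no valid {trial_type} sequence within {max_attempts} attempts"
    )


@dataclass(frozen=True)
class TaskClock:
    """Within-trial timing constants (all ms).

    The inter-trial screen opens the trial; tokens appear after it and
    the first jump follows the pre-jump delay.  The baseline TMS pulse
    precedes tokens onset by ``baseline_pulse_lead_ms`` and therefore
    precedes Jump_1 by the lead plus the pre-jump delay (1,300 ms by
    default).
    """

    pre_jump_delay_ms: int = 800
    inter_jump_ms: int = 200
    feedback_ms: int = 500
    inter_trial_ms: int = 2500
    baseline_pulse_lead_ms: int = 500

    @property
    def tokens_onset_ms(self) -> int:
        return self.inter_trial_ms

    @property
    def trial_duration_ms(self) -> int:
        return (
            self.inter_trial_ms
            + self.pre_jump_delay_ms
            + (N_TOKENS - 1) * self.inter_jump_ms
            + self.feedback_ms
        )


def trial_timeline(clock: TaskClock = TaskClock()) -> list[tuple[int, str]]:
    """Ordered (time_ms, label) events of one trial, absolute from trial start."""
    events: list[tuple[int, str]] = [(0, "intertrial_onset")]
    onset = clock.tokens_onset_ms
    events.append((onset - clock.baseline_pulse_lead_ms, "baseline_pulse"))
    events.append((onset, "tokens_onset"))
    jump1 = onset + clock.pre_jump_delay_ms
    for k in range(N_TOKENS):
        events.append((jump1 + k * clock.inter_jump_ms, f"jump{k + 1}"))
    feedback_on = jump1 + (N_TOKENS - 1) * clock.inter_jump_ms
    events.append((feedback_on, "feedback_onset"))
    events.append((feedback_on + clock.feedback_ms, "trial_end"))
    events.sort(key=lambda e: e[0])
    return events


@dataclass(frozen=True)
class PayoffScheme:
    """Reward/penalty schedule of one speed-accuracy context (euro cents)."""

    context: str  # 'hasty' | 'cautious'
    penalty_incorrect_cents: int
    penalty_no_response_cents: int = -4

    @classmethod
    def for_context(cls, context: str) -> "PayoffScheme":
        if context == "hasty":
            return cls("hasty", -4)
        if context == "cautious":
            return cls("cautious", -14)
        raise ValueError(f"unknown context {context!r}")


def outcome_score(
    correct: bool,
    response_interval: int | None,
    scheme: PayoffScheme,
) -> int:
    """Score (cents) of one trial.

    ``response_interval`` = k means the key press fell between Jump_k and
    Jump_{k+1} (k in 1..14), so ``15 - k`` tokens remained in the centre;
    the reward for a correct choice equals that count.  ``None`` encodes
    a no-response trial (-4 cents in both contexts).
    """
    if response_interval is None:
        return scheme.penalty_no_response_cents
    if not 1 <= response_interval <= N_TOKENS - 1:
        raise ValueError("response must fall between Jump_1 and Jump_15")
    if correct:
        return N_TOKENS - response_interval
    return scheme.penalty_incorrect_cents


@dataclass(frozen=True)
class ScheduledTrial:
    index: int
    trial: TokenTrial
    tms_event: str


#: Session composition: (trial_type, tms_event) -> trial count.  The
#: deliberation pulses of ambiguous trials split 58/56/56 across
#: Jump_1/4/7; obvious and misleading splits are balanced with the
#: remainder to the earliest timing.  291 of the 320 trials carry a pulse.
DEFAULT_COMPOSITION: dict[tuple[str, str], int] = {
    ("ambiguous", "none"): 17,
    ("ambiguous", "jump1"): 58,
    ("ambiguous", "jump4"): 56,
    ("ambiguous", "jump7"): 56,
    ("obvious", "none"): 3,
    ("obvious", "jump1"): 16,
    ("obvious", "jump4"): 15,
    ("obvious", "jump7"): 15,
    ("misleading", "none"): 6,
    ("misleading", "jump1"): 16,
    ("misleading", "jump4"): 16,
    ("misleading", "jump7"): 16,
    ("random", "none"): 3,
    ("random", "baseline"): 27,
}

SESSION_TRIALS = 320


@dataclass
class SessionSchedule:
    """One session's 320 trials with their TMS-timing assignments."""

    entries: list[ScheduledTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def cross_tab(self) -> dict[tuple[str, str], int]:
        tab: dict[tuple[str, str], int] = {}
        for e in self.entries:
            key = (e.trial.trial_type, e.tms_event)
            tab[key] = tab.get(key, 0) + 1
        return tab

    def n_stimulated(self) -> int:
        return sum(1 for e in self.entries if e.tms_event != "none")


def build_session_schedule(
    composition: dict[tuple[str, str], int] | None = None,
    rng: np.random.Generator | None = None,
) -> SessionSchedule:
    """Shuffled 320-trial schedule whose type x timing cross-tab equals
    ``composition`` (default: the experiment's composition table)."""
    if composition is None:
        composition = DEFAULT_COMPOSITION
    if rng is None:
        rng = np.random.default_rng()
    for (ttype, event), n in composition.items():
        if ttype not in TRIAL_TYPES or event not in TMS_EVENTS:
            raise ConfigError(f"invalid composition cell ({ttype}, {event})")
        if n < 0:
            raise ConfigError("composition counts must be non-negative")
        if event == "baseline" and ttype != "random":
            raise ConfigError("baseline pulses are restricted to random trials")
    total = sum(composition.values())
    if total != SESSION_TRIALS:
        raise ConfigError(f"composition sums to {total}, expected {SESSION_TRIALS}")

    slots: list[tuple[str, str]] = []
    for key, n in composition.items():
        slots.extend([key] * n)
    order = rng.permutation(len(slots))
    entries = []
    for i, j in enumerate(order):
        ttype, event = slots[j]
        entries.append(ScheduledTrial(i, generate_trial(ttype, rng), event))
    return SessionSchedule(entries)
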