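"""Synthetic cohorts with known ground truth for end-to-end pipeline tests.

Generates complete datasets mimicking the structure of a two-session
speed-accuracy experiment: urgency-gating agents whose context-dependent
intercepts produce the speed-accuracy shift; per-trial MEP amplitudes
drawn from a configurable excitability model (time-increasing gain,
context gains per representation x side class x timing, a shared
trial-level gain controlling cross-muscle coupling, multiplicative
observation noise); and raw EMG traces embedding biphasic MEP waveforms
and voluntary pre-press bursts in Gaussian background noise.  Every
dataset is accompanied by its ground truth, so recovery of configured
effects by the analysis pipelines is directly testable.

The default configuration encodes the study conditions: the session
composition of the experiment, a hasty urgency intercept about twice the
cautious one, a 20% amplification of the chosen index and a 15%
suppression of the adjacent thumb/pinky at the late pulse, a context-
independent unchosen side, and stronger cross-muscle trial coupling in
the cautious context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decision_sim import UrgencyGatingParams, simulate_session
from .mep import EmgTrace, SEARCH_WINDOW_FINGER, SEARCH_WINDOW_LEG
from .task_model import (
    DEFAULT_COMPOSITION,
    TMS_EVENT_JUMP,
    build_session_schedule,
)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "default_context_gains",
    "agent_parameters",
    "simulate_behavior",
    "emulate_sat_shift",
    "generate_mep_table",
    "mep_template",
    "synthesize_trial_emg",
    "generate_cohort",
]

CONTEXTS = ("hasty", "cautious")
FINGER_MUSCLES = ("index", "thumb", "pinky")
LEG_MUSCLES = ("ta", "lg", "mg")
#: muscle -> somatotopic representation
REPRESENTATION = {
    "index": "index",
    "thumb": "thumb",
    "pinky": "pinky",
    "ta": "leg",
    "lg": "leg",
    "mg": "leg",
}
BASELINE_PULSE_MS = -1300.0
TRACE_START_MS = -1800.0
TRACE_SAMPLES = 8000


def default_context_gains() -> dict:
    """Hasty-context excitability multipliers per (representation,
    side_class, tms_event); unlisted cells are 1.  Chosen-index
    amplification and thumb/pinky surround suppression act at the late
    pulse; the leg amplification is a main effect across deliberation."""
    gains = {}
    gains[("index", "chosen", "jump7")] = 1.20
    gains[("thumb", "chosen", "jump7")] = 0.85
    gains[("pinky", "chosen", "jump7")] = 0.85
    for event in ("jump1", "jump4", "jump7"):
        gains[("leg", "chosen", event)] = 1.15
    return gains


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the study conditions."""

    n_participants: int = 20
    group: str = "finger"  # 'finger' | 'leg'
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    # urgency-gating agents (a ~ N, b ~ N per context, truncated at >= 0)
    a_mean: float = 0.6
    a_sd: float = 0.15
    b_mean: dict = field(
        default_factory=lambda: {"hasty": 0.45, "cautious": 0.15}
    )
    b_sd: float = 0.12
    decision_noise_sd: float = 0.5
    srt_median_ms: float = 250.0
    srt_sigma: float = 0.15
    # excitability model
    baseline_amplitude_uv: dict = field(
        default_factory=lambda: {
            "index": 800.0,
            "thumb": 600.0,
            "pinky": 500.0,
            "ta": 200.0,
            "lg": 120.0,
            "mg": 120.0,
        }
    )
    timing_gain: dict = field(
        default_factory=lambda: {
            "rest": 1.0,
            "baseline": 1.0,
            "jump1": 1.05,
            "jump4": 1.15,
            "jump7": 1.30,
        }
    )
    context_gain_hasty: dict = field(default_factory=default_context_gains)
    context_gain_cautious: dict = field(default_factory=dict)
    coupling_sd: dict = field(
        default_factory=lambda: {"hasty": 0.05, "cautious": 0.25}
    )
    mep_noise_sigma: float = 0.25
    n_rest_trials: int = 40
    # raw EMG synthesis
    emg_noise_uv: float = 3.0
    mep_onset_ms: dict = field(
        default_factory=lambda: {"finger": 20.0, "leg": 30.0}
    )
    mep_duration_ms: float = 15.0
    vigor_burst_uv: float = 300.0
    vigor_burst_other_uv: float = 60.0
    vigor_burst_duration_ms: float = 150.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("finger", "leg"):
            raise ValueError("group must be 'finger' or 'leg'")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        for v in list(self.baseline_amplitude_uv.values()) + [
            self.decision_noise_sd,
            self.mep_noise_sigma,
            self.emg_noise_uv,
        ]:
            if v < 0:
                raise ValueError("amplitudes and SDs must be non-negative")

    @property
    def muscles(self) -> tuple[str, ...]:
        return FINGER_MUSCLES if self.group == "finger" else LEG_MUSCLES

    @property
    def body_sides(self) -> tuple[str, ...]:
        return ("left", "right") if self.group == "finger" else ("right",)

    def context_gain(
        self, context: str, representation: str, side_class: str, event: str
    ) -> float:
        table = (
            self.context_gain_hasty
            if context == "hasty"
            else self.context_gain_cautious
        )
        return table.get((representation, side_class, event), 1.0)


@dataclass
class GroundTruth:
    """True generative parameters serialized alongside each dataset."""

    agents: pd.DataFrame  # participant, context, a, b
    config: CohortConfig

    def to_json(self, path) -> None:
        payload = {
            "agents": self.agents.to_dict(orient="records"),
            "config": {
                k: v for k, v in asdict(self.config).items()
                if not isinstance(v, dict)
            }
            | {
                "context_gain_hasty": {
                    "|".join(k): v
                    for k, v in self.config.context_gain_hasty.items()
                },
                "coupling_sd": self.config.coupling_sd,
                "b_mean": self.config.b_mean,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _spawn(config: CohortConfig, *key: int) -> np.random.Generator:
    """Named sub-stream of the master seed: independent, reproducible."""
    return np.random.default_rng(np.random.SeedSequence((config.master_seed, *key)))


def agent_parameters(config: CohortConfig) -> pd.DataFrame:
    """Per-agent urgency parameters (a shared, b per context)."""
    rng = _spawn(config, 0)
    rows = []
    for p in range(config.n_participants):
        a = max(rng.normal(config.a_mean, config.a_sd), 0.05)
        for context in CONTEXTS:
            b = max(rng.normal(config.b_mean[context], config.b_sd), 0.0)
            rows.append({"participant": p, "context": context, "a": a, "b": b})
    return pd.DataFrame(rows)


def simulate_behavior(
    config: CohortConfig, agents: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Behavior tables for every agent x context session."""
    if agents is None:
        agents = agent_parameters(config)
    frames = []
    for row in agents.itertuples():
        rng = _spawn(config, 1, int(row.participant), CONTEXTS.index(row.context))
        schedule = build_session_schedule(config.composition, rng)
        params = UrgencyGatingParams(
            a=row.a, b=row.b, noise_sd=config.decision_noise_sd
        )
        frames.append(
            simulate_session(
                schedule,
                params,
                row.context,
                rng,
                participant=int(row.participant),
                srt_median_ms=config.srt_median_ms,
                srt_sigma=config.srt_sigma,
            )
        )
    return pd.concat(frames, ignore_index=True)


def emulate_sat_shift(config: CohortConfig) -> pd.DataFrame:
    """Behavior-only cohort exhibiting the context-dependent SAT shift
    (hastier intercepts in the hasty context)."""
    return simulate_behavior(config)


def _side_class(body_side: str, chosen_side: str) -> str:
    return "chosen" if body_side == chosen_side else "unchosen"


def _amplitude(
    config: CohortConfig,
    rng: np.random.Generator,
    muscle: str,
    context: str,
    event: str,
    side_class: str | None,
    shared_gain: float,
) -> float:
    base = config.baseline_amplitude_uv[muscle]
    gain = config.timing_gain[event]
    if side_class is not None:
        gain *= config.context_gain(
            context, REPRESENTATION[muscle], side_class, event
        )
    noise = rng.lognormal(0.0, config.mep_noise_sigma)
    return base * gain * shared_gain * noise


def generate_mep_table(
    config: CohortConfig,
    behavior: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Behavior plus a tidy single-observation MEP amplitude table.

    One row per stimulated trial x recorded muscle, with ``tms_event`` in
    {rest, baseline, jump1, jump4, jump7}.  Deliberation rows exist only
    for responded trials (the chosen/unchosen classification needs a
    response); rest rows are extra-task stimulations without trial
    context.  This is the fast path for pipeline tests -- amplitudes are
    drawn directly from the excitability model without waveform synthesis.
    """
    agents = agent_parameters(config)
    if behavior is None:
        behavior = simulate_behavior(config, agents)
    rows = []
    for (participant, context), session in behavior.groupby(
        ["participant", "context"], sort=True
    ):
        rng = _spawn(config, 2, int(participant), CONTEXTS.index(context))
        for _ in range(config.n_rest_trials):
            for muscle in config.muscles:
                for body_side in config.body_sides:
                    rows.append(
                        {
                            "participant": participant,
                            "context": context,
                            "trial": -1,
                            "tms_event": "rest",
                            "muscle": muscle,
                            "body_side": body_side,
                            "representation": REPRESENTATION[muscle],
                            "side_class": None,
                            "rt_ms": np.nan,
                            "amplitude_uv": _amplitude(
                                config, rng, muscle, context, "rest", None, 1.0
                            ),
                        }
                    )
        for trial in session.itertuples():
            event = trial.tms_event
            if event not in config.timing_gain or event == "none":
                continue
            is_baseline = event == "baseline"
            if not is_baseline and trial.no_response:
                continue
            shared = rng.lognormal(0.0, config.coupling_sd[context])
            for muscle in config.muscles:
                for body_side in config.body_sides:
                    side_class = (
                        None
                        if is_baseline
                        else _side_class(body_side, trial.chosen_side)
                    )
                    rows.append(
                        {
                            "participant": participant,
                            "context": context,
                            "trial": trial.trial,
                            "tms_event": event,
                            "muscle": muscle,
                            "body_side": body_side,
                            "representation": REPRESENTATION[muscle],
                            "side_class": side_class,
                            "rt_ms": trial.rt_ms,
                            "amplitude_uv": _amplitude(
                                config,
                                rng,
                                muscle,
                                context,
                                event,
                                side_class,
                                1.0 if is_baseline else shared,
                            ),
                        }
                    )
    meps = pd.DataFrame(rows)
    # attach trial metadata needed by the inclusion filter
    meta = behavior[
        ["participant", "context", "trial", "trial_type", "no_response"]
    ].drop_duplicates()
    meps = meps.merge(meta, on=["participant", "context", "trial"], how="left")
    meps["trial_type"] = meps["trial_type"].fillna("rest")
    meps["no_response"] = meps["no_response"].eq(True)  # NaN (rest rows) -> False
    return behavior, meps, GroundTruth(agents, config)


def mep_template(
    duration_ms: float = 15.0, sampling_rate_hz: float = 2000.0
) -> np.ndarray:
    """Unit peak-to-peak biphasic MEP waveform: one sine cycle under a
    raised-cosine (Hann) envelope."""
    n = max(int(round(duration_ms * sampling_rate_hz / 1000.0)), 4)
    t = np.arange(n) / n
    w = np.sin(2 * np.pi * t) * 0.5 * (1 - np.cos(2 * np.pi * t))
    return w / (w.max() - w.min())


def synthesize_trial_emg(
    config: CohortConfig,
    rng: np.random.Generator,
    amplitudes: dict[str, float],
    pulse_ms: float | None,
    press_ms: float | None,
    chosen_side: str | None,
) -> EmgTrace:
    """Raw multi-channel EMG for one trial.

    Gaussian background noise, one scaled MEP template per channel at the
    pulse (if any), and a raised-cosine voluntary burst before the key
    press on the chosen hand (largest in the prime-mover index channel).
    ``amplitudes`` maps channel name ('muscle_side') to the target MEP
    peak-to-peak amplitude.
    """
    channels = [
        f"{m}_{s}" for s in config.body_sides for m in config.muscles
    ]
    rate = 2000.0
    samples = rng.normal(0.0, config.emg_noise_uv, size=(len(channels), TRACE_SAMPLES))
    trace = EmgTrace(
        channels,
        samples,
        start_ms=TRACE_START_MS,
        sampling_rate_hz=rate,
        markers={"pulse_ms": pulse_ms, "press_ms": press_ms},
    )
    template = mep_template(config.mep_duration_ms, rate)
    if pulse_ms is not None:
        onset = pulse_ms + config.mep_onset_ms[config.group]
        i0 = trace._index(onset)
        for row, ch in enumerate(channels):
            amp = amplitudes.get(ch, 0.0)
            seg = samples[row, i0 : i0 + len(template)]
            seg += amp * template[: len(seg)]
    if press_ms is not None and chosen_side is not None:
        dur = config.vigor_burst_duration_ms
        n = int(dur * rate / 1000.0)
        env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
        i0 = trace._index(press_ms - dur)
        for row, ch in enumerate(channels):
            muscle, side = ch.rsplit("_", 1)
            if side != chosen_side:
                continue
            amp = (
                config.vigor_burst_uv
                if muscle == "index"
                else config.vigor_burst_other_uv
            )
            burst = amp * env * np.abs(rng.normal(1.0, 0.3, size=n))
            seg = samples[row, i0 : i0 + n]
            seg += burst[: len(seg)] * np.sign(rng.normal(size=len(seg)))
    return trace


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict, GroundTruth]:
    """Full synthetic dataset: behavior, MEP amplitude table, and raw EMG
    traces for every stimulated trial.

    Traces are keyed by (participant, context, trial).  Memory scales
    with participants x trials x 8,000 samples x channels; use reduced
    compositions for large cohorts.
    """
    behavior, meps, truth = generate_mep_table(config)
    pulse_by_event = {"baseline": BASELINE_PULSE_MS} | {
        e: 200.0 * (j - 1) for e, j in TMS_EVENT_JUMP.items()
    }
    traces: dict = {}
    for (participant, context), session in behavior.groupby(
        ["participant", "context"], sort=True
    ):
        rng = _spawn(config, 3, int(participant), CONTEXTS.index(context))
        sub = meps[
            (meps["participant"] == participant) & (meps["context"] == context)
        ]
        for trial in session.itertuples():
            pulse = pulse_by_event.get(trial.tms_event)
            obs = sub[sub["trial"] == trial.trial]
            amplitudes = {
                f"{r.muscle}_{r.body_side}": r.amplitude_uv
                for r in obs.itertuples()
            }
            trace_end_ms = TRACE_START_MS + TRACE_SAMPLES * 0.5  # 2,200 ms
            press = (
                float(trial.rt_ms)
                if not trial.no_response
                and np.isfinite(trial.rt_ms)
                and trial.rt_ms <= trace_end_ms
                else None
            )
            traces[(participant, context, trial.trial)] = synthesize_trial_emg(
                config, rng, amplitudes, pulse, press, trial.chosen_side
            )
    return behavior, meps, traces, truth
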