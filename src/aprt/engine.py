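"""Trial execution engine.

Each press resolves to one of three exclusive outcomes — reward, neutral,
or injury — by sampling injury first (probability ``p_injury``) and then,
conditional on no injury, reward (probability ``p_reward``). Health and
points update after every press; a trial ends when the agent quits
(banking its points) or when health drops to or below zero (a "death",
forfeiting the trial's points). The cool mode enforces a fixed delay
between consecutive presses, reflected in simulated timestamps.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DesignMatrix, TrialSpec, FactorConfig

MODE_HOT = "hot"
MODE_COOL = "cool"

ACTION_PRESS = "press"
ACTION_QUIT = "quit"

OUTCOME_REWARD = "reward"
OUTCOME_NEUTRAL = "neutral"
OUTCOME_INJURY = "injury"
OUTCOME_NONE = "none"  # logged for quit rows

TERMINATED_ONGOING = "ongoing"
TERMINATED_QUIT = "quit"
TERMINATED_DEATH = "death"

DEFAULT_COOL_DELAY_MS = 1500
DEFAULT_HOT_LATENCY_MS = 600
DEFAULT_PRESS_CAP = 10_000


class StateError(RuntimeError):
    """An outcome was applied to an already-terminated trial state."""


class RunawayPolicyError(RuntimeError):
    """A policy exceeded the configured press cap without terminating."""


class ParseError(ValueError):
    """A session log file failed to parse; carries the offending row."""


@dataclass(frozen=True)
class EngineConfig:
    mode: str = MODE_HOT
    delay_ms: int | None = None
    seed: int = 0
    points_floor_at_zero: bool = True
    press_cap: int = DEFAULT_PRESS_CAP
    response_latency_ms: int = DEFAULT_HOT_LATENCY_MS

    def __post_init__(self):
        if self.mode not in (MODE_HOT, MODE_COOL):
            raise ValueError(f"mode must be 'hot' or 'cool', got {self.mode!r}")
        if self.delay_ms is None:
            object.__setattr__(
                self,
                "delay_ms",
                DEFAULT_COOL_DELAY_MS if self.mode == MODE_COOL else 0,
            )
        if self.delay_ms < 0:
            raise ValueError("delay_ms must be nonnegative")
        if self.mode == MODE_COOL and self.delay_ms == 0:
            raise ValueError("cool mode requires delay_ms > 0")
        if self.press_cap < 1:
            raise ValueError("press_cap must be >= 1")

    @property
    def press_step_ms(self) -> int:
        """Simulated time between consecutive presses."""
        if self.mode == MODE_COOL:
            return self.delay_ms
        return self.response_latency_ms


@dataclass(frozen=True)
class TrialState:
    health: int
    points: int
    presses: int = 0
    terminated_by: str = TERMINATED_ONGOING

    @property
    def ongoing(self) -> bool:
        return self.terminated_by == TERMINATED_ONGOING


def initial_state(config: FactorConfig | None = None) -> TrialState:
    config = config or FactorConfig()
    return TrialState(health=config.initial_health, points=config.initial_points)


@dataclass(frozen=True)
class OutcomeEvent:
    kind: str
    magnitude: int = 0

    def __post_init__(self):
        if self.kind not in (OUTCOME_REWARD, OUTCOME_NEUTRAL, OUTCOME_INJURY):
            raise ValueError(f"unknown outcome kind {self.kind!r}")
        if self.kind == OUTCOME_NEUTRAL and self.magnitude != 0:
            raise ValueError("neutral outcomes have magnitude 0")
        if self.kind != OUTCOME_NEUTRAL and self.magnitude <= 0:
            raise ValueError("reward/injury magnitudes must be positive")


def sample_press_outcome(spec: TrialSpec, rng: np.random.Generator) -> OutcomeEvent:
    """Sample one press outcome: injury with ``p_injury``; otherwise reward
    with ``p_reward``; otherwise neutral. Magnitudes are uniform over the
    trial's inclusive integer range, drawn independently per event."""
    if rng.random() < spec.p_injury:
        lo, hi = spec.injury_mag_range
        return OutcomeEvent(OUTCOME_INJURY, int(rng.integers(lo, hi + 1)))
    if rng.random() < spec.p_reward:
        lo, hi = spec.reward_mag_range
        return OutcomeEvent(OUTCOME_REWARD, int(rng.integers(lo, hi + 1)))
    return OutcomeEvent(OUTCOME_NEUTRAL, 0)


def apply_outcome(
    state: TrialState, event: OutcomeEvent, config: EngineConfig
) -> TrialState:
    """Update health/points for one outcome.

    Rewards add points; neutral changes nothing; injuries subtract the
    magnitude from both health and points (points clamped at zero when
    configured). Health at or below zero terminates the trial as a death
    and forfeits all trial points.
    """
    if not state.ongoing:
        raise StateError(
            f"cannot apply outcome to a state terminated by {state.terminated_by}"
        )
    health, points = state.health, state.points
    if event.kind == OUTCOME_REWARD:
        points += event.magnitude
    elif event.kind == OUTCOME_INJURY:
        health -= event.magnitude
        points -= event.magnitude
        if config.points_floor_at_zero:
            points = max(points, 0)
    if health <= 0:
        return TrialState(
            health=health,
            points=0,
            presses=state.presses + 1,
            terminated_by=TERMINATED_DEATH,
        )
    return TrialState(health=health, points=points, presses=state.presses + 1)


@dataclass
class TrialRecord:
    spec: TrialSpec
    events: list
    banked_points: int
    go_presses: int
    injuries: int
    remaining_health: int
    died: bool


@dataclass
class SessionLog:
    participant_id: str
    mode: str
    events: pd.DataFrame  # one row per logged action
    records: list  # TrialRecord, practice included
    grand_total_points: int


_EVENT_COLUMNS = [
    "participant_id",
    "mode",
    "trial_index",
    "is_practice",
    "press_index",
    "action",
    "outcome",
    "magnitude",
    "points_after",
    "health_after",
    "timestamp_ms",
]


def run_trial(
    spec: TrialSpec,
    policy,
    config: EngineConfig,
    rng: np.random.Generator,
    factor_config: FactorConfig | None = None,
    outcome_sampler=sample_press_outcome,
    clock_start_ms: int = 0,
):
    """Run one trial to termination.

    ``policy`` is a callable ``(state, spec, rng) -> 'press' | 'quit'``.
    Returns ``(TrialRecord, event_rows, clock_end_ms)``; event rows carry
    simulated timestamps spaced by the mode's press step.
    """
    state = initial_state(factor_config)
    events = []
    rows = []
    clock = clock_start_ms
    step = config.press_step_ms
    press_index = 0
    while True:
        if press_index >= config.press_cap:
            raise RunawayPolicyError(
                f"policy exceeded press cap of {config.press_cap} on trial "
                f"{spec.trial_index}"
            )
        action = policy(state, spec, rng)
        if action not in (ACTION_PRESS, ACTION_QUIT):
            raise ValueError(f"policy returned unknown action {action!r}")
        clock += step
        press_index += 1
        if action == ACTION_QUIT:
            state = replace(state, terminated_by=TERMINATED_QUIT)
            rows.append(
                {
                    "trial_index": spec.trial_index,
                    "is_practice": spec.is_practice,
                    "press_index": press_index,
                    "action": ACTION_QUIT,
                    "outcome": OUTCOME_NONE,
                    "magnitude": 0,
                    "points_after": state.points,
                    "health_after": state.health,
                    "timestamp_ms": clock,
                }
            )
            break
        event = outcome_sampler(spec, rng)
        state = apply_outcome(state, event, config)
        events.append(event)
        rows.append(
            {
                "trial_index": spec.trial_index,
                "is_practice": spec.is_practice,
                "press_index": press_index,
                "action": ACTION_PRESS,
                "outcome": event.kind,
                "magnitude": event.magnitude,
                "points_after": state.points,
                "health_after": state.health,
                "timestamp_ms": clock,
            }
        )
        if not state.ongoing:
            break
    died = state.terminated_by == TERMINATED_DEATH
    record = TrialRecord(
        spec=spec,
        events=events,
        banked_points=0 if died else state.points,
        go_presses=sum(1 for e in events),
        injuries=sum(1 for e in events if e.kind == OUTCOME_INJURY),
        remaining_health=max(state.health, 0),
        died=died,
    )
    return record, rows, clock


def run_session(
    design: DesignMatrix,
    policy,
    config: EngineConfig,
    rng: np.random.Generator | None = None,
    practice=None,
    participant_id: str = "p0",
) -> SessionLog:
    """Run practice trials (flagged, unscored) then the full design.

    Fully reproducible from the design, the engine seed, and the policy's
    parameters; the grand total sums banked points over non-practice
    trials only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    all_rows = []
    clock = 0
    grand_total = 0
    trials = list(practice or []) + list(design.trials)
    for spec in trials:
        record, rows, clock = run_trial(
            spec,
            policy,
            config,
            rng,
            factor_config=design.config,
            clock_start_ms=clock,
        )
        records.append(record)
        all_rows.extend(rows)
        if not spec.is_practice:
            grand_total += record.banked_points
    events = pd.DataFrame(all_rows, columns=_EVENT_COLUMNS[2:])
    events.insert(0, "mode", config.mode)
    events.insert(0, "participant_id", participant_id)
    return SessionLog(
        participant_id=participant_id,
        mode=config.mode,
        events=events,
        records=records,
        grand_total_points=grand_total,
    )


def trial_records_frame(log: SessionLog) -> pd.DataFrame:
    """Per-trial summary rows (practice flagged, not dropped)."""
    rows = []
    for r in log.records:
        rows.append(
            {
                "participant_id": log.participant_id,
                "mode": log.mode,
                "trial_index": r.spec.trial_index,
                "is_practice": r.spec.is_practice,
                "picture_category": r.spec.picture_category,
                "injury_prob_level": r.spec.injury_prob_level,
                "injury_mag_level": r.spec.injury_mag_level,
                "reward_prob_level": r.spec.reward_prob_level,
                "reward_mag_level": r.spec.reward_mag_level,
                "points": r.banked_points,
                "go_presses": r.go_presses,
                "injuries": r.injuries,
                "remaining_health": r.remaining_health,
                "died": r.died,
            }
        )
    return pd.DataFrame(rows)


def write_session(log: SessionLog, path) -> None:
    log.events.to_csv(path, index=False)


def write_trials(log: SessionLog, path) -> None:
    trial_records_frame(log).to_csv(path, index=False)


def _records_from_events(events: pd.DataFrame, design: DesignMatrix | None):
    spec_by_index = {}
    if design is not None:
        for t in design.trials:
            spec_by_index[(False, t.trial_index)] = t
    records = []
    for (is_practice, trial_index), grp in events.groupby(
        ["is_practice", "trial_index"], sort=False
    ):
        presses = grp[grp["action"] == ACTION_PRESS]
        quit_rows = grp[grp["action"] == ACTION_QUIT]
        died = bool(
            (presses["health_after"] <= 0).any()
        ) and quit_rows.empty
        final = grp.iloc[-1]
        spec = spec_by_index.get((bool(is_practice), int(trial_index)))
        records.append(
            TrialRecord(
                spec=spec,
                events=[
                    OutcomeEvent(row["outcome"], int(row["magnitude"]))
                    for _, row in presses.iterrows()
                ],
                banked_points=0 if died else int(final["points_after"]),
                go_presses=int(len(presses)),
                injuries=int((presses["outcome"] == OUTCOME_INJURY).sum()),
                remaining_health=max(int(final["health_after"]), 0),
                died=died,
            )
        )
    return records


def read_session(path, design: DesignMatrix | None = None) -> SessionLog:
    """Read an events CSV back into a SessionLog.

    If a design is supplied, trial records are re-linked to their specs;
    malformed rows raise :class:`ParseError` with the row number.
    """
    try:
        events = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - normalize to ParseError
        raise ParseError(f"cannot read session file {path}: {exc}") from exc
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ParseError(f"session file missing columns: {missing}")
    for i, row in events.iterrows():
        if row["action"] not in (ACTION_PRESS, ACTION_QUIT):
            raise ParseError(f"row {i}: unknown action {row['action']!r}")
        if row["action"] == ACTION_PRESS and row["outcome"] not in (
            OUTCOME_REWARD,
            OUTCOME_NEUTRAL,
            OUTCOME_INJURY,
        ):
            raise ParseError(f"row {i}: unknown outcome {row['outcome']!r}")
    if events.empty:
        return SessionLog(
            participant_id="",
            mode=MODE_HOT,
            events=events,
            records=[],
            grand_total_points=0,
        )
    participant_id = str(events["participant_id"].iloc[0])
    mode = str(events["mode"].iloc[0])
    records = _records_from_events(events, design)
    grand_total = sum(
        r.banked_points
        for r, (_, grp) in zip(
            records, events.groupby(["is_practice", "trial_index"], sort=False)
        )
        if not grp["is_practice"].iloc[0]
    )
    return SessionLog(
        participant_id=participant_id,
        mode=mode,
        events=events,
        records=records,
        grand_total_points=grand_total,
    )
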