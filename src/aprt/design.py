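"""Counterbalanced factorial trial design.

Each trial is defined by a picture category and four binary risk factors
(injury probability, injury magnitude, reward probability, reward
magnitude). One full factorial replicate — every level combination
exactly once — is generated per session and presented in a
seed-determined shuffled order.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LOW = "low"
HIGH = "high"
LEVELS = (LOW, HIGH)

BINARY_FACTORS = ("injury_prob", "injury_mag", "reward_prob", "reward_mag")
DEFAULT_CATEGORIES = ("animal", "cliff", "disaster", "hero")

DESCRIPTION_TEMPLATES = {
    "animal": "You are encountering a dangerous animal.",
    "cliff": "You are standing on the edge of a high cliff.",
    "disaster": "You are attempting to photograph natural disasters.",
    "hero": "You are attempting to rescue someone in physical danger.",
}

BORDER_SOLID = "solid"
BORDER_STRIPED = "striped"
BORDER_BLUE = "blue"
BORDER_YELLOW = "yellow"


class ConfigError(ValueError):
    """A task configuration field is out of its allowed domain."""


def _default_injury_prob():
    return {LOW: 1 / 15, HIGH: 1 / 5}


def _default_reward_prob():
    return {LOW: 2 / 3, HIGH: 9 / 10}


def _default_injury_mag_range():
    return {LOW: (5, 35), HIGH: (60, 90)}


def _default_reward_mag_range():
    return {LOW: (5, 25), HIGH: (50, 250)}


@dataclass(frozen=True)
class FactorConfig:
    """Factor levels and their resolved numeric parameters.

    Defaults are the published task parameters: injury probability
    1/15 vs 1/5, reward probability 2/3 vs 9/10, injury magnitude
    5-35 vs 60-90 health points, reward magnitude 5-25 vs 50-250
    points, 100 starting health and 0 starting points.
    """

    picture_categories: tuple = DEFAULT_CATEGORIES
    injury_prob: dict = field(default_factory=_default_injury_prob)
    reward_prob: dict = field(default_factory=_default_reward_prob)
    injury_mag_range: dict = field(default_factory=_default_injury_mag_range)
    reward_mag_range: dict = field(default_factory=_default_reward_mag_range)
    initial_health: int = 100
    initial_points: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "picture_categories", tuple(self.picture_categories)
        )
        cats = self.picture_categories
        if len(cats) == 0:
            raise ConfigError("picture_categories: must be non-empty")
        if len(set(cats)) != len(cats):
            raise ConfigError("picture_categories: labels must be unique")
        for name in ("injury_prob", "reward_prob"):
            probs = getattr(self, name)
            for level in LEVELS:
                if level not in probs:
                    raise ConfigError(f"{name}.{level}: missing")
                p = probs[level]
                if not (0.0 < p < 1.0):
                    raise ConfigError(
                        f"{name}.{level}: probability {p} not in (0, 1)"
                    )
        if self.injury_prob[HIGH] < self.injury_prob[LOW]:
            raise ConfigError("injury_prob: high level must be >= low level")
        for name in ("injury_mag_range", "reward_mag_range"):
            ranges = getattr(self, name)
            for level in LEVELS:
                if level not in ranges:
                    raise ConfigError(f"{name}.{level}: missing")
                lo, hi = ranges[level]
                if int(lo) != lo or int(hi) != hi:
                    raise ConfigError(
                        f"{name}.{level}: bounds must be integers"
                    )
                if lo <= 0:
                    raise ConfigError(
                        f"{name}.{level}: magnitudes must be positive"
                    )
                if lo > hi:
                    raise ConfigError(f"{name}.{level}: min {lo} > max {hi}")
        if self.initial_health <= 0:
            raise ConfigError("initial_health: must be positive")
        if self.initial_points < 0:
            raise ConfigError("initial_points: must be nonnegative")


@dataclass(frozen=True)
class TrialSpec:
    """One trial: factor levels plus resolved parameters and display cues."""

    trial_index: int
    picture_category: str
    injury_prob_level: str
    injury_mag_level: str
    reward_prob_level: str
    reward_mag_level: str
    p_injury: float
    p_reward: float
    injury_mag_range: tuple
    reward_mag_range: tuple
    border_pattern: str
    border_color: str
    description_text: str
    is_practice: bool = False

    @property
    def level_tuple(self):
        """The 5-tuple of factor levels identifying this trial."""
        return (
            self.picture_category,
            self.injury_prob_level,
            self.injury_mag_level,
            self.reward_prob_level,
            self.reward_mag_level,
        )


def _border_for(reward_prob_level: str, injury_prob_level: str):
    pattern = BORDER_SOLID if reward_prob_level == HIGH else BORDER_STRIPED
    color = BORDER_YELLOW if injury_prob_level == HIGH else BORDER_BLUE
    return pattern, color


def cue_encoding(spec: TrialSpec) -> dict:
    """Border cues for a trial: solid border = high reward probability,
    striped = low; yellow border = high injury probability, blue = low."""
    pattern, color = _border_for(spec.reward_prob_level, spec.injury_prob_level)
    return {"border_pattern": pattern, "border_color": color}


def cue_decoding(border_pattern: str, border_color: str) -> dict:
    """Invert :func:`cue_encoding` back to the two probability levels."""
    if border_pattern not in (BORDER_SOLID, BORDER_STRIPED):
        raise ValueError(f"unknown border pattern {border_pattern!r}")
    if border_color not in (BORDER_BLUE, BORDER_YELLOW):
        raise ValueError(f"unknown border color {border_color!r}")
    return {
        "reward_prob_level": HIGH if border_pattern == BORDER_SOLID else LOW,
        "injury_prob_level": HIGH if border_color == BORDER_YELLOW else LOW,
    }


def make_trial_spec(
    config: FactorConfig,
    trial_index: int,
    picture_category: str,
    injury_prob_level: str,
    injury_mag_level: str,
    reward_prob_level: str,
    reward_mag_level: str,
    is_practice: bool = False,
) -> TrialSpec:
    """Resolve a level combination into a fully parameterized TrialSpec."""
    pattern, color = _border_for(reward_prob_level, injury_prob_level)
    description = DESCRIPTION_TEMPLATES.get(
        picture_category, f"You are facing a risky situation: {picture_category}."
    )
    return TrialSpec(
        trial_index=trial_index,
        picture_category=picture_category,
        injury_prob_level=injury_prob_level,
        injury_mag_level=injury_mag_level,
        reward_prob_level=reward_prob_level,
        reward_mag_level=reward_mag_level,
        p_injury=config.injury_prob[injury_prob_level],
        p_reward=config.reward_prob[reward_prob_level],
        injury_mag_range=tuple(config.injury_mag_range[injury_mag_level]),
        reward_mag_range=tuple(config.reward_mag_range[reward_mag_level]),
        border_pattern=pattern,
        border_color=color,
        description_text=description,
        is_practice=is_practice,
    )


@dataclass(frozen=True)
class DesignMatrix:
    """An ordered, seed-reproducible set of trials for one session."""

    trials: tuple
    seed: int
    config: FactorConfig

    def __len__(self):
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def to_frame(self) -> pd.DataFrame:
        return design_to_frame(self.trials)


def _all_combinations(config: FactorConfig):
    return list(
        itertools.product(
            config.picture_categories, LEVELS, LEVELS, LEVELS, LEVELS
        )
    )


def generate_design(config: FactorConfig, seed: int) -> DesignMatrix:
    """Full factorial crossing of picture category x 4 binary factors,
    each combination exactly once, shuffled into a seed-determined
    presentation order (4 categories -> 64 trials at defaults)."""
    combos = _all_combinations(config)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    trials = tuple(
        make_trial_spec(config, i, *combos[j]) for i, j in enumerate(order)
    )
    return DesignMatrix(trials=trials, seed=seed, config=config)


def generate_practice(config: FactorConfig, seed: int) -> list:
    """One practice trial per picture category with seed-drawn binary
    levels; flagged so scoring excludes them."""
    rng = np.random.default_rng(seed)
    specs = []
    for i, cat in enumerate(config.picture_categories):
        levels = [LEVELS[k] for k in rng.integers(0, 2, size=4)]
        specs.append(make_trial_spec(config, i, cat, *levels, is_practice=True))
    return specs


def design_balance_report(design: DesignMatrix) -> dict:
    """Cell counts per factor level and per two-way level combination,
    plus a uniqueness check on the 5-tuples of factor levels."""
    df = design.to_frame()
    factor_cols = ["picture_category"] + [f"{f}_level" for f in BINARY_FACTORS]

    level_rows = []
    for col in factor_cols:
        for level, count in df[col].value_counts().sort_index().items():
            level_rows.append(
                {"factor": col, "level": level, "count": int(count)}
            )
    pair_rows = []
    for a, b in itertools.combinations(factor_cols, 2):
        cells = df.groupby([a, b], observed=True).size()
        for (la, lb), count in cells.sort_index().items():
            pair_rows.append(
                {
                    "factor_a": a,
                    "level_a": la,
                    "factor_b": b,
                    "level_b": lb,
                    "count": int(count),
                }
            )
    keys = [t.level_tuple for t in design.trials]
    seen, duplicates = set(), []
    for key in keys:
        if key in seen:
            duplicates.append(key)
        seen.add(key)
    return {
        "level_counts": pd.DataFrame(level_rows),
        "pairwise_counts": pd.DataFrame(pair_rows),
        "is_unique": not duplicates,
        "duplicates": duplicates,
    }


# ---------------------------------------------------------------------------
# CSV plumbing

_DESIGN_COLUMNS = [
    "trial_index",
    "picture_category",
    "injury_prob_level",
    "injury_mag_level",
    "reward_prob_level",
    "reward_mag_level",
    "p_injury",
    "p_reward",
    "injury_mag_min",
    "injury_mag_max",
    "reward_mag_min",
    "reward_mag_max",
    "border_pattern",
    "border_color",
    "description_text",
    "is_practice",
]


def design_to_frame(trials) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "picture_category": t.picture_category,
                "injury_prob_level": t.injury_prob_level,
                "injury_mag_level": t.injury_mag_level,
                "reward_prob_level": t.reward_prob_level,
                "reward_mag_level": t.reward_mag_level,
                "p_injury": t.p_injury,
                "p_reward": t.p_reward,
                "injury_mag_min": t.injury_mag_range[0],
                "injury_mag_max": t.injury_mag_range[1],
                "reward_mag_min": t.reward_mag_range[0],
                "reward_mag_max": t.reward_mag_range[1],
                "border_pattern": t.border_pattern,
                "border_color": t.border_color,
                "description_text": t.description_text,
                "is_practice": t.is_practice,
            }
        )
    return pd.DataFrame(rows, columns=_DESIGN_COLUMNS)


def write_design(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, config: FactorConfig | None = None) -> DesignMatrix:
    """Read a design CSV written by :func:`write_design`.

    The resolved numeric columns in the file are authoritative; the
    optional ``config`` is attached for downstream consumers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design file missing columns: {missing}")
    trials = []
    for _, row in df.iterrows():
        trials.append(
            TrialSpec(
                trial_index=int(row["trial_index"]),
                picture_category=row["picture_category"],
                injury_prob_level=row["injury_prob_level"],
                injury_mag_level=row["injury_mag_level"],
                reward_prob_level=row["reward_prob_level"],
                reward_mag_level=row["reward_mag_level"],
                p_injury=float(row["p_injury"]),
                p_reward=float(row["p_reward"]),
                injury_mag_range=(
                    int(row["injury_mag_min"]),
                    int(row["injury_mag_max"]),
                ),
                reward_mag_range=(
                    int(row["reward_mag_min"]),
                    int(row["reward_mag_max"]),
                ),
                border_pattern=row["border_pattern"],
                border_color=row["border_color"],
                description_text=row["description_text"],
                is_practice=bool(row["is_practice"]),
            )
        )
    if config is None:
        config = FactorConfig()
    return DesignMatrix(trials=tuple(trials), seed=-1, config=config)
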