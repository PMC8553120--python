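"""Simulated participants.

A latent trait profile is translated into press/quit behavior by a
stochastic satisficing policy: the agent quits once its trial points
reach a personal target; otherwise it presses with probability

    pi = clip(theta_eff * exp(-s * n_high_injury_cues) * (health/100)^h, 0, 1)

where ``n_high_injury_cues`` counts how many of the two injury factors
(probability, magnitude) are at their high level for the trial. In cool
mode the baseline drive ``theta`` is shrunk toward a cautious constant,
attenuating between-agent differences. The cohort generator adds
trait-correlated synthetic self-report scale scores for validity
analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import engine
from .design import HIGH, DesignMatrix, FactorConfig
from .engine import (
    ACTION_PRESS,
    ACTION_QUIT,
    MODE_COOL,
    MODE_HOT,
    EngineConfig,
    TrialState,
    run_session,
)

#: cautious press drive an attenuated agent is pulled toward in cool mode
COOL_BASELINE_THETA = 0.30


@dataclass(frozen=True)
class TraitProfile:
    """Latent agent parameters.

    theta: baseline press drive in [0, 1].
    cue_sensitivity: s >= 0; down-weights pressing under high injury cues.
    satisfice_target: quit once trial points reach this target (> 0).
    health_caution: h >= 0; press drive scales with (health/100)^h.
    delay_attenuation: a in [0, 1]; cool-mode shrinkage of theta toward
        the cautious baseline.
    """

    theta: float
    cue_sensitivity: float = 0.0
    satisfice_target: float = np.inf
    health_caution: float = 0.0
    delay_attenuation: float = 0.0
    cool_baseline: float = COOL_BASELINE_THETA

    def __post_init__(self):
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.cue_sensitivity < 0:
            raise ValueError("cue_sensitivity must be >= 0")
        if not self.satisfice_target > 0:
            raise ValueError("satisfice_target must be > 0")
        if self.health_caution < 0:
            raise ValueError("health_caution must be >= 0")
        if not 0.0 <= self.delay_attenuation <= 1.0:
            raise ValueError("delay_attenuation must be in [0, 1]")


def n_high_injury_cues(spec) -> int:
    """Count of injury factors at their high level for a trial (0, 1, 2)."""
    return int(spec.injury_prob_level == HIGH) + int(
        spec.injury_mag_level == HIGH
    )


def press_probability(
    state: TrialState, spec, profile: TraitProfile, mode: str
) -> float:
    """Deterministic part of the policy: the per-press continue probability."""
    theta = profile.theta
    if mode == MODE_COOL:
        a = profile.delay_attenuation
        theta = (1.0 - a) * theta + a * profile.cool_baseline
    pi = (
        theta
        * np.exp(-profile.cue_sensitivity * n_high_injury_cues(spec))
        * (max(state.health, 0) / 100.0) ** profile.health_caution
    )
    return float(np.clip(pi, 0.0, 1.0))


def policy_decide(
    state: TrialState,
    spec,
    profile: TraitProfile,
    mode: str,
    rng: np.random.Generator,
) -> str:
    """Press/quit decision for one state: quit when satisfied, otherwise
    press with the trait-determined probability."""
    if state.points >= profile.satisfice_target:
        return ACTION_QUIT
    if rng.random() < press_probability(state, spec, profile, mode):
        return ACTION_PRESS
    return ACTION_QUIT


#: nominal presses a maximally driven agent plans under no injury cues
DEFAULT_PRESS_BUDGET = 12.0


def planned_presses(
    spec, profile: TraitProfile, mode: str, press_budget: float = DEFAULT_PRESS_BUDGET
) -> int:
    """Number of presses an agent plans for a trial before it starts.

    The plan scales the press budget by the (mode-attenuated) drive and
    the exponential injury-cue down-weighting, so cue-insensitive agents
    (s = 0) plan identically across injury conditions.
    """
    theta = profile.theta
    if mode == MODE_COOL:
        a = profile.delay_attenuation
        theta = (1.0 - a) * theta + a * profile.cool_baseline
    return int(
        round(
            press_budget
            * theta
            * np.exp(-profile.cue_sensitivity * n_high_injury_cues(spec))
        )
    )


def planned_decide(
    state: TrialState,
    spec,
    profile: TraitProfile,
    mode: str,
    rng: np.random.Generator,
    press_budget: float = DEFAULT_PRESS_BUDGET,
) -> str:
    """Press-budget variant of the trait policy.

    The agent quits when satisfied (points >= target) or when its
    planned press count for the trial is exhausted; otherwise it presses,
    gated stochastically by the health-caution factor (health/100)^h.
    This deterministic-count translation identifies the traits far
    better than per-press stochastic stopping, whose geometric press
    counts confound drive and cue sensitivity; it is the cohort default.
    """
    if state.points >= profile.satisfice_target:
        return ACTION_QUIT
    if state.presses >= planned_presses(spec, profile, mode, press_budget):
        return ACTION_QUIT
    gate = (max(state.health, 0) / 100.0) ** profile.health_caution
    if rng.random() < gate:
        return ACTION_PRESS
    return ACTION_QUIT


def make_policy(kind: str, **params):
    """Build a decision function ``(state, spec, rng) -> action``.

    Kinds: ``never_quit``, ``always_quit``, ``satisficer`` (requires
    ``target``), ``cue_sensitive`` (requires ``profile``, optional
    ``mode``), ``planned`` (requires ``profile``; optional ``mode``,
    ``press_budget``), and ``scripted`` (requires ``actions``, a finite
    sequence replayed in order; quits when exhausted).
    """
    if kind == "never_quit":
        return lambda state, spec, rng: ACTION_PRESS
    if kind == "always_quit":
        return lambda state, spec, rng: ACTION_QUIT
    if kind == "satisficer":
        target = params["target"]
        return (
            lambda state, spec, rng: ACTION_QUIT
            if state.points >= target
            else ACTION_PRESS
        )
    if kind == "cue_sensitive":
        profile = params["profile"]
        mode = params.get("mode", MODE_HOT)
        return lambda state, spec, rng: policy_decide(
            state, spec, profile, mode, rng
        )
    if kind == "planned":
        profile = params["profile"]
        mode = params.get("mode", MODE_HOT)
        budget = params.get("press_budget", DEFAULT_PRESS_BUDGET)
        return lambda state, spec, rng: planned_decide(
            state, spec, profile, mode, rng, press_budget=budget
        )
    if kind == "scripted":
        actions = list(params["actions"])
        counter = {"i": 0}

        def scripted(state, spec, rng):
            if counter["i"] >= len(actions):
                return ACTION_QUIT
            action = actions[counter["i"]]
            counter["i"] += 1
            return action

        return scripted
    raise ValueError(f"unknown policy kind {kind!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Trait distributions and synthetic-scale layout for a cohort.

    Defaults: theta ~ Beta(theta_a, theta_b), cue sensitivity
    s ~ Gamma(s_shape, s_scale), satisficing target T ~ LogNormal(t_mu,
    t_sigma); health caution and delay attenuation are fixed values.
    Convergent scales load on theta with loading ``loading``; divergent
    scales are independent noise.
    """

    n: int = 200
    seed: int = 0
    theta_a: float = 3.0
    theta_b: float = 1.8
    s_shape: float = 2.0
    s_scale: float = 0.2
    t_mu: float = float(np.log(2000.0))
    t_sigma: float = 0.6
    health_caution: float = 0.0
    delay_attenuation: float = 0.6
    loading: float = 0.6
    n_convergent: int = 3
    n_divergent: int = 3

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not -1.0 <= self.loading <= 1.0:
            raise ValueError("loading must be in [-1, 1]")
        if self.n_convergent < 0 or self.n_divergent < 0:
            raise ValueError("scale counts must be >= 0")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Draw trait profiles and synthetic self-report scale scores.

    Convergent scale_j = loading * z(theta) + sqrt(1 - loading^2) * noise,
    standardized; divergent scales are independent standard noise. The
    delay arm follows the parity rule: even participant ids run cool
    (delayed), odd ids run hot.
    """
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n
    theta = rng.beta(cohort.theta_a, cohort.theta_b, size=n)
    s = rng.gamma(cohort.s_shape, cohort.s_scale, size=n)
    target = rng.lognormal(cohort.t_mu, cohort.t_sigma, size=n)
    df = pd.DataFrame(
        {
            "participant_id": np.arange(n),
            "arm": np.where(np.arange(n) % 2 == 0, MODE_COOL, MODE_HOT),
            "theta": theta,
            "cue_sensitivity": s,
            "satisfice_target": target,
            "health_caution": cohort.health_caution,
            "delay_attenuation": cohort.delay_attenuation,
        }
    )
    lam = cohort.loading
    z_theta = _zscore(theta)
    for j in range(cohort.n_convergent):
        noise = rng.standard_normal(n)
        raw = lam * z_theta + np.sqrt(1.0 - lam**2) * noise
        df[f"conv_{j + 1}"] = _zscore(raw)
    for j in range(cohort.n_divergent):
        df[f"div_{j + 1}"] = _zscore(rng.standard_normal(n))
    return df


def profile_from_row(row) -> TraitProfile:
    return TraitProfile(
        theta=float(row["theta"]),
        cue_sensitivity=float(row["cue_sensitivity"]),
        satisfice_target=float(row["satisfice_target"]),
        health_caution=float(row["health_caution"]),
        delay_attenuation=float(row["delay_attenuation"]),
    )


def simulate_cohort(
    participants: pd.DataFrame,
    design: DesignMatrix,
    cohort_seed: int,
    practice=None,
    delay_ms: int = engine.DEFAULT_COOL_DELAY_MS,
    policy_kind: str = "planned",
) -> list:
    """Run one session per participant; even ids cool, odd ids hot.

    Per-participant engine streams are spawned from the cohort seed, so
    an identical cohort seed reproduces the full set of logs.
    """
    streams = np.random.SeedSequence(cohort_seed).spawn(len(participants))
    logs = []
    for (_, row), stream in zip(participants.iterrows(), streams):
        pid = int(row["participant_id"])
        mode = MODE_COOL if pid % 2 == 0 else MODE_HOT
        config = EngineConfig(
            mode=mode, delay_ms=delay_ms if mode == MODE_COOL else None
        )
        profile = profile_from_row(row)
        policy = make_policy(policy_kind, profile=profile, mode=mode)
        rng = np.random.default_rng(stream)
        logs.append(
            run_session(
                design,
                policy,
                config,
                rng=rng,
                practice=practice,
                participant_id=f"p{pid}",
            )
        )
    return logs
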