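"""Configuration loading: YAML/JSON files with strict schemas.

Missing fields take the published task defaults; unknown keys are
rejected with their full field path.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields

import yaml

from .agents import CohortSpec
from .design import LEVELS, ConfigError, FactorConfig

_FACTOR_KEYS = {
    "picture_categories",
    "injury_prob",
    "reward_prob",
    "injury_mag_range",
    "reward_mag_range",
    "initial_health",
    "initial_points",
}
_ENGINE_KEYS = {
    "mode",
    "delay_ms",
    "points_floor_at_zero",
    "press_cap",
    "response_latency_ms",
}
_COHORT_KEYS = {
    "n",
    "seed",
    "theta_a",
    "theta_b",
    "s_shape",
    "s_scale",
    "t_mu",
    "t_sigma",
    "health_caution",
    "delay_attenuation",
    "loading",
    "n_convergent",
    "n_divergent",
}
_TOP_KEYS = {"factors", "engine", "cohort"}


@dataclass
class RunConfig:
    factors: FactorConfig = field(default_factory=FactorConfig)
    engine: dict = field(default_factory=dict)
    cohort: CohortSpec = field(default_factory=CohortSpec)


def _check_keys(mapping, allowed, path):
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{path}.{sorted(unknown)[0]}: unknown key")


def _leveled(mapping, path, pair=False):
    _check_keys(mapping, set(LEVELS), path)
    out = {}
    for level, value in mapping.items():
        if pair:
            if not isinstance(value, (list, tuple)) or len(value) != 2:
                raise ConfigError(f"{path}.{level}: expected [min, max]")
            out[level] = tuple(value)
        else:
            out[level] = value
    return out


def parse_config(raw: dict | None) -> RunConfig:
    """Validate a raw config mapping into a RunConfig (empty -> defaults)."""
    raw = raw or {}
    _check_keys(raw, _TOP_KEYS, "config")

    factors_raw = dict(raw.get("factors") or {})
    _check_keys(factors_raw, _FACTOR_KEYS, "factors")
    kwargs = {}
    for key in ("injury_prob", "reward_prob"):
        if key in factors_raw:
            kwargs[key] = _leveled(factors_raw[key], f"factors.{key}")
    for key in ("injury_mag_range", "reward_mag_range"):
        if key in factors_raw:
            kwargs[key] = _leveled(factors_raw[key], f"factors.{key}", pair=True)
    for key in ("picture_categories", "initial_health", "initial_points"):
        if key in factors_raw:
            kwargs[key] = factors_raw[key]
    try:
        factors = FactorConfig(**kwargs)
    except ConfigError as exc:
        raise ConfigError(f"factors.{exc}") from exc

    engine_raw = dict(raw.get("engine") or {})
    _check_keys(engine_raw, _ENGINE_KEYS, "engine")

    cohort_raw = dict(raw.get("cohort") or {})
    _check_keys(cohort_raw, _COHORT_KEYS, "cohort")
    try:
        cohort = CohortSpec(**cohort_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"cohort: {exc}") from exc

    return RunConfig(factors=factors, engine=engine_raw, cohort=cohort)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        return parse_config({})
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return parse_config(raw)


def dump_config(config: RunConfig) -> dict:
    """Round-trippable plain mapping for a RunConfig."""
    f = config.factors
    cohort = {
        fld.name: getattr(config.cohort, fld.name)
        for fld in fields(config.cohort)
    }
    return {
        "factors": {
            "picture_categories": list(f.picture_categories),
            "injury_prob": dict(f.injury_prob),
            "reward_prob": dict(f.reward_prob),
            "injury_mag_range": {k: list(v) for k, v in f.injury_mag_range.items()},
            "reward_mag_range": {k: list(v) for k, v in f.reward_mag_range.items()},
            "initial_health": f.initial_health,
            "initial_points": f.initial_points,
        },
        "engine": dict(config.engine),
        "cohort": cohort,
    }


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            json.dump(dump_config(config), fh, indent=2)
        else:
            yaml.safe_dump(dump_config(config), fh, sort_keys=False)
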