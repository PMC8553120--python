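"""End-to-end orchestration: design -> cohort -> simulate -> score -> analyze.

Every stage writes a CSV artifact; a JSON manifest records the config
hash, stage seeds, and a file inventory so a run can be reproduced
byte-for-byte (timestamps aside) from the same seeds.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .agents import generate_cohort, simulate_cohort
from .analysis import (
    AnalysisError,
    build_panel,
    correlation_families,
    decompose_interaction,
    fit_factorial_effects,
)
from .config import RunConfig, dump_config
from .design import generate_design, generate_practice, write_design
from .engine import trial_records_frame
from .scoring import score_table, trial_scores_from_frame

logger = logging.getLogger("aprt.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict:
    import numpy as np

    state = np.random.SeedSequence(seed).generate_state(3)
    return {
        "root": int(seed),
        "design": int(state[0]),
        "cohort": int(state[1]),
        "engine": int(state[2]),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dump_config(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _interaction_decompositions(term_name: str):
    """Translate a rejected interaction term into simple-effect layouts.

    Picture terms expand into the two picture contrasts; delay is placed
    as the stratifying factor, matching the published table layout.
    """
    parts = term_name.split(" x ")
    if len(parts) != 2:
        return []
    a, b = parts
    contrasts = ("animal_cliff", "disaster_hero")
    if "picture" in parts:
        other = b if a == "picture" else a
        return [(other, c) for c in contrasts]
    if "delay" in parts:
        other = b if a == "delay" else a
        return [("delay", other)]
    return [(a, b)]


def run_pipeline(
    config: RunConfig,
    out_dir,
    seed: int,
    n: int | None = None,
    cov_struct: str = "unstructured",
) -> dict:
    """Execute the full pipeline and return the run manifest.

    Simulation artifacts are always written; if the cohort is too small
    for the statistical stage, analysis is skipped with a logged reason
    rather than aborting the run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    manifest = {
        "config_hash": _config_hash(config),
        "config": dump_config(config),
        "seeds": seeds,
        "version": __version__,
        "created_unix": time.time(),
        "stages": {},
        "files": {},
    }

    stage = "design"
    try:
        logger.info("[%s] generating trial design", stage)
        design = generate_design(config.factors, seeds["design"])
        practice = generate_practice(config.factors, seeds["design"])
        write_design(design, out / "design.csv")
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "cohort"
    try:
        cohort_spec = dataclasses.replace(
            config.cohort,
            seed=seeds["cohort"],
            **({"n": n} if n is not None else {}),
        )
        logger.info("[%s] generating cohort of %d", stage, cohort_spec.n)
        participants = generate_cohort(cohort_spec)
        participants.to_csv(out / "participants.csv", index=False)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "simulate"
    try:
        logger.info("[%s] running %d sessions", stage, len(participants))
        logs = simulate_cohort(
            participants, design, seeds["engine"], practice=practice
        )
        pd.concat([log.events for log in logs], ignore_index=True).to_csv(
            out / "events.csv", index=False
        )
        trials = pd.concat(
            [trial_records_frame(log) for log in logs], ignore_index=True
        )
        trials.to_csv(out / "trials.csv", index=False)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "score"
    try:
        logger.info("[%s] computing score tables", stage)
        trials = trials.copy()
        trials["participant_id"] = (
            trials["participant_id"].str.removeprefix("p").astype(int)
        )
        by_pid = trial_scores_from_frame(trials)
        scores = score_table(by_pid)
        scores.to_csv(out / "scores.csv", index=False)
        manifest["stages"][stage] = "ok"
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "analyze"
    arm_counts = participants["arm"].value_counts()
    if len(participants) < 8 or (arm_counts < 4).any() or len(arm_counts) < 2:
        reason = (
            f"insufficient participants for analysis "
            f"(n={len(participants)}, arms={arm_counts.to_dict()})"
        )
        logger.warning("[%s] %s; skipping", stage, reason)
        manifest["stages"][stage] = f"skipped: {reason}"
    else:
        try:
            logger.info("[%s] fitting factorial models", stage)
            panel = build_panel(by_pid, participants)
            effect_frames = []
            posthoc_frames = []
            from .scoring import OUTCOMES

            for outcome in OUTCOMES:
                table, _ = fit_factorial_effects(
                    panel, outcome=outcome, cov_struct=cov_struct
                )
                table.insert(0, "outcome", outcome)
                effect_frames.append(table)
                rejected = table[
                    table["reject_adj"] & table["term"].str.contains(" x ")
                ]
                for term_name in rejected["term"]:
                    for pair in _interaction_decompositions(term_name):
                        try:
                            dec = decompose_interaction(
                                panel, pair, outcome=outcome
                            )
                        except AnalysisError as exc:
                            logger.warning(
                                "[%s] decomposition %s (%s) skipped: %s",
                                stage,
                                pair,
                                outcome,
                                exc,
                            )
                            continue
                        dec.insert(0, "outcome", outcome)
                        posthoc_frames.append(dec)
            pd.concat(effect_frames, ignore_index=True).to_csv(
                out / "effects.csv", index=False
            )
            posthoc = (
                pd.concat(posthoc_frames, ignore_index=True)
                if posthoc_frames
                else pd.DataFrame()
            )
            posthoc.to_csv(out / "posthoc.csv", index=False)

            conv = [c for c in participants.columns if c.startswith("conv_")]
            div = [c for c in participants.columns if c.startswith("div_")]
            family_map = {"convergent": conv, "divergent": div}
            score_cols = [
                c
                for c in scores.columns
                if c.endswith("__total") or "__diff_" in c
            ]
            correlations = correlation_families(
                scores, participants, family_map, score_cols=score_cols
            )
            correlations.to_csv(out / "correlations.csv", index=False)
            manifest["stages"][stage] = "ok"
        except AnalysisError as exc:
            logger.warning("[%s] skipped: %s", stage, exc)
            manifest["stages"][stage] = f"skipped: {exc}"
        except Exception as exc:
            raise StageError(stage, exc) from exc

    for path in sorted(out.glob("*.csv")):
        manifest["files"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
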