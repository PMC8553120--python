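"""Outcome scoring and internal-consistency statistics.

Four scores are computed per trial — banked points, go presses,
injuries, remaining health — and aggregated per participant into
totals, per-condition means, and low-minus-high difference scores.
All contrasts are standardized as low minus high; the two picture
contrasts treat animal and disaster as "low" and cliff and hero as
"high" (animal - cliff, disaster - hero).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BINARY_FACTORS, HIGH, LOW
from .engine import SessionLog, trial_records_frame

OUTCOMES = ("points", "go_presses", "injuries", "remaining_health")

#: picture contrasts as (name, low category, high category)
PICTURE_CONTRASTS = (
    ("animal_cliff", "animal", "cliff"),
    ("disaster_hero", "disaster", "hero"),
)

DIFF_FACTORS = BINARY_FACTORS + tuple(name for name, _, _ in PICTURE_CONTRASTS)


class DesignError(ValueError):
    """Trial scores are missing a level required by the scoring layout."""


def score_session(log: SessionLog) -> pd.DataFrame:
    """Per-trial score rows for the non-practice trials of one session."""
    df = trial_records_frame(log)
    if df.empty:
        raise DesignError("session log contains no trials")
    df = df[~df["is_practice"]].reset_index(drop=True)
    if set(df["trial_index"]) != set(range(len(df))):
        raise DesignError("session log is missing trials")
    return df.drop(columns=["is_practice"])


def condition_means(trial_scores: pd.DataFrame, factor: str, outcome: str) -> pd.Series:
    """Mean outcome at each level of a factor.

    ``factor`` is one of the binary factors or ``picture_category``;
    every expected level must be present in the trial scores.
    """
    if factor == "picture_category":
        col = "picture_category"
        levels = sorted(trial_scores[col].unique())
    else:
        if factor not in BINARY_FACTORS:
            raise DesignError(f"unknown factor {factor!r}")
        col = f"{factor}_level"
        levels = [LOW, HIGH]
    means = trial_scores.groupby(col, observed=True)[outcome].mean()
    missing = [lv for lv in levels if lv not in means.index]
    if missing:
        raise DesignError(f"no trials at {factor}={missing}")
    return means.reindex(levels)


def difference_scores(trial_scores: pd.DataFrame, outcome: str) -> dict:
    """Six low-minus-high difference scores for one outcome."""
    out = {}
    for factor in BINARY_FACTORS:
        means = condition_means(trial_scores, factor, outcome)
        out[factor] = float(means[LOW] - means[HIGH])
    cat_means = trial_scores.groupby("picture_category", observed=True)[outcome].mean()
    for name, low_cat, high_cat in PICTURE_CONTRASTS:
        if low_cat not in cat_means.index or high_cat not in cat_means.index:
            raise DesignError(f"missing picture categories for contrast {name}")
        out[name] = float(cat_means[low_cat] - cat_means[high_cat])
    return out


def participant_scores(trial_scores: pd.DataFrame) -> dict:
    """Wide score row for one participant's per-trial scores."""
    row = {}
    for outcome in OUTCOMES:
        row[f"{outcome}__total"] = float(trial_scores[outcome].mean())
        if outcome == "points":
            row["points__grand_total"] = float(trial_scores[outcome].sum())
        for factor in BINARY_FACTORS:
            means = condition_means(trial_scores, factor, outcome)
            for level in (LOW, HIGH):
                row[f"{outcome}__{factor}_{level}"] = float(means[level])
        cat_means = trial_scores.groupby("picture_category", observed=True)[
            outcome
        ].mean()
        for cat, value in cat_means.items():
            row[f"{outcome}__picture_{cat}"] = float(value)
        for factor, diff in difference_scores(trial_scores, outcome).items():
            row[f"{outcome}__diff_{factor}"] = diff
    return row


def score_table(trial_scores_by_pid: dict) -> pd.DataFrame:
    """Per-participant score table from {participant_id: trial scores}."""
    rows = []
    for pid, trial_scores in trial_scores_by_pid.items():
        row = {"participant_id": pid}
        row.update(participant_scores(trial_scores))
        rows.append(row)
    return pd.DataFrame(rows)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a participants x items matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of sums),
    with unbiased (n-1) variances.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional")
    n, k = X.shape
    if k < 2:
        raise ValueError("alpha requires at least 2 items")
    if n < 2:
        raise ValueError("alpha requires at least 2 participants")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero variance of item sums")
    item_vars = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def difference_score_reliability(
    r_xx: float, r_yy: float, r_xy: float, sd_x: float, sd_y: float
) -> float:
    """Reliability of a difference score X - Y from component
    reliabilities, their correlation, and their standard deviations."""
    for name, r in (("r_xx", r_xx), ("r_yy", r_yy)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if not -1.0 <= r_xy <= 1.0:
        raise ValueError("r_xy must be in [-1, 1]")
    if sd_x <= 0 or sd_y <= 0:
        raise ValueError("standard deviations must be positive")
    denom = sd_x**2 + sd_y**2 - 2 * r_xy * sd_x * sd_y
    if denom <= 0:
        raise ValueError("degenerate difference: denominator <= 0")
    num = r_xx * sd_x**2 + r_yy * sd_y**2 - 2 * r_xy * sd_x * sd_y
    return float(num / denom)


def _item_matrix(trial_scores_by_pid: dict, outcome: str, mask_fn) -> np.ndarray:
    """Participants x items matrix with items identified by the level
    5-tuple so columns align across participants."""
    columns = None
    rows = []
    for pid in sorted(trial_scores_by_pid):
        ts = trial_scores_by_pid[pid]
        sub = ts[mask_fn(ts)]
        keyed = sub.set_index(
            [
                "picture_category",
                "injury_prob_level",
                "injury_mag_level",
                "reward_prob_level",
                "reward_mag_level",
            ]
        )[outcome].sort_index()
        if columns is None:
            columns = keyed.index
        rows.append(keyed.reindex(columns).to_numpy())
    return np.asarray(rows)


def reliability_report(trial_scores_by_pid: dict) -> pd.DataFrame:
    """Cronbach's alpha per outcome x factor x level (trials as items)
    and the implied reliability of each low-high difference score."""
    rows = []
    for outcome in OUTCOMES:
        for factor in BINARY_FACTORS:
            col = f"{factor}_level"
            stats = {}
            for level in (LOW, HIGH):
                X = _item_matrix(
                    trial_scores_by_pid, outcome, lambda ts, c=col, l=level: ts[c] == l
                )
                try:
                    alpha = cronbach_alpha(X)
                except ValueError:
                    alpha = np.nan
                stats[level] = (alpha, X.mean(axis=1))
                rows.append(
                    {
                        "outcome": outcome,
                        "factor": factor,
                        "level": level,
                        "alpha": alpha,
                        "n_items": X.shape[1],
                    }
                )
            a_low, low_means = stats[LOW]
            a_high, high_means = stats[HIGH]
            diff_rel = np.nan
            if np.isfinite(a_low) and np.isfinite(a_high):
                sd_x = low_means.std(ddof=1)
                sd_y = high_means.std(ddof=1)
                if sd_x > 0 and sd_y > 0:
                    r_xy = float(np.corrcoef(low_means, high_means)[0, 1])
                    try:
                        diff_rel = difference_score_reliability(
                            min(max(a_low, 0.0), 1.0),
                            min(max(a_high, 0.0), 1.0),
                            r_xy,
                            sd_x,
                            sd_y,
                        )
                    except ValueError:
                        diff_rel = np.nan
            rows.append(
                {
                    "outcome": outcome,
                    "factor": factor,
                    "level": "difference",
                    "alpha": diff_rel,
                    "n_items": np.nan,
                }
            )
    return pd.DataFrame(rows)


def trial_scores_from_frame(trials: pd.DataFrame) -> dict:
    """Split a multi-participant trials table (as written by the CLI)
    into the {participant_id: trial scores} mapping used for scoring."""
    required = {"participant_id", "is_practice", "trial_index"}
    missing = required - set(trials.columns)
    if missing:
        raise DesignError(f"trials table missing columns: {sorted(missing)}")
    out = {}
    for pid, grp in trials.groupby("participant_id", sort=True):
        out[pid] = (
            grp[~grp["is_practice"]]
            .drop(columns=["is_practice"])
            .reset_index(drop=True)
        )
    return out
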