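"""Factorial statistics pipeline.

Per-participant x condition-cell outcomes enter a marginal (estimating-
equation) model with all main effects, two-way interactions among the
five within-subject factors, and within x delay interactions — 21 terms.
Dependent variables are Winsorized at +3 SD (upper tail only) and, for
the skewed count-like scores, log(x + 1) transformed. Wald statistics
are reported per term, raw and Holm-Sidak adjusted. Rejected
interactions can be decomposed into simple-effect contrasts, and
convergent/divergent correlation families are screened with the same
step-down correction applied within each family.

The estimating-equation solver itself is delegated to statsmodels; term
construction, coding, Wald assembly, and all corrections live here.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .design import BINARY_FACTORS, HIGH, LOW
from .scoring import OUTCOMES, PICTURE_CONTRASTS

logger = logging.getLogger("aprt.analysis")

WITHIN_FACTORS = ("picture",) + BINARY_FACTORS
DELAY = "delay"

#: outcomes that are log(x+1)-transformed before modelling
SKEWED_OUTCOMES = ("go_presses", "injuries")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transforms


def winsorize_upper(values, k: float = 3.0) -> np.ndarray:
    """Single-pass upper Winsorization: values above mean + k*SD of the
    input are replaced by that cap; the lower tail is untouched."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise AnalysisError("winsorize requires at least 2 values")
    if not np.all(np.isfinite(x)):
        raise AnalysisError("winsorize requires finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy()
    cap = x.mean() + k * sd
    return np.minimum(x, cap)


def log_shift_transform(values) -> np.ndarray:
    """Natural log of (value + 1); monotone and zero-preserving."""
    x = np.asarray(values, dtype=float)
    if np.any(x < 0):
        raise AnalysisError("log transform requires nonnegative values")
    return np.log1p(x)


def prepare_outcome(
    panel: pd.DataFrame,
    outcome: str,
    winsorize_k: float = 3.0,
    log_skewed: bool = True,
) -> np.ndarray:
    """Winsorize (+k SD) then, for skewed count scores, log(x+1)."""
    y = winsorize_upper(panel[outcome].to_numpy(), k=winsorize_k)
    if log_skewed and outcome in SKEWED_OUTCOMES:
        y = log_shift_transform(y)
    return y


# ---------------------------------------------------------------------------
# Model terms and coding


@dataclass(frozen=True)
class ModelTerm:
    name: str
    factors: tuple
    df: int


def build_model_terms(within_factors=None, delay: bool = True) -> list:
    """Main effects + within two-way interactions + within x delay terms.

    ``within_factors`` maps factor name -> number of levels; the default
    five-factor layout with delay yields 6 + 10 + 5 = 21 terms, df 1
    except picture terms (df 3).
    """
    if within_factors is None:
        within_factors = {"picture": 4, **{f: 2 for f in BINARY_FACTORS}}
    names = list(within_factors)
    terms = [
        ModelTerm(name, (name,), within_factors[name] - 1) for name in names
    ]
    if delay:
        terms.append(ModelTerm(DELAY, (DELAY,), 1))
    for a, b in itertools.combinations(names, 2):
        df = (within_factors[a] - 1) * (within_factors[b] - 1)
        terms.append(ModelTerm(f"{a} x {b}", (a, b), df))
    if delay:
        for a in names:
            terms.append(
                ModelTerm(f"{a} x {DELAY}", (a, DELAY), within_factors[a] - 1)
            )
    return terms


def _factor_codes(panel: pd.DataFrame, factor: str) -> np.ndarray:
    """Sum-to-zero coding: binary factors one +/-1 column (high = +1),
    picture three columns, delay one column (cool/delayed = +1)."""
    if factor == "picture":
        cats = sorted(panel["picture_category"].unique())
        if len(cats) < 2:
            raise AnalysisError("picture factor needs >= 2 categories")
        cols = np.zeros((len(panel), len(cats) - 1))
        codes = pd.Categorical(panel["picture_category"], categories=cats).codes
        for j in range(len(cats) - 1):
            cols[:, j] = np.where(
                codes == j, 1.0, np.where(codes == len(cats) - 1, -1.0, 0.0)
            )
        return cols
    if factor == DELAY:
        return np.where(panel["delay_arm"].to_numpy() == "cool", 1.0, -1.0)[
            :, None
        ]
    if factor in BINARY_FACTORS:
        return np.where(panel[f"{factor}_level"].to_numpy() == HIGH, 1.0, -1.0)[
            :, None
        ]
    raise AnalysisError(f"unknown factor {factor!r}")


def _design_matrix(panel: pd.DataFrame, terms) -> tuple:
    """Exog matrix with intercept plus term blocks; returns the matrix
    and a {term name: column indices} map."""
    blocks = [np.ones((len(panel), 1))]
    index_map = {}
    col = 1
    for term in terms:
        parts = [_factor_codes(panel, f) for f in term.factors]
        block = parts[0]
        for part in parts[1:]:
            block = np.einsum("ij,ik->ijk", block, part).reshape(
                len(panel), -1
            )
        blocks.append(block)
        index_map[term.name] = list(range(col, col + block.shape[1]))
        col += block.shape[1]
    return np.hstack(blocks), index_map


# ---------------------------------------------------------------------------
# Holm-Sidak step-down correction


def holm_sidak_adjust(p_values, alpha: float = 0.05):
    """Step-down Sidak adjustment.

    Ordered ascending, adjusted p_(i) = 1 - (1 - p_(i))^(m - i + 1),
    made nondecreasing by a running maximum; hypotheses are rejected
    while the adjusted p stays at or below alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise AnalysisError("p_values must be 1-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise AnalysisError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, adj)
        adjusted[idx] = running
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if adjusted[idx] <= alpha:
            reject[idx] = True
        else:
            break
    return adjusted, reject


# ---------------------------------------------------------------------------
# Panel construction


def build_panel(trial_scores_by_pid: dict, participants: pd.DataFrame) -> pd.DataFrame:
    """Long-format rows: participant, delay arm, the five within
    factors, and the four per-trial outcome scores (one row per cell)."""
    arm_by_pid = {}
    for _, row in participants.iterrows():
        arm_by_pid[f"p{int(row['participant_id'])}"] = row["arm"]
        arm_by_pid[int(row["participant_id"])] = row["arm"]
        arm_by_pid[str(row["participant_id"])] = row["arm"]
    frames = []
    for pid, ts in trial_scores_by_pid.items():
        if pid not in arm_by_pid:
            raise AnalysisError(f"participant {pid!r} missing from cohort table")
        df = ts.copy()
        df["participant"] = pid
        df["delay_arm"] = arm_by_pid[pid]
        frames.append(df)
    panel = pd.concat(frames, ignore_index=True)
    cols = [
        "participant",
        "delay_arm",
        "picture_category",
        "injury_prob_level",
        "injury_mag_level",
        "reward_prob_level",
        "reward_mag_level",
        *OUTCOMES,
    ]
    return panel[cols]


def _cell_index(panel: pd.DataFrame) -> np.ndarray:
    """Stable condition-cell index (0..63 at defaults) for the working
    correlation's repeated-measure dimension."""
    key = (
        panel["picture_category"].astype(str)
        + "|"
        + panel["injury_prob_level"].astype(str)
        + "|"
        + panel["injury_mag_level"].astype(str)
        + "|"
        + panel["reward_prob_level"].astype(str)
        + "|"
        + panel["reward_mag_level"].astype(str)
    )
    cats = sorted(key.unique())
    return pd.Categorical(key, categories=cats).codes.astype(int)


def _wald_from_fit(params, cov, idx):
    b = params[idx]
    V = cov[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise AnalysisError("singular covariance in Wald test") from exc
    return stat


def fit_factorial_effects(
    panel: pd.DataFrame,
    terms=None,
    outcome: str = "points",
    cov_struct: str = "unstructured",
    alpha: float = 0.05,
    winsorize_k: float = 3.0,
    log_skewed: bool = True,
):
    """Fit the factorial marginal model and assemble the effect table.

    Returns ``(EffectTable DataFrame, fit details dict)``. The working
    correlation defaults to unstructured; with fewer participants than
    condition cells (or on solver failure) it falls back to exchangeable
    with a logged warning.
    """
    if terms is None:
        has_delay = panel["delay_arm"].nunique() > 1
        terms = build_model_terms(delay=has_delay)
    pids = panel["participant"].unique()
    if len(pids) < 2:
        raise AnalysisError("at least 2 participants are required")
    y = prepare_outcome(panel, outcome, winsorize_k=winsorize_k, log_skewed=log_skewed)
    exog, index_map = _design_matrix(panel, terms)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise AnalysisError("singular design matrix")
    groups = panel["participant"].to_numpy()
    time = _cell_index(panel)
    n_cells = int(time.max()) + 1

    requested = cov_struct
    if cov_struct == "unstructured" and len(pids) <= n_cells:
        logger.warning(
            "unstructured working correlation needs more participants (%d) "
            "than cells (%d); falling back to exchangeable",
            len(pids),
            n_cells,
        )
        cov_struct = "exchangeable"
    result = None
    for attempt in ([cov_struct] if cov_struct == "exchangeable" else [cov_struct, "exchangeable"]):
        struct = (
            sm.cov_struct.Unstructured()
            if attempt == "unstructured"
            else sm.cov_struct.Exchangeable()
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GEE(
                    y, exog, groups=groups, time=time[:, None], cov_struct=struct
                )
                result = model.fit()
            cov_struct = attempt
            break
        except Exception:  # noqa: BLE001 - solver failure triggers fallback
            if attempt == "exchangeable":
                raise
            logger.warning(
                "unstructured working-correlation fit failed; "
                "falling back to exchangeable"
            )
    params = np.asarray(result.params)
    cov = np.asarray(result.cov_params())
    rows = []
    for term in terms:
        idx = index_map[term.name]
        stat = _wald_from_fit(params, cov, idx)
        rows.append(
            {
                "term": term.name,
                "df": term.df,
                "wald": stat,
                "p_raw": float(sps.chi2.sf(stat, term.df)),
            }
        )
    table = pd.DataFrame(rows)
    adjusted, reject = holm_sidak_adjust(table["p_raw"].to_numpy(), alpha=alpha)
    table["p_adj"] = adjusted
    table["reject_raw"] = table["p_raw"] <= alpha
    table["reject_adj"] = reject
    details = {
        "result": result,
        "index_map": index_map,
        "terms": terms,
        "cov_struct": cov_struct,
        "requested_cov_struct": requested,
        "outcome": outcome,
    }
    return table, details


# ---------------------------------------------------------------------------
# Post hoc interaction decomposition

_CONTRAST_CATS = {name: (low, high) for name, low, high in PICTURE_CONTRASTS}


def _simple_factor_columns(factor: str):
    """(column, low label, high label, subset categories) for a simple-
    effect factor; picture contrasts map two categories to low/high."""
    if factor in BINARY_FACTORS:
        return f"{factor}_level", LOW, HIGH, None
    if factor == DELAY:
        return "delay_arm", "hot", "cool", None
    if factor in _CONTRAST_CATS:
        low_cat, high_cat = _CONTRAST_CATS[factor]
        return "picture_category", low_cat, high_cat, (low_cat, high_cat)
    raise AnalysisError(f"unknown simple-effect factor {factor!r}")


def _participant_cell_means(sub: pd.DataFrame, col: str, outcome: str):
    by = sub.groupby(["participant", col], observed=True)[outcome].mean()
    return by.unstack(col)


def decompose_interaction(
    panel: pd.DataFrame,
    term,
    outcome: str = "points",
    alpha: float = 0.05,
    winsorize_k: float = 3.0,
    log_skewed: bool = True,
) -> pd.DataFrame:
    """Simple-effect decomposition of a fitted two-way interaction.

    ``term`` is a pair of factor names (binary factors, ``delay``, or a
    picture contrast such as ``animal_cliff``). Per level of the first
    factor, the second factor's low/high levels are contrasted with a
    df-1 Wald test; p-values are Holm-Sidak adjusted within the
    decomposition.
    """
    term = tuple(term)
    if len(term) != 2:
        raise AnalysisError(
            f"decomposition requires a two-way interaction, got {term!r}"
        )
    v1, v2 = term
    if v1 == v2:
        raise AnalysisError("interaction factors must differ")
    col1, low1, high1, cats1 = _simple_factor_columns(v1)
    col2, low2, high2, cats2 = _simple_factor_columns(v2)
    if col1 == col2:
        raise AnalysisError("interaction factors must use distinct columns")

    data = panel.copy()
    data["_y"] = prepare_outcome(
        data, outcome, winsorize_k=winsorize_k, log_skewed=log_skewed
    )
    if cats1 is not None:
        data = data[data[col1].isin(cats1)]
    if cats2 is not None:
        data = data[data[col2].isin(cats2)]
    if data.empty:
        raise AnalysisError("no panel rows for this interaction")

    rows = []
    for level1 in (low1, high1):
        sub = data[data[col1] == level1]
        if sub.empty:
            raise AnalysisError(f"no rows at {v1}={level1}")
        cell = _participant_cell_means(sub, col2, "_y")
        for lv in (low2, high2):
            if lv not in cell.columns:
                raise AnalysisError(f"no rows at {v2}={lv} within {v1}={level1}")
        x = np.where(sub[col2].to_numpy() == high2, 1.0, -1.0)
        exog = np.column_stack([np.ones(len(sub)), x])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = sm.GEE(
                sub["_y"].to_numpy(),
                exog,
                groups=sub["participant"].to_numpy(),
                cov_struct=sm.cov_struct.Exchangeable(),
            ).fit()
        stat = _wald_from_fit(
            np.asarray(result.params), np.asarray(result.cov_params()), [1]
        )
        n = cell.shape[0]
        rows.append(
            {
                "term": f"{v1} x {v2}",
                "v1": v1,
                "v1_level": level1,
                "v2": v2,
                "mean_low": float(cell[low2].mean()),
                "se_low": float(cell[low2].std(ddof=1) / np.sqrt(n)),
                "mean_high": float(cell[high2].mean()),
                "se_high": float(cell[high2].std(ddof=1) / np.sqrt(n)),
                "wald": stat,
                "df": 1,
                "p_raw": float(sps.chi2.sf(stat, 1)),
            }
        )
    table = pd.DataFrame(rows)
    adjusted, reject = holm_sidak_adjust(table["p_raw"].to_numpy(), alpha=alpha)
    table["p_adj"] = adjusted
    table["reject"] = reject
    return table


# ---------------------------------------------------------------------------
# Correlation families


def correlation_families(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    family_map: dict,
    score_cols=None,
    by_arm: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between task scores and self-report scales,
    Holm-Sidak corrected within each (score column, family, arm)."""
    all_scales = [s for scales in family_map.values() for s in scales]
    if len(set(all_scales)) != len(all_scales):
        raise AnalysisError("families must partition the scales (duplicates found)")
    missing = [s for s in all_scales if s not in participants.columns]
    if missing:
        raise AnalysisError(f"scales missing from participants table: {missing}")
    if score_cols is None:
        score_cols = [c for c in scores.columns if "__" in c]
    merged = scores.merge(
        participants, on="participant_id", how="inner", validate="one_to_one"
    )
    if merged.empty:
        raise AnalysisError("no participants common to scores and cohort table")
    arms = sorted(merged["arm"].unique()) if by_arm else ["all"]
    rows = []
    for arm in arms:
        sub = merged if arm == "all" else merged[merged["arm"] == arm]
        if len(sub) < 4:
            raise AnalysisError(f"arm {arm!r} has fewer than 4 participants")
        for score_col in score_cols:
            for family, scales in family_map.items():
                batch = []
                for scale in scales:
                    x = sub[score_col].to_numpy(dtype=float)
                    z = sub[scale].to_numpy(dtype=float)
                    if np.std(x) == 0 or np.std(z) == 0:
                        batch.append(
                            {
                                "arm": arm,
                                "score": score_col,
                                "family": family,
                                "scale": scale,
                                "r": np.nan,
                                "n": len(sub),
                                "p_raw": np.nan,
                                "constant": True,
                            }
                        )
                        continue
                    r, p = sps.pearsonr(x, z)
                    batch.append(
                        {
                            "arm": arm,
                            "score": score_col,
                            "family": family,
                            "scale": scale,
                            "r": float(r),
                            "n": len(sub),
                            "p_raw": float(p),
                            "constant": False,
                        }
                    )
                valid = [b for b in batch if not b["constant"]]
                if valid:
                    adjusted, reject = holm_sidak_adjust(
                        np.array([b["p_raw"] for b in valid]), alpha=alpha
                    )
                    for b, adj, rej in zip(valid, adjusted, reject):
                        b["p_adj"] = float(adj)
                        b["reject"] = bool(rej)
                for b in batch:
                    b.setdefault("p_adj", np.nan)
                    b.setdefault("reject", False)
                rows.extend(batch)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic panels with known ground truth (calibration harness)


def simulate_panel(
    n_participants: int,
    seed: int,
    effects: dict | None = None,
    sigma_between: float = 1.0,
    sigma_within: float = 1.0,
    intercept: float = 10.0,
    outcome: str = "points",
) -> pd.DataFrame:
    """Generate a balanced panel with exchangeable correlation and known
    injected effects, for calibrating the factorial pipeline.

    ``effects`` maps a factor name (or a tuple of two names) to the
    coefficient on its +/-1 sum coding; unnamed terms are null.
    """
    effects = effects or {}
    rng = np.random.default_rng(seed)
    cats = ("animal", "cliff", "disaster", "hero")
    cells = list(itertools.product(cats, (LOW, HIGH), (LOW, HIGH), (LOW, HIGH), (LOW, HIGH)))
    rows = []
    for pid in range(n_participants):
        arm = "cool" if pid % 2 == 0 else "hot"
        b_i = rng.normal(0.0, sigma_between)
        for cat, ip, im, rp, rm in cells:
            rows.append(
                {
                    "participant": pid,
                    "delay_arm": arm,
                    "picture_category": cat,
                    "injury_prob_level": ip,
                    "injury_mag_level": im,
                    "reward_prob_level": rp,
                    "reward_mag_level": rm,
                    "_b": b_i,
                }
            )
    panel = pd.DataFrame(rows)
    y = np.full(len(panel), float(intercept))
    y += panel["_b"].to_numpy()
    code = {
        "injury_prob": np.where(panel["injury_prob_level"] == HIGH, 1.0, -1.0),
        "injury_mag": np.where(panel["injury_mag_level"] == HIGH, 1.0, -1.0),
        "reward_prob": np.where(panel["reward_prob_level"] == HIGH, 1.0, -1.0),
        "reward_mag": np.where(panel["reward_mag_level"] == HIGH, 1.0, -1.0),
        "delay": np.where(panel["delay_arm"] == "cool", 1.0, -1.0),
    }
    for key, beta in effects.items():
        if isinstance(key, tuple):
            x = np.ones(len(panel))
            for f in key:
                x = x * code[f]
        else:
            x = code[key]
        y += beta * x
    y += rng.normal(0.0, sigma_within, size=len(panel))
    panel = panel.drop(columns=["_b"])
    for out in OUTCOMES:
        panel[out] = 0.0
    panel[outcome] = y
    return panel
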