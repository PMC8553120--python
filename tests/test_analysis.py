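import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from aprt.analysis import (
    DELAY,
    AnalysisError,
    build_model_terms,
    build_panel,
    correlation_families,
    decompose_interaction,
    fit_factorial_effects,
    holm_sidak_adjust,
    log_shift_transform,
    prepare_outcome,
    simulate_panel,
    winsorize_upper,
)


def brute_force_holm_sidak(p, alpha=0.05):
    """Independent oracle: explicit step-down loop over ordered hypotheses."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    reject = np.zeros(m, dtype=bool)
    prev_adj = 0.0
    rejecting = True
    for i, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - i)
        adj = max(adj, prev_adj)
        prev_adj = adj
        adjusted[idx] = adj
        if rejecting and adj <= alpha:
            reject[idx] = True
        else:
            rejecting = False
    return adjusted, reject


class TestWinsorizeUpper:
    def test_constant_vector_unchanged(self):
        x = np.full(10, 3.0)
        assert (winsorize_upper(x) == x).all()

    def test_single_outlier_capped_at_oracle_value(self):
        x = np.array([0.0] * 10 + [10.0])
        cap = x.mean() + 3 * x.std(ddof=1)
        out = winsorize_upper(x)
        assert out[-1] == pytest.approx(cap)
        assert (out[:-1] == 0).all()

    def test_lower_tail_untouched(self):
        x = np.array([-50.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        out = winsorize_upper(x)
        assert out[0] == -50.0

    @given(
        x=st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=50
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_max_bounded_by_cap(self, x):
        x = np.asarray(x)
        out = winsorize_upper(x)
        cap = x.mean() + 3 * x.std(ddof=1)
        assert out.max() <= cap + 1e-6 or x.std(ddof=1) == 0

    def test_too_few_values(self):
        with pytest.raises(AnalysisError):
            winsorize_upper([1.0])


class TestLogShiftTransform:
    def test_zero_preserving(self):
        assert log_shift_transform([0.0])[0] == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert log_shift_transform([np.e - 1])[0] == pytest.approx(1.0)

    def test_monotone_on_random_vectors(self, rng):
        x = rng.gamma(2.0, 5.0, size=500)
        y = log_shift_transform(x)
        assert (np.argsort(x) == np.argsort(y)).all()

    def test_negative_rejected(self):
        with pytest.raises(AnalysisError):
            log_shift_transform([-0.5])


class TestBuildModelTerms:
    def test_default_is_21_terms(self):
        terms = build_model_terms()
        assert len(terms) == 21
        assert sum(1 for t in terms if len(t.factors) == 1) == 6
        within_two_way = [
            t for t in terms if len(t.factors) == 2 and DELAY not in t.factors
        ]
        delay_two_way = [
            t for t in terms if len(t.factors) == 2 and DELAY in t.factors
        ]
        assert len(within_two_way) == 10
        assert len(delay_two_way) == 5

    def test_picture_terms_have_df_3(self):
        by_name = {t.name: t for t in build_model_terms()}
        assert by_name["picture"].df == 3
        assert by_name["picture x injury_mag"].df == 3
        assert by_name["picture x delay"].df == 3
        assert by_name["injury_mag"].df == 1
        assert by_name["injury_prob x injury_mag"].df == 1

    def test_two_factors_no_delay(self):
        terms = build_model_terms({"a": 2, "b": 2}, delay=False)
        assert len(terms) == 3


class TestHolmSidak:
    def test_single_p_unchanged(self):
        adj, rej = holm_sidak_adjust([0.04])
        assert adj[0] == pytest.approx(0.04)
        assert rej[0]

    def test_first_critical_value_m3(self):
        # smallest of three is tested against 1-(1-alpha)^(1/3)
        crit = 1 - 0.95 ** (1 / 3)
        adj, rej = holm_sidak_adjust([crit - 1e-6, 0.9, 0.9])
        assert rej[0]
        adj, rej = holm_sidak_adjust([crit + 1e-3, 0.9, 0.9])
        assert not rej.any()

    def test_all_ones(self):
        adj, rej = holm_sidak_adjust([1.0, 1.0, 1.0])
        assert (adj == 1.0).all()
        assert not rej.any()

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 21)
            p = rng.random(m)
            adj, rej = holm_sidak_adjust(p)
            oadj, orej = brute_force_holm_sidak(p)
            np.testing.assert_allclose(adj, oadj, atol=1e-12)
            assert (rej == orej).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(AnalysisError):
            holm_sidak_adjust([0.5, 1.2])


class TestFitFactorialEffects:
    def test_injected_effect_detected_single_fit(self):
        panel = simulate_panel(60, seed=4, effects={"injury_prob": 0.5})
        table, details = fit_factorial_effects(
            panel, outcome="points", cov_struct="exchangeable"
        )
        assert len(table) == 21
        hit = table.set_index("term").loc["injury_prob"]
        assert hit["reject_adj"]
        assert hit["p_adj"] < 1e-6

    def test_single_participant_errors(self):
        panel = simulate_panel(1, seed=0)
        with pytest.raises(AnalysisError, match="participants"):
            fit_factorial_effects(panel, outcome="points")

    def test_unstructured_falls_back_for_small_n(self, caplog):
        panel = simulate_panel(10, seed=1)
        with caplog.at_level("WARNING", logger="aprt.analysis"):
            table, details = fit_factorial_effects(
                panel, outcome="points", cov_struct="unstructured"
            )
        assert details["cov_struct"] == "exchangeable"
        assert any("falling back" in r.message for r in caplog.records)

    def test_transforms_change_statistics_not_term_count(self):
        panel = simulate_panel(30, seed=2, effects={"injury_mag": 0.4})
        panel["go_presses"] = np.abs(panel["points"])
        raw, _ = fit_factorial_effects(
            panel, outcome="go_presses", cov_struct="exchangeable", log_skewed=False
        )
        logged, _ = fit_factorial_effects(
            panel, outcome="go_presses", cov_struct="exchangeable", log_skewed=True
        )
        assert len(raw) == len(logged) == 21
        assert not np.allclose(raw["wald"], logged["wald"])

    def test_null_p_values_uniform(self):
        # reduced-scale uniformity check of one null term's p distribution
        pvals = []
        for rep in range(300):
            panel = simulate_panel(30, seed=10_000 + rep)
            table, _ = fit_factorial_effects(
                panel, outcome="points", cov_struct="exchangeable"
            )
            pvals.append(
                table.set_index("term").loc["injury_mag", "p_raw"]
            )
        stat = sps.kstest(pvals, "uniform").pvalue
        assert stat > 0.01

    def test_effect_direction_recovered_as_n_grows(self):
        rejections = []
        for n in (25, 100):
            panel = simulate_panel(n, seed=60 + n, effects={"reward_mag": 0.15})
            table, _ = fit_factorial_effects(
                panel, outcome="points", cov_struct="exchangeable"
            )
            rejections.append(
                bool(table.set_index("term").loc["reward_mag", "reject_raw"])
            )
        assert rejections[-1]


class TestDecomposeInteraction:
    def test_crossover_interaction_both_simple_effects(self):
        panel = simulate_panel(
            80, seed=5, effects={("injury_mag", "injury_prob"): 0.6}
        )
        dec = decompose_interaction(panel, ("injury_mag", "injury_prob"))
        assert len(dec) == 2
        assert dec["reject"].all()
        d_low = dec.iloc[0]["mean_high"] - dec.iloc[0]["mean_low"]
        d_high = dec.iloc[1]["mean_high"] - dec.iloc[1]["mean_low"]
        assert np.sign(d_low) != np.sign(d_high)

    def test_additive_panel_equal_simple_effects(self):
        panel = simulate_panel(
            150, seed=6, effects={"injury_mag": 0.5, "injury_prob": 0.5}
        )
        dec = decompose_interaction(panel, ("injury_mag", "injury_prob"))
        d_low = dec.iloc[0]["mean_high"] - dec.iloc[0]["mean_low"]
        d_high = dec.iloc[1]["mean_high"] - dec.iloc[1]["mean_low"]
        se = np.hypot(
            dec.iloc[0][["se_low", "se_high"]].sum(),
            dec.iloc[1][["se_low", "se_high"]].sum(),
        )
        assert abs(d_low - d_high) < 3 * se

    def test_picture_contrast_decomposition(self):
        panel = simulate_panel(40, seed=7, effects={"injury_prob": 0.5})
        dec = decompose_interaction(panel, ("injury_prob", "disaster_hero"))
        assert set(dec["v1_level"]) == {"low", "high"}

    def test_delay_decomposition(self):
        panel = simulate_panel(40, seed=8, effects={"delay": 0.5})
        dec = decompose_interaction(panel, ("delay", "injury_prob"))
        assert list(dec["v1_level"]) == ["hot", "cool"]

    def test_main_effect_term_rejected(self):
        panel = simulate_panel(10, seed=9)
        with pytest.raises(AnalysisError, match="two-way"):
            decompose_interaction(panel, ("injury_mag",))

    def test_identical_factors_rejected(self):
        panel = simulate_panel(10, seed=9)
        with pytest.raises(AnalysisError):
            decompose_interaction(panel, ("injury_mag", "injury_mag"))


class TestCorrelationFamilies:
    @staticmethod
    def _tables(n=40, seed=0):
        rng = np.random.default_rng(seed)
        participants = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "arm": np.where(np.arange(n) % 2 == 0, "cool", "hot"),
                "scale_a": rng.standard_normal(n),
                "scale_b": rng.standard_normal(n),
            }
        )
        scores = pd.DataFrame(
            {
                "participant_id": np.arange(n),
                "points__total": participants["scale_a"],
            }
        )
        return scores, participants

    def test_identical_scale_gives_r_one(self):
        scores, participants = self._tables()
        report = correlation_families(
            scores,
            participants,
            {"convergent": ["scale_a"], "divergent": ["scale_b"]},
            score_cols=["points__total"],
        )
        ra = report[report["scale"] == "scale_a"]["r"]
        assert np.allclose(ra, 1.0)

    def test_families_must_partition(self):
        scores, participants = self._tables()
        with pytest.raises(AnalysisError, match="partition"):
            correlation_families(
                scores,
                participants,
                {"f1": ["scale_a"], "f2": ["scale_a"]},
            )

    def test_constant_column_flagged(self):
        scores, participants = self._tables()
        participants["scale_b"] = 1.0
        report = correlation_families(
            scores,
            participants,
            {"f": ["scale_b"]},
            score_cols=["points__total"],
        )
        assert report["constant"].all()
        assert report["r"].isna().all()

    def test_small_arm_rejected(self):
        scores, participants = self._tables(n=6)
        with pytest.raises(AnalysisError, match="fewer than 4"):
            correlation_families(
                scores,
                participants,
                {"f": ["scale_a"]},
                score_cols=["points__total"],
            )

    def test_adjustment_within_family_only(self):
        scores, participants = self._tables(n=100, seed=3)
        report = correlation_families(
            scores,
            participants,
            {"f1": ["scale_a"], "f2": ["scale_b"]},
            score_cols=["points__total"],
        )
        # scale_a is identical to the score: its family has m=1, so its
        # adjusted p equals its raw p
        ra = report[report["scale"] == "scale_a"]
        assert np.allclose(ra["p_adj"], ra["p_raw"])


class TestBuildPanel:
    def test_panel_shape_and_columns(self, design):
        from aprt.agents import CohortSpec, generate_cohort, simulate_cohort
        from aprt.engine import trial_records_frame
        from aprt.scoring import trial_scores_from_frame

        coh = generate_cohort(CohortSpec(n=6, seed=0))
        logs = simulate_cohort(coh, design, cohort_seed=1)
        trials = pd.concat(
            [trial_records_frame(log) for log in logs], ignore_index=True
        )
        trials["participant_id"] = (
            trials["participant_id"].str.removeprefix("p").astype(int)
        )
        panel = build_panel(trial_scores_from_frame(trials), coh)
        assert len(panel) == 6 * 64
        assert set(panel["delay_arm"]) == {"hot", "cool"}
        assert panel.groupby("participant")["delay_arm"].nunique().max() == 1
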