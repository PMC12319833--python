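import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urnbid import behavior
from urnbid.agents import AgentProfile, CohortSpec, simulate_cohort
from urnbid.behavior import (
    MERGED_NONNORMATIVE_NEGATIVE,
    UndefinedTestError,
    aggregate_categories,
    backward_select,
    category_summaries,
    compute_dev,
    correlate_covariate,
    fit_mixed_model,
    fit_process_lmm,
    fit_valence_normativity_lmm,
    valence_normativity_cells,
    wilcoxon_one_sample,
)


def wilcoxon_enumeration_oracle(values, mu0=0.0):
    """Full sign-pattern enumeration of the signed-rank null (midranks)."""
    d = np.asarray(values, float) - mu0
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_all = np.array(
        [np.dot(ranks, signs) for signs in itertools.product([0, 1], repeat=len(d))]
    )
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    p = min(1.0, 2 * min(p_le, p_ge))
    rb = (w_obs - (total - w_obs)) / total
    return w_obs, p, rb


class TestWilcoxon:
    def test_all_positive_small_sample(self):
        res = wilcoxon_one_sample([1, 2, 3, 4, 5])
        assert res.statistic == 15
        assert res.pvalue == pytest.approx(0.0625)
        assert res.rank_biserial == pytest.approx(1.0)
        assert res.method == "exact"

    def test_symmetric_values_have_zero_effect_size(self):
        res = wilcoxon_one_sample([-2, -1, 1, 2])
        assert res.rank_biserial == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_differences_are_dropped(self):
        res = wilcoxon_one_sample([0, 0, 1, 2, 3], mu0=0)
        assert res.n_used == 3 and res.n_zero == 2

    def test_all_ties_with_mu0_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_one_sample([2.0, 2.0, 2.0], mu0=2.0)

    def test_matches_enumeration_oracle_on_random_vectors(self):
        """Exact p and rank-biserial versus brute-force sign enumeration."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(3, 13)
            vals = rng.integers(-3, 4, size=n).astype(float)
            if np.all(vals == 0):
                vals[0] = 1.0
            w, p, rb = wilcoxon_enumeration_oracle(vals)
            res = wilcoxon_one_sample(vals)
            assert res.statistic == pytest.approx(w)
            assert res.pvalue == pytest.approx(p, abs=1e-12)
            assert res.rank_biserial == pytest.approx(rb)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0.4, 1.0, size=30)
        exact = wilcoxon_one_sample(vals, exact_max_n=40)
        approx = wilcoxon_one_sample(vals)  # n > 25 -> approximation
        assert approx.method == "approx" and exact.method == "exact"
        assert approx.pvalue == pytest.approx(exact.pvalue, abs=0.01)


class TestAggregation:
    def _toy(self):
        return pd.DataFrame(
            {
                "participant": ["p1"] * 4 + ["p2"] * 4,
                "category": [
                    "normative_positive", "normative_positive",
                    "nonnormative_negative_risky_draw_in_ambiguous",
                    "nonnormative_negative_ambiguous_draw_in_risky",
                ] * 2,
                "delta_wts": [1.0, -1.0, 2.0, 4.0, 3.0, 1.0, np.nan, 0.0],
                "predicted_update": [1.25, 1.25, 0.0, 0.0] * 2,
            }
        )

    def test_cell_means_and_missing_exclusion(self):
        wide = aggregate_categories(self._toy())
        assert wide.loc["p1", "normative_positive"] == pytest.approx(0.0)
        assert wide.loc["p2", "normative_positive"] == pytest.approx(2.0)
        assert np.isnan(
            wide.loc["p2", "nonnormative_negative_risky_draw_in_ambiguous"]
        )

    def test_merge_pools_the_two_mismatch_categories(self):
        wide = aggregate_categories(self._toy(), merge_nonnormative_negative=True)
        assert wide.loc["p1", MERGED_NONNORMATIVE_NEGATIVE] == pytest.approx(3.0)
        # merging is idempotent: re-merging the merged table changes nothing
        again = aggregate_categories(
            self._toy().assign(), merge_nonnormative_negative=True
        )
        pd.testing.assert_frame_equal(wide, again)


class TestDev:
    def test_perfect_bayesian_has_zero_deviation(self, plan):
        from urnbid.agents import simulate_session

        # noise-free agent following the model except for integer rounding:
        # use the raw prediction as the bid change by construction
        df = simulate_session(AgentProfile(w_belief=1.0), plan, seed=0)
        df["delta_wts"] = df["predicted_update"]
        dev = compute_dev(df)
        assert np.allclose(dev["dev"], 0.0)

    def test_sign_flip_is_involutive_and_directional(self, old_cohort):
        trials, _ = old_cohort
        flipped = compute_dev(trials, sign_flip_negative=True)
        raw = compute_dev(trials, sign_flip_negative=False)
        neg = raw["category"].isin(behavior.NEGATIVE_CATEGORIES)
        assert np.allclose(flipped.loc[neg, "dev"], -raw.loc[neg, "dev"])
        assert np.allclose(flipped.loc[~neg, "dev"], raw.loc[~neg, "dev"])
        # |DEV| is invariant to the flip
        assert np.allclose(flipped["abs_dev"], raw["abs_dev"])

    def test_under_updating_agent_has_negative_dev_in_normative_trials(
        self, recovery_cohort_factory
    ):
        trials, _ = recovery_cohort_factory(0, w_belief=0.5, w_ev_pos=0.0, w_ev_neg=0.0)
        dev = compute_dev(trials, sign_flip_negative=True)
        norm = dev[dev["category"].str.startswith("normative")]
        means = norm.groupby("category")["dev"].mean()
        assert (means < 0).all()

    def test_dev_linearity_under_urn_averaging(self, old_cohort):
        trials, _ = old_cohort
        t = trials.dropna(subset=["delta_wts"])
        direct = (
            (t["delta_wts"] - t["predicted_update"])
            .groupby([t["participant"], t["category"]])
            .mean()
        )
        cells = (
            t.assign(d=t["delta_wts"] - t["predicted_update"])
            .groupby(["participant", "category", "urn"], observed=True)["d"]
            .agg(["mean", "size"])
        )
        by_urn = (
            (cells["mean"] * cells["size"]).groupby(
                ["participant", "category"], observed=True
            ).sum()
            / cells["size"].groupby(["participant", "category"], observed=True).sum()
        )
        # predictions are constant within an urn x category cell, so
        # pre-averaging those trials and recombining reproduces the direct DEV
        assert np.allclose(direct, by_urn, atol=1e-9)


def gls_oracle(cells):
    """Closed-form GLS for the balanced random-intercept two-factor design.

    Builds the treatment-coded design by hand, estimates the variance
    components by the method of moments, and solves the GLS normal
    equations directly.
    """
    df = cells.sort_values(["participant", "valence", "normativity"]).reset_index(drop=True)
    x_val = (df["valence"] == "positive").astype(float)
    x_norm = (df["normativity"] == "normative").astype(float)
    X = np.column_stack([np.ones(len(df)), x_norm, x_val, x_val * x_norm])
    pids = df["participant"].unique()
    Z = (df["participant"].to_numpy()[:, None] == pids[None, :]).astype(float)
    y = df["value"].to_numpy()
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    k = len(df) // len(pids)
    subj_means = Z.T @ resid / k
    sigma2 = np.sum((resid - Z @ subj_means) ** 2) / (len(df) - len(pids) - X.shape[1] + 1)
    tau2 = max(subj_means.var(ddof=1) - sigma2 / k, 1e-8)
    V = sigma2 * np.eye(len(df)) + tau2 * Z @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return dict(zip(["Intercept", "norm", "val", "val:norm"], beta))


class TestValenceNormativityLmm:
    def _cells(self, seed=0, effects=(0.5, -0.3, 0.2, 0.1), n=8, noise=0.4):
        rng = np.random.default_rng(seed)
        mu, b_norm, b_val, b_int = effects
        rows = []
        for i in range(n):
            u = rng.normal(0, 0.5)
            for val in ("negative", "positive"):
                for norm in ("nonnormative", "normative"):
                    y = (
                        mu
                        + b_norm * (norm == "normative")
                        + b_val * (val == "positive")
                        + b_int * (val == "positive") * (norm == "normative")
                        + u
                        + rng.normal(0, noise)
                    )
                    rows.append(
                        {"participant": f"s{i}", "valence": val,
                         "normativity": norm, "value": y}
                    )
        return pd.DataFrame(rows)

    def test_estimates_match_gls_oracle_on_balanced_toy_design(self):
        cells = self._cells()
        res = fit_valence_normativity_lmm(cells)
        oracle = gls_oracle(cells)
        assert res.params["Intercept"] == pytest.approx(oracle["Intercept"], abs=1e-6)
        assert res.params["normativity[T.normative]"] == pytest.approx(
            oracle["norm"], abs=1e-6
        )
        assert res.params["valence[T.positive]"] == pytest.approx(oracle["val"], abs=1e-6)
        assert res.params[
            "valence[T.positive]:normativity[T.normative]"
        ] == pytest.approx(oracle["val:norm"], abs=1e-6)

    def test_minimal_two_participant_design_matches_oracle(self):
        cells = self._cells(seed=3, n=2, noise=0.2)
        res = fit_valence_normativity_lmm(cells)
        oracle = gls_oracle(cells)
        assert res.params["Intercept"] == pytest.approx(oracle["Intercept"], abs=1e-6)

    def test_null_world_gives_null_fixed_effects(self):
        cells = self._cells(seed=1, effects=(0.0, 0.0, 0.0, 0.0), n=20)
        res = fit_valence_normativity_lmm(cells)
        for term in res.params.index:
            if term == "Intercept":
                continue
            assert abs(res.params[term]) < 4 * res.bse[term]

    def test_valence_asymmetry_detected_in_asymmetric_cohort(self, old_cohort):
        trials, _ = old_cohort
        res = fit_valence_normativity_lmm(trials)
        row = res.anova.set_index("term").loc["valence"]
        assert row["pvalue"] < 0.05
        # after sign-flipping, negative trials show the larger updating
        contrast = res.contrasts.iloc[0]
        assert contrast["contrast"] == "negative - positive"
        assert contrast["estimate"] > 0

    def test_cells_layout_merges_and_flips(self, old_cohort):
        trials, _ = old_cohort
        cells = valence_normativity_cells(trials)
        assert set(cells["valence"]) == {"positive", "negative"}
        assert set(cells["normativity"]) == {"normative", "nonnormative"}
        assert cells.groupby("participant").size().max() <= 4


class TestProcessLmm:
    def test_heuristic_cohort_direction_and_elimination(self):
        spec = CohortSpec(
            n_agents=46, label="h", seed=0, sds={},
            means=AgentProfile(w_belief=0.0, w_ev_pos=0.0, w_ev_neg=0.6,
                               ambiguity_premium=3.0, noise_sd=1.0),
        )
        trials, _ = simulate_cohort(spec)
        res = fit_process_lmm(
            trials, "nonnormative_negative_ambiguous_draw_in_risky", stepwise=True
        )
        assert "expectancy_violation" in res.params.index
        assert res.params["expectancy_violation"] < 0
        assert res.pvalues["expectancy_violation"] < 0.001
        assert "belief_update" not in res.params.index
        assert any(e["removed"] == "belief_update" for e in res.elimination_path)

    def test_bayesian_cohort_keeps_only_the_belief_term(self):
        spec = CohortSpec(
            n_agents=46, label="b", seed=1, sds={},
            means=AgentProfile(w_belief=1.0, noise_sd=0.8),
        )
        trials, _ = simulate_cohort(spec)
        res = fit_process_lmm(
            trials, "normative_positive", stepwise=True,
            belief_predictor="predicted_update",
        )
        assert "predicted_update" in res.params.index
        assert res.pvalues["predicted_update"] < 0.001
        assert "expectancy_violation" not in res.params.index

    def test_constant_predictor_dropped_with_warning(self, old_cohort, caplog):
        trials, _ = old_cohort
        with caplog.at_level("WARNING", logger="urnbid.behavior"):
            res = fit_process_lmm(
                trials, "nonnormative_negative_risky_draw_in_ambiguous"
            )
        assert "belief_update" not in res.params.index
        assert any("constant" in r.message for r in caplog.records)

    def test_recovers_generative_weight_within_two_se(self, recovery_cohort_factory):
        trials, _ = recovery_cohort_factory(5)
        res = fit_process_lmm(trials, "nonnormative_negative_risky_draw_in_ambiguous")
        est = res.params["expectancy_violation"]
        se = res.bse["expectancy_violation"]
        assert abs(est - (-1.0)) <= 2 * se  # generative -w_ev_neg * 10 = -1.0


class TestBackwardSelect:
    def test_removes_noise_terms_keeps_signal(self):
        rng = np.random.default_rng(0)
        n, m = 30, 8
        rows = []
        for i in range(m):
            u = rng.normal(0, 0.3)
            x1 = rng.normal(size=n)
            x2 = rng.normal(size=n)
            y = 1.5 * x1 + u + rng.normal(0, 0.5, size=n)
            rows.append(pd.DataFrame(
                {"participant": f"s{i}", "y": y, "x1": x1, "x2": x2}))
        data = pd.concat(rows, ignore_index=True)
        terms, path = backward_select(data, "y", ["x1", "x2"])
        assert terms == ["x1"]
        assert path[0]["removed"] == "x2"

    def test_respects_marginality(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(8):
            x1 = rng.normal(size=20)
            x2 = rng.normal(size=20)
            y = x1 * x2 * 2.0 + rng.normal(0, 0.5, size=20)
            rows.append(pd.DataFrame(
                {"participant": f"s{i}", "y": y, "x1": x1, "x2": x2}))
        data = pd.concat(rows, ignore_index=True)
        terms, _ = backward_select(data, "y", ["x1", "x2", "x1:x2"])
        assert "x1:x2" in terms and "x1" in terms and "x2" in terms


@pytest.fixture(scope="module")
def two_cohorts():
    t_old, c_old = simulate_cohort(CohortSpec.preset("old_like", seed=21, n_agents=20))
    t_young, c_young = simulate_cohort(
        CohortSpec.preset("young_like", seed=22, n_agents=20)
    )
    return (
        pd.concat([t_old, t_young], ignore_index=True),
        pd.concat([c_old, c_young], ignore_index=True),
    )


class TestAgeModels:
    def test_age_by_normativity_interaction_old_exceeds_young_nonnormatively(
        self, two_cohorts
    ):
        trials, cov = two_cohorts
        models = behavior.fit_age_group_lmms(trials, cov)
        anova = models["updating"].anova.set_index("term")
        assert anova.loc["age_group:normativity", "pvalue"] < 0.05
        contrasts = models["updating"].contrasts.set_index("normativity")
        assert contrasts.loc["nonnormative", "estimate"] > 0
        assert contrasts.loc["nonnormative", "pvalue_adj"] < 0.05
        assert contrasts.loc["normative", "pvalue_adj"] > 0.05

    def test_predraw_premium_appears_only_in_ambiguous_gambles(self, two_cohorts):
        trials, cov = two_cohorts
        models = behavior.fit_age_group_lmms(trials, cov)
        anova = models["predraw"].anova.set_index("term")
        assert anova.loc["age_group:gamble_type", "pvalue"] < 0.05
        contrasts = models["predraw"].contrasts.set_index("gamble_type")
        assert contrasts.loc["ambiguous", "estimate"] > 0
        assert contrasts.loc["ambiguous", "pvalue_adj"] < 0.05
        # and the age difference does not interact with phase three-way
        anova3 = models["phase"].anova.set_index("term")
        assert anova3.loc["age_group:gamble_type:phase", "pvalue"] > 0.01

    def test_identical_presets_show_no_age_effects(self):
        t1, c1 = simulate_cohort(CohortSpec.preset("old_like", seed=31, n_agents=15))
        t2, c2 = simulate_cohort(CohortSpec.preset("old_like", seed=32, n_agents=15))
        t2 = t2.assign(age_group="old_like_b",
                       participant=t2["participant"] + "b")
        c2 = c2.assign(age_group="old_like_b",
                       participant=c2["participant"] + "b")
        trials = pd.concat([t1, t2], ignore_index=True)
        cov = pd.concat([c1, c2], ignore_index=True)
        models = behavior.fit_age_group_lmms(trials, cov)
        anova = models["updating"].anova.set_index("term")
        assert anova.loc["age_group", "pvalue"] > 0.001
        assert anova.loc["age_group:normativity", "pvalue"] > 0.001

    def test_single_cohort_rejected(self, old_cohort):
        trials, cov = old_cohort
        with pytest.raises(ValueError):
            behavior.fit_age_group_lmms(trials, cov)


class TestCovariateCorrelation:
    def test_perfect_monotone_map(self):
        x = np.array([0.2, 0.5, 0.9, 1.3, 2.0, 2.5])
        rho, p = correlate_covariate(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1, _ = correlate_covariate(x, y)
        r2, _ = correlate_covariate(np.exp(x), y**3 + 5 * y)
        assert r1 == pytest.approx(r2)

    def test_semi_partial_removes_control_driven_association(self):
        rng = np.random.default_rng(1)
        c = rng.normal(size=200)
        x = c + rng.normal(0, 0.3, 200)
        y = c + rng.normal(0, 0.3, 200)  # related only through the control
        r_raw, _ = correlate_covariate(x, y)
        r_sp, _ = correlate_covariate(x, y, controls=c)
        assert abs(r_sp) < abs(r_raw) / 2

    def test_linkage_recovery_median_within_band(self):
        """Cohorts with rank linkage -0.4 recover a clearly negative rho.

        The linkage world is defined with low bid noise so the generative
        deviation dominates realized |DEV|.  The median across replicates is
        asserted (the 95%-envelope formulation is infeasible at n=46 even at
        true rho = -0.4; Spearman's sampling SD alone is ~0.13).
        """
        rhos = []
        for seed in range(8):
            spec = CohortSpec(
                n_agents=46, label="link", seed=seed,
                means=AgentProfile(w_belief=0.5, w_ev_pos=0.08, w_ev_neg=0.12,
                                   ambiguity_premium=0.5, noise_sd=0.8),
                sds={"w_belief": 0.25, "w_ev_pos": 0.06, "w_ev_neg": 0.06,
                     "ambiguity_premium": 0.3, "noise_sd": 0.2},
            )
            trials, cov = simulate_cohort(spec)
            abs_dev = behavior.overall_abs_dev(trials)
            merged = cov.set_index("participant").loc[abs_dev.index]
            rho, _ = correlate_covariate(abs_dev, merged["covariate_score"])
            rhos.append(rho)
        assert -0.6 < np.median(rhos) < -0.2

    def test_error_conditions(self):
        with pytest.raises(UndefinedTestError):
            correlate_covariate([1, 2, 3], [1, 2, 3])  # too few
        with pytest.raises(UndefinedTestError):
            correlate_covariate([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])


def test_category_summaries_tidy_output(old_cohort):
    trials, _ = old_cohort
    summ = category_summaries(trials)
    assert len(summ) == 5
    assert summ["rank_biserial"].abs().le(1).all()
    assert (summ["pvalue"] <= 1).all() and (summ["pvalue"] >= 0).all()


def test_fit_mixed_model_metadata_records_df_method(old_cohort):
    trials, _ = old_cohort
    res = fit_valence_normativity_lmm(trials)
    assert res.metadata["df_method"] == "residual"
    assert res.metadata["reml"] is True
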