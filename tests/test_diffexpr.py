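"""Design construction, per-gene OLS, variance moderation, permutations, eigengene."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replisig import (
    ModeratedTTest,
    VariancePrior,
    build_design,
    estimate_variance_prior,
    fit_gene_models,
    moderated_statistics,
    module_eigengene,
    permutation_pvalues,
    sample_gene_variances,
)
from replisig.diffexpr import DesignMatrix, GeneModelFits
from replisig.exceptions import ConfigError, DesignError


def make_fits(sigma2, beta=None, d=10, c_group=0.1):
    sigma2 = np.asarray(sigma2, dtype=float)
    beta = np.zeros_like(sigma2) if beta is None else np.asarray(beta, dtype=float)
    coef = pd.DataFrame(
        {"group[case]": beta},
        index=[f"g{i}" for i in range(len(sigma2))],
    )
    return GeneModelFits(
        coef=coef, sigma2=sigma2, df_residual=d, c_group=c_group, group_col="group[case]"
    )


class TestBuildDesign:
    def test_full_model_has_six_columns(self, toy_study):
        study = toy_study(np.zeros((3, 8)))
        design = build_design(study.samples)
        assert list(design.columns) == [
            "intercept", "group[case]", "batch[2]", "sex[female]", "age", "anxiety[1]",
        ]
        assert np.all(design.frame["intercept"] == 1.0)

    def test_single_batch_column_dropped_with_warning(self, toy_study, caplog):
        study = toy_study(np.zeros((3, 8)), batch=[1] * 8)
        with caplog.at_level("WARNING"):
            design = build_design(study.samples)
        assert design.frame.shape[1] == 5
        assert "batch" in caplog.text

    def test_single_group_level_is_an_error(self, toy_study):
        study = toy_study(np.zeros((2, 8)))
        table = study.samples.copy()
        table["group"] = "case"
        with pytest.raises(DesignError):
            build_design(table)

    def test_missing_covariate_values_rejected(self, toy_study):
        study = toy_study(np.zeros((2, 8)))
        table = study.samples.copy()
        table.loc[table.index[0], "age"] = np.nan
        with pytest.raises(DesignError):
            build_design(table)


class TestFitGeneModels:
    def test_noiseless_response_recovered_exactly(self, toy_study):
        study = toy_study(np.zeros((3, 8)))
        design = build_design(study.samples)
        true_beta = np.array(
            [[7, 0.8, -0.2, 0.1, 0.01, 0.3],
             [5, -1.0, 0.0, 0.0, 0.0, 0.0],
             [6, 0.0, 0.5, -0.5, -0.02, 0.1]]
        )
        y = true_beta @ design.values.T
        study = toy_study(y)
        fits = fit_gene_models(study, design)
        np.testing.assert_allclose(fits.coef.to_numpy(), true_beta, atol=1e-9)
        np.testing.assert_allclose(fits.sigma2, 0.0, atol=1e-16)

    def test_matches_hand_normal_equations_on_3x2_toy(self):
        # X = [[1,0],[1,1],[1,2]], y = [0,1,1] -> beta = (1/6, 1/2) by hand
        import replisig.study as st

        X = pd.DataFrame(
            {"intercept": [1.0, 1.0, 1.0], "group[case]": [0.0, 1.0, 2.0]},
            index=["s1", "s2", "s3"],
        )
        design = DesignMatrix(frame=X, group_col="group[case]")
        expr = pd.DataFrame([[0.0, 1.0, 1.0]], index=["g1"], columns=X.index)
        meta = pd.DataFrame(
            {"group": ["control", "case", "case"]}, index=X.index
        )
        study = st.ExpressionStudy(expr, meta, name="hand")
        fits = fit_gene_models(study, design)
        np.testing.assert_allclose(fits.coef.loc["g1"], [1 / 6, 1 / 2], atol=1e-12)
        assert fits.df_residual == 1

    def test_df_is_n_minus_rank(self, planted_pair):
        s1, _, _, _ = planted_pair
        design = build_design(s1.samples)
        fits = fit_gene_models(s1, design)
        assert fits.df_residual == s1.n_samples - design.frame.shape[1]

    def test_more_columns_than_samples_rejected(self, toy_study):
        study = toy_study(np.zeros((2, 8)))
        design = build_design(study.samples)
        small = study.expression.iloc[:, :5]
        import replisig.study as st

        tiny = st.ExpressionStudy(small, study.samples.loc[small.columns], "tiny")
        with pytest.raises(DesignError):
            fit_gene_models(tiny, DesignMatrix(design.frame.loc[small.columns], design.group_col))


class TestVariancePrior:
    def test_identical_variances_flag_infinite_prior(self):
        prior = estimate_variance_prior(make_fits([0.5] * 100))
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.5)

    def test_hyperparameters_recovered_from_simulated_variances(self):
        rng = np.random.default_rng(3)
        sigma2 = sample_gene_variances(8000, d0=4.0, s0_sq=2.0, seed=rng)
        d = 10
        s2 = sigma2 * rng.chisquare(d, 8000) / d
        prior = estimate_variance_prior(make_fits(s2, d=d))
        assert prior.d0 == pytest.approx(4.0, abs=0.75)
        assert prior.s0_sq == pytest.approx(2.0, rel=0.08)

    def test_two_genes_returns_estimate_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            prior = estimate_variance_prior(make_fits([0.3, 0.9]))
        assert prior.s0_sq > 0
        assert "prior" in caplog.text or "genes" in caplog.text


class TestModeratedStatistics:
    def test_hand_shrinkage_example(self):
        # d=4, s2=4, d0=4, s0^2=1, beta=1, c_g=0.25 -> s~2=2.5, t=1.2649, df=8
        fits = make_fits([4.0], beta=[1.0], d=4, c_group=0.25)
        out = moderated_statistics(fits, VariancePrior(d0=4.0, s0_sq=1.0))
        assert out["s2_post"].iloc[0] == pytest.approx(2.5)
        assert out["t"].iloc[0] == pytest.approx(1.0 / math.sqrt(0.25 * 2.5), abs=1e-9)
        assert out["t"].iloc[0] == pytest.approx(1.2649, abs=1e-4)
        assert out["df"].iloc[0] == 8

    def test_zero_prior_df_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(0)
        s2 = rng.chisquare(5, 50)
        beta = rng.normal(size=50)
        d, c_g = 8, 0.2
        fits = make_fits(s2, beta=beta, d=d, c_group=c_g)
        out = moderated_statistics(fits, VariancePrior(d0=0.0, s0_sq=1.0))
        ordinary_t = beta / np.sqrt(c_g * s2)
        np.testing.assert_allclose(out["t"].to_numpy(), ordinary_t, rtol=0, atol=0)
        np.testing.assert_allclose(
            out["pvalue"], 2 * stats.t.sf(np.abs(ordinary_t), df=d)
        )

    def test_zero_effect_gives_t_zero_p_one(self):
        out = moderated_statistics(
            make_fits([1.0], beta=[0.0]), VariancePrior(4.0, 1.0)
        )
        assert out["t"].iloc[0] == 0.0
        assert out["pvalue"].iloc[0] == 1.0

    def test_posterior_variance_interpolates_monotonically_in_d0(self):
        s2, s0 = 4.0, 1.0
        posts = [
            moderated_statistics(
                make_fits([s2]), VariancePrior(d0, s0)
            )["s2_post"].iloc[0]
            for d0 in (0.0, 1.0, 4.0, 50.0, math.inf)
        ]
        assert posts[0] == s2 and posts[-1] == s0
        assert all(a > b for a, b in zip(posts, posts[1:]))

    def test_results_invariant_to_gene_and_sample_order(self, planted_pair):
        s1, _, _, _ = planted_pair
        base = ModeratedTTest().fit(s1).results_
        rng = np.random.default_rng(1)
        gperm = rng.permutation(s1.n_genes)
        sperm = rng.permutation(s1.n_samples)
        import replisig.study as st

        shuffled = st.ExpressionStudy(
            s1.expression.iloc[gperm, sperm],
            s1.samples.iloc[sperm],
            "shuffled",
        )
        again = ModeratedTTest().fit(shuffled).results_
        pd.testing.assert_frame_equal(
            base.sort_index(), again.sort_index(), rtol=1e-9, atol=1e-12
        )

    def test_omitting_anxiety_moves_only_anxiety_loaded_genes(self):
        # anxiety is made prevalent in cases so omitting it confounds the
        # group contrast, but only for genes that actually load on anxiety
        rng = np.random.default_rng(8)
        n = 120
        group = np.array(["case"] * 60 + ["control"] * 60)
        anx = (rng.uniform(size=n) < np.where(group == "case", 0.8, 0.2)).astype(int)
        meta = pd.DataFrame(
            {
                "group": group,
                "batch": rng.integers(1, 3, n),
                "sex": rng.choice(["male", "female"], n),
                "age": rng.uniform(20, 65, n),
                "anxiety": anx,
            },
            index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
        )
        loaded = 2.0 * anx + rng.normal(0, 0.3, (40, n))
        unloaded = rng.normal(0, 0.3, (40, n))
        expr = pd.DataFrame(
            np.vstack([loaded, unloaded]),
            index=[f"g{i}" for i in range(80)],
            columns=meta.index,
        )
        import replisig.study as st

        study = st.ExpressionStudy(expr, meta, "anx")
        full = ModeratedTTest().fit(study).results_
        reduced = ModeratedTTest(
            covariates=("group", "batch", "sex", "age")
        ).fit(study).results_
        shift = (full["log2fc"] - reduced["log2fc"]).abs()
        assert shift.iloc[:40].median() > 10 * shift.iloc[40:].median()


class TestPermutationPvalues:
    def test_minimum_attainable_p_is_one_over_b_plus_one(self, toy_study):
        # 10v10 so that 99 random relabelings essentially never reproduce the
        # observed labelling (or its |t|-equivalent complement)
        rng = np.random.default_rng(4)
        y = rng.normal(0, 0.05, (5, 20))
        y[0, :10] += 10.0  # overwhelming case effect
        study = toy_study(y, n_cases=10)
        design = build_design(study.samples, covariates=("group",))
        p = permutation_pvalues(
            study, design, VariancePrior(4.0, 1.0), n_perm=99, seed=0, strata=None
        )
        assert p.iloc[0] == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_independent_oracle(self):
        # 2 cases vs 2 controls, single stratum: all C(4,2)=6 assignments
        import replisig.study as st

        rng = np.random.default_rng(7)
        expr = pd.DataFrame(
            rng.normal(size=(6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=["s1", "s2", "s3", "s4"],
        )
        meta = pd.DataFrame(
            {"group": ["case", "case", "control", "control"]}, index=expr.columns
        )
        study = st.ExpressionStudy(expr, meta, "tiny")
        design = build_design(meta, covariates=("group",))
        prior = VariancePrior(2.0, 1.0)
        p = permutation_pvalues(study, design, prior, strata=None, exact=True)

        # oracle: brute-force OLS + shrinkage over every labelling
        y = expr.to_numpy()

        def tstats(labels):
            X = np.column_stack([np.ones(4), labels])
            xtx_inv = np.linalg.inv(X.T @ X)
            beta = y @ X @ xtx_inv
            resid = y - beta @ X.T
            s2 = (resid**2).sum(axis=1) / 2
            s2_post = (prior.d0 * prior.s0_sq + 2 * s2) / (prior.d0 + 2)
            return beta[:, 1] / np.sqrt(xtx_inv[1, 1] * s2_post)

        obs = np.abs(tstats(np.array([1.0, 1.0, 0.0, 0.0])))
        count = np.zeros(6)
        for pick in itertools.combinations(range(4), 2):
            labels = np.zeros(4)
            labels[list(pick)] = 1.0
            count += np.abs(tstats(labels)) >= obs
        np.testing.assert_allclose(p.to_numpy(), count / 6)

    def test_null_permutation_p_tracks_asymptotic_p(self):
        # under the generator's hierarchical-variance null the moderated t is
        # close to pivotal per gene and the two p-values agree closely
        from replisig import SimConfig, generate_two_studies

        cfg = SimConfig(
            n_genes=800, n_cases=(40, 40), n_controls=(40, 40),
            n_shared_de=0, n_specific_de=(0, 0), rho_target=0.0, seed=6,
        )
        study, _, _ = generate_two_studies(cfg)
        model = ModeratedTTest().fit(study)
        p_perm = permutation_pvalues(
            study, model.design_, model.prior_, n_perm=2000, seed=5
        )
        rms = np.sqrt(np.mean((p_perm.to_numpy() - model.results_["pvalue"]) ** 2))
        assert rms < 0.02

    def test_single_label_stratum_rejected(self, toy_study):
        # batch-1 stratum holds cases only: labels cannot be shuffled in it
        study = toy_study(np.zeros((2, 8)), batch=[1, 1, 2, 2, 2, 2, 2, 2])
        design = build_design(study.samples)
        with pytest.raises(ConfigError):
            permutation_pvalues(study, design, VariancePrior(4, 1), n_perm=10)


class TestModuleEigengene:
    def test_identical_genes_give_standardized_common_profile(self, toy_study):
        rng = np.random.default_rng(2)
        profile = rng.normal(size=8)
        study = toy_study(np.tile(profile, (4, 1)))
        eig, _ = module_eigengene(study, study.gene_ids)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), z, atol=1e-10)

    def test_two_gene_module_matches_hand_eigendecomposition(self, toy_study):
        rng = np.random.default_rng(6)
        y = rng.normal(size=(2, 8))
        study = toy_study(y)
        eig, _ = module_eigengene(study, study.gene_ids)
        z = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, ddof=1, keepdims=True)
        w, v = np.linalg.eigh(np.corrcoef(z))
        lead = v[:, np.argmax(w)]
        scores = lead @ z
        scores /= scores.std(ddof=1)
        if np.dot(scores, z.mean(axis=0)) < 0:
            scores = -scores
        np.testing.assert_allclose(eig.to_numpy(), scores, atol=1e-8)

    def test_detects_planted_group_shift(self):
        import replisig.study as st

        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=(20, 200))
            y[:, :100] += 1.0  # 1-sd shift in cases
            expr = pd.DataFrame(
                y, index=[f"g{i}" for i in range(20)],
                columns=[f"s{j}" for j in range(200)],
            )
            meta = pd.DataFrame(
                {"group": ["case"] * 100 + ["control"] * 100}, index=expr.columns
            )
            study = st.ExpressionStudy(expr, meta, "shift")
            _, pvalue = module_eigengene(study, expr.index)
            hits += pvalue < 0.05
        assert hits >= 95
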