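"""Gibbs sampler validity, heterogeneity partition, folded-normal summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from sexplas.meta import (
    ConvergenceError,
    HeterogeneityStats,
    MetaConfig,
    MetaFit,
    build_M,
    fit_meta,
    fit_moderators,
    folded_mean,
    folded_normal_mean,
    heterogeneity,
    publication_bias,
    typical_sampling_variance,
)

QUICK = MetaConfig(n_iter=1500, burn_in=500, thin=2, n_chains=1, seed=0)


def flat_effects(y, V, sex=None, experiment=None):
    n = len(y)
    return pd.DataFrame(
        {
            "value": y,
            "variance": V,
            "sex": sex if sex is not None else ["F"] * n,
            "species": [f"sp{i}" for i in range(n)],
            "study_id": [f"st{i}" for i in range(n)],
            "experiment_id": experiment if experiment is not None else [f"e{i}" for i in range(n)],
        }
    )


class TestBuildM:
    def test_single_effect(self):
        assert build_M(np.array([0.2]), np.array(["e1"])).tolist() == [[0.2]]

    def test_within_experiment_covariance(self):
        M = build_M(np.array([0.04, 0.09]), np.array(["e1", "e1"]))
        assert M[0, 1] == pytest.approx(0.5 * 0.2 * 0.3)
        assert M[0, 0] == 0.04 and M[1, 1] == 0.09

    def test_across_experiments_zero(self):
        M = build_M(np.array([0.04, 0.09]), np.array(["e1", "e2"]))
        assert M[0, 1] == 0.0

    def test_psd(self, rng):
        V = rng.uniform(0.01, 0.5, 30)
        exps = rng.choice(["a", "b", "c", "d"], 30)
        M = build_M(V, exps)
        assert np.linalg.eigvalsh(M).min() > 0

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            build_M(np.array([0.1, 0.0]), np.array(["e1", "e2"]))


class TestSamplerValidity:
    def test_matches_closed_form_ivw_posterior(self, rng):
        """Fixed-effect special case: flat-prior posterior for the mean is
        N(sum(y/V)/sum(1/V), 1/sum(1/V))."""
        n = 40
        V = rng.uniform(0.02, 0.2, n)
        y = 0.7 + rng.normal(0, np.sqrt(V))
        eff = flat_effects(y, V)
        cfg = MetaConfig(n_iter=4000, burn_in=500, thin=1, n_chains=2, seed=3,
                         components=(), residual="none")
        fit = fit_meta(eff, config=cfg)
        w = 1 / V
        draws = fit.beta_draws("intercept")
        assert draws.mean() == pytest.approx((w * y).sum() / w.sum(), abs=0.01)
        assert draws.std() == pytest.approx(math.sqrt(1 / w.sum()), rel=0.1)

    def test_constant_data_centres_on_common_value(self, rng):
        y = np.full(30, 0.4)
        V = np.full(30, 0.05)
        sex = ["F", "M"] * 15
        eff = flat_effects(y, V, sex=sex)
        cfg = MetaConfig(n_iter=3000, burn_in=500, thin=2, n_chains=1, seed=1,
                         components=(), residual="none")
        fit = fit_meta(eff, config=cfg)
        assert fit.beta_draws("intercept").mean() == pytest.approx(0.4, abs=0.02)
        assert fit.beta_draws("sex_M").mean() == pytest.approx(0.0, abs=0.03)

    def test_sex_relabelling_flips_coefficient(self, rng):
        n = 60
        sex = np.where(np.arange(n) % 2 == 0, "F", "M")
        y = np.where(sex == "M", -0.5, 0.3) + rng.normal(0, 0.1, n)
        V = np.full(n, 0.04)
        eff = flat_effects(y, V, sex=sex)
        swapped = eff.copy()
        swapped["sex"] = np.where(sex == "M", "F", "M")
        cfg = MetaConfig(n_iter=3000, burn_in=500, thin=2, n_chains=1, seed=9,
                         components=(), residual="none")
        b1 = fit_meta(eff, config=cfg).beta_draws("sex_M").mean()
        b2 = fit_meta(swapped, config=cfg).beta_draws("sex_M").mean()
        assert b1 == pytest.approx(-b2, abs=0.03)
        assert b1 < 0 < b2

    def test_determinism_same_seed(self, hedges_effects):
        cfg = MetaConfig(n_iter=400, burn_in=100, thin=2, n_chains=2, seed=5,
                         force=True)
        f1 = fit_meta(hedges_effects, config=cfg)
        f2 = fit_meta(hedges_effects, config=cfg)
        assert np.array_equal(f1.beta, f2.beta)
        for k in f1.sigma2:
            assert np.array_equal(f1.sigma2[k], f2.sigma2[k])

    def test_rhat_gate_raises_then_force_overrides(self, hedges_effects):
        cfg = MetaConfig(n_iter=60, burn_in=10, thin=1, n_chains=3, seed=2)
        with pytest.raises(ConvergenceError, match="R-hat"):
            fit_meta(hedges_effects, config=cfg)
        import dataclasses

        fit = fit_meta(hedges_effects, config=dataclasses.replace(cfg, force=True))
        assert fit.beta.shape[0] == 3

    def test_singular_design_rejected(self):
        eff = flat_effects(np.ones(10), np.full(10, 0.1), sex=["F"] * 10)
        eff["egger_se"] = 1.0  # duplicates the intercept
        with pytest.raises(ValueError):
            fit_meta(eff, config=QUICK, continuous=("egger_se",))

    def test_recovers_sex_deviation_from_synthetic_truth(self, hedges_effects,
                                                         small_synth):
        from sexplas.phylo import grafen_correlation

        A = grafen_correlation(
            small_synth.newick, sorted(hedges_effects["species"].unique())
        ).to_dataframe()
        cfg = MetaConfig(n_iter=2500, burn_in=800, thin=2, n_chains=1, seed=7)
        fit = fit_meta(hedges_effects, A_phylo=A, config=cfg)
        draws = fit.beta_draws("sex_M")
        lo, hi = np.quantile(draws, [0.025, 0.975])
        truth = small_synth.truth["config"].sex_delta
        assert lo - 0.3 < truth < hi + 0.3


class TestFoldedNormal:
    def test_standard_normal_closed_form(self):
        assert folded_normal_mean(0.0, 1.0) == pytest.approx(
            math.sqrt(2 / math.pi), abs=1e-12
        )

    def test_large_mean_limit(self):
        assert folded_normal_mean(50.0, 1.0) == pytest.approx(50.0, abs=1e-9)
        assert folded_normal_mean(-50.0, 1.0) == pytest.approx(50.0, abs=1e-9)

    def test_monte_carlo_agreement(self, rng):
        mc = np.abs(rng.normal(1.0, 1.0, 2_000_000)).mean()
        assert folded_normal_mean(1.0, 1.0) == pytest.approx(mc, abs=2e-3)

    def test_posterior_folded_summary_exceeds_directional(self, hedges_effects):
        cfg = MetaConfig(n_iter=1500, burn_in=500, thin=2, n_chains=1, seed=4)
        fit = fit_meta(hedges_effects, config=cfg)
        folded = folded_mean(fit, "F")
        assert folded["mean"] >= abs(fit.beta_draws("intercept").mean()) - 1e-9
        assert folded["ci_2.5"] <= folded["mean"] <= folded["ci_97.5"]

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            folded_normal_mean(1.0, 0.0)


class TestHeterogeneity:
    def test_typical_sampling_variance_equal_weights(self):
        # equal V: formula reduces to V itself
        V = np.full(10, 0.3)
        assert typical_sampling_variance(V) == pytest.approx(0.3)

    def test_partition_sums_to_total(self, hedges_effects):
        cfg = MetaConfig(n_iter=1200, burn_in=400, thin=2, n_chains=1, seed=6)
        fit = fit_meta(hedges_effects, config=cfg)
        het = heterogeneity(fit)
        assert sum(het.i2.values()) == pytest.approx(het.i2_total, abs=1e-9)
        assert 0 <= het.i2_total <= 100
        assert 0 <= het.r2_marginal <= het.r2_conditional <= 1

    def test_equal_components_partition(self):
        """Components (1,1,1,1) with residual 0 and typical variance 1:
        each I2 = 20%, total 80%."""
        ones = np.ones((1, 50))
        fit = MetaFit(
            beta=np.zeros((1, 50, 2)),
            beta_names=["intercept", "sex_M"],
            sigma2={k: ones.copy() for k in
                    ("species", "phylogeny", "study", "experiment")},
            sigma2_resid={"F": ones * 1e-12, "M": ones * 1e-12},
            X=np.column_stack([np.ones(4), [0, 1, 0, 1]]),
            y=np.zeros(4),
            V=np.full(4, 1.0),
            sex=np.array([0, 1, 0, 1]),
            config=MetaConfig(),
        )
        het = heterogeneity(fit)
        for k in ("species", "phylogeny", "study", "experiment"):
            assert het.i2[k] == pytest.approx(20.0, abs=1e-6)
        assert het.i2_total == pytest.approx(80.0, abs=1e-6)

    def test_no_heterogeneity_means_zero_i2(self):
        z = np.full((1, 50), 1e-14)
        fit = MetaFit(
            beta=np.zeros((1, 50, 1)), beta_names=["intercept"],
            sigma2={k: z.copy() for k in
                    ("species", "phylogeny", "study", "experiment")},
            sigma2_resid={"F": z.copy(), "M": z.copy()},
            X=np.ones((4, 1)), y=np.zeros(4), V=np.full(4, 1.0),
            sex=np.array([0, 1, 0, 1]), config=MetaConfig(),
        )
        assert heterogeneity(fit).i2_total == pytest.approx(0.0, abs=1e-9)


class TestModeratorsAndBias:
    def test_constant_moderator_reduces_to_base_model(self, hedges_effects):
        eff = hedges_effects.copy()
        eff["treatment_type"] = "acclimation"
        cfg = MetaConfig(n_iter=800, burn_in=200, thin=2, n_chains=1, seed=8)
        fit = fit_moderators(eff, "treatment_type", config=cfg)
        assert fit.beta_names == ["intercept", "sex_M"]

    def test_interaction_recovers_opposite_sign_subgroup(self, rng):
        """Mirrors a subgroup (acute treatments) whose true effect has the
        opposite sign: the interaction model recovers both cell means."""
        n_exp = 60
        rows = []
        for i in range(n_exp):
            kind = "acute" if i % 2 else "acclimation"
            mu = -0.8 if kind == "acute" else 0.8
            for sex in ("F", "M"):
                V = float(rng.uniform(0.02, 0.06))
                rows.append({
                    "value": mu + rng.normal(0, math.sqrt(V + 0.02)),
                    "variance": V, "sex": sex,
                    "species": f"sp{i % 10}", "study_id": f"st{i}",
                    "experiment_id": f"e{i}", "treatment": kind,
                })
        eff = pd.DataFrame(rows)
        cfg = MetaConfig(n_iter=2000, burn_in=600, thin=2, n_chains=1, seed=10)
        fit = fit_moderators(eff, "treatment", config=cfg)
        inter = fit.beta_draws("intercept").mean()  # acclimation females
        shift = fit.beta_draws("treatment_acute").mean()
        assert inter == pytest.approx(0.8, abs=0.15)
        assert inter + shift == pytest.approx(-0.8, abs=0.15)

    def test_unbiased_funnel_has_null_egger_slope(self, rng):
        n = 120
        V = rng.uniform(0.01, 0.3, n)
        y = 0.5 + rng.normal(0, np.sqrt(V + 0.05))
        eff = flat_effects(y, V, sex=["F", "M"] * (n // 2))
        cfg = MetaConfig(n_iter=2000, burn_in=600, thin=2, n_chains=1, seed=11,
                         components=())
        fit = publication_bias(eff, config=cfg)
        lo, hi = np.quantile(fit.beta_draws("egger_se"), [0.025, 0.975])
        assert lo < 0 < hi

    def test_censored_funnel_yields_positive_slope(self, rng):
        from sexplas.synth import censor_effects

        n = 300
        V = rng.uniform(0.01, 0.4, n)
        y = 0.3 + rng.normal(0, np.sqrt(V + 0.02))
        eff = flat_effects(y, V, sex=["F", "M"] * (n // 2))
        censored = censor_effects(eff, threshold=1.5, prob=1.0, seed=1)
        assert len(censored) < n
        cfg = MetaConfig(n_iter=2000, burn_in=600, thin=2, n_chains=1, seed=12,
                         components=())
        fit = publication_bias(censored, config=cfg)
        lo, _ = np.quantile(fit.beta_draws("egger_se"), [0.025, 0.975])
        assert lo > 0

    def test_zero_variance_se_column_rejected(self):
        eff = flat_effects(np.ones(10), np.full(10, 0.1))
        with pytest.raises(ValueError, match="zero variance"):
            publication_bias(eff, config=QUICK)
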