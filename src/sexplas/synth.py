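"""Synthetic meta-analytic datasets with known truth.

Generates group-summary tables in the exact schema the pipeline consumes
(one row per study x experiment x treatment level x sex, with sample
mean, SD and n), together with a random Yule phylogeny over the species
and a truth record of every latent quantity, so that each downstream
stage — effect-size computation, the Grafen matrix, the multilevel model
— can be tested for recovery without any external data.

Generative model (mirroring the fitted meta-regression's hierarchy):

    d_true(exp, sex) = mu_class + delta_sex * [male]
                       + u_species + u_phylo + u_study + u_experiment
                       + e_resid(sex)

with u_phylo ~ N(0, sigma2_phylo * A_grafen) on the simulated tree and
the other components i.i.d.  Group means are back-constructed so the
minuend group's population mean exceeds the subtrahend's by
d_true * sigma_pop; reported means and SDs are then *sampled* statistics
(mean ~ N(mu, sigma^2/n), SD^2 ~ sigma^2 chi2_{n-1}/(n-1)), so computed
Hedges' d scatters around d_true with exactly the sampling variance the
meta-analysis assumes.

Defaults emulate the cold-resistance regime of sex-specific thermal
plasticity: a large female response (mean d = 1.76), a male deficit
(delta = -0.82), and heterogeneity dominated by the residual.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
from dendropy.simulate import treesim
import numpy as np
import pandas as pd

from .effects import COLD_MINUEND_CLASSES
from .phylo import grafen_correlation

__all__ = ["SynthConfig", "SynthResult", "generate", "censor_effects"]


@dataclass(frozen=True)
class SynthConfig:
    """Fully specified generative model for one trait class."""

    n_species: int = 30
    studies_per_species: int = 1
    experiments_per_study: int = 3
    levels_per_experiment: int = 2  # 2-4
    trait_class: str = "cold_resistance"
    mean_d: float = 1.76  # female fixed-effect mean
    sex_delta: float = -0.82  # male deviation
    sigma2_species: float = 0.05
    sigma2_phylo: float = 0.05
    sigma2_study: float = 0.10
    sigma2_experiment: float = 0.10
    sigma2_resid_f: float = 0.20
    sigma2_resid_m: float = 0.20
    n_low: int = 5
    n_high: int = 50
    baseline_mean: float = 100.0
    cv: float = 0.15
    temperatures: tuple[float, ...] = (18.0, 22.0, 25.0, 28.0)
    warm_cv_inflation: float = 1.0  # >1 gives lnCVR_treatment structure

    def __post_init__(self) -> None:
        if self.levels_per_experiment < 2 or self.levels_per_experiment > 4:
            raise ValueError("levels_per_experiment must be in 2..4")
        if self.levels_per_experiment > len(self.temperatures):
            raise ValueError("not enough temperatures for the requested levels")
        for name in (
            "sigma2_species", "sigma2_phylo", "sigma2_study",
            "sigma2_experiment", "sigma2_resid_f", "sigma2_resid_m",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1 <= self.n_low <= self.n_high):
            raise ValueError("need 1 <= n_low <= n_high")


@dataclass
class SynthResult:
    data: pd.DataFrame
    newick: str
    truth: dict = field(repr=False)


def _yule_tree(n_species: int, seed: int) -> tuple[str, list[str]]:
    names = [f"Synthspecies_{i:03d}" for i in range(1, n_species + 1)]
    if n_species == 1:
        return f"({names[0]});", names
    taxa = dendropy.TaxonNamespace(names)
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    return tree.as_string(schema="newick").strip(), names


def generate(config: SynthConfig, seed: int = 0) -> SynthResult:
    """Simulate a group-summary dataset, its phylogeny and the truth record.

    Deterministic for a given (config, seed).
    """
    rng = np.random.default_rng(seed)
    newick, species = _yule_tree(config.n_species, seed)
    A = grafen_correlation(newick, species).matrix

    u_species = rng.normal(0.0, np.sqrt(config.sigma2_species), config.n_species)
    if config.sigma2_phylo > 0 and config.n_species > 1:
        L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
        u_phylo = np.sqrt(config.sigma2_phylo) * (L @ rng.standard_normal(len(A)))
    else:
        u_phylo = np.zeros(config.n_species)

    cold_first = config.trait_class in COLD_MINUEND_CLASSES
    sigma_pop = config.cv * config.baseline_mean
    rows: list[dict] = []
    truth_effects: list[dict] = []
    u_study_rec: dict[str, float] = {}
    u_exp_rec: dict[str, float] = {}

    for i_sp, sp in enumerate(species):
        for i_st in range(config.studies_per_species):
            study_id = f"{sp}_study{i_st + 1}"
            u_study = rng.normal(0.0, np.sqrt(config.sigma2_study))
            u_study_rec[study_id] = u_study
            for i_ex in range(config.experiments_per_study):
                exp_id = f"exp{i_ex + 1}"
                u_exp = rng.normal(0.0, np.sqrt(config.sigma2_experiment))
                u_exp_rec[f"{study_id}//{exp_id}"] = u_exp
                temps = sorted(
                    rng.choice(
                        config.temperatures,
                        size=config.levels_per_experiment,
                        replace=False,
                    )
                )
                t_span = temps[-1] - temps[0]
                base = config.mean_d + u_species[i_sp] + u_phylo[i_sp] + u_study + u_exp
                for sex, resid_var, delta in (
                    ("F", config.sigma2_resid_f, 0.0),
                    ("M", config.sigma2_resid_m, config.sex_delta),
                ):
                    # per-(experiment, sex) realised d across the full span;
                    # with 2 levels this is exactly the per-contrast residual
                    d_true = base + delta + rng.normal(0.0, np.sqrt(resid_var))
                    # population means along the temperature gradient: the
                    # minuend end of the span sits d_true*sigma above the other
                    for j, temp in enumerate(temps):
                        frac = (temp - temps[0]) / t_span
                        shift = (1.0 - frac) if cold_first else frac
                        mu = config.baseline_mean + d_true * sigma_pop * shift
                        sigma = sigma_pop * (
                            config.warm_cv_inflation if j == len(temps) - 1 else 1.0
                        )
                        n = int(rng.integers(config.n_low, config.n_high + 1))
                        m_hat = rng.normal(mu, sigma / np.sqrt(n))
                        s_hat = sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1))
                        rows.append(
                            {
                                "study_id": study_id,
                                "experiment_id": exp_id,
                                "species": sp,
                                "trait_class": config.trait_class,
                                "trait_name": f"{config.trait_class}_trait",
                                "treatment_type": "acclimation",
                                "treatment_level_id": f"L{j + 1}",
                                "temperature": float(temp),
                                "sex": sex,
                                "mean": float(m_hat),
                                "sd": float(s_hat),
                                "n": n,
                            }
                        )
                    truth_effects.append(
                        {
                            "study_id": study_id,
                            "experiment_id": exp_id,
                            "species": sp,
                            "sex": sex,
                            "d_true": float(d_true),
                        }
                    )

    truth = {
        "config": config,
        "seed": seed,
        "u_species": dict(zip(species, u_species.tolist())),
        "u_phylo": dict(zip(species, u_phylo.tolist())),
        "u_study": u_study_rec,
        "u_experiment": u_exp_rec,
        "effects": pd.DataFrame(truth_effects),
    }
    return SynthResult(data=pd.DataFrame(rows), newick=newick, truth=truth)


def censor_effects(
    effects: pd.DataFrame,
    threshold: float = 1.5,
    prob: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Funnel-censoring rule for publication-bias simulations.

    Drops each effect whose |value|/SE falls below ``threshold`` with
    probability ``prob`` — small, noisy effects vanish from the record,
    producing the asymmetric funnel an Egger-style regression detects.
    """
    rng = np.random.default_rng(seed)
    z = effects["value"].abs() / np.sqrt(effects["variance"])
    drop = (z < threshold) & (rng.random(len(effects)) < prob)
    return effects.loc[~drop.to_numpy()].reset_index(drop=True)
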