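"""Bayesian phylogenetic multilevel meta-regression with known sampling error.

The model for a vector of effect sizes y (one row per contrast x sex):

    y = X beta + Z_sp u_sp + Z_ph u_ph + Z_st u_st + Z_ex u_ex + s + e

* ``X`` holds an intercept (female mean) and a sex(male) deviation, plus
  optional moderators crossed with sex;
* ``u_sp`` (species), ``u_st`` (study) and ``u_ex`` (experiment within
  study) are i.i.d. normal random effects; ``u_ph`` is a second
  species-indexed effect with covariance sigma2_ph * A, A the Grafen
  phylogenetic correlation matrix;
* ``s ~ N(0, M)`` is the known sampling error: M carries each effect's
  sampling variance on the diagonal and a within-experiment correlation
  of r = 0.5 off the diagonal;
* ``e`` is a heteroscedastic residual with a separate variance per sex.

Everything is conjugate, so the posterior is sampled by a blocked Gibbs
sampler with scaled inverse-gamma priors (shape 0.001, scale 0.001) on
all variance components and a flat prior on beta.  With
``residual="none"`` the residual e is dropped and M becomes the full
error covariance — the classical fixed/random-effects meta-analysis
special cases, where the latent-s scheme would mix poorly.

Post-fit summaries: folded-normal |d| ("analyse-then-transform"), the
I^2 heterogeneity partition (component I^2 sum to total by
construction), marginal/conditional R^2, moderator refits, and an
Egger-style publication-bias refit using the sampling standard error as
a covariate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "MetaConfig",
    "MetaFit",
    "ConvergenceError",
    "build_M",
    "fit_meta",
    "fit_moderators",
    "publication_bias",
    "folded_normal_mean",
    "folded_mean",
    "heterogeneity",
    "HeterogeneityStats",
]

DEFAULT_COMPONENTS = ("species", "phylogeny", "study", "experiment")


class ConvergenceError(RuntimeError):
    """Raised when chains fail the split R-hat gate."""


@dataclass(frozen=True)
class MetaConfig:
    """Sampler settings. Defaults are long chains suitable for production
    fits; tests and simulations pass reduced settings explicitly."""

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    components: tuple[str, ...] = DEFAULT_COMPONENTS
    residual: str = "by_sex"  # "by_sex" | "none"
    rhat_max: float = 1.1
    force: bool = False
    folded_sigma: str = "total"  # "total" | "residual_only"

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.residual not in ("by_sex", "none"):
            raise ValueError("residual must be 'by_sex' or 'none'")
        unknown = set(self.components) - set(DEFAULT_COMPONENTS)
        if unknown:
            raise ValueError(f"unknown random components: {sorted(unknown)}")


def build_M(
    variances: np.ndarray | pd.Series,
    experiment_ids: np.ndarray | pd.Series,
    r: float = 0.5,
) -> np.ndarray:
    """Block-diagonal sampling (co)variance matrix.

    Diagonal: per-effect sampling variances V.  Within an experiment,
    cov_ij = r * sqrt(V_i V_j); zero across experiments.
    """
    V = np.asarray(variances, dtype=float)
    if np.any(V <= 0) or not np.all(np.isfinite(V)):
        raise ValueError("sampling variances must be positive and finite")
    exp_ids = np.asarray(experiment_ids)
    sd = np.sqrt(V)
    same_exp = exp_ids[:, None] == exp_ids[None, :]
    M = np.where(same_exp, r * np.outer(sd, sd), 0.0)
    np.fill_diagonal(M, V)
    return M


def _index(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    cats = pd.Categorical(labels.astype(str))
    return cats.codes.astype(np.intp), list(cats.categories)


def _design(
    effects: pd.DataFrame,
    moderator: str | None,
    continuous: tuple[str, ...] = (),
) -> tuple[np.ndarray, list[str]]:
    n = len(effects)
    sex_male = (effects["sex"].astype(str).str.upper() == "M").to_numpy(float)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n), "sex_M": sex_male}
    for name in continuous:
        cols[name] = effects[name].to_numpy(float)
    if moderator is not None:
        levels = pd.get_dummies(effects[moderator].astype(str), prefix=moderator)
        base = sorted(levels.columns)[0]  # reference level absorbed by intercept
        for name in levels.columns:
            if name == base:
                continue
            v = levels[name].to_numpy(float)
            cols[name] = v
            cols[f"{name}:sex_M"] = v * sex_male
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    # drop unestimable columns (single-sex data, empty or duplicated
    # moderator dummies); explicit continuous covariates are never dropped
    # so a genuinely singular design is reported, not silently repaired
    protected = {"intercept", *continuous}
    keep = []
    seen: list[np.ndarray] = []
    for j in range(X.shape[1]):
        c = X[:, j]
        if names[j] not in protected:
            if not np.any(c) or any(np.array_equal(c, s) for s in seen):
                continue
        keep.append(j)
        seen.append(c)
    return X[:, keep], [names[j] for j in keep]


@dataclass
class MetaFit:
    """Posterior draws and model bookkeeping for one meta-regression.

    Draw arrays have shape (chains, draws) or (chains, draws, dim).
    """

    beta: np.ndarray
    beta_names: list[str]
    sigma2: dict[str, np.ndarray]  # component -> (chains, draws)
    sigma2_resid: dict[str, np.ndarray]  # "F"/"M" -> (chains, draws)
    X: np.ndarray
    y: np.ndarray
    V: np.ndarray
    sex: np.ndarray  # 0 = F, 1 = M
    config: MetaConfig
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def beta_draws(self, name: str) -> np.ndarray:
        j = self.beta_names.index(name)
        return self.beta[:, :, j].reshape(-1)

    def summary(self) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.beta_names):
            d = self.beta[:, :, j].reshape(-1)
            rows.append(
                {
                    "parameter": name,
                    "mean": d.mean(),
                    "ci_2.5": np.quantile(d, 0.025),
                    "ci_97.5": np.quantile(d, 0.975),
                    "rhat": self.rhat.get(name, math.nan),
                    "ess": self.ess.get(name, math.nan),
                }
            )
        for name, d in {**self.sigma2,
                        **{f"resid_{k}": v for k, v in self.sigma2_resid.items()}}.items():
            flat = d.reshape(-1)
            rows.append(
                {
                    "parameter": f"sigma2_{name}",
                    "mean": flat.mean(),
                    "ci_2.5": np.quantile(flat, 0.025),
                    "ci_97.5": np.quantile(flat, 0.975),
                    "rhat": self.rhat.get(f"sigma2_{name}", math.nan),
                    "ess": self.ess.get(f"sigma2_{name}", math.nan),
                }
            )
        return pd.DataFrame(rows)


def _chol_draw(prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(prec^-1 lin, prec^-1) via a Cholesky factor of prec."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin)
    z = rng.standard_normal(len(lin))
    return mean + np.linalg.solve(L.T, z)


def _run_chain(
    y: np.ndarray,
    X: np.ndarray,
    V: np.ndarray,
    sex: np.ndarray,
    idx: dict[str, np.ndarray],
    sizes: dict[str, int],
    A_inv: np.ndarray | None,
    M: np.ndarray,
    cfg: MetaConfig,
    seed: np.random.SeedSequence,
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    n, p = X.shape
    comps = cfg.components
    a0, b0 = cfg.prior_shape, cfg.prior_scale
    by_sex = cfg.residual == "by_sex"

    M_inv = np.linalg.inv(M)
    # weighted-least-squares start, zero random effects
    w = 1.0 / V
    XtW = X.T * w
    beta = np.linalg.solve(XtW @ X + 1e-10 * np.eye(p), XtW @ y)
    u = {k: np.zeros(sizes[k]) for k in comps}
    sigma2 = {k: 0.1 for k in comps}
    s = np.zeros(n)
    resid0 = y - X @ beta
    if by_sex:
        sig_res = {0: max(resid0.var() / 2, 1e-4), 1: max(resid0.var() / 2, 1e-4)}
    else:
        sig_res = {0: 0.0, 1: 0.0}

    n_keep = (cfg.n_iter - cfg.burn_in) // cfg.thin
    out_beta = np.empty((n_keep, p))
    out_sigma2 = {k: np.empty(n_keep) for k in comps}
    out_resid = {"F": np.empty(n_keep), "M": np.empty(n_keep)}
    sex_mask = {0: sex == 0, 1: sex == 1}
    n_sex = {g: int(sex_mask[g].sum()) for g in (0, 1)}

    kept = 0
    for it in range(cfg.n_iter):
        u_sum = np.zeros(n)
        for k in comps:
            u_sum += u[k][idx[k]]

        if by_sex:
            P = np.where(sex == 1, 1.0 / sig_res[1], 1.0 / sig_res[0])
            # beta
            target = y - u_sum - s
            XtP = X.T * P
            beta = _chol_draw(XtP @ X + 1e-10 * np.eye(p), XtP @ target, rng)
            fixed = X @ beta
            # random components
            for k in comps:
                others = u_sum - u[k][idx[k]]
                target = y - fixed - others - s
                wsum = np.bincount(idx[k], weights=P, minlength=sizes[k])
                lin = np.bincount(idx[k], weights=P * target, minlength=sizes[k])
                if k == "phylogeny":
                    prec = np.diag(wsum) + A_inv / sigma2[k]
                    u[k] = _chol_draw(prec, lin, rng)
                else:
                    prec = wsum + 1.0 / sigma2[k]
                    u[k] = lin / prec + rng.standard_normal(sizes[k]) / np.sqrt(prec)
                u_sum = others + u[k][idx[k]]
            # latent sampling error
            target = y - fixed - u_sum
            prec_s = M_inv + np.diag(P)
            s = _chol_draw(prec_s, P * target, rng)
            # residual variances per sex
            e = y - fixed - u_sum - s
            for g in (0, 1):
                if n_sex[g] == 0:  # sex absent: variance drops out of the model
                    continue
                ss = float(e[sex_mask[g]] @ e[sex_mask[g]])
                sig_res[g] = 1.0 / rng.gamma(a0 + 0.5 * n_sex[g], 1.0 / (b0 + 0.5 * ss))
        else:
            # M is the full error covariance; no latent s, no residual update
            target = y - u_sum
            XtMi = X.T @ M_inv
            beta = _chol_draw(XtMi @ X + 1e-10 * np.eye(p), XtMi @ target, rng)
            fixed = X @ beta
            for k in comps:
                others = u_sum - u[k][idx[k]]
                target = y - fixed - others
                Mi_t = M_inv @ target
                lin = np.bincount(idx[k], weights=Mi_t, minlength=sizes[k])
                # Z'M^-1Z is diagonal: blocks of M never span two levels of
                # any grouping factor (an experiment sits inside one species,
                # study and experiment)
                wsum = np.bincount(idx[k], weights=np.sum(M_inv, axis=1), minlength=sizes[k])
                if k == "phylogeny":
                    prec = np.diag(wsum) + A_inv / sigma2[k]
                    u[k] = _chol_draw(prec, lin, rng)
                else:
                    prec = wsum + 1.0 / sigma2[k]
                    u[k] = lin / prec + rng.standard_normal(sizes[k]) / np.sqrt(prec)
                u_sum = others + u[k][idx[k]]

        # component variances
        for k in comps:
            if k == "phylogeny":
                ss = float(u[k] @ A_inv @ u[k])
            else:
                ss = float(u[k] @ u[k])
            sigma2[k] = 1.0 / rng.gamma(a0 + 0.5 * sizes[k], 1.0 / (b0 + 0.5 * ss))

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out_beta[kept] = beta
            for k in comps:
                out_sigma2[k][kept] = sigma2[k]
            out_resid["F"][kept] = sig_res[0]
            out_resid["M"][kept] = sig_res[1]
            kept += 1

    return {"beta": out_beta[:kept], "sigma2": {k: v[:kept] for k, v in out_sigma2.items()},
            "resid": {k: v[:kept] for k, v in out_resid.items()}}


def fit_meta(
    effects: pd.DataFrame,
    M: np.ndarray | None = None,
    A_phylo: pd.DataFrame | np.ndarray | None = None,
    config: MetaConfig | None = None,
    moderator: str | None = None,
    continuous: tuple[str, ...] = (),
) -> MetaFit:
    """Fit the multilevel meta-regression by blocked Gibbs sampling.

    ``effects`` needs columns value, variance, sex, species, study_id,
    experiment_id (the output of :func:`sexplas.effects.compute_effects`,
    filtered to one effect kind).  ``M`` defaults to
    ``build_M(effects.variance, effects.experiment_id)``.  ``A_phylo``
    is the Grafen correlation (DataFrame indexed by species, or an array
    in species-category order); identity if omitted.

    Refuses to return when any monitored split R-hat exceeds
    ``config.rhat_max`` (two or more chains), unless ``config.force``.
    """
    config = config or MetaConfig()
    effects = effects.reset_index(drop=True)
    y = effects["value"].to_numpy(float)
    V = effects["variance"].to_numpy(float)
    if np.any(V <= 0):
        raise ValueError("sampling variances must be positive")
    X, names = _design(effects, moderator, continuous)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    sex = (effects["sex"].astype(str).str.upper() == "M").to_numpy(int)

    sp_idx, sp_levels = _index(effects["species"])
    st_idx, st_levels = _index(effects["study_id"])
    ex_idx, ex_levels = _index(
        effects["study_id"].astype(str) + "//" + effects["experiment_id"].astype(str)
    )
    idx = {"species": sp_idx, "phylogeny": sp_idx, "study": st_idx, "experiment": ex_idx}
    sizes = {
        "species": len(sp_levels),
        "phylogeny": len(sp_levels),
        "study": len(st_levels),
        "experiment": len(ex_levels),
    }

    A_inv = None
    if "phylogeny" in config.components:
        if A_phylo is None:
            A = np.eye(len(sp_levels))
        elif isinstance(A_phylo, pd.DataFrame):
            missing = [s for s in sp_levels if s not in A_phylo.index]
            if missing:
                raise ValueError(f"species missing from phylogenetic matrix: {missing}")
            A = A_phylo.loc[sp_levels, sp_levels].to_numpy(float)
        else:
            A = np.asarray(A_phylo, dtype=float)
            if A.shape != (len(sp_levels), len(sp_levels)):
                raise ValueError("A_phylo has the wrong shape")
        eigmin = float(np.linalg.eigvalsh(A)[0])
        if eigmin < -1e-8:
            raise ValueError("phylogenetic matrix is not positive semi-definite")
        if eigmin < 1e-10:  # ridge for exactly singular trees
            A = A + 1e-8 * np.eye(len(A))
        A_inv = np.linalg.inv(A)

    if M is None:
        M = build_M(V, effects["experiment_id"].to_numpy())
    M = np.asarray(M, dtype=float)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(y, X, V, sex, idx, sizes, A_inv, M, config, sd) for sd in seeds
    ]
    beta = np.stack([c["beta"] for c in chains])
    sigma2 = {
        k: np.stack([c["sigma2"][k] for c in chains]) for k in config.components
    }
    resid = {g: np.stack([c["resid"][g] for c in chains]) for g in ("F", "M")}

    fit = MetaFit(
        beta=beta,
        beta_names=names,
        sigma2=sigma2,
        sigma2_resid=resid,
        X=X,
        y=y,
        V=V,
        sex=sex,
        config=config,
    )
    _diagnose(fit)
    if config.n_chains >= 2 and not config.force:
        bad = {k: v for k, v in fit.rhat.items() if np.isfinite(v) and v > config.rhat_max}
        if bad:
            raise ConvergenceError(
                f"split R-hat above {config.rhat_max}: {bad}; rerun with longer "
                "chains or force=True"
            )
    return fit


def _diagnose(fit: MetaFit) -> None:
    import arviz as az

    data = {name: fit.beta[:, :, j] for j, name in enumerate(fit.beta_names)}
    for k, v in fit.sigma2.items():
        data[f"sigma2_{k}"] = v
    if fit.config.residual == "by_sex":
        for g, v in fit.sigma2_resid.items():
            data[f"sigma2_resid_{g}"] = v
    ds = az.convert_to_dataset(data)
    if fit.beta.shape[0] >= 2:
        rhat = az.rhat(ds)
        fit.rhat = {k: float(rhat[k].values) for k in data}
    ess = az.ess(ds)
    fit.ess = {k: float(ess[k].values) for k in data}


# ---------------------------------------------------------------- summaries


def folded_normal_mean(mu: np.ndarray | float, sigma: np.ndarray | float) -> np.ndarray | float:
    """E|X| for X ~ Normal(mu, sigma^2).

    E|X| = sigma sqrt(2/pi) exp(-mu^2 / 2 sigma^2) + mu (1 - 2 Phi(-mu/sigma)).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    val = sigma * math.sqrt(2.0 / math.pi) * np.exp(-(mu**2) / (2 * sigma**2)) + mu * (
        1.0 - 2.0 * ndtr(-mu / sigma)
    )
    return val if val.ndim else float(val)


def folded_mean(fit: MetaFit, sex: str = "F") -> dict[str, float]:
    """Posterior mean and 95% CrI of |d| for one sex (analyse-then-transform).

    Per posterior draw, mu is the sex-specific fixed-effect mean and
    sigma^2 the summed heterogeneity variances: all random components
    plus that sex's residual (``config.folded_sigma == "total"``) or the
    residual alone (``"residual_only"``).
    """
    mu = fit.beta_draws("intercept").copy()
    if sex.upper() == "M":
        if "sex_M" in fit.beta_names:
            mu += fit.beta_draws("sex_M")
    sig2 = np.zeros_like(mu)
    if fit.config.folded_sigma == "total":
        for v in fit.sigma2.values():
            sig2 += v.reshape(-1)
    if fit.config.residual == "by_sex":
        sig2 += fit.sigma2_resid[sex.upper()].reshape(-1)
    if np.any(sig2 <= 0):
        raise ValueError("non-positive heterogeneity variance draw")
    draws = folded_normal_mean(mu, np.sqrt(sig2))
    return {
        "mean": float(np.mean(draws)),
        "ci_2.5": float(np.quantile(draws, 0.025)),
        "ci_97.5": float(np.quantile(draws, 0.975)),
    }


def typical_sampling_variance(V: np.ndarray) -> float:
    """Higgins-style 'typical' within-effect sampling variance.

    sigma2_m = sum(w) (k - 1) / (sum(w)^2 - sum(w^2)), w = 1/V.
    """
    w = 1.0 / np.asarray(V, dtype=float)
    k = len(w)
    return float(w.sum() * (k - 1) / (w.sum() ** 2 - (w**2).sum()))


@dataclass(frozen=True)
class HeterogeneityStats:
    """Posterior-mean I^2 partition (percent) and R^2 summaries."""

    i2: dict[str, float]
    i2_total: float
    r2_marginal: float
    r2_conditional: float


def heterogeneity(fit: MetaFit) -> HeterogeneityStats:
    """I^2 partition and marginal/conditional R^2 for a fitted model.

    I^2_k = sigma2_k / (sum_j sigma2_j + sigma2_resid + sigma2_typical),
    evaluated per draw and averaged; components therefore sum to
    I^2_total exactly.  The residual variance is the sample-size-weighted
    mean of the per-sex residual variances.  R^2 uses the fixed-predictor
    variance var(X beta) over the observed design; conditional counts the
    non-residual components as explained.
    """
    s2_typ = typical_sampling_variance(fit.V)
    comps = {k: v.reshape(-1) for k, v in fit.sigma2.items()}
    n_f = int((fit.sex == 0).sum())
    n_m = int((fit.sex == 1).sum())
    if fit.config.residual == "by_sex":
        resid = (
            n_f * fit.sigma2_resid["F"].reshape(-1)
            + n_m * fit.sigma2_resid["M"].reshape(-1)
        ) / max(n_f + n_m, 1)
    else:
        resid = np.zeros(fit.n_draws)
    total_het = sum(comps.values()) + resid
    denom = total_het + s2_typ
    i2 = {k: float(np.mean(v / denom)) * 100.0 for k, v in comps.items()}
    i2["residual"] = float(np.mean(resid / denom)) * 100.0
    i2_total = float(np.mean(total_het / denom)) * 100.0

    nb = fit.beta.shape[-1]
    bmat = fit.beta.reshape(-1, nb)
    fixed_var = np.var(bmat @ fit.X.T, axis=1)
    rand = sum(comps.values())
    r2_denom = fixed_var + total_het + s2_typ
    r2_marg = float(np.mean(fixed_var / r2_denom))
    r2_cond = float(np.mean((fixed_var + rand) / r2_denom))
    return HeterogeneityStats(
        i2=i2, i2_total=i2_total, r2_marginal=r2_marg, r2_conditional=r2_cond
    )


def fit_moderators(
    effects: pd.DataFrame,
    moderator: str,
    M: np.ndarray | None = None,
    A_phylo: pd.DataFrame | np.ndarray | None = None,
    config: MetaConfig | None = None,
) -> MetaFit:
    """Meta-regression with a categorical moderator crossed with sex."""
    if effects[moderator].astype(str).nunique() < 2:
        # constant moderator: reduces to the base model
        return fit_meta(effects, M=M, A_phylo=A_phylo, config=config)
    return fit_meta(effects, M=M, A_phylo=A_phylo, config=config, moderator=moderator)


def publication_bias(
    effects: pd.DataFrame,
    M: np.ndarray | None = None,
    A_phylo: pd.DataFrame | np.ndarray | None = None,
    config: MetaConfig | None = None,
) -> MetaFit:
    """Egger-style refit: sampling standard error as a fixed covariate.

    A slope ('egger_se') whose credible interval excludes zero flags
    funnel asymmetry.
    """
    effects = effects.copy().reset_index(drop=True)
    se = np.sqrt(effects["variance"].to_numpy(float))
    if np.std(se) == 0:
        raise ValueError("sampling SE column has zero variance; slope unestimable")
    effects["egger_se"] = se
    return fit_meta(
        effects, M=M, A_phylo=A_phylo, config=config, continuous=("egger_se",)
    )
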