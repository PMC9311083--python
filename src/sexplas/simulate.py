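"""Deterministic forward simulator of the two-sex moving-optimum model.

This is the infinite-population mean-dynamics recursion: no drift, no
mutation, fixed G-matrix, fixed reaction norms.  It exists as an
independent numerical oracle for the closed forms in
:mod:`sexplas.theory` — the algebra there was transcribed by derivation,
and it is the agreement with this recursion that certifies it.

Per generation t (environment eps(t)):

    theta_s = B_s * eps          sex-specific optimum
    z_s     = a_s + b_s * eps    sex-specific mean phenotype
    L_s     = z_s - theta_s      lag behind the optimum
    beta_s  = -gamma_s * L_s     directional selection gradient
    delta a = (1/2) G [beta_f, beta_m]^T

with growth r(t) = r_max minus demographically weighted Gaussian lag
loads (gamma_s/2) L_s^2 and quadratic plasticity costs.  The factor 1/2
in the response reflects autosomal inheritance: each sex inherits half
its breeding value from mothers and half from fathers.

Cyclic environments are realised as eps(t) = sqrt(A) * sin(2 pi t /
period), so the mean-square environment is A/2 and the amplitude term A
enters the fast-cycle load exactly as in the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .theory import CyclicMode, Demography, EnvRegime, TheoryParams, _plasticity_cost

__all__ = ["SimConfig", "SimState", "step", "run", "steady_state_growth"]

_DIVERGENCE_LIMIT = 1e6


@dataclass
class SimState:
    """Mean state of the population at one generation."""

    generation: int = 0
    a_f: float = 0.0  # mean female breeding value (trait units)
    a_m: float = 0.0  # mean male breeding value
    env: float = 0.0
    z_f: float = 0.0
    z_m: float = 0.0
    r: float = 0.0


@dataclass
class SimConfig:
    params: TheoryParams = field(default_factory=TheoryParams)
    regime: EnvRegime = field(default_factory=EnvRegime)
    demography: Demography = Demography.FEMALE_DOMINANCE
    generations: int = 5000
    burn_in: int | None = None  # default: 40% of generations
    conv_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.demography = Demography(self.demography)
        if self.burn_in is None:
            self.burn_in = int(0.4 * self.generations)
        if not (0 <= self.burn_in < self.generations):
            raise ValueError("need generations > burn_in >= 0")

    def environment(self, t: int) -> float:
        reg = self.regime
        if reg.mode is CyclicMode.DIRECTIONAL:
            return reg.eta * t
        if reg.mode is CyclicMode.CYCLIC_SLOW:
            # slow regime: a trend realised directly (the closed form says
            # slow cycles behave like the directional case)
            return reg.eta * t
        return math.sqrt(reg.A) * math.sin(2.0 * math.pi * t / reg.period)


def _growth(cfg: SimConfig, L_f: float, L_m: float) -> float:
    p = cfg.params
    lag_f = 0.5 * p.gamma_f * L_f * L_f
    lag_m = 0.5 * p.gamma_m * L_m * L_m
    cost_f = _plasticity_cost(p, "f")
    cost_m = _plasticity_cost(p, "m")
    if cfg.demography is Demography.FEMALE_DOMINANCE:
        return p.r_max - lag_f - cost_f
    return p.r_max - 0.5 * (lag_f + cost_f) - 0.5 * (lag_m + cost_m)


def step(state: SimState, cfg: SimConfig) -> SimState:
    """Advance the mean-trait recursion by one generation."""
    p = cfg.params
    eps = cfg.environment(state.generation)
    z_f = state.a_f + p.b_f * eps
    z_m = state.a_m + p.b_m * eps
    L_f = z_f - p.B_f * eps
    L_m = z_m - p.B_m * eps
    if abs(L_f) > _DIVERGENCE_LIMIT or abs(L_m) > _DIVERGENCE_LIMIT:
        raise RuntimeError(
            f"simulation diverged at generation {state.generation}: "
            f"lags ({L_f:.3g}, {L_m:.3g})"
        )
    beta_f = -p.gamma_f * L_f
    beta_m = -p.gamma_m * L_m
    C = p.genetic_covariance()
    a_f = state.a_f + 0.5 * (p.V_A_f * beta_f + C * beta_m)
    a_m = state.a_m + 0.5 * (C * beta_f + p.V_A_m * beta_m)
    return SimState(
        generation=state.generation + 1,
        a_f=a_f,
        a_m=a_m,
        env=eps,
        z_f=z_f,
        z_m=z_m,
        r=_growth(cfg, L_f, L_m),
    )


def run(cfg: SimConfig) -> pd.DataFrame:
    """Run the recursion, returning the full trajectory.

    Columns: generation, env, zbar_f, zbar_m, lag_f, lag_m, r.  The loop
    body is inlined for speed; a property test pins it to :func:`step`.
    """
    p = cfg.params
    C = p.genetic_covariance()
    a_f = a_m = 0.0
    rows = []
    for t in range(cfg.generations):
        eps = cfg.environment(t)
        z_f = a_f + p.b_f * eps
        z_m = a_m + p.b_m * eps
        L_f = z_f - p.B_f * eps
        L_m = z_m - p.B_m * eps
        if abs(L_f) > _DIVERGENCE_LIMIT or abs(L_m) > _DIVERGENCE_LIMIT:
            raise RuntimeError(
                f"simulation diverged at generation {t}: lags ({L_f:.3g}, {L_m:.3g})"
            )
        rows.append((t, eps, z_f, z_m, L_f, L_m, _growth(cfg, L_f, L_m)))
        a_f += 0.5 * (p.V_A_f * (-p.gamma_f * L_f) + C * (-p.gamma_m * L_m))
        a_m += 0.5 * (C * (-p.gamma_f * L_f) + p.V_A_m * (-p.gamma_m * L_m))
    return pd.DataFrame(
        rows, columns=["generation", "env", "zbar_f", "zbar_m", "lag_f", "lag_m", "r"]
    )


@dataclass(frozen=True)
class SteadyState:
    r_eq: float
    converged: bool
    n_generations: int


def steady_state_growth(cfg: SimConfig) -> SteadyState:
    """Time-averaged post-burn-in growth rate.

    For cyclic regimes the averaging window is trimmed to an integer
    number of cycles.  Convergence is flagged by comparing the means of
    the two halves of the window (tolerance ``cfg.conv_tol``, scaled by
    max(1, |r_max|)).
    """
    traj = run(cfg)
    r = traj["r"].to_numpy()[cfg.burn_in :]
    if cfg.regime.mode is CyclicMode.CYCLIC_FAST:
        period = cfg.regime.period
        n_cycles = len(r) // period
        if n_cycles < 1:
            raise ValueError("post-burn-in window shorter than one cycle")
        r = r[: n_cycles * period]
        half = (n_cycles // 2) * period
    else:
        half = len(r) // 2
    mean_r = float(r.mean())
    scale = max(1.0, abs(cfg.params.r_max))
    converged = bool(
        half > 0 and abs(float(r[:half].mean()) - float(r[half:].mean())) <= cfg.conv_tol * scale
    )
    return SteadyState(r_eq=mean_r, converged=converged, n_generations=cfg.generations)
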