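"""Closed-form two-sex moving-optimum theory of population persistence.

The model tracks a single ecological trait expressed in both sexes. Each
sex's optimum moves with the environment at rate ``B_s`` (per unit
environmental change) while a fixed reaction norm of slope ``b_s`` moves
the phenotype plastically.  What is left over, ``K_s = B_s - b_s``, is the
*effective* rate of optimum change that evolution must track.  Under
Gaussian stabilising selection of strength ``gamma_s`` and a constant
cross-sex G-matrix

    G = [[V_A_f,               r_mf*sqrt(V_A_f*V_A_m)],
         [r_mf*sqrt(V_A_f*V_A_m),             V_A_m]],

the sex-specific trait means lag behind their optima at steady state, and
the lag load depresses the intrinsic growth rate below ``r_max``.  Growth
depends on female adaptation only (*female demographic dominance*) or on
both sexes equally (*demographic co-dominance*).

This module evaluates the steady-state growth rate under directional and
cyclic environmental change, and the sexual dimorphism in plasticity
``b_SD = b_f - b_m`` that maximises it, holding the average plasticity
``b_bar`` fixed.  All formulas are closed-form and deterministic; the
forward simulator in :mod:`sexplas.simulate` serves as an independent
numerical oracle for every expression here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Callable, Iterable, Sequence

import pandas as pd

__all__ = [
    "TheoryParams",
    "EnvRegime",
    "Demography",
    "GrowthOutcome",
    "effective_rates",
    "growth_directional",
    "growth_cyclic",
    "optimal_bsd",
    "sweep_figure1",
    "golden_section_max",
]


class Demography(str, Enum):
    """Demographic weighting of the sexes in population growth."""

    FEMALE_DOMINANCE = "female_dominance"
    CODOMINANCE = "codominance"


class CyclicMode(str, Enum):
    DIRECTIONAL = "directional"
    CYCLIC_SLOW = "cyclic_slow"
    CYCLIC_FAST = "cyclic_fast"


@dataclass(frozen=True)
class EnvRegime:
    """Environmental change regime.

    Parameters
    ----------
    mode:
        ``directional`` (linear trend), ``cyclic_slow`` (cycles slow
        relative to evolution; the directional result applies), or
        ``cyclic_fast`` (cycles fast relative to evolution).
    eta:
        Rate of directional change per generation (environmental units).
    A:
        Amplitude term of the environmental cycle as it enters the
        fast-cycle load, i.e. the squared sinusoid amplitude: the
        realised environment is ``eps(t) = sqrt(A) * sin(2*pi*t/period)``
        so its mean square is A/2.
    period:
        Generations per full cycle (used by the simulator).
    """

    mode: CyclicMode = CyclicMode.DIRECTIONAL
    eta: float = 0.0
    A: float = 0.0
    period: int = 10

    def __post_init__(self) -> None:
        mode = CyclicMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not math.isfinite(self.eta):
            raise ValueError("eta must be finite")
        if self.A < 0:
            raise ValueError("cycle amplitude A must be >= 0")
        if mode is not CyclicMode.DIRECTIONAL and self.period < 2:
            raise ValueError("cyclic regimes need period >= 2")


@dataclass(frozen=True)
class TheoryParams:
    """One parameterisation of the two-sex model (all Table-style symbols).

    Units: trait in arbitrary trait units (TU), environment in
    environmental units (EU).  ``B_*`` and ``b_*`` are TU/EU, genetic
    variances TU^2, selection strengths 1/TU^2, ``r_max`` per generation.
    """

    B_f: float = 1.0
    B_m: float = 1.0
    b_f: float = 0.5
    b_m: float = 0.5
    V_A_f: float = 0.5
    V_A_m: float = 0.5
    r_mf: float = 0.5
    gamma_f: float = 1.0
    gamma_m: float = 1.0
    gamma_b_f: float = 0.0
    gamma_b_m: float = 0.0
    r_max: float = 0.05

    def __post_init__(self) -> None:
        if self.V_A_f <= 0 or self.V_A_m <= 0:
            raise ValueError("additive genetic variances must be positive")
        if self.gamma_f <= 0 or self.gamma_m <= 0:
            raise ValueError("stabilising selection strengths must be positive")
        if abs(self.r_mf) > 1:
            raise ValueError("cross-sex genetic correlation must lie in [-1, 1]")
        if self.gamma_b_f < 0 or self.gamma_b_m < 0:
            raise ValueError("plasticity costs must be >= 0")

    @property
    def b_bar(self) -> float:
        """Average plasticity (b_f + b_m)/2."""
        return 0.5 * (self.b_f + self.b_m)

    @property
    def b_sd(self) -> float:
        """Sexual dimorphism in plasticity, b_f - b_m."""
        return self.b_f - self.b_m

    def with_bsd(self, b_sd: float, b_bar: float | None = None) -> "TheoryParams":
        """Return a copy with reaction norms set from (b_bar, b_sd)."""
        if b_bar is None:
            b_bar = self.b_bar
        return replace(self, b_f=b_bar + 0.5 * b_sd, b_m=b_bar - 0.5 * b_sd)

    def genetic_covariance(self) -> float:
        return self.r_mf * math.sqrt(self.V_A_f * self.V_A_m)


@dataclass(frozen=True)
class GrowthOutcome:
    """Steady-state growth and its per-sex decomposition.

    ``lag_load_f + lag_load_m == r_max - r_eq`` exactly: each field is the
    full demographically weighted subtractive term for that sex (lag load
    plus that sex's plasticity cost).
    """

    r_eq: float
    K_f: float
    K_m: float
    alpha: float
    lag_load_f: float
    lag_load_m: float

    @property
    def persists(self) -> bool:
        return self.r_eq > 0


def effective_rates(params: TheoryParams) -> tuple[float, float]:
    """Effective rates of optimum change, K_f = B_f - b_f, K_m = B_m - b_m."""
    return params.B_f - params.b_f, params.B_m - params.b_m


def _alpha(params: TheoryParams, K_f: float, K_m: float) -> float:
    """Variance-weighted ratio of effective male vs. female optimum change.

    alpha = (K_m / K_f) * sqrt(V_A_f / V_A_m); NaN when K_f == 0.
    """
    if K_f == 0:
        return math.nan
    return (K_m / K_f) * math.sqrt(params.V_A_f / params.V_A_m)


def _check_r_mf(params: TheoryParams) -> None:
    if abs(params.r_mf) == 1.0:
        raise ValueError(
            "perfect cross-sex genetic correlation (|r_mf| = 1) makes the "
            "steady-state lag singular"
        )


def _plasticity_cost(params: TheoryParams, sex: str) -> float:
    """Quadratic fitness cost of plasticity for one sex: (gamma_b_s/2) b_s^2.

    Kept behind this single function so the placement of the cost can be
    revised without touching any caller.
    """
    if sex == "f":
        return 0.5 * params.gamma_b_f * params.b_f**2
    return 0.5 * params.gamma_b_m * params.b_m**2


def _steady_lags(params: TheoryParams, eta: float) -> tuple[float, float]:
    """Steady-state per-sex lags of the trait mean behind its optimum.

    Solves the stationarity of the two-sex breeder's equation
    delta_a = (1/2) G beta with beta_s = -gamma_s * L_s, requiring each
    sex's mean breeding value to advance by K_s * eta per generation:

        L_f = -(2 eta / (gamma_f V_A_f (1 - r^2))) (K_f - r K_m sqrt(V_A_f/V_A_m))
        L_m = -(2 eta / (gamma_m V_A_m (1 - r^2))) (K_m - r K_f sqrt(V_A_m/V_A_f))
    """
    _check_r_mf(params)
    K_f, K_m = effective_rates(params)
    r = params.r_mf
    one_minus_r2 = 1.0 - r * r
    s = math.sqrt(params.V_A_f / params.V_A_m)
    L_f = -2.0 * eta * (K_f - r * K_m * s) / (params.gamma_f * params.V_A_f * one_minus_r2)
    L_m = -2.0 * eta * (K_m - r * K_f / s) / (params.gamma_m * params.V_A_m * one_minus_r2)
    return L_f, L_m


def growth_directional(
    params: TheoryParams,
    eta: float,
    demography: Demography | str = Demography.FEMALE_DOMINANCE,
) -> GrowthOutcome:
    """Steady-state intrinsic growth rate under directional change.

    Under female demographic dominance

        r_eq = r_max - (gamma_f/2) L_f^2 - cost_f,

    and under co-dominance

        r_eq = r_max - (gamma_f/4) L_f^2 - (gamma_m/4) L_m^2
                     - (cost_f + cost_m)/2,

    with L_s the steady-state lags (equivalently, the female load equals
    (2/gamma_f) (eta K_f / V_A_f)^2 ((1 - r_mf alpha)/(1 - r_mf^2))^2).
    """
    demography = Demography(demography)
    L_f, L_m = _steady_lags(params, eta)
    K_f, K_m = effective_rates(params)
    lag_f = 0.5 * params.gamma_f * L_f**2
    lag_m = 0.5 * params.gamma_m * L_m**2
    cost_f = _plasticity_cost(params, "f")
    cost_m = _plasticity_cost(params, "m")
    if demography is Demography.FEMALE_DOMINANCE:
        load_f = lag_f + cost_f
        load_m = 0.0
    else:
        load_f = 0.5 * (lag_f + cost_f)
        load_m = 0.5 * (lag_m + cost_m)
    r_eq = params.r_max - load_f - load_m
    return GrowthOutcome(
        r_eq=r_eq,
        K_f=K_f,
        K_m=K_m,
        alpha=_alpha(params, K_f, K_m),
        lag_load_f=load_f,
        lag_load_m=load_m,
    )


def growth_cyclic(
    params: TheoryParams,
    regime: EnvRegime,
    demography: Demography | str = Demography.FEMALE_DOMINANCE,
) -> GrowthOutcome:
    """Mean steady-state growth rate under cyclic environmental change.

    Slow cycles reduce to the directional result (evolution tracks the
    cycle).  Fast cycles leave no time for evolutionary tracking, so the
    mean lag load over a cycle is set by the plastic mismatch alone:

        female dominance:  rbar_eq = r_max - (gamma_f/4) A K_f^2
        co-dominance:      rbar_eq = r_max - (gamma_f/8) A K_f^2
                                           - (gamma_m/8) A K_m^2

    (plasticity costs, if any, subtract with the same demographic weights
    as under directional change).
    """
    demography = Demography(demography)
    mode = CyclicMode(regime.mode)
    if mode is CyclicMode.DIRECTIONAL:
        raise ValueError("growth_cyclic expects a cyclic regime; use growth_directional")
    if mode is CyclicMode.CYCLIC_SLOW:
        return growth_directional(params, regime.eta, demography)
    _check_r_mf(params)
    K_f, K_m = effective_rates(params)
    lag_f = 0.25 * params.gamma_f * regime.A * K_f**2
    lag_m = 0.25 * params.gamma_m * regime.A * K_m**2
    cost_f = _plasticity_cost(params, "f")
    cost_m = _plasticity_cost(params, "m")
    if demography is Demography.FEMALE_DOMINANCE:
        load_f = lag_f + cost_f
        load_m = 0.0
    else:
        load_f = 0.5 * lag_f + 0.5 * cost_f
        load_m = 0.5 * lag_m + 0.5 * cost_m
    r_eq = params.r_max - load_f - load_m
    return GrowthOutcome(
        r_eq=r_eq,
        K_f=K_f,
        K_m=K_m,
        alpha=_alpha(params, K_f, K_m),
        lag_load_f=load_f,
        lag_load_m=load_m,
    )


def optimal_bsd(
    params: TheoryParams,
    eta: float,
    demography: Demography | str = Demography.FEMALE_DOMINANCE,
) -> float:
    """Closed-form b_SD maximising directional steady-state growth.

    The average plasticity ``params.b_bar`` is held fixed while
    ``b_SD = b_f - b_m`` varies.  Growth is quadratic in b_SD, so the
    stationary point below is the unique maximiser.

    Female dominance (cost gamma_b_f on the female norm only):

        b_hat = [w_f (1 + r s) P_f - (gamma_b_f/2) b_bar]
                / [(w_f/2) (1 + r s)^2 + gamma_b_f/4]

    with s = sqrt(V_A_f/V_A_m), P_f = (B_f - b_bar) - r s (B_m - b_bar)
    and w_f = (2/gamma_f) (eta / (V_A_f (1 - r^2)))^2.  When B_f = B_m,
    gamma_b_f = 0 and V_A_f = V_A_m this collapses to the simple form
    2 (B_f - b_bar)(1 - r_mf)/(1 + r_mf).

    Co-dominance additionally assumes equal costs in the two sexes
    (gamma_b_f == gamma_b_m, enforced); with t_s = (1/gamma_s) / V_A_s^2,
    P_m the male analogue of P_f:

        b_hat = [t_f (1+r s) P_f - t_m (1+r/s) P_m]
                / [(t_f (1+r s)^2 + t_m (1+r/s)^2)/2
                   + gamma_b (1-r^2)^2 / (4 eta^2)]

    Raises ``ValueError`` when |r_mf| = 1, or when eta = 0 with no cost
    (growth is then independent of b_SD).
    """
    demography = Demography(demography)
    _check_r_mf(params)
    r = params.r_mf
    s = math.sqrt(params.V_A_f / params.V_A_m)
    b_bar = params.b_bar
    P_f = (params.B_f - b_bar) - r * s * (params.B_m - b_bar)
    one_minus_r2 = 1.0 - r * r

    if demography is Demography.FEMALE_DOMINANCE:
        w_f = (2.0 / params.gamma_f) * (eta / (params.V_A_f * one_minus_r2)) ** 2
        num = w_f * (1.0 + r * s) * P_f - 0.5 * params.gamma_b_f * b_bar
        den = 0.5 * w_f * (1.0 + r * s) ** 2 + 0.25 * params.gamma_b_f
        if den == 0.0:
            raise ValueError(
                "growth is independent of b_SD (eta = 0 and no plasticity cost)"
            )
        return num / den

    if params.gamma_b_f != params.gamma_b_m:
        raise ValueError(
            "the co-dominance closed form assumes equal plasticity costs "
            "in the two sexes (gamma_b_f == gamma_b_m)"
        )
    gamma_b = params.gamma_b_f
    P_m = (params.B_m - b_bar) - (r / s) * (params.B_f - b_bar)
    t_f = 1.0 / (params.gamma_f * params.V_A_f**2)
    t_m = 1.0 / (params.gamma_m * params.V_A_m**2)
    num = t_f * (1.0 + r * s) * P_f - t_m * (1.0 + r / s) * P_m
    den = 0.5 * (t_f * (1.0 + r * s) ** 2 + t_m * (1.0 + r / s) ** 2)
    if gamma_b > 0:
        if eta == 0:
            raise ValueError(
                "with eta = 0 the lag load vanishes; the cost-only optimum "
                "is b_SD = 0 by symmetry but the closed form is degenerate"
            )
        den += gamma_b * one_minus_r2**2 / (4.0 * eta**2)
    if den == 0.0:
        raise ValueError("growth is independent of b_SD (eta = 0 and no plasticity cost)")
    return num / den


_INV_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def golden_section_max(
    f: Callable[[float], float],
    lo: float = -10.0,
    hi: float = 10.0,
    tol: float = 1e-8,
) -> float:
    """Deterministic golden-section maximisation of a unimodal function."""
    a, b = lo, hi
    c = b - _INV_GOLDEN * (b - a)
    d = a + _INV_GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _INV_GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INV_GOLDEN * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def numeric_optimal_bsd(
    params: TheoryParams,
    eta: float,
    demography: Demography | str = Demography.FEMALE_DOMINANCE,
    lo: float = -10.0,
    hi: float = 10.0,
    tol: float = 1e-8,
) -> float:
    """Golden-section maximisation of directional growth over b_SD.

    Independent numerical check on :func:`optimal_bsd`; the bracket is in
    units of the mean optimum-change rate.
    """

    def r_of(b_sd: float) -> float:
        return growth_directional(params.with_bsd(b_sd), eta, demography).r_eq

    return golden_section_max(r_of, lo, hi, tol)


def sweep_figure1(
    curves: dict[str, TheoryParams] | Sequence[tuple[str, TheoryParams]],
    eta: float,
    demography: Demography | str = Demography.FEMALE_DOMINANCE,
    b_sd_grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Growth-versus-dimorphism curves (the classic four-panel sweep).

    Each named parameter set is swept over a grid of b_SD values at fixed
    b_bar.  Returns a tidy frame with columns
    ``curve_id, b_sd, r_eq, persists, female_biased`` (the last marking
    the shaded b_SD > 0 region).
    """
    if b_sd_grid is None:
        b_sd_grid = [i / 100.0 for i in range(-150, 151)]
    items = curves.items() if isinstance(curves, dict) else curves
    rows = []
    for curve_id, base in items:
        for b_sd in b_sd_grid:
            out = growth_directional(base.with_bsd(b_sd), eta, demography)
            rows.append(
                {
                    "curve_id": curve_id,
                    "b_sd": b_sd,
                    "r_eq": out.r_eq,
                    "persists": out.persists,
                    "female_biased": b_sd > 0,
                }
            )
    return pd.DataFrame(rows)


def figure1_curves(mean_V: float = 0.5, mean_B: float = 1.0) -> dict[str, TheoryParams]:
    """The three standard curve parameterisations used in the sweeps.

    black: symmetric sexes; orange: female optimum shifts faster and males
    carry more genetic variance; blue: the mirror case.
    """
    base = dict(b_f=0.5, b_m=0.5, r_mf=0.5, gamma_f=1.0, gamma_m=1.0, r_max=0.05)
    return {
        "black": TheoryParams(B_f=mean_B, B_m=mean_B, V_A_f=mean_V, V_A_m=mean_V, **base),
        "orange": TheoryParams(
            B_f=mean_B + 0.1, B_m=mean_B - 0.1, V_A_f=mean_V - 0.05, V_A_m=mean_V + 0.05, **base
        ),
        "blue": TheoryParams(
            B_f=mean_B - 0.1, B_m=mean_B + 0.1, V_A_f=mean_V + 0.05, V_A_m=mean_V - 0.05, **base
        ),
    }
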