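"""Randomised cross-validation of the closed forms against the simulator.

The closed-form growth rates were transcribed by derivation, so the
package treats simulator agreement — not the transcription — as the
ground truth.  This module draws random valid parameter sets and
measures the discrepancy between each closed form and the forward
recursion, for use by the test suite and the analysis scripts.

Parameter ranges are chosen so each regime's own validity condition
holds: directional draws use selection strong enough (gamma_s V_A_s of
order 0.1-1) that the lag equilibrates well within the simulated
horizon; fast-cycle draws keep gamma_s V_A_s * period << 1, the meaning
of "cycles fast relative to the tempo of evolution", and scale the cycle
amplitude so the plastic load stays a modest fraction of r_max.
"""

from __future__ import annotations

import numpy as np

from .simulate import SimConfig, steady_state_growth
from .theory import (
    Demography,
    EnvRegime,
    TheoryParams,
    growth_cyclic,
    growth_directional,
)

__all__ = [
    "draw_directional_params",
    "draw_fast_cycle_setup",
    "directional_discrepancies",
    "fast_cycle_discrepancies",
]


def draw_directional_params(rng: np.random.Generator) -> tuple[TheoryParams, float]:
    """One random valid parameter set and rate eta for the directional regime."""
    params = TheoryParams(
        B_f=rng.uniform(0.6, 1.4),
        B_m=rng.uniform(0.6, 1.4),
        b_f=rng.uniform(0.0, 1.0),
        b_m=rng.uniform(0.0, 1.0),
        V_A_f=rng.uniform(0.2, 1.0),
        V_A_m=rng.uniform(0.2, 1.0),
        r_mf=rng.uniform(-0.8, 0.8),
        gamma_f=rng.uniform(0.5, 2.0),
        gamma_m=rng.uniform(0.5, 2.0),
        r_max=0.05,
    )
    eta = rng.uniform(0.005, 0.05)
    return params, eta


def draw_fast_cycle_setup(rng: np.random.Generator) -> tuple[TheoryParams, EnvRegime]:
    """One random parameter set and fast-cycle regime within its validity range."""
    params = TheoryParams(
        B_f=rng.uniform(0.8, 1.2),
        B_m=rng.uniform(0.8, 1.2),
        b_f=rng.uniform(0.2, 0.7),
        b_m=rng.uniform(0.2, 0.7),
        V_A_f=rng.uniform(0.05, 0.2),
        V_A_m=rng.uniform(0.05, 0.2),
        r_mf=rng.uniform(-0.6, 0.6),
        gamma_f=rng.uniform(0.05, 0.3),
        gamma_m=rng.uniform(0.05, 0.3),
        r_max=0.05,
    )
    period = int(rng.integers(4, 7))
    # amplitude set so the predicted plastic load is ~30% of r_max
    K_f = params.B_f - params.b_f
    K_m = params.B_m - params.b_m
    load_per_A = 0.25 * max(params.gamma_f * K_f**2, params.gamma_m * K_m**2)
    A = 0.3 * params.r_max / load_per_A
    return params, EnvRegime(mode="cyclic_fast", A=A, period=period)


def directional_discrepancies(
    n_sets: int,
    seed: int = 0,
    generations: int = 4000,
) -> np.ndarray:
    """|simulated r_eq - closed form| / r_max for random directional draws.

    Alternates the two demographic modes across draws.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_sets)
    for i in range(n_sets):
        params, eta = draw_directional_params(rng)
        dem = Demography.FEMALE_DOMINANCE if i % 2 == 0 else Demography.CODOMINANCE
        pred = growth_directional(params, eta, dem).r_eq
        sim = steady_state_growth(
            SimConfig(
                params=params,
                regime=EnvRegime(mode="directional", eta=eta),
                demography=dem,
                generations=generations,
            )
        )
        out[i] = abs(sim.r_eq - pred) / abs(params.r_max)
    return out


def fast_cycle_discrepancies(
    n_sets: int,
    seed: int = 0,
    n_cycles: int = 400,
) -> np.ndarray:
    """|simulated mean growth - fast-cycle closed form| / r_max."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_sets)
    for i in range(n_sets):
        params, regime = draw_fast_cycle_setup(rng)
        dem = Demography.FEMALE_DOMINANCE if i % 2 == 0 else Demography.CODOMINANCE
        pred = growth_cyclic(params, regime, dem).r_eq
        generations = regime.period * n_cycles
        sim = steady_state_growth(
            SimConfig(
                params=params,
                regime=regime,
                demography=dem,
                generations=generations,
                burn_in=regime.period * (n_cycles // 2),
            )
        )
        out[i] = abs(sim.r_eq - pred) / abs(params.r_max)
    return out
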