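import numpy as np
import pandas as pd
import pytest

from sexplas.effects import compute_effects
from sexplas.synth import SynthConfig, generate


def make_group(study, exp, level, sex, mean, sd, n, temp, trait="longevity",
               species="Testus exemplaris", treatment="rearing"):
    return {
        "study_id": study, "experiment_id": exp, "species": species,
        "trait_class": trait, "trait_name": trait, "treatment_type": treatment,
        "treatment_level_id": level, "temperature": temp, "sex": sex,
        "mean": mean, "sd": sd, "n": n,
    }


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic dataset shared across tests (truth known)."""
    return generate(SynthConfig(n_species=8, experiments_per_study=2), seed=11)


@pytest.fixture(scope="session")
def small_effects(small_synth):
    eff, exc = compute_effects(small_synth.data)
    return eff, exc


@pytest.fixture(scope="session")
def hedges_effects(small_effects):
    eff, _ = small_effects
    return eff[eff["kind"] == "hedges_d"].reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
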