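import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wssgwas.datatypes import Pedigree
from wssgwas.simulate import SimConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


def make_pedigree(rows):
    """rows: (animal, sire, dam, generation[, sex]) tuples."""
    recs = [r if len(r) == 5 else (*r, "F") for r in rows]
    return Pedigree(pd.DataFrame(
        recs, columns=["animal", "sire", "dam", "generation", "sex"]))


@pytest.fixture(scope="session")
def trio():
    """Two unrelated founders and their offspring."""
    return make_pedigree([("S", "0", "0", 0, "M"), ("D", "0", "0", 0),
                          ("O", "S", "D", 1)])


@pytest.fixture(scope="session")
def small_sim():
    """~720-animal population shared by read-only tests."""
    cfg = SimConfig(seed=42, n_founders=120, n_generations=5,
                    n_markers=600, n_qtl=40, genotyped_fraction=0.2,
                    progeny_per_sire=20.0, natural_progeny_per_sire=5.0)
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
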