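import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from telotrace.synthetic_data import GenomeRecipe, make_genomes


@pytest.fixture(scope="session")
def small_recipe() -> GenomeRecipe:
    """Three small genomes, one motif-mutated, with everything planted."""
    return GenomeRecipe(
        n_genomes=3,
        scaffold_length=120_000,
        n_decoy_template_loci=15,
        telomere_array_copies=(40, 60),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_recipe):
    return make_genomes(small_recipe)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
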