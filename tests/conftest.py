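import warnings

import numpy as np
import pytest

from ploidyhic.contacts import kr_balance
from ploidyhic.genome import GenomeLayout
from ploidyhic.simulate import CONDITIONS, SimulationConfig, generate


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic cohort at the default (study-like) conditions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(SimulationConfig(rng_seed=1))


@pytest.fixture(scope="session")
def balanced_pair(default_dataset):
    """KR-balanced contact maps for both conditions of the default cohort."""
    return {c: kr_balance(default_dataset.contacts[c]) for c in CONDITIONS}


@pytest.fixture
def toy_layout():
    """Two chromosomes, 50-kb bins, central pericentromeres."""
    return GenomeLayout(
        chromosomes=[("chr1", 500_000), ("chr2", 400_000)],
        bin_size=50_000,
        pericentromeres={"chr1": (200_000, 300_000), "chr2": (150_000, 250_000)},
    )


@pytest.fixture
def single_chrom_layout():
    """One chromosome of 20 bins without a pericentromere entry."""
    return GenomeLayout(chromosomes=[("chr1", 1_000_000)], bin_size=50_000)
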