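import numpy as np
import pandas as pd
import pytest

from sgekit import (
    Pedigree,
    build_reference_design,
    scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def textbook_pedigree() -> Pedigree:
    """Two founders, two full sibs, and an offspring of the full-sib mating."""
    return Pedigree.from_frame(pd.DataFrame({
        "id": ["p1", "p2", "c1", "c2", "x"],
        "sire": ["0", "0", "p1", "p1", "c1"],
        "dam": ["0", "0", "p2", "p2", "c2"],
    }))


@pytest.fixture(scope="session")
def small_design():
    """A 60-mouse cohort (20 full-sib families, cages of 3, 80% genotyped)."""
    return build_reference_design(n_families=20, family_size=3, n_loci=300, seed=11)


@pytest.fixture(scope="session")
def medium_design():
    """A 300-mouse cohort for calibration studies."""
    return build_reference_design(n_families=100, family_size=3, n_loci=800, seed=7)


@pytest.fixture(scope="session")
def reference_design():
    """The full 600-mouse reference cohort of the simulation study."""
    return build_reference_design(seed=1)


@pytest.fixture(scope="session")
def average_vc():
    return scenario("average")


@pytest.fixture(scope="session")
def high_sge_vc():
    return scenario("high-sge")
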