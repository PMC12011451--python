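import numpy as np
import pytest

from gtpanel.power import LocusFrequencies
from gtpanel.synth import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def biallelic_half():
    """One biallelic locus with p = q = 0.5."""
    return LocusFrequencies("L1", ["A", "B"], np.array([0.5, 0.5]))


@pytest.fixture
def random_loci(rng):
    """Ten loci with 2-4 alleles and random frequencies."""
    loci = []
    for i in range(10):
        k = int(rng.integers(2, 5))
        f = rng.dirichlet(np.ones(k))
        f = np.clip(f, 1e-4, None)
        f /= f.sum()
        alleles = [f"H{j}" for j in range(k)]
        loci.append(LocusFrequencies(f"L{i + 1:03d}", alleles, f))
    return loci


@pytest.fixture
def small_config():
    return SimConfig(seed=7, n_loci=12, alleles_per_locus=3, depth_mean=60.0)
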