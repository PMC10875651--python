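import sys
from fractions import Fraction
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from oecspin import SpinCluster, SpinSite, published_fixtures, validate_cluster


@pytest.fixture(scope="session")
def bundle():
    """The transcribed published tables (31 models + references)."""
    return published_fixtures()


@pytest.fixture(scope="session")
def doublet_names(bundle):
    return bundle.doublet_models()


def make_cluster(spins, couplings, name="test"):
    """Cluster from float/Fraction spins and 0-based coupling dict."""
    sites = tuple(
        SpinSite(
            index=k + 1,
            label=f"site{k + 1}",
            oxidation_state="other",
            local_spin=Fraction(s),
            is_mn=False,
        )
        for k, s in enumerate(spins)
    )
    return validate_cluster(
        SpinCluster(name=name, sites=sites, couplings=dict(couplings))
    )


@pytest.fixture
def cluster_factory():
    return make_cluster


def random_cluster(rng, n_sites=3, max_spin=1.5):
    """Random small cluster with half-integer spins and couplings in +-30."""
    choices = [Fraction(1, 2), Fraction(1), Fraction(3, 2), Fraction(2)]
    choices = [s for s in choices if s <= Fraction(max_spin).limit_denominator(2)]
    spins = [choices[rng.integers(len(choices))] for _ in range(n_sites)]
    couplings = {
        (i, j): float(np.round(rng.uniform(-30, 30), 3))
        for i in range(n_sites)
        for j in range(i + 1, n_sites)
    }
    return make_cluster(spins, couplings, name="random")


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)
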