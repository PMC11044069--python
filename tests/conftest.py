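import numpy as np
import pytest

from phylanchor.landmark_io import (
    LandmarkConfiguration,
    read_newick_string,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the worked-example tree."""
    return read_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    return read_newick_string("(A:1,B:1,C:1,D:1,E:1);")


def random_config(rng, k=12, n_fixed=5, specimen_id="sp"):
    """A non-degenerate random configuration with one semilandmark group."""
    coords = rng.normal(size=(k, 2)) * 3.0
    roles = np.array(["fixed"] * n_fixed + ["semilandmark"] * (k - n_fixed), dtype=object)
    return LandmarkConfiguration(
        specimen_id=specimen_id,
        coordinates=coords,
        point_roles=roles,
        semilandmark_groups=(k - n_fixed,) if k > n_fixed else (),
    )


@pytest.fixture
def random_config_factory():
    return random_config


def random_yule_tree(rng, n):
    """Random ultrametric pure-birth tree via the package generator."""
    from phylanchor.synthetic import simulate_tree

    return simulate_tree(n, mode="yule", seed=int(rng.integers(2**31 - 1)))
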