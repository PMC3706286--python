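import numpy as np
import pytest

from beephylo.trees import parse_newick


@pytest.fixture
def caterpillar4():
    return parse_newick("(((a,b),c),d);")


@pytest.fixture
def cherry3():
    return parse_newick("((a,b),c);")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_coverage(rng, labels, k_max=4):
    """Random partition taxon sets over ``labels`` (test helper)."""
    from beephylo.decisiveness import CoveragePattern

    n = len(labels)
    k = int(rng.integers(1, k_max + 1))
    parts = []
    for _ in range(k):
        size = int(rng.integers(2, n + 1))
        parts.append(set(rng.choice(labels, size=size, replace=False)))
    return CoveragePattern.from_sets(parts, universe=labels)
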