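"""Shared fixtures and web builders."""

import numpy as np
import pytest

from ecotraits.foodweb import FoodWeb, Link, Species


def make_web(links, species=None, timestamp=None, **species_kwargs):
    """Quick web builder: links as (pred, prey, flow); species inferred."""
    if species is None:
        ids = sorted({l[0] for l in links} | {l[1] for l in links})
        species = [Species(id=i, **species_kwargs) for i in ids]
    return FoodWeb(
        species=species,
        links=[Link(p, q, c) for p, q, c in links],
        timestamp=timestamp,
    )


def random_weighted_web(rng, n=None, p_link=0.3):
    """Random directed web with lognormal flows; at least one link."""
    n = n or rng.integers(3, 25)
    ids = [f"s{i}" for i in range(n)]
    links = []
    for i in range(n):
        for j in range(n):
            if rng.random() < p_link:
                links.append((ids[i], ids[j], float(rng.lognormal(0.0, 1.0))))
    if not links:
        links.append((ids[0], ids[1], 1.0))
    return make_web(links, species=[Species(id=i) for i in ids])


def threshold_web(n=100, weighted=False, rng=None):
    """Web where i eats j iff i + j >= n: all three topology metrics take
    distinct values with one common ordering, so hub indices are distinct."""
    ids = [f"n{i:03d}" for i in range(n)]
    links = []
    for i in range(n):
        for j in range(n):
            if i + j >= n:
                flow = float(rng.lognormal(0.0, 0.3)) if (weighted and rng) else 1.0
                links.append((ids[i], ids[j], flow))
    return make_web(links, species=[Species(id=i) for i in ids])


@pytest.fixture
def chain_web():
    """A eats B (flow 1), B eats C (flow 2)."""
    return make_web([("A", "B", 1.0), ("B", "C", 2.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
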