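"""Topology metrics and the Hub Index.

The Hub Index of a node combines three centrality rankings::

    Hub_Index = min(R_degree, R_degree_out, R_pagerank)

where the ranks (1 = best, competition/"1224" ranking) are over degree
(number of trophic partners: predators + prey), degree-out (number of
predators, or for a habitat the number of dependent species) and PageRank.
Degree catches widely connected consumers, degree-out catches basal groups
feeding many sub-webs, and PageRank catches centrally placed, heavily
consumed prey.  The species in the best 5% of the network by Hub Index are
designated hub species; their loss disproportionately degrades structural
integrity, so the composite index weights them highly.

PageRank runs on the graph oriented predator -> prey (consumers "cite"
their resources), weighted by consumption by default so that both the
number and the strength of links count; an unweighted mode supports
binary presence/absence diet data.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateNetworkError
from .foodweb import FoodWeb

#: Fraction of the network designated as hub species.
DEFAULT_HUB_PERCENTILE = 0.05
#: Classic PageRank damping factor.
DEFAULT_DAMPING = 0.85


def _partner_sets(web: FoodWeb) -> tuple[dict[str, set], dict[str, set]]:
    """(prey-of, predators-of) sets per species, zero-flow links excluded."""
    prey_of: dict[str, set] = {i: set() for i in web.ids}
    predators_of: dict[str, set] = {i: set() for i in web.ids}
    for link in web.active_links():
        prey_of[link.predator].add(link.prey)
        predators_of[link.prey].add(link.predator)
    return prey_of, predators_of


def degree(web: FoodWeb, species_id: str) -> int:
    """Number of trophic partners: distinct prey plus distinct predators.

    A partner appearing in both roles counts twice; a cannibal self-link
    contributes 2 (the species is its own prey and its own predator).
    """
    if species_id not in web:
        raise KeyError(f"unknown species id {species_id!r}")
    prey_of, predators_of = _partner_sets(web)
    return len(prey_of[species_id]) + len(predators_of[species_id])


def degree_out(web: FoodWeb, species_id: str) -> int:
    """Number of distinct predators (out-edges in the energy-flow
    orientation prey -> predator); for a habitat node, the number of
    species dependent on it."""
    if species_id not in web:
        raise KeyError(f"unknown species id {species_id!r}")
    _, predators_of = _partner_sets(web)
    return len(predators_of[species_id])


def pagerank(
    web: FoodWeb,
    damping: float = DEFAULT_DAMPING,
    weighted: bool = True,
    tol: float = 1e-10,
) -> pd.Series:
    """PageRank on the predator -> prey graph.

    Edge weights are consumption flows when ``weighted`` (the default), so
    the score reflects both the number and the strength of links; dangling
    mass is redistributed uniformly.  Scores sum to 1 and, in the weighted
    mode, are invariant under global rescaling of all flows because out-edge
    weights are row-normalised.

    Parameters
    ----------
    damping
        Teleportation damping factor in (0, 1).
    tol
        L1 convergence tolerance of the power iteration.
    """
    if not 0 < damping < 1:
        raise ValueError(f"damping must lie in (0, 1), got {damping}")
    active = web.active_links()
    if not active:
        raise DegenerateNetworkError("PageRank needs at least one link with flow")
    graph = nx.DiGraph()
    graph.add_nodes_from(web.ids)
    for link in active:
        graph.add_edge(link.predator, link.prey, weight=link.consumption)
    scores = nx.pagerank(
        graph,
        alpha=damping,
        weight="weight" if weighted else None,
        tol=tol / max(len(web.ids), 1),
        max_iter=1000,
    )
    return pd.Series(scores, name="pagerank").reindex(web.ids)


def rank_descending(values) -> pd.Series:
    """Competition ("1224") ranks, largest value first.

    The largest value gets rank 1; tied values share the smallest rank of
    their block, so ranking is deterministic and never exceeds N.
    """
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise ValueError("cannot rank an empty collection")
    ranks = rankdata(-series.to_numpy(), method="min")
    return pd.Series(ranks.astype(int), index=series.index, name="rank")


def hub_index(
    web: FoodWeb,
    damping: float = DEFAULT_DAMPING,
    weighted: bool = True,
    percentile: float = DEFAULT_HUB_PERCENTILE,
) -> pd.DataFrame:
    """Per-species topology metrics, ranks, Hub Index and hub flag.

    Returns a frame indexed by species id with columns ``degree``,
    ``degree_out``, ``pagerank``, ``R_degree``, ``R_degree_out``,
    ``R_pagerank``, ``hub_index`` and ``is_hub``.
    """
    web.require_links()
    prey_of, predators_of = _partner_sets(web)
    ids = web.ids
    scores = pd.DataFrame(index=pd.Index(ids, name="id"))
    scores["degree"] = [len(prey_of[i]) + len(predators_of[i]) for i in ids]
    scores["degree_out"] = [len(predators_of[i]) for i in ids]
    scores["pagerank"] = pagerank(web, damping=damping, weighted=weighted)
    scores["R_degree"] = rank_descending(scores["degree"]).to_numpy()
    scores["R_degree_out"] = rank_descending(scores["degree_out"]).to_numpy()
    scores["R_pagerank"] = rank_descending(scores["pagerank"]).to_numpy()
    scores["hub_index"] = scores[["R_degree", "R_degree_out", "R_pagerank"]].min(axis=1)
    scores["is_hub"] = scores.index.isin(hub_species(scores, percentile=percentile))
    return scores


def hub_species(scores: pd.DataFrame, percentile: float = DEFAULT_HUB_PERCENTILE) -> set[str]:
    """Species in the best ``percentile`` of the network by Hub Index.

    The target set size is ``max(1, ceil(percentile * N))`` so small webs
    still yield a hub; ties at the cutoff are all included, so the set may
    exceed the ceiling when Hub Index values tie at the boundary.
    """
    if not 0 < percentile <= 1:
        raise ValueError(f"percentile must lie in (0, 1], got {percentile}")
    values = scores["hub_index"].sort_values(kind="stable")
    n_target = max(1, math.ceil(percentile * len(values)))
    cutoff = values.iloc[n_target - 1]
    return set(scores.index[scores["hub_index"] <= cutoff])
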