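"""Exhaustive TF-trio selection on the co-expression network.

A trio's coverage is the size of the union of the three TFs' open
neighborhoods; redundancy is the sum of the three pairwise neighborhood
intersections.  The best trio maximizes coverage, breaking ties by lower
redundancy and then lexicographically by id.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

__all__ = ["TrioScore", "enumerate_trios", "score_trio", "best_trio"]


@dataclass(frozen=True)
class TrioScore:
    tf_triplet: tuple[str, str, str]
    coverage: int
    redundancy: int


def enumerate_trios(tf_ids: list[str], k: int = 3) -> list[tuple[str, ...]]:
    """All C(n, k) unordered TF subsets, each sorted internally,
    enumerated lexicographically by id."""
    ids = sorted(tf_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate TF ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} TFs, got {len(ids)}")
    return list(combinations(ids, k))


def _neighborhoods(
    network: nx.Graph, triplet: tuple[str, ...]
) -> list[set[str]]:
    for tf in triplet:
        if tf not in network:
            raise ValueError(f"TF {tf!r} is not a node of the network")
    return [set(network.neighbors(tf)) for tf in triplet]


def score_trio(network: nx.Graph, triplet: tuple[str, ...]) -> TrioScore:
    """Coverage and redundancy of a TF triple (open neighborhoods: a TF
    does not cover itself, but trio members may cover each other)."""
    if len(set(triplet)) != len(triplet):
        raise ValueError("trio members must be distinct")
    hoods = _neighborhoods(network, triplet)
    coverage = len(set().union(*hoods))
    redundancy = sum(
        len(hoods[i] & hoods[j]) for i, j in combinations(range(len(hoods)), 2)
    )
    return TrioScore(
        tf_triplet=tuple(sorted(triplet)), coverage=coverage, redundancy=redundancy
    )


def best_trio(
    network: nx.Graph, tf_ids: list[str], k: int = 3
) -> tuple[TrioScore, nx.Graph]:
    """Exhaustive argmax of coverage over all C(n, k) TF subsets.

    Ties break by minimum redundancy, then lexicographic triplet id.
    Returns the winning score and the induced subnetwork of the trio plus
    its joint neighborhood.
    """
    in_network = [tf for tf in tf_ids if tf in network]
    missing = sorted(set(tf_ids) - set(in_network))
    if missing:
        raise ValueError(f"TF id(s) not in network: {missing[:5]}")
    best: TrioScore | None = None
    for triplet in enumerate_trios(in_network, k=k):
        score = score_trio(network, triplet)
        if best is None or (-score.coverage, score.redundancy, score.tf_triplet) < (
            -best.coverage,
            best.redundancy,
            best.tf_triplet,
        ):
            best = score
    assert best is not None
    nodes = set(best.tf_triplet)
    for tf in best.tf_triplet:
        nodes |= set(network.neighbors(tf))
    return best, network.subgraph(nodes).copy()


def rank_trios(network: nx.Graph, tf_ids: list[str], k: int = 3) -> list[TrioScore]:
    """All trios sorted best-first (coverage desc, redundancy asc, id)."""
    scores = [score_trio(network, t) for t in enumerate_trios(tf_ids, k=k)]
    return sorted(scores, key=lambda s: (-s.coverage, s.redundancy, s.tf_triplet))
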