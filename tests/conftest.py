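"""Shared fixtures and independent brute-force oracles.

The oracles deliberately share no code with the miners they check: cohesive
subgraphs are found by enumerating all vertex subsets, collections by
enumerating all ID subsets.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest

from sremine import MCS, ProfileMatrix, SREGraph, all_kmers


def connected(subset: frozenset[str], adj: dict[str, set[str]]) -> bool:
    """Undirected connectivity by BFS, self-loops irrelevant."""
    start = next(iter(subset))
    seen = {start}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for u in adj[v] & subset:
            if u not in seen:
                seen.add(u)
                queue.append(u)
    return seen == subset


def brute_force_mcs(
    graph: SREGraph, matrix: ProfileMatrix, alpha: int
) -> set[tuple[frozenset[str], frozenset[str]]]:
    """All locally-maximal alpha-cohesive connected induced subgraphs, by
    exhaustive enumeration of every vertex subset (use only for <= ~12
    vertices)."""
    vertices = sorted(graph.vertex_set)
    adj = {v: graph.neighbors(v) for v in vertices}
    out = set()
    for r in range(1, len(vertices) + 1):
        for combo in itertools.combinations(vertices, r):
            subset = frozenset(combo)
            if not connected(subset, adj):
                continue
            shared = matrix.shared_exons(subset)
            if len(shared) < alpha:
                continue
            frontier = {u for v in subset for u in adj[v]} - subset
            if all(
                len(matrix.shared_exons(subset | {u})) < alpha for u in frontier
            ):
                out.add((subset, shared))
    return out


def brute_force_collections(
    exon_sets: dict[int, frozenset[str]], theta: int, beta: int
) -> set[tuple[tuple[int, ...], frozenset[str]]]:
    """All qualifying MCS collections by enumerating every ID subset."""
    ids = sorted(exon_sets)
    out = set()
    for r in range(beta, len(ids) + 1):
        for combo in itertools.combinations(ids, r):
            shared = frozenset.intersection(*(exon_sets[i] for i in combo))
            if len(shared) >= theta:
                out.add((combo, shared))
    return out


def random_instance(
    rng: np.random.Generator,
    n_vertices: int = 10,
    n_exons: int = 15,
    k: int = 3,
    density: float = 0.5,
    element_type: str = "enhancer",
) -> tuple[SREGraph, ProfileMatrix]:
    """A random small SRE graph (random k-mer subset, so realistic de Bruijn
    adjacency) plus a random sparse profile over a small exon universe."""
    universe = all_kmers(k)
    chosen = list(rng.choice(universe, size=n_vertices, replace=False))
    exons = [f"x{j}" for j in range(n_exons)]
    support = {
        v: {e for e in exons if rng.random() < density} for v in chosen
    }
    graph = SREGraph(element_type=element_type, k=k, vertex_set=frozenset(chosen))
    matrix = ProfileMatrix(support, exons)
    return graph, matrix


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def make_mcs(
    id: int, vertices: set[str], exons: set[str], element_type: str = "enhancer"
) -> MCS:
    return MCS(
        id=id,
        element_type=element_type,
        vertex_set=frozenset(vertices),
        exon_set=frozenset(exons),
    )
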