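"""First mining level: maximal alpha-cohesive connected subgraphs (MCSs).

A connected induced subgraph G_S of an SRE graph is *alpha-cohesive* when
its vertices share at least alpha exons, |T(S)| >= alpha.  It is *maximal*
when no connected supergraph is still cohesive; by anti-monotonicity of
T(.) this is equivalent to the local condition that every single-vertex
extension by an adjacent vertex drops the shared-exon count below alpha.
Each MCS is a candidate variable-length regulatory element: its vertices
spell sequences longer than k.

The miner prunes every vertex whose own support is below alpha, then grows
subgraphs depth-first from each surviving vertex, extending only through
adjacent vertices (undirected adjacency, self-loops ignored) while the
shared support stays >= alpha.  Already-visited vertex sets are memoised so
each subgraph is expanded once.  Overlapping MCSs that share vertices are
all retained; strict subset pairs cannot both be maximal, so the output is
an antichain under inclusion.  IDs are assigned after mining by sorting the
vertex sets, making the output independent of traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .debruijn import SREGraph
from .errors import InputError, ParameterError
from .profile import ProfileMatrix


@dataclass(frozen=True)
class MCS:
    """A maximal alpha-cohesive connected subgraph with its shared exon set."""

    id: int
    element_type: str  # "enhancer" | "silencer"
    vertex_set: frozenset[str]
    exon_set: frozenset[str]

    def sorted_vertices(self) -> tuple[str, ...]:
        return tuple(sorted(self.vertex_set))


def mine_mcs(
    graph: SREGraph,
    matrix: ProfileMatrix,
    alpha: int,
    start_id: int = 1,
) -> list[MCS]:
    """Enumerate every maximal alpha-cohesive connected subgraph of ``graph``.

    Parameters
    ----------
    graph
        The SRE graph to mine; its vertices must all be rows of ``matrix``.
    matrix
        Occurrence profile supplying T(.) queries.
    alpha
        Minimum number of shared exons (>= 1).
    start_id
        First ID to assign (IDs run consecutively in canonical vertex-set
        order).

    Returns
    -------
    list of :class:`MCS`, sorted by their sorted vertex tuples.
    """
    if not isinstance(alpha, int) or alpha < 1:
        raise ParameterError(f"alpha must be an integer >= 1, got {alpha!r}")

    # initial pruning: a vertex whose own support is below alpha can belong
    # to no cohesive subgraph (anti-monotonicity)
    kept = {v for v in graph.vertex_set if len(matrix.support(v)) >= alpha}
    adj = {v: sorted(u for u in graph.neighbors(v) if u in kept) for v in kept}

    seen: set[frozenset[str]] = set()
    maximal: dict[frozenset[str], frozenset[str]] = {}

    def extend(subset: frozenset[str], exons: frozenset[str]) -> None:
        if subset in seen:
            return
        seen.add(subset)
        frontier = sorted({u for v in subset for u in adj[v]} - subset)
        is_maximal = True
        for u in frontier:
            extended = exons & matrix.support(u)
            if len(extended) >= alpha:
                is_maximal = False
                extend(subset | {u}, extended)
        if is_maximal:
            maximal[subset] = exons

    for v in sorted(kept):
        extend(frozenset((v,)), matrix.support(v))

    ordered = sorted(maximal.items(), key=lambda item: tuple(sorted(item[0])))
    return [
        MCS(
            id=start_id + i,
            element_type=graph.element_type,
            vertex_set=vertices,
            exon_set=exons,
        )
        for i, (vertices, exons) in enumerate(ordered)
    ]


def combine_mcs(*groups: Sequence[MCS]) -> list[MCS]:
    """Merge MCS lists from separate runs (e.g. enhancer + silencer) into one
    table with fresh consecutive IDs in canonical order."""
    merged = [m for group in groups for m in group]
    merged.sort(key=lambda m: (m.sorted_vertices(), m.element_type))
    return [replace(m, id=i + 1) for i, m in enumerate(merged)]


_COLUMNS = ["mcs_id", "element_type", "kmers", "n_exons", "exon_ids"]


def mcs_table(mcss: Sequence[MCS]) -> pd.DataFrame:
    """The MCS table keyed by ID: vertex set and exon set per row."""
    ids = [m.id for m in mcss]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate MCS ids in table")
    rows = [
        {
            "mcs_id": m.id,
            "element_type": m.element_type,
            "kmers": ",".join(m.sorted_vertices()),
            "n_exons": len(m.exon_set),
            "exon_ids": ",".join(sorted(m.exon_set)),
        }
        for m in sorted(mcss, key=lambda m: m.id)
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_mcs_table(mcss: Sequence[MCS], path: Union[str, Path]) -> pd.DataFrame:
    table = mcs_table(mcss)
    table.to_csv(path, sep="\t", index=False)
    return table


def read_mcs_table(path: Union[str, Path]) -> list[MCS]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"MCS table {path} lacks columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        exons = frozenset(x for x in row["exon_ids"].split(",") if x)
        if len(exons) != int(row["n_exons"]):
            raise InputError(f"MCS {row['mcs_id']}: n_exons disagrees with exon_ids")
        out.append(
            MCS(
                id=int(row["mcs_id"]),
                element_type=row["element_type"],
                vertex_set=frozenset(row["kmers"].split(",")),
                exon_set=exons,
            )
        )
    ids = [m.id for m in out]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate MCS ids in table")
    return out
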