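"""De Bruijn graphs over the DNA alphabet and score-ranked SRE subgraphs.

The k-dimensional de Bruijn graph has one vertex per length-k DNA string and a
directed edge (u, v) whenever the (k-1)-suffix of u equals the (k-1)-prefix of
v.  Every vertex therefore has out-degree 4 (including a self-loop on each
homopolymer), so |V| = 4^k and |E| = 4^(k+1).  Edges are fully determined by
the vertex strings, so the graph is stored implicitly: only vertex membership
is ever materialised, which keeps induced subgraphs cheap at any k.

An *SRE graph* is the vertex-induced subgraph over the R best-ranked k-mers
(enhancer side) or the R worst-ranked k-mers (silencer side) of a score
ranking.  Walking its edges spells candidate regulatory elements longer than
k: a path through m vertices spells an (m + k - 1)-mer.

Self-loops exist and count toward the edge total, but they are ignored for
connectivity and path spelling — a loop never connects a vertex to a
neighbour and traversing it would not terminate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Iterator, Sequence

import networkx as nx

from .errors import ParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .scores import KmerRecord

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")

#: largest k for which the full vertex/edge set may be materialised
_MATERIALIZE_MAX_K = 8


@dataclass(frozen=True)
class DeBruijnGraph:
    """The k-dimensional de Bruijn graph over {A, C, G, T}, edges implicit."""

    k: int

    @property
    def n_vertices(self) -> int:
        return 4**self.k

    @property
    def n_edges(self) -> int:
        return 4 ** (self.k + 1)

    def vertices(self) -> Iterator[str]:
        """All 4^k k-mers in lexicographic order (A < C < G < T)."""
        for letters in itertools.product(DNA_ALPHABET, repeat=self.k):
            yield "".join(letters)

    def has_vertex(self, kmer: str) -> bool:
        return len(kmer) == self.k and all(c in "ACGT" for c in kmer)

    def has_edge(self, u: str, v: str) -> bool:
        """True iff (u, v) is a directed edge: suffix_{k-1}(u) == prefix_{k-1}(v)."""
        return self.has_vertex(u) and self.has_vertex(v) and u[1:] == v[: self.k - 1]

    def successors(self, kmer: str) -> list[str]:
        return [kmer[1:] + c for c in DNA_ALPHABET]

    def predecessors(self, kmer: str) -> list[str]:
        return [c + kmer[:-1] for c in DNA_ALPHABET]

    def to_networkx(self) -> nx.DiGraph:
        """Materialise the full graph (guarded: only for k <= 8)."""
        if self.k > _MATERIALIZE_MAX_K:
            raise ParameterError(
                f"refusing to materialise 4^{self.k} vertices; k must be <= "
                f"{_MATERIALIZE_MAX_K} for full construction"
            )
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices())
        for u in self.vertices():
            g.add_edges_from((u, v) for v in self.successors(u))
        return g


def build_debruijn(k: int) -> DeBruijnGraph:
    """Construct the k-dimensional de Bruijn graph over the DNA alphabet.

    Parameters
    ----------
    k
        Word length; must satisfy 1 <= k <= 12 (4^12 vertices is the point
        beyond which even implicit vertex enumeration stops being sensible).
    """
    if not isinstance(k, int) or not 1 <= k <= 12:
        raise ParameterError(f"k must be an integer in [1, 12], got {k!r}")
    return DeBruijnGraph(k)


@dataclass(frozen=True)
class SREGraph:
    """Vertex-induced de Bruijn subgraph over a chosen k-mer set.

    The edge set is always exactly the induced one — it is recomputed from
    the vertex strings on demand, so it can neither gain nor lose edges.
    ``element_type`` records which side of the score ranking the vertices
    came from ("enhancer" for the top, "silencer" for the bottom).
    """

    element_type: str
    k: int
    vertex_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.element_type not in ("enhancer", "silencer"):
            raise ParameterError(
                f"element_type must be 'enhancer' or 'silencer', got {self.element_type!r}"
            )
        for v in self.vertex_set:
            if len(v) != self.k or any(c not in "ACGT" for c in v):
                raise ParameterError(f"invalid {self.k}-mer vertex {v!r}")

    def edges(self) -> Iterator[tuple[str, str]]:
        """Induced directed edges, including self-loops on homopolymers."""
        for u in sorted(self.vertex_set):
            for c in DNA_ALPHABET:
                v = u[1:] + c
                if v in self.vertex_set:
                    yield (u, v)

    def successors_in(self, v: str) -> list[str]:
        """Directed successors within the vertex set, self-loops excluded."""
        return [u for u in (v[1:] + c for c in DNA_ALPHABET) if u != v and u in self.vertex_set]

    def neighbors(self, v: str) -> set[str]:
        """Undirected neighbours within the vertex set (self-loops excluded).

        Connectivity and subgraph growth are evaluated on the underlying
        undirected graph: co-occurrence of regulatory elements carries no
        edge-direction semantics.
        """
        out = {v[1:] + c for c in DNA_ALPHABET}
        inc = {c + v[:-1] for c in DNA_ALPHABET}
        return {(u) for u in (out | inc) if u != v and u in self.vertex_set}

    def adjacency(self) -> dict[str, frozenset[str]]:
        """Undirected adjacency restricted to the vertex set."""
        return {v: frozenset(self.neighbors(v)) for v in self.vertex_set}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.vertex_set))
        g.add_edges_from(self.edges())
        return g


def induce(k: int, vertices: Iterable[str], element_type: str = "enhancer") -> SREGraph:
    """Induce an SRE graph on an explicit vertex set (induction is idempotent)."""
    return SREGraph(element_type=element_type, k=k, vertex_set=frozenset(vertices))


def build_sre_graph(
    debruijn: DeBruijnGraph,
    ranked: Sequence["KmerRecord"],
    R: int,
    side: str,
) -> SREGraph:
    """Induce the enhancer (``side='top'``) or silencer (``side='bottom'``)
    SRE graph over the R extreme-ranked k-mers.

    Rank 1 is the highest score, so ``side='top'`` selects ranks 1..R and
    ``side='bottom'`` selects ranks 4^k-R+1..4^k.
    """
    n = debruijn.n_vertices
    if not isinstance(R, int) or not 1 <= R <= n:
        raise ParameterError(f"R must be an integer in [1, 4^k={n}], got {R!r}")
    if side not in ("top", "bottom"):
        raise ParameterError(f"side must be 'top' or 'bottom', got {side!r}")
    if len(ranked) != n:
        raise ParameterError(
            f"ranking covers {len(ranked)} k-mers but the graph has {n} vertices"
        )
    if side == "top":
        chosen = [rec.kmer for rec in ranked if rec.rank <= R]
        element_type = "enhancer"
    else:
        chosen = [rec.kmer for rec in ranked if rec.rank > n - R]
        element_type = "silencer"
    return SREGraph(element_type=element_type, k=debruijn.k, vertex_set=frozenset(chosen))


def export_sre_graph(graph: SREGraph, ranked: Sequence["KmerRecord"], prefix: str) -> None:
    """Write an SRE graph as TSV edge and vertex lists for inspection.

    ``<prefix>.vertices.tsv`` has columns kmer/rank/score; ``<prefix>.edges.tsv``
    has columns source/target.
    """
    by_kmer = {rec.kmer: rec for rec in ranked}
    with open(f"{prefix}.vertices.tsv", "w") as fh:
        fh.write("kmer\trank\tscore\n")
        for v in sorted(graph.vertex_set):
            rec = by_kmer[v]
            fh.write(f"{v}\t{rec.rank}\t{rec.score:.6g}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")
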