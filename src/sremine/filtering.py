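"""Filtering stage: spell MCSs into sequences, locate them in exon windows,
merge same-type overlaps, and emit the final combinatorial SRE sets.

Each MCS spells one sequence per maximal simple path of its induced de
Bruijn subgraph (a path through m k-mer vertices spells an (m+k-1)-mer);
spellings that are substrings of another retained spelling are dropped.
For every exon shared by a collection, all spelled sequences are located in
the window (every exact occurrence, overlaps allowed).  Occurrences of the
SAME element type that overlap by at least one nucleotide are transitively
merged into a single longer element whose sequence is read off the exon
itself; enhancer/silencer overlaps are deliberately left unmerged, since an
ESE and an ESS sharing sequence is exactly the antagonistic arrangement the
method is after.  Each exon thus witnesses one candidate element multiset;
identical candidates are aggregated across exons and a candidate becomes a
final SRE set when it still has >= 2 elements (a layout that collapses to
one long element is discarded) and is witnessed by >= theta exons.

With ``merge_same_type`` off the per-exon candidate is instead the set of
distinct spelled sequences present in the window — the alternative reading
in which overlapping same-type elements are genuinely different regulators.
Both interpretations are first-class outputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .collections import MCSCollection
from .debruijn import DNA_ALPHABET, SREGraph
from .errors import InputError, ParameterError, QueryError
from .mcs import MCS
from .profile import ExonWindow


@dataclass(frozen=True)
class SpelledSequence:
    """A maximal path spelling of one MCS (length >= k)."""

    sequence: str
    element_type: str
    source_mcs: int


@dataclass(frozen=True)
class PlacedElement:
    """An element within one exon window; coordinates 1-based inclusive."""

    sequence: str
    element_type: str
    start: int
    end: int


@dataclass(frozen=True)
class SRESet:
    """A final co-occurring set of typed sequences with its exon support."""

    elements: tuple[tuple[str, str], ...]  # sorted multiset of (sequence, type)
    n_supporting_exons: int
    supporting_exons: frozenset[str]
    source_members: tuple[int, ...]  # MCS ids of the source collection


def spell_mcs(mcs: MCS, graph: Optional[SREGraph] = None) -> list[SpelledSequence]:
    """Spell all maximal path sequences of an MCS.

    Enumerates maximal simple paths of the vertex-induced de Bruijn subgraph
    (self-loops ignored; a single vertex spells itself), then removes any
    spelling that is a substring of another retained spelling.
    """
    vertices = sorted(mcs.vertex_set)
    if not vertices:
        return []
    if graph is not None and not mcs.vertex_set <= graph.vertex_set:
        raise QueryError("MCS vertices are not all contained in the given SRE graph")

    vset = mcs.vertex_set
    succ = {
        v: [u for u in (v[1:] + c for c in DNA_ALPHABET) if u != v and u in vset]
        for v in vertices
    }

    spellings: set[str] = set()

    def walk(path: list[str], in_path: set[str]) -> None:
        extensions = [u for u in succ[path[-1]] if u not in in_path]
        if not extensions:
            seq = path[0] + "".join(v[-1] for v in path[1:])
            spellings.add(seq)
            return
        for u in extensions:
            path.append(u)
            in_path.add(u)
            walk(path, in_path)
            in_path.discard(u)
            path.pop()

    for v in vertices:
        walk([v], {v})

    # drop spellings subsumed by a longer spelling
    retained = [
        s
        for s in sorted(spellings, key=lambda s: (-len(s), s))
        if not any(s != t and s in t for t in spellings)
    ]
    retained.sort()
    return [
        SpelledSequence(sequence=s, element_type=mcs.element_type, source_mcs=mcs.id)
        for s in retained
    ]


def locate_occurrences(
    sequences: Sequence[SpelledSequence],
    window: ExonWindow,
) -> list[tuple[int, int, int]]:
    """All exact occurrences of each sequence in the window.

    Returns (sequence index, start, end) triplets with 1-based inclusive
    coordinates; overlapping occurrences are all reported.
    """
    hits: list[tuple[int, int, int]] = []
    text = window.sequence
    for idx, spelled in enumerate(sequences):
        pat = spelled.sequence
        pos = text.find(pat)
        while pos != -1:
            hits.append((idx, pos + 1, pos + len(pat)))
            pos = text.find(pat, pos + 1)
    return hits


def merge_same_type_occurrences(
    occurrences: Sequence[PlacedElement],
    window_sequence: str,
) -> list[PlacedElement]:
    """Transitively merge same-type occurrences that overlap by >= 1 nt.

    Merging intervals [a, b] and [c, d] with c <= b yields [a, max(b, d)];
    the merged sequence is read from the window itself, so chained merges of
    m distinct consecutive k-mers produce one (m+k-1)-mer.  Adjacency
    without overlap (c == b + 1) does not merge.  Different element types
    are never merged.
    """
    out: list[PlacedElement] = []
    for etype in sorted({o.element_type for o in occurrences}):
        ivs = sorted(
            ((o.start, o.end) for o in occurrences if o.element_type == etype)
        )
        cur_a, cur_b = ivs[0]
        spans = []
        for a, b in ivs[1:]:
            if a <= cur_b:  # genuine positional overlap
                cur_b = max(cur_b, b)
            else:
                spans.append((cur_a, cur_b))
                cur_a, cur_b = a, b
        spans.append((cur_a, cur_b))
        for a, b in spans:
            out.append(
                PlacedElement(
                    sequence=window_sequence[a - 1 : b],
                    element_type=etype,
                    start=a,
                    end=b,
                )
            )
    out.sort(key=lambda e: (e.start, e.end, e.element_type))
    return out


def exon_layout(
    sequences: Sequence[SpelledSequence],
    window: ExonWindow,
    merge_same_type: bool = True,
) -> list[PlacedElement]:
    """The witnessed element layout of one exon window.

    All occurrences of all sequences participate; with merging enabled the
    same-type transitive overlap merge is applied to the full layout.
    """
    occs = [
        PlacedElement(
            sequence=sequences[idx].sequence,
            element_type=sequences[idx].element_type,
            start=start,
            end=end,
        )
        for idx, start, end in locate_occurrences(sequences, window)
    ]
    if not occs:
        return []
    if not merge_same_type:
        return sorted(occs, key=lambda e: (e.start, e.end, e.element_type))
    return merge_same_type_occurrences(occs, window.sequence)


def _candidate_key(
    layout: Sequence[PlacedElement], merge_same_type: bool
) -> tuple[tuple[str, str], ...]:
    pairs = [(e.sequence, e.element_type) for e in layout]
    if not merge_same_type:
        # unmerged interpretation: candidate identity is the distinct set of
        # located sequences
        pairs = list(set(pairs))
    return tuple(sorted(pairs))


def merge_and_emit(
    collection: MCSCollection,
    spelled: Mapping[int, Sequence[SpelledSequence]],
    windows: Union[Sequence[ExonWindow], Mapping[str, ExonWindow]],
    theta: int,
    merge_same_type: bool = True,
) -> list[SRESet]:
    """Generate the final SRE sets of one MCS collection.

    Parameters
    ----------
    collection
        The collection whose shared exons are scanned.
    spelled
        Spelled sequences per member MCS id (see :func:`spell_mcs`).
    windows
        Exon windows covering the collection's shared exons.
    theta
        Minimum number of witnessing exons for a candidate set — the same
        threshold used to mine the collections.
    merge_same_type
        On (default): merged interpretation; off: unmerged interpretation.

    Returns
    -------
    SRE sets with >= 2 elements witnessed by >= theta exons, sorted by
    decreasing support then by elements.
    """
    if not isinstance(theta, int) or theta < 1:
        raise ParameterError(f"theta must be an integer >= 1, got {theta!r}")
    if isinstance(windows, Mapping):
        by_id = dict(windows)
    else:
        by_id = {w.exon_id: w for w in windows}
    missing = set(collection.shared_exons) - set(by_id)
    if missing:
        raise InputError(
            f"windows do not cover {len(missing)} shared exons of the collection"
        )

    # distinct (sequence, type) across member MCSs: two members may spell an
    # identical sequence, which must not double its occurrences in a layout
    seen_seq: set[tuple[str, str]] = set()
    sequences: list[SpelledSequence] = []
    for mid in collection.members:
        for s in spelled.get(mid, ()):
            key = (s.sequence, s.element_type)
            if key not in seen_seq:
                seen_seq.add(key)
                sequences.append(s)

    if not sequences:
        return []

    witnesses: dict[tuple[tuple[str, str], ...], set[str]] = {}
    for exon_id in sorted(collection.shared_exons):
        layout = exon_layout(sequences, by_id[exon_id], merge_same_type)
        if not layout:
            continue
        key = _candidate_key(layout, merge_same_type)
        witnesses.setdefault(key, set()).add(exon_id)

    out = [
        SRESet(
            elements=key,
            n_supporting_exons=len(exons),
            supporting_exons=frozenset(exons),
            source_members=collection.members,
        )
        for key, exons in witnesses.items()
        if len(key) >= 2 and len(exons) >= theta
    ]
    out.sort(key=lambda s: (-s.n_supporting_exons, s.elements))
    return out


_TYPE_CODE = {"enhancer": "E", "silencer": "S"}

_COLUMNS = ["sre_set", "element_types", "n_exons", "source_collection"]


def sre_set_table(sre_sets: Sequence[SRESet]) -> pd.DataFrame:
    """Final output table: one row per SRE set."""
    rows = [
        {
            "sre_set": ",".join(seq for seq, _ in s.elements),
            "element_types": ",".join(_TYPE_CODE[t] for _, t in s.elements),
            "n_exons": s.n_supporting_exons,
            "source_collection": ",".join(str(m) for m in s.source_members),
        }
        for s in sorted(sre_sets, key=lambda s: (-s.n_supporting_exons, s.elements))
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_sre_sets(sre_sets: Sequence[SRESet], path: Union[str, Path]) -> pd.DataFrame:
    df = sre_set_table(sre_sets)
    df.to_csv(path, sep="\t", index=False)
    return df


def witness_table(
    collection: MCSCollection,
    spelled: Mapping[int, Sequence[SpelledSequence]],
    windows: Union[Sequence[ExonWindow], Mapping[str, ExonWindow]],
    merge_same_type: bool = True,
) -> pd.DataFrame:
    """Per-exon witness layout: ``exon_id  start  end  sequence  type``
    (1-based inclusive coordinates)."""
    if isinstance(windows, Mapping):
        by_id = dict(windows)
    else:
        by_id = {w.exon_id: w for w in windows}
    seqs: list[SpelledSequence] = []
    seen: set[tuple[str, str]] = set()
    for mid in collection.members:
        for s in spelled.get(mid, ()):
            if (s.sequence, s.element_type) not in seen:
                seen.add((s.sequence, s.element_type))
                seqs.append(s)
    rows = []
    for exon_id in sorted(collection.shared_exons):
        for e in exon_layout(seqs, by_id[exon_id], merge_same_type):
            rows.append(
                {
                    "exon_id": exon_id,
                    "start": e.start,
                    "end": e.end,
                    "sequence": e.sequence,
                    "type": _TYPE_CODE[e.element_type],
                }
            )
    return pd.DataFrame(rows, columns=["exon_id", "start", "end", "sequence", "type"])


def distinct_element_multisets(sre_sets: Sequence[SRESet]) -> int:
    """Number of distinct element multisets across SRE sets (collections can
    re-derive the same set)."""
    return len(Counter(s.elements for s in sre_sets))
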