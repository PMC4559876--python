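"""Exon windows and the sparse k-mer x exon occurrence profile.

Regulatory-element search is restricted to a fixed window of each exon
(default the first 50 nt, optionally the last 50 nt).  The profile matrix P
is the binary relation p_ij = 1 iff k-mer y_i occurs at least once as an
exact substring of exon x_j's window; multiplicity is discarded.  T(y) is
the support of one k-mer (the exons containing it) and T(Y') the shared
support of a k-mer set — the intersection of the members' supports, which
is anti-monotone in Y' and underwrites every pruning step downstream.

Sequences are uppercased on ingestion; the ambiguity code N (or any
non-ACGT character) matches nothing, so a window position overlapping an N
can never witness an occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .errors import InputError, ParameterError, QueryError

FastaSource = Union[str, Path, Iterable]


@dataclass(frozen=True)
class ExonWindow:
    """The analysed window of one exon (<= W nt), plus provenance."""

    exon_id: str
    sequence: str  # the window itself, uppercase
    window_used: str  # "first" | "last"
    full_length: int  # length of the exon the window was cut from
    gene_id: Optional[str] = None


def window_exons(
    source: FastaSource,
    window: int = 50,
    end: str = "first",
) -> list[ExonWindow]:
    """Read exon sequences and cut the fixed analysis window from each.

    Parameters
    ----------
    source
        FASTA path (or open handle), or an iterable of Bio.SeqRecord.
    window
        Window length W in nucleotides (default 50).  An exon shorter than W
        contributes its entire sequence.
    end
        "first" takes the leading W nt, "last" the trailing W nt.

    The record ID is the first whitespace-delimited token of the header.
    Duplicate IDs are a hard error — exon supports are sets of IDs.
    """
    if end not in ("first", "last"):
        raise ParameterError(f"end must be 'first' or 'last', got {end!r}")
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        records = list(SeqIO.parse(source, "fasta"))
    else:
        records = list(source)
    if not records:
        raise InputError("no sequences found in exon input")

    out: list[ExonWindow] = []
    seen: set[str] = set()
    for rec in records:
        exon_id = rec.id
        if exon_id in seen:
            raise InputError(f"duplicate exon ID {exon_id!r}")
        seen.add(exon_id)
        seq = str(rec.seq).upper()
        win = seq[:window] if end == "first" else seq[-window:]
        out.append(
            ExonWindow(
                exon_id=exon_id,
                sequence=win,
                window_used=end,
                full_length=len(seq),
            )
        )
    return out


class ProfileMatrix:
    """Sparse binary k-mer x exon occurrence matrix.

    Stored as one support set per k-mer row; the exon universe is the full
    column set (an exon stays a column even if no k-mer occurs in it).
    """

    def __init__(self, support: Mapping[str, Iterable[str]], exons: Sequence[str]):
        self.exons: tuple[str, ...] = tuple(exons)
        universe = frozenset(self.exons)
        if len(universe) != len(self.exons):
            raise InputError("duplicate exon IDs in profile universe")
        self._support: dict[str, frozenset[str]] = {}
        for kmer, exon_ids in support.items():
            sup = frozenset(exon_ids)
            if not sup <= universe:
                raise InputError(f"support of {kmer!r} references unknown exons")
            self._support[str(kmer)] = sup
        self.kmers: tuple[str, ...] = tuple(sorted(self._support))

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.exons)

    def support(self, kmer: str) -> frozenset[str]:
        """T(y): the exons whose window contains the k-mer."""
        try:
            return self._support[kmer]
        except KeyError:
            raise QueryError(f"k-mer {kmer!r} is not a row of this profile") from None

    def shared_exons(self, kmers: Iterable[str]) -> frozenset[str]:
        """T(Y'): intersection of the members' supports.

        The empty set returns the full exon universe (the neutral element
        of intersection).
        """
        result: Optional[frozenset[str]] = None
        for kmer in kmers:
            sup = self.support(kmer)
            result = sup if result is None else (result & sup)
            if not result:
                break
        return self.universe if result is None else result

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return set(self.exons) == set(other.exons) and self._support == other._support

    def __repr__(self) -> str:  # pragma: no cover
        nnz = sum(len(s) for s in self._support.values())
        return f"ProfileMatrix({len(self.kmers)} k-mers x {len(self.exons)} exons, {nnz} entries)"

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write presence triplets ``kmer  exon_id`` (presence rows only)."""
        with open(path, "w") as fh:
            fh.write("kmer\texon_id\n")
            for kmer in self.kmers:
                for exon_id in sorted(self._support[kmer]):
                    fh.write(f"{kmer}\t{exon_id}\n")


def build_profile(sre_vertices: Iterable[str], windows: Sequence[ExonWindow]) -> ProfileMatrix:
    """Scan every window for every k-mer and assemble the profile matrix.

    Presence is exact substring matching (overlapping occurrences allowed;
    only presence/absence is kept).  A window shorter than k contributes no
    occurrences but remains a column of the matrix.
    """
    kmer_set = {str(v) for v in sre_vertices}
    if kmer_set:
        lengths = {len(v) for v in kmer_set}
        if len(lengths) != 1:
            raise InputError(f"k-mers of mixed lengths {sorted(lengths)} in one profile")
        (k,) = lengths
    else:
        k = 0

    support: dict[str, set[str]] = {v: set() for v in kmer_set}
    if k:
        for win in windows:
            seq = win.sequence
            for i in range(len(seq) - k + 1):
                sub = seq[i : i + k]
                if sub in kmer_set:
                    support[sub].add(win.exon_id)
    return ProfileMatrix(support, [w.exon_id for w in windows])


def shared_exons(matrix: ProfileMatrix, kmers: Iterable[str]) -> frozenset[str]:
    """Module-level convenience wrapper for :meth:`ProfileMatrix.shared_exons`."""
    return matrix.shared_exons(kmers)
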