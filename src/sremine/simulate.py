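"""Synthetic score tables and exon FASTA with planted co-occurring motifs.

The generator emulates the study conditions the mining pipeline expects:

* a score table over all 4^k k-mers with enhancer / silencer / neutral
  labels (defaults: 1182 enhancers and 1090 silencers, matching the scale
  of published minigene hexamer screens).  "Boost" k-mers are guaranteed to
  land inside the top-R (enhancers) or bottom-R (silencers) rank region by
  drawing their scores above/below every background score;
* exon sequences of fixed length (default 50 nt, i.e. one whole analysis
  window) of uniform random composition, with chosen motif sets planted
  together — non-overlapping — in exactly ``co_occurrence_count`` exons per
  set.  Rejection sampling keeps the planting contract exact: a background
  exon never contains a complete planted set by chance, and a planted exon
  never accidentally gains a motif from another set or an extra copy of its
  own motifs.

With no motif sets at all the output is the pure-random negative control:
sequences over {A, C, G, T} only, in which the pipeline should find no
co-occurring SRE sets at study thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .debruijn import DNA_ALPHABET
from .errors import GenerationError, InputError
from .scores import all_kmers

_MAX_TRIES = 1000


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: motif sets, how many exons co-carry each, background."""

    motif_sets: tuple[tuple[tuple[str, str], ...], ...]  # ((seq, "E"|"S"), ...) per set
    co_occurrence_count: int
    n_exons: int
    background_length: int = 50
    seed: int = 0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        for mset in self.motif_sets:
            for seq, etype in mset:
                if any(c not in "ACGT" for c in seq):
                    raise InputError(f"planted motif {seq!r} has non-ACGT characters")
                if etype not in ("E", "S"):
                    raise InputError(f"motif type must be 'E' or 'S', got {etype!r}")
        if self.motif_sets and self.co_occurrence_count > self.n_exons:
            raise InputError("co_occurrence_count exceeds n_exons")
        if len(self.motif_sets) * self.co_occurrence_count > self.n_exons:
            raise InputError("motif sets need more planted exons than n_exons provides")


def gen_score_table(
    seed: int,
    k: int = 6,
    n_enh: int = 1182,
    n_sil: int = 1090,
    boost_kmers: Sequence[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Generate a full 4^k-row score table, reproducible from ``seed``.

    Background enhancer scores are drawn uniformly in (0.05, 1.5), silencer
    scores in (-1.5, -0.05), neutral k-mers score 0.  Boost k-mers — pairs
    (kmer, "E"|"S") — receive scores in (1.6, 2.0) or (-2.0, -1.6), strictly
    beyond every background score, so they are guaranteed inside the top-R
    (resp. bottom-R) rank region for any R at least the boost count.
    """
    universe = all_kmers(k)
    if n_enh < 0 or n_sil < 0 or n_enh + n_sil > len(universe):
        raise InputError(f"n_enh + n_sil must be within [0, 4^{k}]")
    boosts: dict[str, str] = {}
    for kmer, etype in boost_kmers:
        kmer = kmer.upper()
        if len(kmer) != k or any(c not in "ACGT" for c in kmer):
            raise InputError(f"boost k-mer {kmer!r} is not a valid {k}-mer")
        if etype not in ("E", "S"):
            raise InputError(f"boost type must be 'E' or 'S', got {etype!r}")
        boosts[kmer] = etype
    n_boost_e = sum(1 for t in boosts.values() if t == "E")
    n_boost_s = sum(1 for t in boosts.values() if t == "S")
    if n_boost_e > n_enh or n_boost_s > n_sil:
        raise InputError("more boost k-mers than labelled slots of their type")

    rng = np.random.default_rng(seed)
    rest = [km for km in universe if km not in boosts]
    rng.shuffle(rest)
    enh = rest[: n_enh - n_boost_e]
    sil = rest[n_enh - n_boost_e : n_enh - n_boost_e + (n_sil - n_boost_s)]
    enh_set, sil_set = set(enh), set(sil)

    rows = []
    for km in universe:
        if km in boosts:
            if boosts[km] == "E":
                rows.append((km, float(rng.uniform(1.6, 2.0)), "E"))
            else:
                rows.append((km, float(rng.uniform(-2.0, -1.6)), "S"))
        elif km in enh_set:
            rows.append((km, float(rng.uniform(0.05, 1.5)), "E"))
        elif km in sil_set:
            rows.append((km, float(rng.uniform(-1.5, -0.05)), "S"))
        else:
            rows.append((km, 0.0, "N"))
    return pd.DataFrame(rows, columns=["kmer", "score", "label"])


def _random_seq(rng: np.random.Generator, length: int, probs: Sequence[float]) -> str:
    return "".join(rng.choice(DNA_ALPHABET, size=length, p=list(probs)))


def _contains_all(seq: str, motifs: Sequence[str]) -> bool:
    return all(m in seq for m in motifs)


def _count_overlapping(seq: str, motif: str) -> int:
    count, pos = 0, seq.find(motif)
    while pos != -1:
        count += 1
        pos = seq.find(motif, pos + 1)
    return count


def _plant(rng: np.random.Generator, background: str, motifs: Sequence[str]) -> str:
    """Overlay motifs at random non-overlapping positions in the background."""
    L = len(background)
    if sum(len(m) for m in motifs) > L:
        raise GenerationError("planted motifs do not fit in the background length")
    for _ in range(_MAX_TRIES):
        starts = sorted(
            (int(rng.integers(0, L - len(m) + 1)), i) for i, m in enumerate(motifs)
        )
        spans = [(s, s + len(motifs[i])) for s, i in starts]
        if all(spans[j][1] <= spans[j + 1][0] for j in range(len(spans) - 1)):
            chars = list(background)
            for s, i in starts:
                chars[s : s + len(motifs[i])] = motifs[i]
            return "".join(chars)
    raise GenerationError("could not place motifs without overlap")


def gen_exons(spec: PlantSpec) -> list[SeqRecord]:
    """Generate the exon set described by ``spec`` (deterministic in seed).

    Exons 1..(n_sets * count) carry the planted sets in consecutive blocks;
    the remainder are pure background.  Record IDs are ``exon_00001`` etc.;
    planted records note their set index in the description.
    """
    rng = np.random.default_rng(spec.seed)
    motif_seqs = [tuple(seq for seq, _ in mset) for mset in spec.motif_sets]

    records: list[SeqRecord] = []
    n_planted = len(spec.motif_sets) * spec.co_occurrence_count
    for i in range(spec.n_exons):
        set_idx = i // spec.co_occurrence_count if i < n_planted else None
        for attempt in range(_MAX_TRIES):
            seq = _random_seq(rng, spec.background_length, spec.base_composition)
            if set_idx is not None:
                seq = _plant(rng, seq, motif_seqs[set_idx])
                # exact planting contract: each own motif appears exactly once,
                # and no other set's full complement sneaks in
                own = motif_seqs[set_idx]
                if any(_count_overlapping(seq, m) != 1 for m in own):
                    continue
                if any(
                    _contains_all(seq, other)
                    for j, other in enumerate(motif_seqs)
                    if j != set_idx
                ):
                    continue
            else:
                if any(_contains_all(seq, mset) for mset in motif_seqs):
                    continue  # background exon may not co-carry a full set
            break
        else:
            raise GenerationError("rejection sampling failed to produce a valid exon")
        desc = f"set={set_idx}" if set_idx is not None else "background"
        records.append(
            SeqRecord(Seq(seq), id=f"exon_{i + 1:05d}", description=desc)
        )
    return records


def write_fasta(records: Sequence[SeqRecord], path: Union[str, Path]) -> None:
    """Write records as plain two-line-per-record FASTA (byte-deterministic)."""
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n{str(rec.seq)}\n")
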