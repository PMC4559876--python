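"""k-mer enrichment-score tables and score ranking.

The upstream evidence is a table assigning every k-mer a log-scale splicing
enrichment score (e.g. a minigene LEIsc-style index) and a regulatory label:
enhancer, silencer or neutral.  Neutral k-mers carry score exactly 0 by
definition; any nonzero score supplied for a neutral row is coerced to 0
before ranking.  Ranks 1..4^k are assigned in descending score order, rank 1
being the strongest enhancer evidence and rank 4^k the strongest silencer
evidence.  Score ties are broken lexicographically (A < C < G < T) so the
ranking is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .debruijn import DNA_ALPHABET
from .errors import InputError

LABEL_CODES = {"E": "enhancer", "S": "silencer", "N": "neutral"}
CODE_OF_LABEL = {v: k for k, v in LABEL_CODES.items()}


@dataclass(frozen=True)
class KmerRecord:
    """One k-mer with its enrichment score, label and descending-score rank."""

    kmer: str
    score: float
    label: str  # "enhancer" | "silencer" | "neutral"
    rank: int


def _normalize_label(raw: str) -> str:
    label = str(raw).strip()
    if label in LABEL_CODES:
        return LABEL_CODES[label]
    if label in CODE_OF_LABEL:
        return label
    raise InputError(f"unknown label {raw!r}; expected E/S/N or enhancer/silencer/neutral")


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product(DNA_ALPHABET, repeat=k)]


def read_score_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a score TSV with header columns ``kmer  score  label``."""
    df = pd.read_csv(path, sep="\t", dtype={"kmer": str, "label": str}, keep_default_na=False)
    missing = {"kmer", "score", "label"} - set(df.columns)
    if missing:
        raise InputError(f"score table {path} lacks columns: {sorted(missing)}")
    return df[["kmer", "score", "label"]]


def write_score_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    out = table.copy()
    out["label"] = [CODE_OF_LABEL.get(_normalize_label(l), "N") for l in out["label"]]
    out.to_csv(path, sep="\t", index=False)


def rank_kmers(
    scores: Union[pd.DataFrame, Iterable[tuple[str, float, str]]],
    k: int,
    fill_missing: bool = True,
) -> list[KmerRecord]:
    """Rank all 4^k k-mers by descending score.

    Parameters
    ----------
    scores
        DataFrame with columns kmer/score/label, or an iterable of
        (kmer, score, label) tuples.  Labels may be codes (E/S/N) or full
        words.
    k
        Word length; every k-mer must appear exactly once.
    fill_missing
        If True (default), k-mers absent from the table are added as neutral
        with score 0; if False their absence is an error.

    Returns
    -------
    list of KmerRecord sorted by rank (1..4^k).
    """
    if isinstance(scores, pd.DataFrame):
        rows = list(zip(scores["kmer"], scores["score"], scores["label"]))
    else:
        rows = [(km, sc, lb) for km, sc, lb in scores]

    entries: dict[str, tuple[float, str]] = {}
    for kmer, score, raw_label in rows:
        kmer = str(kmer).upper()
        if len(kmer) != k:
            raise InputError(f"k-mer {kmer!r} has length {len(kmer)}, expected {k}")
        if any(c not in "ACGT" for c in kmer):
            raise InputError(f"k-mer {kmer!r} contains characters outside {{A,C,G,T}}")
        if kmer in entries:
            raise InputError(f"duplicate k-mer row {kmer!r}")
        label = _normalize_label(raw_label)
        # neutral means "no evidence either way": score is zero by definition
        score = 0.0 if label == "neutral" else float(score)
        entries[kmer] = (score, label)

    universe = all_kmers(k)
    absent = [km for km in universe if km not in entries]
    if absent:
        if not fill_missing:
            raise InputError(f"{len(absent)} k-mers missing from the score table")
        for km in absent:
            entries[km] = (0.0, "neutral")

    ordered = sorted(entries.items(), key=lambda item: (-item[1][0], item[0]))
    return [
        KmerRecord(kmer=km, score=sc, label=lb, rank=i + 1)
        for i, (km, (sc, lb)) in enumerate(ordered)
    ]
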