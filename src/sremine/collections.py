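"""Second mining level: MCS collections via ordered set enumeration.

An *MCS collection* M is a set of at least beta mined MCSs whose shared
exon set T(M) — the intersection of the members' exon sets — has size at
least theta.  Enhancer and silencer MCSs mix freely in one collection;
that mixing is the point, since splicing outcomes hinge on the interplay
of both element types in the same exons.

Enumeration follows an ordered set-enumeration tree over MCS IDs: each
collection is extended only by IDs larger than its current maximum, so
every subset is generated exactly once, and a branch is abandoned as soon
as |T(M)| < theta (subset-infrequency pruning; sound because T(.) is
anti-monotone).  The tree is an implementation detail — the contract is
the exact set { M : |M| >= beta, |T(M)| >= theta }.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .errors import InputError, ParameterError
from .mcs import MCS


@dataclass(frozen=True)
class MCSCollection:
    """A qualifying set of MCS IDs with its shared exon set."""

    members: tuple[int, ...]  # strictly increasing MCS ids
    shared_exons: frozenset[str]

    @property
    def depth(self) -> int:
        return len(self.members)


def enumerate_collections(
    mcss: Sequence[MCS],
    theta: int,
    beta: int,
    maximal_only: bool = False,
) -> list[MCSCollection]:
    """Enumerate every MCS collection: |M| >= beta and |T(M)| >= theta.

    Parameters
    ----------
    mcss
        The combined MCS table (enhancers and silencers) with unique IDs.
    theta
        Minimum shared-exon count (>= 1).
    beta
        Minimum collection size (>= 1); beta = 2 asks for at least pairs.
    maximal_only
        If True, keep only collections with no qualifying strict superset.

    Returns
    -------
    Collections sorted by decreasing |T(M)|, then by member tuple.  All
    qualifying collections are reported, not only maximal ones, unless
    ``maximal_only`` is set.
    """
    if not isinstance(theta, int) or theta < 1:
        raise ParameterError(f"theta must be an integer >= 1, got {theta!r}")
    if not isinstance(beta, int) or beta < 1:
        raise ParameterError(f"beta must be an integer >= 1, got {beta!r}")

    ids = sorted(m.id for m in mcss)
    if len(set(ids)) != len(ids):
        raise InputError("duplicate MCS ids")
    exon_of = {m.id: m.exon_set for m in mcss}

    results: list[MCSCollection] = []

    def grow(prefix: tuple[int, ...], shared: Optional[frozenset[str]], start: int) -> None:
        for j in range(start, len(ids)):
            mid = ids[j]
            extended = exon_of[mid] if shared is None else (shared & exon_of[mid])
            if len(extended) < theta:
                continue  # this branch of the tree is pruned
            members = prefix + (mid,)
            if len(members) >= beta:
                results.append(MCSCollection(members=members, shared_exons=extended))
            grow(members, extended, j + 1)

    grow((), None, 0)

    if maximal_only:
        reported = {c.members for c in results}
        results = [
            c
            for c in results
            if not any(
                other != c.members and set(c.members) < set(other) for other in reported
            )
        ]

    results.sort(key=lambda c: (-len(c.shared_exons), c.members))
    return results


_COLUMNS = ["collection_id", "mcs_ids", "element_types", "n_shared_exons", "shared_exon_ids"]


def collection_report(
    collections: Sequence[MCSCollection],
    mcss: Iterable[MCS],
    path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Tabulate collections: member IDs, k-mer sets, types, shared-exon count.

    Rows are sorted by |T(M)| descending, then members lexicographically.
    """
    type_of = {m.id: m.element_type for m in mcss}
    ordered = sorted(collections, key=lambda c: (-len(c.shared_exons), c.members))
    rows = [
        {
            "collection_id": i + 1,
            "mcs_ids": ",".join(str(m) for m in c.members),
            "element_types": ",".join(type_of[m] for m in c.members),
            "n_shared_exons": len(c.shared_exons),
            "shared_exon_ids": ",".join(sorted(c.shared_exons)),
        }
        for i, c in enumerate(ordered)
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def read_collections(path: Union[str, Path]) -> list[MCSCollection]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"collections table {path} lacks columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        members = tuple(int(x) for x in row["mcs_ids"].split(","))
        exons = frozenset(x for x in row["shared_exon_ids"].split(",") if x)
        if len(exons) != int(row["n_shared_exons"]):
            raise InputError(
                f"collection {row['collection_id']}: n_shared_exons disagrees with IDs"
            )
        out.append(MCSCollection(members=members, shared_exons=exons))
    return out
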