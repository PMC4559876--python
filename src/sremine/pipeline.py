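"""End-to-end orchestration: scores + exons -> SRE graphs -> profiles ->
MCSs -> collections -> SRE sets.

The cohesive-subgraph miner runs twice — once on the enhancer graph with
its profile, once on the silencer graph — against the SAME exon windows,
so shared-exon intersections across element types are well defined.  The
union of both MCS lists (re-identified in canonical order) feeds one
shared set-enumeration pass, whose collections are then filtered into
final SRE sets under both overlap interpretations (merged and unmerged).

Every stage output is written as TSV with deterministic row order, and the
run log records parameters and stage counts; identical inputs and
configuration reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .collections import MCSCollection, collection_report, enumerate_collections
from .debruijn import build_debruijn, build_sre_graph
from .errors import InputError, ParameterError
from .filtering import (
    SRESet,
    distinct_element_multisets,
    merge_and_emit,
    spell_mcs,
    write_sre_sets,
)
from .mcs import MCS, combine_mcs, mine_mcs, write_mcs_table
from .profile import build_profile, window_exons
from .scores import rank_kmers, read_score_table


@dataclass
class RunConfig:
    """All run parameters; defaults are the reference study conditions."""

    scores: Union[str, Path, pd.DataFrame]
    exons: Union[str, Path, Sequence]
    out_dir: Optional[Union[str, Path]] = None
    k: int = 6
    rank_r: int = 400
    alpha: int = 1000
    theta: int = 100
    beta: int = 2
    window: int = 50
    window_end: str = "first"
    merge_same_type: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "theta", "beta"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not 1 <= self.rank_r <= 4**self.k:
            raise ParameterError(f"rank_r must be in [1, 4^k]")
        if self.window < self.k:
            raise ParameterError(f"window ({self.window}) must be >= k ({self.k})")
        if self.window_end not in ("first", "last"):
            raise ParameterError("window_end must be 'first' or 'last'")


@dataclass
class RunArtifacts:
    """Everything a run produced, in memory plus (optionally) on disk."""

    config: RunConfig
    mcss: list[MCS]
    collections: list[MCSCollection]
    sre_sets_merged: list[SRESet]
    sre_sets_unmerged: list[SRESet]
    counts: dict[str, int] = field(default_factory=dict)
    out_dir: Optional[Path] = None

    @property
    def sre_sets(self) -> list[SRESet]:
        """The interpretation selected by the run configuration."""
        return self.sre_sets_merged if self.config.merge_same_type else self.sre_sets_unmerged


def run_pipeline(config: RunConfig) -> RunArtifacts:
    """Run the full two-level mining pipeline under ``config``.

    Raises
    ------
    InputError / ParameterError with a stage-labelled message on bad inputs.
    """
    log_lines: list[str] = [f"sremine {__version__}"]

    def log(msg: str) -> None:
        log_lines.append(msg)

    cfg = config
    log(
        "parameters: "
        f"k={cfg.k} R={cfg.rank_r} alpha={cfg.alpha} theta={cfg.theta} "
        f"beta={cfg.beta} window={cfg.window} window_end={cfg.window_end} "
        f"merge_same_type={cfg.merge_same_type} seed={cfg.seed}"
    )

    # stage 1: score ranking and SRE graphs
    try:
        table = cfg.scores if isinstance(cfg.scores, pd.DataFrame) else read_score_table(cfg.scores)
        debruijn = build_debruijn(cfg.k)
        ranked = rank_kmers(table, cfg.k)
    except InputError as exc:
        raise InputError(f"[scores] {exc}") from exc
    enhancer_graph = build_sre_graph(debruijn, ranked, cfg.rank_r, "top")
    silencer_graph = build_sre_graph(debruijn, ranked, cfg.rank_r, "bottom")
    log(f"sre-graphs: {len(enhancer_graph.vertex_set)} enhancer vertices, "
        f"{len(silencer_graph.vertex_set)} silencer vertices")

    # stage 2: exon windows and the two profiles (same exon universe)
    try:
        windows = window_exons(cfg.exons, window=cfg.window, end=cfg.window_end)
    except InputError as exc:
        raise InputError(f"[exons] {exc}") from exc
    profile_e = build_profile(enhancer_graph.vertex_set, windows)
    profile_s = build_profile(silencer_graph.vertex_set, windows)
    log(f"profile: {len(windows)} exon windows")

    # stage 3: cohesive subgraph mining, one run per element type
    mcs_e = mine_mcs(enhancer_graph, profile_e, cfg.alpha)
    mcs_s = mine_mcs(silencer_graph, profile_s, cfg.alpha)
    mcss = combine_mcs(mcs_e, mcs_s)
    log(f"mcs: {len(mcs_e)} enhancer + {len(mcs_s)} silencer = {len(mcss)} total")

    # stage 4: one shared set-enumeration pass over the combined MCS table
    collections = enumerate_collections(mcss, theta=cfg.theta, beta=cfg.beta)
    log(f"collections: {len(collections)}")

    # stage 5: spelling, locating, overlap merging — both interpretations
    spelled = {m.id: spell_mcs(m) for m in mcss}
    windows_by_id = {w.exon_id: w for w in windows}
    merged: list[SRESet] = []
    unmerged: list[SRESet] = []
    for coll in collections:
        merged.extend(
            merge_and_emit(coll, spelled, windows_by_id, cfg.theta, merge_same_type=True)
        )
        unmerged.extend(
            merge_and_emit(coll, spelled, windows_by_id, cfg.theta, merge_same_type=False)
        )
    merged.sort(key=lambda s: (-s.n_supporting_exons, s.elements, s.source_members))
    unmerged.sort(key=lambda s: (-s.n_supporting_exons, s.elements, s.source_members))
    log(
        f"sre-sets: {len(merged)} merged ({distinct_element_multisets(merged)} distinct), "
        f"{len(unmerged)} unmerged ({distinct_element_multisets(unmerged)} distinct)"
    )
    log(
        "note: to gauge significance, rerun on the same number of pure-random "
        "windows (simulate-exons with no planted motifs, several seeds) and "
        "check that the final SRE-set table is empty"
    )

    counts = {
        "n_exons": len(windows),
        "mcs_enhancer": len(mcs_e),
        "mcs_silencer": len(mcs_s),
        "mcs_total": len(mcss),
        "collections": len(collections),
        "sre_sets_merged": len(merged),
        "sre_sets_unmerged": len(unmerged),
        "distinct_sre_sets_merged": distinct_element_multisets(merged),
        "distinct_sre_sets_unmerged": distinct_element_multisets(unmerged),
    }

    artifacts = RunArtifacts(
        config=cfg,
        mcss=mcss,
        collections=collections,
        sre_sets_merged=merged,
        sre_sets_unmerged=unmerged,
        counts=counts,
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mcs_table(mcss, out / "mcstable.tsv")
        collection_report(collections, mcss, out / "collections.tsv")
        write_sre_sets(merged, out / "sre_sets_merged.tsv")
        write_sre_sets(unmerged, out / "sre_sets_unmerged.tsv")
        summarize_run(artifacts).to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        artifacts.out_dir = out

    return artifacts


def summarize_run(artifacts: RunArtifacts) -> pd.DataFrame:
    """Per-stage counts as a two-column table (stage, count)."""
    return pd.DataFrame(
        [{"stage": key, "count": value} for key, value in artifacts.counts.items()],
        columns=["stage", "count"],
    )
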