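"""Spelling, occurrence location, overlap merging and SRE-set emission."""

import numpy as np
import pytest

from sremine import (
    MCSCollection,
    PlacedElement,
    SpelledSequence,
    ExonWindow,
    exon_layout,
    locate_occurrences,
    merge_and_emit,
    merge_same_type_occurrences,
    spell_mcs,
)
from conftest import make_mcs


def window(seq: str, exon_id: str = "e1") -> ExonWindow:
    return ExonWindow(exon_id=exon_id, sequence=seq, window_used="first", full_length=len(seq))


def spelled(*seqs: str, element_type: str = "enhancer", source: int = 1):
    return [SpelledSequence(s, element_type, source) for s in seqs]


class TestSpelling:
    def test_two_overlapping_6mers_spell_a_7mer(self):
        mcs = make_mcs(1, {"GTCATC", "TCATCC"}, {"x1"})
        (result,) = spell_mcs(mcs)
        assert result.sequence == "GTCATCC"
        assert len(result.sequence) == 7

    def test_singleton_spells_itself(self):
        mcs = make_mcs(1, {"AGAGGA"}, {"x1"})
        (result,) = spell_mcs(mcs)
        assert result.sequence == "AGAGGA"

    @pytest.mark.parametrize("m", [2, 3, 4, 6])
    def test_chain_of_m_6mers_spells_m_plus_5(self, m):
        base = "ACGTCAGGTACG"  # no repeated 6-mer within the first m+5 chars
        kmers = {base[i : i + 6] for i in range(m)}
        mcs = make_mcs(1, kmers, {"x1"})
        (result,) = spell_mcs(mcs)
        assert result.sequence == base[: m + 5]
        assert len(result.sequence) == m + 5

    def test_subsumed_spellings_removed(self):
        # AAC->ACG->CGT: every sub-path spelling is a substring of AACGT
        mcs = make_mcs(1, {"AAC", "ACG", "CGT"}, {"x1"})
        assert [s.sequence for s in spell_mcs(mcs)] == ["AACGT"]

    def test_branching_subgraph_spells_all_maximal_paths(self):
        # ACG forks to CGA and CGT
        mcs = make_mcs(1, {"ACG", "CGA", "CGT"}, {"x1"})
        assert {s.sequence for s in spell_mcs(mcs)} == {"ACGA", "ACGT"}

    def test_self_loop_ignored(self):
        mcs = make_mcs(1, {"AAA", "AAC"}, {"x1"})
        assert {s.sequence for s in spell_mcs(mcs)} == {"AAAC"}

    def test_spelling_carries_type_and_source(self):
        mcs = make_mcs(7, {"GTCATC"}, {"x1"}, element_type="silencer")
        (result,) = spell_mcs(mcs)
        assert result.element_type == "silencer" and result.source_mcs == 7


class TestLocate:
    def test_single_hit_with_one_based_coordinates(self):
        hits = locate_occurrences(spelled("GGGAGG"), window("AAGGGAGGAC"))
        assert hits == [(0, 3, 8)]

    def test_no_hits(self):
        assert locate_occurrences(spelled("GGGAGG"), window("ACACAC")) == []

    def test_overlapping_occurrences_all_reported(self):
        hits = locate_occurrences(spelled("AAA"), window("AAAAA"))
        assert hits == [(0, 1, 3), (0, 2, 4), (0, 3, 5)]

    def test_matches_naive_scan(self, rng):
        seqs = spelled(
            *{"".join(rng.choice(list("ACGT"), size=int(rng.integers(3, 7)))) for _ in range(20)}
        )
        for _ in range(100):
            text = "".join(rng.choice(list("ACGT"), size=50))
            hits = locate_occurrences(seqs, window(text))
            naive = [
                (i, j + 1, j + len(s.sequence))
                for i, s in enumerate(seqs)
                for j in range(50 - len(s.sequence) + 1)
                if text[j : j + len(s.sequence)] == s.sequence
            ]
            assert sorted(hits) == sorted(naive)


class TestMerging:
    def test_four_chained_6mers_merge_to_one_9mer(self):
        lay = exon_layout(
            spelled("CCCGGA", "CCGGAG", "CGGAGC", "GGAGCC"),
            window("TTCCCGGAGCCTT"),
        )
        assert [(e.sequence, e.start, e.end) for e in lay] == [("CCCGGAGCC", 3, 11)]

    def test_partial_merge_yields_8mer_and_separate_6mer(self):
        lay = exon_layout(
            spelled("CCCGGA", "CCGGAG", "CGGAGC", "GGAGCC"),
            window("CCCGGAGCTTTTGGAGCCTT"),
        )
        assert [(e.sequence, e.start, e.end) for e in lay] == [
            ("CCCGGAGC", 1, 8),
            ("GGAGCC", 13, 18),
        ]

    def test_merge_span_law(self):
        merged = merge_same_type_occurrences(
            [
                PlacedElement("AAAA", "enhancer", 2, 5),
                PlacedElement("AACC", "enhancer", 4, 7),
            ],
            "TAAAACCGG",
        )
        (element,) = merged
        assert (element.start, element.end) == (2, 7)
        assert element.sequence == "AAAACC"
        assert len(element.sequence) == 7 - 2 + 1

    def test_adjacency_without_overlap_does_not_merge(self):
        merged = merge_same_type_occurrences(
            [
                PlacedElement("AAA", "enhancer", 1, 3),
                PlacedElement("CCC", "enhancer", 4, 6),
            ],
            "AAACCCGG",
        )
        assert len(merged) == 2

    def test_different_types_never_merge(self):
        lay = exon_layout(
            spelled("GGGAGG") + spelled("GAGGAC", element_type="silencer", source=2),
            window("TTGGGAGGACTT"),
        )
        assert {(e.sequence, e.element_type) for e in lay} == {
            ("GGGAGG", "enhancer"),
            ("GAGGAC", "silencer"),
        }

    def test_merge_is_transitive_across_a_chain(self):
        # A overlaps B, B overlaps C, A does not touch C: still one element
        merged = merge_same_type_occurrences(
            [
                PlacedElement("AAAA", "enhancer", 1, 4),
                PlacedElement("AACC", "enhancer", 3, 6),
                PlacedElement("CCGG", "enhancer", 5, 8),
            ],
            "AAAACCGGTT",
        )
        assert [(e.start, e.end) for e in merged] == [(1, 8)]


class TestEmission:
    def _setup_pair(self, n_exons=5):
        """Planted GGGAGG (enhancer) + GAGGAC (silencer), never overlapping."""
        mcss = [
            make_mcs(1, {"GGGAGG"}, {f"e{i}" for i in range(n_exons)}),
            make_mcs(2, {"GAGGAC"}, {f"e{i}" for i in range(n_exons)}, element_type="silencer"),
        ]
        coll = MCSCollection(
            members=(1, 2), shared_exons=frozenset(f"e{i}" for i in range(n_exons))
        )
        spelled_map = {m.id: spell_mcs(m) for m in mcss}
        windows = {
            f"e{i}": window("TTGGGAGGTTTTGAGGACTT", exon_id=f"e{i}")
            for i in range(n_exons)
        }
        return coll, spelled_map, windows

    def test_non_overlapping_pair_passes_through(self):
        coll, spelled_map, windows = self._setup_pair()
        (result,) = merge_and_emit(coll, spelled_map, windows, theta=5)
        assert result.elements == (
            ("GAGGAC", "silencer"),
            ("GGGAGG", "enhancer"),
        )
        assert result.n_supporting_exons == 5
        assert result.supporting_exons <= coll.shared_exons
        assert result.source_members == (1, 2)

    def test_theta_above_support_emits_nothing(self):
        coll, spelled_map, windows = self._setup_pair()
        assert merge_and_emit(coll, spelled_map, windows, theta=6) == []

    def test_fully_merged_same_type_layout_is_eliminated(self):
        # both enhancer 6-mers overlap everywhere -> single long element -> no set
        mcss = [
            make_mcs(1, {"CCCGGA"}, {"e0"}),
            make_mcs(2, {"CCGGAG"}, {"e0"}),
        ]
        coll = MCSCollection(members=(1, 2), shared_exons=frozenset({"e0"}))
        spelled_map = {m.id: spell_mcs(m) for m in mcss}
        windows = {"e0": window("TTCCCGGAGTT", exon_id="e0")}
        assert merge_and_emit(coll, spelled_map, windows, theta=1) == []

    def test_unmerged_interpretation_keeps_sequences_verbatim(self):
        mcss = [make_mcs(1, {"CCCGGA"}, {"e0"}), make_mcs(2, {"CCGGAG"}, {"e0"})]
        coll = MCSCollection(members=(1, 2), shared_exons=frozenset({"e0"}))
        spelled_map = {m.id: spell_mcs(m) for m in mcss}
        windows = {"e0": window("TTCCCGGAGTT", exon_id="e0")}
        (result,) = merge_and_emit(coll, spelled_map, windows, theta=1, merge_same_type=False)
        assert result.elements == (
            ("CCCGGA", "enhancer"),
            ("CCGGAG", "enhancer"),
        )

    def test_enhancer_silencer_overlap_kept_unmerged(self):
        mcss = [
            make_mcs(1, {"GGGAGG"}, {"e0"}),
            make_mcs(2, {"GAGGAC"}, {"e0"}, element_type="silencer"),
        ]
        coll = MCSCollection(members=(1, 2), shared_exons=frozenset({"e0"}))
        spelled_map = {m.id: spell_mcs(m) for m in mcss}
        # overlapping arrangement GGGAGGACA from the two elements
        windows = {"e0": window("TTGGGAGGACATT", exon_id="e0")}
        (result,) = merge_and_emit(coll, spelled_map, windows, theta=1)
        assert result.elements == (
            ("GAGGAC", "silencer"),
            ("GGGAGG", "enhancer"),
        )

    def test_per_exon_layouts_split_into_multiple_sets(self):
        """Different exons with different overlap patterns yield distinct sets."""
        mcss = [make_mcs(i + 1, {km}, {"e0", "e1"}) for i, km in enumerate(
            ["CCCGGA", "CCGGAG", "CGGAGC", "GGAGCC"]
        )]
        coll = MCSCollection(members=(1, 2, 3, 4), shared_exons=frozenset({"e0", "e1"}))
        spelled_map = {m.id: spell_mcs(m) for m in mcss}
        windows = {
            "e0": window("TTCCCGGAGCCTT", exon_id="e0"),  # all four chain: one 9-mer
            "e1": window("CCCGGAGCTTTTGGAGCCTT", exon_id="e1"),  # 8-mer + 6-mer
        }
        results = merge_and_emit(coll, spelled_map, windows, theta=1)
        assert [r.elements for r in results] == [
            (("CCCGGAGC", "enhancer"), ("GGAGCC", "enhancer"))
        ]
        assert results[0].supporting_exons == frozenset({"e1"})

    def test_empty_spelled_input_gives_empty_result(self):
        coll = MCSCollection(members=(1,), shared_exons=frozenset({"e0"}))
        assert merge_and_emit(coll, {}, {"e0": window("ACGT", "e0")}, theta=1) == []
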