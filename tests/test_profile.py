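"""Exon windows, the occurrence profile, and shared-exon queries."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sremine import (
    InputError,
    ParameterError,
    ProfileMatrix,
    QueryError,
    build_profile,
    shared_exons,
    window_exons,
)


def fasta(*records: tuple[str, str]) -> io.StringIO:
    return io.StringIO("".join(f">{name}\n{seq}\n" for name, seq in records))


class TestWindowing:
    def test_first_window_of_long_exon(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        (win,) = window_exons(fasta(("e1", seq)), window=50, end="first")
        assert win.sequence == seq[:50]
        assert win.full_length == 80

    def test_short_exon_kept_whole(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        (win,) = window_exons(fasta(("e1", seq)), window=50, end="first")
        assert win.sequence == seq

    def test_last_window_takes_trailing_positions(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=80))
        (win,) = window_exons(fasta(("e1", seq)), window=50, end="last")
        assert win.sequence == seq[30:]  # 1-based positions 31..80

    def test_sequences_uppercased(self):
        (win,) = window_exons(fasta(("e1", "acgtacgt")), window=50)
        assert win.sequence == "ACGTACGT"

    def test_empty_fasta_rejected(self):
        with pytest.raises(InputError):
            window_exons(fasta(), window=50)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError):
            window_exons(fasta(("e1", "ACGT"), ("e1", "ACGT")))

    def test_bad_end_rejected(self):
        with pytest.raises(ParameterError):
            window_exons(fasta(("e1", "ACGT")), end="middle")


class TestProfile:
    def test_substring_presence(self):
        windows = window_exons(fasta(("e1", "AAGTCATCAAGG")), window=50)
        matrix = build_profile({"GTCATC"}, windows)
        assert matrix.support("GTCATC") == frozenset({"e1"})

    def test_absent_kmer_empty_support(self):
        windows = window_exons(fasta(("e1", "AAAAAAAA")), window=50)
        matrix = build_profile({"GTCATC"}, windows)
        assert matrix.support("GTCATC") == frozenset()

    def test_n_matches_nothing(self):
        # positions overlapping an ambiguity code can never witness a k-mer
        windows = window_exons(fasta(("e1", "AAGTCNTCAA")), window=50)
        matrix = build_profile({"GTCATC", "GTCCTC", "GTCGTC", "GTCTTC"}, windows)
        assert all(matrix.support(km) == frozenset() for km in matrix.kmers)

    def test_window_shorter_than_k_contributes_nothing(self):
        windows = window_exons(fasta(("e1", "ACG"), ("e2", "AAGTCATC")), window=50)
        matrix = build_profile({"GTCATC"}, windows)
        assert matrix.support("GTCATC") == frozenset({"e2"})
        assert "e1" in matrix.universe  # still a column

    def test_matches_naive_per_pair_scan(self, rng):
        kmers = {
            "".join(rng.choice(list("ACGT"), size=4)) for _ in range(50)
        }
        records = [
            (f"e{j}", "".join(rng.choice(list("ACGT"), size=50))) for j in range(200)
        ]
        windows = window_exons(fasta(*records), window=50)
        matrix = build_profile(kmers, windows)
        for kmer in kmers:
            naive = {name for name, seq in records if kmer in seq}
            assert matrix.support(kmer) == naive

    def test_invariant_to_record_order_and_case(self, rng):
        records = [
            (f"e{j}", "".join(rng.choice(list("ACGT"), size=30))) for j in range(30)
        ]
        kmers = {records[0][1][:5], records[5][1][10:15]}
        m1 = build_profile(kmers, window_exons(fasta(*records)))
        lowered = [(n, s.lower()) for n, s in reversed(records)]
        m2 = build_profile(kmers, window_exons(fasta(*lowered)))
        assert m1 == m2

    def test_mixed_kmer_lengths_rejected(self):
        windows = window_exons(fasta(("e1", "ACGTACGT")))
        with pytest.raises(InputError):
            build_profile({"ACG", "ACGT"}, windows)

    def test_empty_vertex_set_gives_empty_matrix(self):
        windows = window_exons(fasta(("e1", "ACGT")))
        matrix = build_profile(set(), windows)
        assert matrix.kmers == ()
        assert matrix.shared_exons([]) == frozenset({"e1"})


class TestSharedExons:
    def _matrix(self):
        return ProfileMatrix(
            {"AAA": {"x1", "x2"}, "CCC": {"x2", "x3"}, "GGG": {"x4"}},
            ["x1", "x2", "x3", "x4"],
        )

    def test_singleton_is_support(self):
        m = self._matrix()
        assert shared_exons(m, {"AAA"}) == m.support("AAA")

    def test_disjoint_supports_empty(self):
        assert shared_exons(self._matrix(), {"AAA", "GGG"}) == frozenset()

    def test_empty_query_returns_universe(self):
        m = self._matrix()
        assert shared_exons(m, set()) == m.universe

    def test_unknown_kmer_rejected(self):
        with pytest.raises(QueryError):
            shared_exons(self._matrix(), {"TTT"})

    @settings(deadline=None, derandomize=True)
    @given(
        supports=st.lists(
            st.sets(st.integers(0, 11), max_size=12), min_size=1, max_size=6
        ),
        split=st.integers(0, 5),
    )
    def test_anti_monotone_in_query_set(self, supports, split):
        """Y' subset of Y'' implies T(Y'') subset of T(Y')."""
        exons = [f"x{j}" for j in range(12)]
        kmers = [f"K{i}" for i in range(len(supports))]
        m = ProfileMatrix(
            {km: {f"x{j}" for j in sup} for km, sup in zip(kmers, supports)}, exons
        )
        smaller = set(kmers[: min(split, len(kmers))])
        assert m.shared_exons(set(kmers)) <= m.shared_exons(smaller)
        inter = frozenset(exons)
        for km in kmers:
            inter &= m.support(km)
        assert m.shared_exons(set(kmers)) == inter
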