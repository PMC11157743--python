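"""Pileup voting, strict-majority consensus, placeholder filling, splits."""

from collections import Counter
from itertools import product

import pytest
from hypothesis import given, settings, strategies as st

from nmthc.corpus import (
    GAP,
    JunctionVotes,
    PileupColumn,
    SentencePair,
    build_corpus,
    build_pileup,
    build_sentence_pair,
    call_consensus,
    fill_placeholders,
    majority_call,
    split_corpus,
)
from nmthc.io_formats import AlignmentRecord, SequenceRecord, parse_extended_cigar
from nmthc.simulate import ERROR_FREE, simulate_dataset, uniform_profile


class TestBuildPileup:
    def test_three_read_worked_example(self, worked_example):
        """Substitution votes at 9-10 from two reads, GAP votes at 11-13
        from every covering read, insertion votes at the 19|20 junction."""
        long_read, alignments = worked_example
        columns, junctions = build_pileup(long_read, alignments)
        assert columns[8].votes == Counter({"A": 2})
        assert columns[9].votes == Counter({"C": 2})
        for pos in (11, 12, 13):
            votes = columns[pos - 1].votes
            assert set(votes) == {GAP}
            assert sum(votes.values()) == {11: 3, 12: 3, 13: 3}[pos]
        j19 = next(j for j in junctions if j.after_pos == 19)
        assert j19.votes == Counter({"AACA": 3})

    def test_no_alignments(self):
        read = SequenceRecord(id="r", bases="ACGTACGT")
        columns, junctions = build_pileup(read, [])
        assert all(not c.votes for c in columns)
        assert junctions == []

    def test_perfect_alignment_votes(self):
        read = SequenceRecord(id="r", bases="ACG")
        aln = AlignmentRecord("s", "r", parse_extended_cigar("1:3M"), "ACG")
        columns, junctions = build_pileup(read, [aln])
        assert [c.votes for c in columns] == [
            Counter({"A": 1}), Counter({"C": 1}), Counter({"G": 1})
        ]
        # both interior junctions are spanned but carry only empty votes
        assert all(set(j.votes) == {""} for j in junctions)

    def test_out_of_bounds_alignment_rejected(self):
        read = SequenceRecord(id="r", bases="ACG")
        aln = AlignmentRecord("s", "r", parse_extended_cigar("2:3M"), "CGT")
        with pytest.raises(ValueError, match="spans"):
            build_pileup(read, [aln])


def _bruteforce_majority(votes: Counter, default):
    """Independent oracle: scan all candidates, demand a unique maximum."""
    best, best_count = default, 0
    tie = False
    for cand, count in votes.items():
        if count > best_count:
            best, best_count, tie = cand, count, False
        elif count == best_count and best_count > 0:
            tie = True
    return default if tie else best


class TestCallConsensus:
    def test_substitution_majority_beats_original(self):
        col = PileupColumn(pos=9, original="G", votes=Counter({"A": 2}))
        calls, _ = call_consensus([col], [])
        assert calls == ["A"]

    def test_uncovered_column_keeps_original(self):
        col = PileupColumn(pos=1, original="T", votes=Counter())
        assert call_consensus([col], [])[0] == ["T"]

    def test_tie_keeps_original_and_unanimous_gap_deletes(self):
        tie = PileupColumn(pos=1, original="G", votes=Counter({"A": 1, "G": 1}))
        gap = PileupColumn(pos=2, original="G", votes=Counter({GAP: 3}))
        calls, _ = call_consensus([tie, gap], [])
        assert calls == ["G", GAP]
        junc = JunctionVotes(after_pos=1, votes=Counter({"AACA": 3}))
        assert call_consensus([], [junc])[1] == {1: "AACA"}

    def test_exhaustive_vote_multisets_match_bruteforce(self):
        """Every column-vote multiset of size <= 4 over {A,C,G,T,GAP}
        agrees with the brute-force majority oracle."""
        symbols = ["A", "C", "G", "T", GAP]
        for size in range(5):
            for combo in product(symbols, repeat=size):
                votes = Counter(combo)
                col = PileupColumn(pos=1, original="T", votes=votes)
                calls, _ = call_consensus([col], [])
                assert calls[0] == _bruteforce_majority(votes, "T"), votes

    def test_junction_multisets_match_bruteforce(self):
        symbols = ["", "A", "AC", "AACA"]
        for size in range(4):
            for combo in product(symbols, repeat=size):
                votes = Counter(combo)
                junc = JunctionVotes(after_pos=3, votes=votes)
                _, calls = call_consensus([], [junc])
                expect = _bruteforce_majority(votes, "")
                assert calls.get(3, "") == expect, votes


class TestFillPlaceholders:
    def test_worked_example_pair(self, worked_example):
        """Deletion calls put '$$$' in the target under original ATC;
        the AACA insertion puts '$$$$' in the source."""
        long_read, alignments = worked_example
        pair = build_sentence_pair(long_read, alignments)
        assert len(pair.source) == len(pair.target)
        assert pair.source.replace("$", "") == long_read.bases
        # columns 9,10 replaced G,T -> A,C; 11-13 deleted; AACA inserted
        assert pair.source == "CATGACGAGTATCGCTACG$$$$TC"
        assert pair.target == "CATGACGAAC" + "$$$" + "GCTACG" + "AACA" + "TC"

    def test_identity_consensus(self):
        read = SequenceRecord(id="r", bases="ACGT")
        pair = fill_placeholders(read, list("ACGT"), {})
        assert pair.source == pair.target == "ACGT"

    def test_single_gap_call(self):
        read = SequenceRecord(id="r", bases="ACGT")
        pair = fill_placeholders(read, ["A", GAP, "G", "T"], {})
        assert pair.source == "ACGT"
        assert pair.target == "A$GT"


class TestSentencePairInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fuzzed_simulated_reads(self, seed):
        """len(source)==len(target); '$'-stripped source is the raw read;
        '$'-stripped target is over {A,C,G,T}."""
        ds = simulate_dataset(genome_len=600, n_long=15, len_range=(60, 120),
                              long_profile=uniform_profile(0.12),
                              coverage=8, seed=seed)
        from nmthc.io_formats import sam_to_alignments
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            ds.write(d)
            alns = sam_to_alignments(os.path.join(d, "truth.sam"),
                                     {r.id: r for r in ds.long_reads})
        raw = {r.id: r.bases for r in ds.long_reads}
        pairs = build_corpus(ds.long_reads, alns)
        assert len(pairs) == len(ds.long_reads)
        for p in pairs:
            assert len(p.source) == len(p.target)
            assert p.source.replace("$", "") == raw[p.read_id]
            assert set(p.target.replace("$", "")) <= set("ACGT")

    def test_double_placeholder_column_rejected(self):
        with pytest.raises(ValueError, match="both"):
            SentencePair("r", "A$G", "A$G", 0.0)


class TestSplitCorpus:
    @staticmethod
    def _pairs(n):
        return [SentencePair(f"r{i}", "ACG", "ACG", 1.0) for i in range(n)]

    @pytest.mark.parametrize("n,sizes", [(10, (8, 1, 1)), (1, (1, 0, 0)),
                                         (1000, (800, 100, 100))])
    def test_sizes(self, n, sizes):
        split = split_corpus(self._pairs(n), seed=5)
        assert (len(split.train), len(split.validation), len(split.test)) == sizes

    def test_deterministic_and_seed_sensitive(self):
        pairs = self._pairs(40)
        a = split_corpus(pairs, seed=1)
        b = split_corpus(pairs, seed=1)
        c = split_corpus(pairs, seed=2)
        key = lambda s: [p.read_id for p in s.train + s.validation + s.test]
        assert key(a) == key(b)
        assert key(a) != key(c)

    def test_partition(self):
        pairs = self._pairs(37)
        split = split_corpus(pairs, seed=9)
        ids = [p.read_id for p in split.train + split.validation + split.test]
        assert sorted(ids) == sorted(p.read_id for p in pairs)
        assert len(set(ids)) == len(ids)

    def test_duplicate_ids_rejected(self):
        pairs = self._pairs(3) + self._pairs(1)
        with pytest.raises(ValueError, match="duplicate"):
            split_corpus(pairs)


def test_error_free_short_reads_recover_truth():
    """With error-free short reads at high coverage, the '$'-stripped
    consensus target equals every long read's truth bases."""
    ds = simulate_dataset(genome_len=800, n_long=20, len_range=(80, 150),
                          long_profile=uniform_profile(0.10),
                          coverage=30, short_profile=ERROR_FREE, seed=11)
    from nmthc.io_formats import sam_to_alignments
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        ds.write(d)
        alns = sam_to_alignments(os.path.join(d, "truth.sam"),
                                 {r.id: r for r in ds.long_reads})
    pairs = build_corpus(ds.long_reads, alns)
    truth = ds.truth_by_id
    assert all(p.target.replace("$", "") == truth[p.read_id] for p in pairs)
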