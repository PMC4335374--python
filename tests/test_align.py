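"""Aligner: oracle score equivalence, operations, full-length rule, pileup."""

import numpy as np
import pytest

from ampliclone import align
from ampliclone.align import GapParams, align_read, align_reads, classify_full_length, pileup, semi_global
from ampliclone.reads import CcsRead
from ampliclone.refmodel import revcomp

from conftest import random_dna
from _oracles import gotoh_overlap_score


def mutate(rng, seq, n_sub=0, n_ins=0, n_del=0):
    s = list(seq)
    for _ in range(n_sub):
        i = int(rng.integers(0, len(s)))
        s[i] = "ACGT"[(("ACGT".index(s[i])) + 1 + int(rng.integers(0, 3))) % 4]
    for _ in range(n_del):
        del s[int(rng.integers(0, len(s)))]
    for _ in range(n_ins):
        s.insert(int(rng.integers(0, len(s) + 1)), "ACGT"[int(rng.integers(0, 4))])
    return "".join(s)


class TestScoreOracle:
    """The production aligner's score equals an exhaustive full-matrix DP."""

    @pytest.mark.parametrize("case", range(12))
    def test_related_pairs(self, case):
        rng = np.random.default_rng(1000 + case)
        ref = random_dna(rng, int(rng.integers(60, 300)))
        read = mutate(
            rng, ref,
            n_sub=int(rng.integers(0, 10)),
            n_ins=int(rng.integers(0, 6)),
            n_del=int(rng.integers(0, 6)),
        )
        score, *_ = semi_global(read, ref)
        assert score == gotoh_overlap_score(read, ref)

    @pytest.mark.parametrize("case", range(6))
    def test_unrelated_random_pairs(self, case):
        rng = np.random.default_rng(2000 + case)
        ref = random_dna(rng, int(rng.integers(40, 200)))
        read = random_dna(rng, int(rng.integers(40, 200)))
        score, *_ = semi_global(read, ref)
        assert score == gotoh_overlap_score(read, ref)

    @pytest.mark.parametrize("case", range(4))
    def test_reads_with_large_insertions(self, case):
        rng = np.random.default_rng(3000 + case)
        ref = random_dna(rng, 250)
        pos = int(rng.integers(20, 230))
        insert = random_dna(rng, int(rng.integers(20, 60)))
        read = ref[:pos] + insert + ref[pos:]
        score, *_ = semi_global(read, ref)
        assert score == gotoh_overlap_score(read, ref)

    @pytest.mark.parametrize("case", range(4))
    def test_align_read_banded_path_matches_oracle(self, case):
        # exercise the heuristic band sizing + retry through align_read itself
        from ampliclone.refmodel import Exon, Gene, build_transcript, in_silico_pcr, revcomp

        rng = np.random.default_rng(4000 + case)
        ref = random_dna(rng, 280)
        model = build_transcript([Exon(Gene.BCR, "BCR-e13", 13, ref)], "e13a2")
        amp = in_silico_pcr(model, ref[:15], revcomp(ref[-15:]))
        read = mutate(rng, ref, n_sub=8, n_ins=4, n_del=4)
        rec = align_read(CcsRead("r", read), amp)
        assert rec.score == gotoh_overlap_score(read, ref)

    def test_score_run_length_consistency(self):
        rng = np.random.default_rng(42)
        ref = random_dna(rng, 200)
        read = mutate(rng, ref, n_sub=4, n_ins=2, n_del=2)
        score, ops, rs, re, qs, qe = semi_global(read, ref)
        p = GapParams()
        total = 0
        for op, ln in ops:
            if op == "=":
                total += p.match * ln
            elif op == "X":
                total += p.mismatch * ln
            else:
                total += p.gap_open + p.gap_extend * ln
        assert total == score
        assert sum(ln for op, ln in ops if op in "=XD") == re - rs
        assert sum(ln for op, ln in ops if op in "=XI") == qe - qs


class TestAlignRead:
    def test_self_alignment(self, amplicon):
        rec = align_read(CcsRead("r", amplicon.sequence), amplicon)
        assert rec.strand == "+"
        assert rec.identity == 1.0
        assert rec.ops == [("=", len(amplicon))]
        assert rec.full_length

    def test_single_substitution_mismatch_column(self, amplicon):
        pos = 500
        s = list(amplicon.sequence)
        s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1) % 4]
        rec = align_read(CcsRead("r", "".join(s)), amplicon)
        assert rec.ops == [("=", pos), ("X", 1), ("=", len(amplicon) - pos - 1)]

    def test_junction_insertion_is_single_gap(self, amplicon):
        junction = next(j for j in amplicon.junctions if j.upstream == "ABL1-a8")
        # first/last insert bases differ from the flanking reference bases so
        # the gap can neither shift nor shrink by accidental matches
        insert = random_dna(np.random.default_rng(5), 35)
        not_after = "ACGT".replace(amplicon.sequence[junction.position], "")[0]
        not_before = "ACGT".replace(amplicon.sequence[junction.position - 1], "")[0]
        insert = not_after + insert[1:-1] + not_before
        read = (
            amplicon.sequence[: junction.position]
            + insert
            + amplicon.sequence[junction.position :]
        )
        rec = align_read(CcsRead("r", read), amplicon)
        ins_ops = [(op, ln) for op, ln in rec.ops if op == "I"]
        assert ins_ops == [("I", 35)]
        events = rec.events(min_length=3)
        assert events[0][0] == "insertion" and events[0][2] == 35

    def test_reverse_complement_same_span_and_ops(self, amplicon):
        rng = np.random.default_rng(11)
        read = mutate(rng, amplicon.sequence, n_sub=10, n_ins=3, n_del=3)
        fwd = align_read(CcsRead("f", read), amplicon)
        rev = align_read(CcsRead("r", revcomp(read)), amplicon)
        assert fwd.strand == "+" and rev.strand == "-"
        assert (fwd.ref_start, fwd.ref_end) == (rev.ref_start, rev.ref_end)
        assert fwd.ops == rev.ops
        assert fwd.score == rev.score

    def test_unrelated_sequence_unmapped(self, amplicon):
        rng = np.random.default_rng(13)
        junk = random_dna(rng, 800)
        assert align_read(CcsRead("j", junk), amplicon) is None


class TestFullLength:
    def test_complete_span_is_full_length(self, amplicon):
        rec = align_read(CcsRead("r", amplicon.sequence), amplicon)
        assert classify_full_length(rec, amplicon) is True

    def test_missing_five_prime_region_is_not(self, amplicon):
        rec = align_read(CcsRead("r", amplicon.sequence[200:]), amplicon)
        assert classify_full_length(rec, amplicon) is False

    @pytest.mark.parametrize("tol", [0, 3, 5])
    def test_end_tolerance_boundary(self, amplicon, tol):
        L = len(amplicon)
        inside = align_read(CcsRead("a", amplicon.sequence[: L - tol]), amplicon)
        assert classify_full_length(inside, amplicon, end_tolerance=tol) is True
        beyond = align_read(CcsRead("b", amplicon.sequence[: L - tol - 1]), amplicon)
        assert classify_full_length(beyond, amplicon, end_tolerance=tol) is False
        start_in = align_read(CcsRead("c", amplicon.sequence[tol:]), amplicon)
        assert classify_full_length(start_in, amplicon, end_tolerance=tol) is True
        start_out = align_read(CcsRead("d", amplicon.sequence[tol + 1 :]), amplicon)
        assert classify_full_length(start_out, amplicon, end_tolerance=tol) is False


class TestPileup:
    def test_identical_perfect_reads(self, amplicon):
        reads = [CcsRead(f"r{i}", amplicon.sequence) for i in range(10)]
        alns, _ = align_reads(reads, amplicon)
        p = pileup(alns, amplicon)
        assert (p.ref_counts == 10).all()
        assert (p.coverage == 10).all()

    def test_minor_allele_counts(self, amplicon):
        pos = 700
        alt = "ACGT"[("ACGT".index(amplicon.sequence[pos]) + 1) % 4]
        s = list(amplicon.sequence)
        s[pos] = alt
        reads = [CcsRead(f"r{i}", amplicon.sequence) for i in range(9)]
        reads.append(CcsRead("alt", "".join(s)))
        alns, _ = align_reads(reads, amplicon)
        p = pileup(alns, amplicon)
        assert p.counts[pos, "ACGT".index(alt)] == 1
        assert p.ref_counts[pos] == 9

    def test_coverage_conservation(self, amplicon):
        rng = np.random.default_rng(17)
        reads = []
        for i in range(30):
            start = int(rng.integers(0, 400))
            end = int(rng.integers(1100, len(amplicon)))
            reads.append(CcsRead(f"r{i}", mutate(rng, amplicon.sequence[start:end], n_sub=5)))
        alns, _ = align_reads(reads, amplicon)
        p = pileup(alns, amplicon)
        consumed = sum(a.ref_end - a.ref_start for a in alns)
        assert int(p.coverage.sum()) == consumed
        assert (p.coverage <= len(alns)).all()

    def test_clean_counts_exclude_indel_neighbourhood(self, amplicon):
        # one read with a deletion: columns within 2 of it vanish from clean
        s = amplicon.sequence
        read = s[:600] + s[602:]
        alns, _ = align_reads([CcsRead("d", read)], amplicon)
        p = pileup(alns, amplicon)
        a = alns[0]
        dels = [(r, ln) for op, ln, r, q in a.walk() if op == "D"]
        assert len(dels) == 1
        start, ln = dels[0][0], dels[0][1]
        assert p.clean_counts[start - 3].sum() == 1
        for pos in range(start - 2, start + ln + 2):
            assert p.clean_counts[pos].sum() == 0
        assert p.clean_counts[start + ln + 2].sum() == 1


class TestSamRoundTrip:
    def test_sam_preserves_records(self, tmp_path, amplicon):
        rng = np.random.default_rng(23)
        reads = [
            CcsRead(f"r{i}", mutate(rng, amplicon.sequence, n_sub=6, n_ins=2, n_del=2))
            for i in range(5)
        ]
        alns, _ = align_reads(reads, amplicon)
        path = tmp_path / "out.sam"
        align.write_sam(alns, amplicon, path)
        back = align.read_sam(path, amplicon)
        assert len(back) == len(alns)
        for a, b in zip(alns, back):
            assert (a.read_id, a.strand, a.ref_start, a.ref_end) == (
                b.read_id, b.strand, b.ref_start, b.ref_end
            )
            assert a.ops == b.ops
            assert a.oriented_sequence == b.oriented_sequence


class TestScoreOracleProperty:
    """Property-based check: for arbitrary short sequence pairs the
    production kernel (full band) scores exactly like the exhaustive DP."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    dna = st.text(alphabet="ACGT", min_size=1, max_size=80)

    @given(read=dna, ref=dna)
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_score_matches_oracle_on_arbitrary_pairs(self, read, ref):
        score, *_ = semi_global(read, ref)
        assert score == gotoh_overlap_score(read, ref)

    @given(seq=dna)
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_self_alignment_scores_all_matches(self, seq):
        score, ops, *_ = semi_global(seq, seq)
        assert score == 2 * len(seq)
        assert ops == [("=", len(seq))]
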