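import numpy as np
import pytest

import strpileup as sp
from strpileup.errors import AlignmentError
from strpileup.realignment import DEFAULT_SCHEME, ops_from_gapless, score_ops
from .oracles import affine_local_max_score, gapless_placements


def _hap(seq, locus_id="t"):
    """Wrap a raw sequence as a single-STR haplotype-like object for align_read."""
    # align_read only touches .sequence; build a minimal real Haplotype when a
    # repeat interval is needed.
    class _H:
        sequence = seq
    return _H()


def _repeat_hap(unit, count, left, right):
    locus = sp.LocusSpec(
        locus_id="t",
        segments=[
            sp.ConstantSegment(left),
            sp.StrSpec(str_id="t", repeat_unit=unit, contig="t",
                       start=len(left), end=len(left) + len(unit) * count),
            sp.ConstantSegment(right),
        ],
    )
    return sp.build_haplotype(locus, {"t": count})


RNG = np.random.default_rng(20240917)
BASES = "ACGT"


def _random_seq(n, rng=RNG):
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


def _mutate_read(read, rng, n_sub=0, n_ins=0, n_del=0):
    read = list(read)
    for _ in range(n_sub):
        i = int(rng.integers(len(read)))
        read[i] = BASES[(BASES.index(read[i]) + 1 + int(rng.integers(3))) % 4]
    for _ in range(n_ins):
        i = int(rng.integers(len(read)))
        read.insert(i, BASES[int(rng.integers(4))])
    for _ in range(n_del):
        if len(read) > 5:
            del read[int(rng.integers(len(read)))]
    return "".join(read)


class TestAlignRead:
    def test_unique_flank_read_has_one_placement(self):
        hap = _repeat_hap("CAG", 20, _random_seq(80), _random_seq(80))
        read = hap.sequence[10:40]
        alns = sp.align_read(read, hap)
        assert len(alns) == 1
        assert alns[0].start == 10
        assert alns[0].score == 30 * DEFAULT_SCHEME.match

    def test_in_repeat_placements_grow_linearly(self):
        left, right = _random_seq(20), _random_seq(20)
        read = "CAG" * 7
        for count in (10, 15, 20):
            hap = _repeat_hap("CAG", count, left, right)
            alns = sp.align_read(read, hap)
            perfect = [a for a in alns if a.score == len(read) * DEFAULT_SCHEME.match]
            oracle = gapless_placements(read, hap.sequence)
            assert sorted(a.start for a in perfect) == oracle
            assert len(oracle) == count - 7 + 1  # one placement per unit offset

    def test_single_mismatch_score(self):
        hap = _repeat_hap("CAG", 10, _random_seq(60), _random_seq(60))
        read = list(hap.sequence[30:70])
        read[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[20]]
        read = "".join(read)
        alns = sp.align_read(read, hap)
        assert alns[0].score == 39 * DEFAULT_SCHEME.match + DEFAULT_SCHEME.mismatch

    def test_empty_read_rejected(self):
        hap = _repeat_hap("CAG", 5, "ACGT" * 5, "TGCA" * 5)
        with pytest.raises(AlignmentError):
            sp.align_read("", hap)

    def test_scores_match_textbook_oracle(self):
        rng = np.random.default_rng(99)
        for trial in range(120):
            ref = _random_seq(int(rng.integers(60, 200)), rng)
            L = int(rng.integers(10, 50))
            start = int(rng.integers(0, len(ref) - L))
            read = _mutate_read(
                ref[start:start + L], rng,
                n_sub=int(rng.integers(0, 4)),
                n_ins=int(rng.integers(0, 2)),
                n_del=int(rng.integers(0, 2)),
            )
            alns = sp.align_read(read, _hap(ref))
            expected = affine_local_max_score(read, ref)
            assert alns[0].score == max(expected, 0)
            for a in alns:
                assert score_ops(a.ops) == a.score

    def test_ops_account_for_every_read_base(self):
        rng = np.random.default_rng(3)
        ref = _random_seq(150, rng)
        read = _mutate_read(ref[40:100], rng, n_sub=2, n_ins=1, n_del=1)
        for a in sp.align_read(read, _hap(ref)):
            assert a.read_length == len(read)
            assert a.end <= len(ref)


class TestProjectGraphAlignment:
    def test_flank_anchored_path_is_unique(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        hap = sp.build_haplotype(cgg_locus, {sid: 30})
        start = 700 - 30  # 30 bp of left flank + 5 repeat units
        rec = sp.ReadRecord(
            fragment_id="f", mate_index=1,
            bases=hap.sequence[start:start + 45],
            graph_alignment=sp.GraphAlignment(((0, start, 30), (1, 0, 15))),
        )
        alns = sp.project_graph_alignment(rec, hap)
        assert [a.start for a in alns] == [start]
        assert alns[0].score == 45 * DEFAULT_SCHEME.match

    def test_in_repeat_path_slides_per_unit(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        hap30 = sp.build_haplotype(cgg_locus, {sid: 30})
        rec = sp.ReadRecord(
            fragment_id="f", mate_index=1, bases="CGG" * 10,
            graph_alignment=sp.GraphAlignment(((1, 0, 30),)),
        )
        alns = sp.project_graph_alignment(rec, hap30)
        assert len(alns) == 21  # 30 - 10 + 1 unit offsets
        oracle = gapless_placements("CGG" * 10, hap30.sequence)
        in_repeat = [a.start for a in alns]
        assert set(in_repeat) <= set(oracle)

    def test_path_longer_than_allele_is_incompatible(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        hap8 = sp.build_haplotype(cgg_locus, {sid: 8})
        rec = sp.ReadRecord(
            fragment_id="f", mate_index=1, bases="CGG" * 10,
            graph_alignment=sp.GraphAlignment(((1, 0, 30),)),
        )
        assert sp.project_graph_alignment(rec, hap8) == []

    def test_unknown_segment_rejected(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        hap = sp.build_haplotype(cgg_locus, {sid: 8})
        rec = sp.ReadRecord(
            fragment_id="f", mate_index=1, bases="CGG",
            graph_alignment=sp.GraphAlignment(((9, 0, 3),)),
        )
        with pytest.raises(AlignmentError, match="segment"):
            sp.project_graph_alignment(rec, hap)


class TestPairScoring:
    def test_error_free_reads_score_sum_of_lengths(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        from .conftest import simulate_locus

        genotypes, pair, reads, _ = simulate_locus(
            cgg_locus, [{sid: 15}, {sid: 40}], base_error=0.0, seed=5, coverage=5.0
        )
        cands = sp.enumerate_haplotype_pairs(cgg_locus, genotypes)
        total = sp.score_haplotype_pair(cands[0], reads)
        assert total == sum(len(r.bases) for r in reads) * DEFAULT_SCHEME.match

    def test_score_invariant_to_read_order_and_hap_swap(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        from .conftest import simulate_locus

        genotypes, pair, reads, _ = simulate_locus(
            cgg_locus, [{sid: 15}, {sid: 40}], base_error=0.005, seed=6, coverage=4.0
        )
        (cand,) = sp.enumerate_haplotype_pairs(cgg_locus, genotypes)
        fwd = sp.score_haplotype_pair(cand, reads)
        rev = sp.score_haplotype_pair(cand, list(reversed(reads)))
        swapped = sp.HaplotypePair(hap1=cand.hap2, hap2=cand.hap1)
        assert fwd == rev == sp.score_haplotype_pair(swapped, reads)

    def test_single_candidate_returned_unscored(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        (cand,) = sp.enumerate_haplotype_pairs(
            cgg_locus, {sid: sp.RepeatGenotype(str_id=sid, allele_sizes=(30, 46))}
        )
        chosen = sp.select_haplotype_pair([cand], [])
        assert chosen is cand and chosen.cumulative_score is None

    def test_two_candidates_higher_score_wins(self):
        locus = sp.make_locus("two", ["CAG", "CCG"], spacers=["ATGCATGC"],
                              flank_len=600, ref_counts=[6, 4], seed=3)
        ids = [s.str_id for s in locus.strs]
        gts = {ids[0]: sp.RepeatGenotype(str_id=ids[0], allele_sizes=(4, 9)),
               ids[1]: sp.RepeatGenotype(str_id=ids[1], allele_sizes=(3, 8))}
        truth = sp.HaplotypePair(
            hap1=sp.build_haplotype(locus, {ids[0]: 4, ids[1]: 8}),
            hap2=sp.build_haplotype(locus, {ids[0]: 9, ids[1]: 3}),
        )
        reads, _ = sp.simulate_read_pairs(sp.SimConfig(truth=truth, base_error=0.0, seed=8))
        cands = sp.enumerate_haplotype_pairs(locus, gts)
        assert len(cands) == 2
        chosen = sp.select_haplotype_pair(cands, reads)
        assert chosen.sequence_key() == truth.sequence_key()
        scores = sorted(c.cumulative_score for c in cands)
        assert scores[0] < scores[1]
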