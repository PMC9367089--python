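import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import strpileup as sp
from strpileup.errors import FormatError, GenotypeError
from .oracles import enumerate_pairings_bruteforce


class TestStructureStrings:
    @pytest.mark.parametrize(
        "text,runs,total",
        [
            ("(CGG)10AGG(CGG)9AGG(CGG)9",
             (("CGG", 10), ("AGG", 1), ("CGG", 9), ("AGG", 1), ("CGG", 9)), 30),
            ("(CGG)9AGG(CGG)9AGG(CGG)13AGG(CGG)12",
             (("CGG", 9), ("AGG", 1), ("CGG", 9), ("AGG", 1), ("CGG", 13),
              ("AGG", 1), ("CGG", 12)), 46),
            ("(CGG)10AGG(CGG)9AGG(CGG)10",
             (("CGG", 10), ("AGG", 1), ("CGG", 9), ("AGG", 1), ("CGG", 10)), 31),
            ("CGG", (("CGG", 1),), 1),
        ],
    )
    def test_parse_and_count(self, text, runs, total):
        s = sp.parse_structure_string(text)
        assert s.runs == runs
        assert sp.count_repeat_units(s) == total

    @pytest.mark.parametrize("bad", ["", "(CGG", "(CGG)0AGG", "(CGX)3", "cgg)", "(CGG)2)"])
    def test_parse_rejects_malformed(self, bad):
        with pytest.raises(FormatError):
            sp.parse_structure_string(bad)

    def test_hand_summed_total(self):
        assert sp.count_repeat_units(sp.parse_structure_string("(CGG)9AGG(CGG)8AGG(CGG)21")) == 40

    def test_empty_structure_counts_zero(self):
        assert sp.count_repeat_units(sp.AlleleStructure(())) == 0
        assert sp.expand_structure(sp.AlleleStructure(())) == ""

    @pytest.mark.parametrize(
        "text,canonical,positions",
        [
            ("(CGG)10AGG(CGG)9AGG(CGG)9", "CGG", [11, 21]),
            ("(CGG)30", "CGG", []),
            ("AGG(CGG)5", "CGG", [1]),
            ("(AGG)2(CGG)3", "CGG", [1, 2]),
        ],
    )
    def test_interruption_positions(self, text, canonical, positions):
        assert sp.interruption_positions(sp.parse_structure_string(text), canonical) == positions

    def test_expand_concatenates(self):
        assert sp.expand_structure(sp.AlleleStructure((("CGG", 2), ("AGG", 1)))) == "CGGCGGAGG"
        assert len(sp.expand_structure(sp.parse_structure_string("(CGG)30"))) == 90

    @given(
        st.lists(
            st.tuples(st.sampled_from(["CGG", "AGG", "CAG", "A"]), st.integers(1, 40)),
            min_size=1, max_size=8,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_parse_expand_round_trip(self, raw_runs):
        s = sp.AlleleStructure(tuple(raw_runs))
        again = sp.parse_structure_string(str(s))
        assert again == s
        assert sp.expand_structure(again) == sp.expand_structure(s)
        if len({len(m) for m, _ in s.runs}) == 1:
            unit_len = len(s.runs[0][0])
            assert sp.count_repeat_units(s) * unit_len == len(sp.expand_structure(s))


class TestBuildHaplotype:
    def test_zero_count_leaves_only_flanks(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        hap = sp.build_haplotype(cgg_locus, {sid: 0})
        assert hap.sequence == cgg_locus.left_flank + cgg_locus.right_flank

    def test_length_closed_form_single_str(self):
        locus = sp.make_locus("one", ["CGG"], flank_len=1000, ref_counts=[30])
        hap = sp.build_haplotype(locus, {locus.strs[0].str_id: 30})
        assert len(hap.sequence) == 2090

    def test_length_closed_form_two_strs(self):
        locus = sp.make_locus("two", ["CAG", "CCG"], spacers=["ACGTT"],
                              flank_len=200, ref_counts=[10, 3])
        counts = {locus.strs[0].str_id: 10, locus.strs[1].str_id: 3}
        hap = sp.build_haplotype(locus, counts)
        assert len(hap.sequence) == 400 + 30 + 9 + 5

    def test_segment_map_tiles_sequence(self, cgg_locus):
        hap = sp.build_haplotype(cgg_locus, {cgg_locus.strs[0].str_id: 25})
        pos = 0
        for a, b in hap.segment_map:
            assert a == pos
            pos = b
        assert pos == len(hap.sequence)

    def test_structure_override_and_mismatch(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        struct = sp.parse_structure_string("(CGG)10AGG(CGG)9AGG(CGG)9")
        hap = sp.build_haplotype(cgg_locus, {sid: 30}, structures={sid: struct})
        rs, re_ = hap.repeat_interval(sid)
        assert hap.sequence[rs:re_] == sp.expand_structure(struct)
        with pytest.raises(GenotypeError, match="structure totals"):
            sp.build_haplotype(cgg_locus, {sid: 31}, structures={sid: struct})


class TestEnumerateHaplotypePairs:
    def _locus(self, n):
        return sp.make_locus(
            "multi", ["CAG", "CCG", "GAA", "CTG", "AAG"][:n],
            spacers=["ACGTT"] * (n - 1), flank_len=60, ref_counts=[5] * n,
        )

    def test_two_het_strs_four_haplotypes_two_pairings(self):
        locus = self._locus(2)
        ids = [s.str_id for s in locus.strs]
        gts = {ids[0]: sp.RepeatGenotype(str_id=ids[0], allele_sizes=(3, 7)),
               ids[1]: sp.RepeatGenotype(str_id=ids[1], allele_sizes=(4, 9))}
        pairs = sp.enumerate_haplotype_pairs(locus, gts)
        assert len(pairs) == 2
        seqs = {h.sequence for p in pairs for h in p.haplotypes}
        assert len(seqs) == 4

    def test_single_str_single_pairing(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        pairs = sp.enumerate_haplotype_pairs(
            cgg_locus, {sid: sp.RepeatGenotype(str_id=sid, allele_sizes=(30, 46))}
        )
        assert len(pairs) == 1
        assert pairs[0].cumulative_score is None

    def test_hom_plus_het_two_haplotypes_one_pairing(self):
        locus = self._locus(2)
        ids = [s.str_id for s in locus.strs]
        gts = {ids[0]: sp.RepeatGenotype(str_id=ids[0], allele_sizes=(10, 10)),
               ids[1]: sp.RepeatGenotype(str_id=ids[1], allele_sizes=(3, 7))}
        pairs = sp.enumerate_haplotype_pairs(locus, gts)
        assert len(pairs) == 1
        assert len({h.sequence for p in pairs for h in p.haplotypes}) == 2

    def test_haploid_gives_single_haplotype(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        pairs = sp.enumerate_haplotype_pairs(
            cgg_locus, {sid: sp.RepeatGenotype(str_id=sid, allele_sizes=(80,))}
        )
        assert len(pairs) == 1 and pairs[0].is_haploid

    def test_missing_genotype_rejected(self, cgg_locus):
        with pytest.raises(GenotypeError, match="missing genotype"):
            sp.enumerate_haplotype_pairs(cgg_locus, {})

    def test_cap_guards_pathological_loci(self):
        locus = self._locus(5)
        gts = {
            s.str_id: sp.RepeatGenotype(str_id=s.str_id, allele_sizes=(2, 3))
            for s in locus.strs
        }
        with pytest.raises(GenotypeError, match="cap"):
            sp.enumerate_haplotype_pairs(locus, gts, max_pairings=8)

    def test_matches_bruteforce_oracle_up_to_five_strs(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            n = int(rng.integers(1, 6))
            locus = self._locus(n)
            sizes = []
            gts = {}
            for s in locus.strs:
                a, b = int(rng.integers(0, 6)), int(rng.integers(0, 6))
                sizes.append(tuple(sorted((a, b))))
                gts[s.str_id] = sp.RepeatGenotype(str_id=s.str_id, allele_sizes=(a, b))
            pairs = sp.enumerate_haplotype_pairs(locus, gts)
            oracle = enumerate_pairings_bruteforce(sizes)
            got = {
                tuple(sorted((p.hap1.str_counts, p.hap2.str_counts))) for p in pairs
            }
            assert got == oracle
            k = sum(1 for a, b in sizes if a != b)
            assert len(pairs) == 2 ** max(k - 1, 0)
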