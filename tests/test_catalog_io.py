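import json

import pytest

import strpileup as sp
from strpileup.catalog_io import (
    ConstantSegment,
    group_fragments,
    write_genotypes_vcf,
    write_locus_catalog,
)
from strpileup.errors import CatalogError, FormatError, GenotypeError

FLANK_L = "ACGTA" * 40
FLANK_R = "TTGCA" * 40


def catalog_entry(strs, **extra):
    entry = {"locus_id": "L1", "strs": strs, "left_flank": FLANK_L, "right_flank": FLANK_R}
    entry.update(extra)
    return json.dumps([entry])


class TestParseLocusCatalog:
    def test_single_str_gives_three_segments(self):
        text = catalog_entry([{"str_id": "A", "repeat_unit": "CGG",
                               "contig": "chrX", "start": 1000, "end": 1060}])
        (locus,) = sp.parse_locus_catalog(text)
        assert len(locus.segments) == 3
        assert locus.left_flank == FLANK_L and locus.right_flank == FLANK_R
        assert locus.strs[0].repeat_unit == "CGG"

    def test_three_strs_give_seven_segments_with_ordinals(self):
        strs = [
            {"str_id": "A", "repeat_unit": "CAG", "contig": "c", "start": 100, "end": 130},
            {"str_id": "B", "repeat_unit": "CCG", "contig": "c", "start": 140, "end": 170},
            {"str_id": "C", "repeat_unit": "GAA", "contig": "c", "start": 200, "end": 230},
        ]
        text = catalog_entry(strs, inter_segments=["ACGTACGTAC", "A" * 30])
        (locus,) = sp.parse_locus_catalog(text)
        assert len(locus.segments) == 7
        assert [s.index_in_locus for s in locus.strs] == [0, 1, 2]

    def test_overlapping_strs_rejected(self):
        strs = [
            {"str_id": "A", "repeat_unit": "CAG", "contig": "c", "start": 100, "end": 160},
            {"str_id": "B", "repeat_unit": "CCG", "contig": "c", "start": 150, "end": 180},
        ]
        with pytest.raises(CatalogError, match="overlap"):
            sp.parse_locus_catalog(catalog_entry(strs, inter_segments=[""]))

    def test_missing_flank_source_is_configuration_error(self):
        text = json.dumps([{
            "locus_id": "L1",
            "strs": [{"repeat_unit": "CGG", "contig": "c", "start": 10, "end": 40}],
        }])
        with pytest.raises(CatalogError, match="flank"):
            sp.parse_locus_catalog(text)

    def test_malformed_json_names_problem(self):
        with pytest.raises(CatalogError, match="JSON"):
            sp.parse_locus_catalog("{not json")

    def test_reference_lookup_fills_flanks(self):
        ref = {"c": "A" * 100 + "CGG" * 10 + "T" * 100}
        text = json.dumps([{
            "locus_id": "L1",
            "strs": [{"repeat_unit": "CGG", "contig": "c", "start": 100, "end": 130}],
        }])
        (locus,) = sp.parse_locus_catalog(text, reference_lookup=ref, flank_len=100)
        assert locus.left_flank == "A" * 100
        assert locus.right_flank == "T" * 100

    def test_round_trip(self, cgg_locus):
        text = write_locus_catalog([cgg_locus])
        (again,) = sp.parse_locus_catalog(text)
        assert again == cgg_locus


class TestGenotypeVcf:
    def _vcf(self, locus, repcn, repci=None):
        s = locus.strs[0]
        fmt = "GT:REPCN" + (":REPCI" if repci else "")
        val = f"1/1:{repcn}" + (f":{repci}" if repci else "")
        return "\n".join([
            "##fileformat=VCFv4.2",
            f"##contig=<ID={s.contig}>",
            '##INFO=<ID=REPID,Number=1,Type=String,Description="x">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
            '##FORMAT=<ID=REPCN,Number=1,Type=String,Description="x">',
            '##FORMAT=<ID=REPCI,Number=1,Type=String,Description="x">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
            f"{s.contig}\t{s.start + 1}\t.\tN\t<STR>\t.\tPASS\tREPID={s.str_id}\t{fmt}\t{val}",
        ]) + "\n"

    def test_diploid_counts(self, cgg_locus):
        gts = sp.parse_genotypes_vcf(self._vcf(cgg_locus, "30/46"), cgg_locus)
        assert gts[cgg_locus.strs[0].str_id].allele_sizes == (30, 46)

    def test_haploid_count(self, cgg_locus):
        gts = sp.parse_genotypes_vcf(self._vcf(cgg_locus, "80"), cgg_locus)
        assert gts[cgg_locus.strs[0].str_id].allele_sizes == (80,)

    def test_sizes_sorted_with_cis_kept_aligned(self, cgg_locus):
        gts = sp.parse_genotypes_vcf(
            self._vcf(cgg_locus, "46/30", repci="44-48/28-32"), cgg_locus
        )
        g = gts[cgg_locus.strs[0].str_id]
        assert g.allele_sizes == (30, 46)
        assert g.size_cis == ((28, 32), (44, 48))

    def test_missing_str_fails_loudly(self, cgg_locus):
        vcf = self._vcf(cgg_locus, "30/46").replace(
            f"REPID={cgg_locus.strs[0].str_id}", "REPID=other"
        )
        with pytest.raises(GenotypeError, match="no genotype"):
            sp.parse_genotypes_vcf(vcf, cgg_locus)

    def test_non_integer_counts_rejected(self, cgg_locus):
        with pytest.raises(FormatError, match="non-integer"):
            sp.parse_genotypes_vcf(self._vcf(cgg_locus, "30/x"), cgg_locus)

    def test_writer_round_trips(self, cgg_locus):
        sid = cgg_locus.strs[0].str_id
        gts = {sid: sp.RepeatGenotype(str_id=sid, allele_sizes=(30, 46),
                                      size_cis=((28, 32), (44, 48)))}
        again = sp.parse_genotypes_vcf(write_genotypes_vcf(cgg_locus, gts), cgg_locus)
        assert again[sid] == gts[sid]


class TestWrapperTsv:
    REF = {"chrX": "A" * 1000 + "CGG" * 20 + "T" * 1000}

    def test_row_maps_to_spec_and_genotype(self):
        tsv = "chrX\t1000\t1060\tCGG\t30/46\n"
        locus, gts = sp.parse_wrapper_tsv(tsv, reference_lookup=self.REF, flank_len=500)
        (s,) = locus.strs
        assert (s.contig, s.start, s.end, s.repeat_unit) == ("chrX", 1000, 1060, "CGG")
        assert gts[s.str_id].allele_sizes == (30, 46)
        assert locus.left_flank == "A" * 500

    def test_haploid_row(self):
        locus, gts = sp.parse_wrapper_tsv(
            "chrX\t1000\t1060\tCGG\t30\n", reference_lookup=self.REF, flank_len=100
        )
        assert gts[locus.strs[0].str_id].allele_sizes == (30,)

    def test_wrong_column_count_names_row(self):
        with pytest.raises(FormatError, match="row 1"):
            sp.parse_wrapper_tsv("chrX\t1000\t1060\tCGG\n", reference_lookup=self.REF)

    def test_comments_and_header_skipped(self):
        tsv = "# a comment\ncontig\tstart\tend\tunit\tgenotype\nchrX\t1000\t1060\tCGG\t5/7\n"
        locus, gts = sp.parse_wrapper_tsv(tsv, reference_lookup=self.REF, flank_len=100)
        assert gts[locus.strs[0].str_id].allele_sizes == (5, 7)


class TestReads:
    def test_group_fragments_pairs_and_orphans(self):
        recs = [
            sp.ReadRecord(fragment_id="f1", mate_index=1, bases="ACGT"),
            sp.ReadRecord(fragment_id="f1", mate_index=2, bases="ACGT"),
            sp.ReadRecord(fragment_id="f2", mate_index=1, bases="ACGT"),
        ]
        pairs, orphans = group_fragments(recs)
        assert set(pairs) == {"f1"}
        assert [o.fragment_id for o in orphans] == ["f2"]

    def test_duplicate_mate_rejected(self):
        recs = [
            sp.ReadRecord(fragment_id="f1", mate_index=1, bases="ACGT"),
            sp.ReadRecord(fragment_id="f1", mate_index=1, bases="ACGT"),
        ]
        with pytest.raises(FormatError, match="duplicate"):
            group_fragments(recs)

    def test_graph_tag_round_trip(self):
        ga = sp.GraphAlignment(((0, 650, 50), (1, 0, 60), (2, 0, 40)))
        assert sp.GraphAlignment.decode(ga.encode()) == ga
        with pytest.raises(FormatError):
            sp.GraphAlignment.decode("junk")
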