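"""Input parsing and normalization for STR locus pileups.

A *locus* is an ordered alternation of constant sequence segments and short
tandem repeats (STRs), flanked on both sides by constant reference sequence.
This module reads the three inputs every pileup needs — the locus catalog
(JSON), the repeat genotypes (VCF in the ExpansionHunter dialect, or the
5-column tab-separated wrapper format), and the reads (an indexed BAM,
optionally carrying graph-alignment tags) — and normalizes them into the
internal types used downstream.

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted from 1-based on ingest.
"""

from __future__ import annotations

import json
import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import pysam

from .errors import CatalogError, FormatError, GenotypeError

logger = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 1000
#: BAM tag carrying the encoded graph-alignment path (see GraphAlignment).
GRAPH_TAG = "XG"

_SEQ_RE = re.compile(r"^[ACGTN]*$")
_MOTIF_RE = re.compile(r"^[ACGTN]{1,20}$")


def _check_seq(seq: str, what: str) -> str:
    seq = seq.upper()
    if not _SEQ_RE.match(seq):
        raise CatalogError(f"{what} contains non-ACGTN characters")
    return seq


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ConstantSegment:
    """A stretch of fixed sequence (flank or inter-repeat spacer)."""

    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_seq(self.sequence, "constant segment"))


@dataclass(frozen=True)
class StrSpec:
    """One short tandem repeat within a locus."""

    str_id: str
    repeat_unit: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    index_in_locus: int = 0

    def __post_init__(self):
        unit = self.repeat_unit.upper()
        if not _MOTIF_RE.match(unit):
            raise CatalogError(
                f"STR {self.str_id!r}: repeat unit must be 1-20 bp of ACGTN, got {self.repeat_unit!r}"
            )
        object.__setattr__(self, "repeat_unit", unit)
        if not self.start < self.end:
            raise CatalogError(
                f"STR {self.str_id!r}: reference interval start must precede end "
                f"({self.start} >= {self.end})"
            )


Segment = Union[ConstantSegment, StrSpec]


@dataclass
class LocusSpec:
    """Ordered alternation of constant segments and STRs, flanks included.

    ``segments[0]`` and ``segments[-1]`` are always constant (the flanks) and
    any two STRs are separated by a (possibly empty) constant segment, so a
    locus with n STRs has 2n+1 segments.
    """

    locus_id: str
    segments: list  # list[Segment]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        segs = self.segments
        if len(segs) < 3 or len(segs) % 2 == 0:
            raise CatalogError(
                f"locus {self.locus_id!r}: expected 2n+1 alternating segments, got {len(segs)}"
            )
        for i, seg in enumerate(segs):
            want_const = i % 2 == 0
            if want_const != isinstance(seg, ConstantSegment):
                raise CatalogError(
                    f"locus {self.locus_id!r}: segment {i} breaks the constant/STR alternation"
                )
        if not segs[0].sequence or not segs[-1].sequence:
            raise CatalogError(f"locus {self.locus_id!r}: flank sequences must be nonempty")
        ordinals = [s.index_in_locus for s in self.strs]
        if ordinals != list(range(len(ordinals))):
            raise CatalogError(f"locus {self.locus_id!r}: STR ordinals must be 0..n-1, got {ordinals}")

    @property
    def strs(self) -> list:
        return [s for s in self.segments if isinstance(s, StrSpec)]

    @property
    def left_flank(self) -> str:
        return self.segments[0].sequence

    @property
    def right_flank(self) -> str:
        return self.segments[-1].sequence

    @property
    def contig(self) -> str:
        return self.strs[0].contig

    def get_str(self, str_id: str) -> StrSpec:
        for s in self.strs:
            if s.str_id == str_id:
                return s
        raise CatalogError(f"locus {self.locus_id!r} has no STR {str_id!r}")

    def region(self) -> tuple:
        """(contig, start, end) covering all STRs (flanks excluded)."""
        strs = self.strs
        return (self.contig, strs[0].start, strs[-1].end)


@dataclass(frozen=True)
class RepeatGenotype:
    """Point genotype for one STR, in repeat units.

    Diploid sizes are stored sorted ascending; ``size_cis`` (when present)
    are per-allele (lower, upper) intervals kept in the same order.
    """

    str_id: str
    allele_sizes: tuple
    size_cis: Optional[tuple] = None

    def __post_init__(self):
        sizes = tuple(int(s) for s in self.allele_sizes)
        if len(sizes) not in (1, 2):
            raise GenotypeError(f"{self.str_id}: expected 1 or 2 allele sizes, got {len(sizes)}")
        if any(s < 0 for s in sizes):
            raise GenotypeError(f"{self.str_id}: negative allele size in {sizes}")
        cis = self.size_cis
        if cis is not None:
            if len(cis) != len(sizes):
                raise GenotypeError(f"{self.str_id}: one CI per allele required")
            order = sorted(range(len(sizes)), key=lambda i: sizes[i])
            cis = tuple(tuple(cis[i]) for i in order)
            sizes = tuple(sorted(sizes))
            for size, (lo, hi) in zip(sizes, cis):
                if not lo <= size <= hi:
                    raise GenotypeError(f"{self.str_id}: CI ({lo},{hi}) does not bracket size {size}")
        else:
            sizes = tuple(sorted(sizes))
        object.__setattr__(self, "allele_sizes", sizes)
        object.__setattr__(self, "size_cis", cis)

    @property
    def ploidy(self) -> int:
        return len(self.allele_sizes)

    @property
    def is_het(self) -> bool:
        return len(set(self.allele_sizes)) > 1


@dataclass(frozen=True)
class GraphAlignment:
    """A read's path through the locus segments.

    ``path`` is a tuple of (segment_index, offset, length) triples: the read
    consumes ``length`` bp of segment ``segment_index`` starting at ``offset``
    bp into that segment (offset as realized on the read's source haplotype;
    for STR segments only ``offset % unit_length`` is meaningful when the
    placement slides). Encoded in BAM as tag ``XG`` = "i@off:len;...".
    """

    path: tuple

    def encode(self) -> str:
        return ";".join(f"{i}@{o}:{n}" for i, o, n in self.path)

    @classmethod
    def decode(cls, text: str) -> "GraphAlignment":
        path = []
        try:
            for tok in text.split(";"):
                seg, rest = tok.split("@")
                off, length = rest.split(":")
                path.append((int(seg), int(off), int(length)))
        except (ValueError, AttributeError) as exc:
            raise FormatError(f"cannot decode graph-alignment tag {text!r}") from exc
        if not path:
            raise FormatError("empty graph-alignment tag")
        return cls(tuple(path))


@dataclass
class ReadRecord:
    """One mate of a sequenced fragment, in aligned (forward) orientation."""

    fragment_id: str
    mate_index: int  # 1 or 2
    bases: str
    quals: Optional[Sequence[int]] = None
    is_reverse: bool = False
    graph_alignment: Optional[GraphAlignment] = None
    linear_alignment: Optional[tuple] = None  # (contig, 0-based pos, cigar)

    def __post_init__(self):
        if not self.bases:
            raise FormatError(f"read {self.fragment_id}/{self.mate_index} has no bases")
        if self.mate_index not in (1, 2):
            raise FormatError(f"read {self.fragment_id}: mate index must be 1 or 2")
        self.bases = _check_seq(self.bases, f"read {self.fragment_id}/{self.mate_index}")


# ---------------------------------------------------------------------------
# reference sequence providers


def as_sequence_provider(source) -> Callable[[str, int, int], str]:
    """Normalize a reference source into ``f(contig, start, end) -> str``.

    Accepts a callable, a mapping contig -> sequence, or any object with a
    pysam/pyfaidx-style ``fetch``/``__getitem__`` interface.
    """
    if source is None:
        raise CatalogError("a reference sequence source is required but none was given")
    if callable(source):
        return source
    if hasattr(source, "fetch"):
        return lambda contig, start, end: str(source.fetch(contig, start, end))
    if isinstance(source, Mapping):
        def _from_mapping(contig, start, end, _m=source):
            try:
                seq = _m[contig]
            except KeyError:
                raise CatalogError(f"contig {contig!r} not in reference mapping") from None
            return str(seq[max(start, 0):end])
        return _from_mapping
    # pyfaidx.Fasta supports fasta[contig][start:end]
    if hasattr(source, "__getitem__"):
        return lambda contig, start, end: str(source[contig][max(start, 0):end])
    raise CatalogError(f"cannot use {type(source).__name__} as a reference sequence source")


# ---------------------------------------------------------------------------
# catalog parsing


def _build_locus(locus_id, str_dicts, left, right, inters) -> LocusSpec:
    strs = []
    for i, d in enumerate(str_dicts):
        strs.append(
            StrSpec(
                str_id=d["str_id"],
                repeat_unit=d["repeat_unit"],
                contig=d["contig"],
                start=int(d["start"]),
                end=int(d["end"]),
                index_in_locus=i,
            )
        )
    segments: list = [ConstantSegment(left)]
    for i, s in enumerate(strs):
        if i > 0:
            segments.append(ConstantSegment(inters[i - 1]))
        segments.append(s)
    segments.append(ConstantSegment(right))
    return LocusSpec(locus_id=locus_id, segments=segments)


def parse_locus_catalog(
    catalog_text: str,
    reference_lookup=None,
    flank_len: int = DEFAULT_FLANK_LEN,
) -> list:
    """Parse a JSON locus catalog into a list of :class:`LocusSpec`.

    Each catalog entry gives a ``locus_id`` and one or more STR definitions
    (``str_id``, ``repeat_unit``, ``contig``, ``start``, ``end``; 0-based
    half-open). Flank and inter-repeat sequences may be inline
    (``left_flank``, ``right_flank``, ``inter_segments``) or fetched from
    ``reference_lookup``. STRs are ordered by reference coordinate.
    """
    try:
        doc = json.loads(catalog_text)
    except json.JSONDecodeError as exc:
        raise CatalogError(f"catalog is not valid JSON: {exc}") from exc
    entries = doc.get("loci") if isinstance(doc, dict) else doc
    if not isinstance(entries, list):
        raise CatalogError("catalog must be a JSON list of loci or {'loci': [...]}")

    loci = []
    for n, entry in enumerate(entries):
        where = f"catalog entry {n}"
        if not isinstance(entry, dict) or "locus_id" not in entry:
            raise CatalogError(f"{where}: missing 'locus_id'")
        locus_id = entry["locus_id"]
        where = f"catalog entry {n} ({locus_id!r})"
        raw_strs = entry.get("strs")
        if not raw_strs:
            raise CatalogError(f"{where}: no STRs defined")
        str_dicts = []
        for d in raw_strs:
            missing = {"repeat_unit", "start", "end"} - set(d)
            if missing:
                raise CatalogError(f"{where}: STR missing fields {sorted(missing)}")
            str_dicts.append(
                {
                    "str_id": d.get("str_id", locus_id),
                    "repeat_unit": d["repeat_unit"],
                    "contig": d.get("contig", entry.get("contig")),
                    "start": int(d["start"]),
                    "end": int(d["end"]),
                }
            )
            if str_dicts[-1]["contig"] is None:
                raise CatalogError(f"{where}: STR has no contig")
        str_dicts.sort(key=lambda d: d["start"])
        for a, b in zip(str_dicts, str_dicts[1:]):
            if b["start"] < a["end"]:
                raise CatalogError(
                    f"{where}: STR intervals {a['str_id']} and {b['str_id']} overlap"
                )
        entry_flank = int(entry.get("flank_len", flank_len))
        contig = str_dicts[0]["contig"]
        lo, hi = str_dicts[0]["start"], str_dicts[-1]["end"]
        lookup = None
        if "left_flank" in entry:
            left = _check_seq(entry["left_flank"], f"{where} left flank")
        else:
            lookup = as_sequence_provider(reference_lookup) if reference_lookup else None
            if lookup is None:
                raise CatalogError(f"{where}: no inline left_flank and no reference source")
            left = _check_seq(lookup(contig, max(lo - entry_flank, 0), lo), f"{where} left flank")
        if "right_flank" in entry:
            right = _check_seq(entry["right_flank"], f"{where} right flank")
        else:
            lookup = lookup or as_sequence_provider(reference_lookup)
            right = _check_seq(lookup(contig, hi, hi + entry_flank), f"{where} right flank")
        inters = entry.get("inter_segments")
        if inters is None:
            if len(str_dicts) > 1:
                lookup = lookup or as_sequence_provider(reference_lookup)
                inters = [
                    lookup(contig, a["end"], b["start"])
                    for a, b in zip(str_dicts, str_dicts[1:])
                ]
            else:
                inters = []
        if len(inters) != len(str_dicts) - 1:
            raise CatalogError(
                f"{where}: need {len(str_dicts) - 1} inter-repeat segments, got {len(inters)}"
            )
        inters = [_check_seq(s, f"{where} inter-repeat segment") for s in inters]
        loci.append(_build_locus(locus_id, str_dicts, left, right, inters))
    return loci


def write_locus_catalog(loci: Sequence[LocusSpec]) -> str:
    """Serialize loci back to catalog JSON (inverse of :func:`parse_locus_catalog`)."""
    entries = []
    for locus in loci:
        strs = locus.strs
        inters = [
            seg.sequence
            for i, seg in enumerate(locus.segments[1:-1], start=1)
            if isinstance(seg, ConstantSegment)
        ]
        entries.append(
            {
                "locus_id": locus.locus_id,
                "strs": [
                    {
                        "str_id": s.str_id,
                        "repeat_unit": s.repeat_unit,
                        "contig": s.contig,
                        "start": s.start,
                        "end": s.end,
                    }
                    for s in strs
                ],
                "left_flank": locus.left_flank,
                "right_flank": locus.right_flank,
                "inter_segments": inters,
            }
        )
    return json.dumps({"loci": entries}, indent=1)


# ---------------------------------------------------------------------------
# genotypes


def _parse_size_field(text: str, str_id: str) -> tuple:
    parts = str(text).split("/")
    try:
        return tuple(int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"{str_id}: non-integer repeat count in {text!r}") from exc


def _parse_ci_field(text: str, str_id: str):
    cis = []
    for part in str(text).split("/"):
        m = re.match(r"^(\d+)-(\d+)$", part)
        if not m:
            return None
        cis.append((int(m.group(1)), int(m.group(2))))
    return tuple(cis)


def parse_genotypes_vcf(vcf_source, locus: LocusSpec) -> dict:
    """Extract one :class:`RepeatGenotype` per locus STR from a VCF.

    ``vcf_source`` is a path or the VCF text itself. Records are matched to
    STRs through the ``REPID`` (or ``VARID``) INFO field; repeat counts come
    from the first sample's ``REPCN`` field ("30/46" or "80") and per-allele
    confidence intervals from ``REPCI`` ("28-32/40-50") when present.
    """
    text_mode = isinstance(vcf_source, str) and "\n" in vcf_source
    if text_mode:
        tmp = tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False)
        tmp.write(vcf_source)
        tmp.close()
        path = tmp.name
    else:
        path = os.fspath(vcf_source)
    wanted = {s.str_id for s in locus.strs}
    out: dict = {}
    try:
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                repid = rec.info.get("REPID") or rec.info.get("VARID") or rec.id
                if isinstance(repid, tuple):
                    repid = repid[0]
                if repid not in wanted:
                    continue
                if not rec.samples:
                    raise FormatError(f"VCF record for {repid} carries no sample")
                sample = rec.samples[0]
                repcn = sample.get("REPCN")
                if repcn is None:
                    raise FormatError(f"VCF record for {repid} has no REPCN field")
                if isinstance(repcn, tuple):
                    repcn = "/".join(str(x) for x in repcn)
                sizes = _parse_size_field(repcn, repid)
                repci = sample.get("REPCI")
                if isinstance(repci, tuple):
                    repci = "/".join(str(x) for x in repci)
                cis = _parse_ci_field(repci, repid) if repci not in (None, ".") else None
                out[repid] = RepeatGenotype(str_id=repid, allele_sizes=sizes, size_cis=cis)
    finally:
        if text_mode:
            os.unlink(path)
    missing = wanted - set(out)
    if missing:
        raise GenotypeError(
            f"locus {locus.locus_id!r}: no genotype for STR(s) {sorted(missing)}"
        )
    return out


def write_genotypes_vcf(locus: LocusSpec, genotypes: Mapping[str, RepeatGenotype],
                        sample: str = "SAMPLE") -> str:
    """Emit genotypes as ExpansionHunter-dialect VCF text."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={locus.contig}>",
        '##INFO=<ID=REPID,Number=1,Type=String,Description="Repeat identifier">',
        '##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=REPCN,Number=1,Type=String,Description="Repeat counts">',
        '##FORMAT=<ID=REPCI,Number=1,Type=String,Description="Repeat count CIs">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for s in locus.strs:
        g = genotypes[s.str_id]
        repcn = "/".join(str(x) for x in g.allele_sizes)
        if g.size_cis:
            repci = "/".join(f"{lo}-{hi}" for lo, hi in g.size_cis)
        else:
            repci = "/".join(f"{x}-{x}" for x in g.allele_sizes)
        gt = "1/1" if g.ploidy == 2 else "1"
        lines.append(
            f"{s.contig}\t{s.start + 1}\t{s.str_id}\tN\t<STR>\t.\tPASS\t"
            f"REPID={s.str_id};RU={s.repeat_unit}\tGT:REPCN:REPCI\t{gt}:{repcn}:{repci}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# wrapper TSV


def parse_wrapper_tsv(
    tsv_text: str,
    reference_lookup=None,
    locus_id: str = "locus",
    flank_len: int = DEFAULT_FLANK_LEN,
) -> tuple:
    """Parse the 5-column wrapper format into ``(LocusSpec, genotypes)``.

    Columns: contig, start, end, repeat unit, genotype ("30/46" or "30");
    coordinates 0-based half-open; '#' comment lines and an optional header
    row are ignored. Flank and spacer sequences are taken from
    ``reference_lookup`` (typically the reference FASTA).
    """
    rows = []
    seen_data = False
    for lineno, raw in enumerate(tsv_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if not seen_data and fields[0].lower() in {"contig", "chrom", "chr"}:
            continue
        seen_data = True
        if len(fields) != 5:
            raise FormatError(f"row {lineno}: expected 5 columns, got {len(fields)}")
        contig, start, end, unit, gt = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-integer coordinates") from exc
        sizes = _parse_size_field(gt, f"row {lineno}")
        rows.append((lineno, contig, start_i, end_i, unit, sizes))
    if not rows:
        raise FormatError("wrapper TSV contains no STR rows")
    contigs = {r[1] for r in rows}
    if len(contigs) > 1:
        raise FormatError(f"wrapper TSV mixes contigs {sorted(contigs)}; one locus per file")
    rows.sort(key=lambda r: r[2])
    lookup = as_sequence_provider(reference_lookup)
    str_dicts = []
    genotypes = {}
    for lineno, contig, start, end, unit, sizes in rows:
        str_id = f"{contig}_{start}_{end}"
        str_dicts.append(
            {"str_id": str_id, "repeat_unit": unit, "contig": contig, "start": start, "end": end}
        )
        genotypes[str_id] = RepeatGenotype(str_id=str_id, allele_sizes=sizes)
    lo, hi = str_dicts[0]["start"], str_dicts[-1]["end"]
    contig = str_dicts[0]["contig"]
    left = lookup(contig, max(lo - flank_len, 0), lo)
    right = lookup(contig, hi, hi + flank_len)
    inters = [
        lookup(contig, a["end"], b["start"]) for a, b in zip(str_dicts, str_dicts[1:])
    ]
    locus = _build_locus(locus_id, str_dicts, left, right, inters)
    return locus, genotypes


# ---------------------------------------------------------------------------
# reads


def load_reads(bam_path, locus: LocusSpec, fetch_margin: int = DEFAULT_FLANK_LEN) -> list:
    """Load read records overlapping the locus region ± ``fetch_margin``.

    Secondary and supplementary alignments are skipped; graph-alignment tags
    are decoded when present. Mates are joined downstream by
    :func:`group_fragments`.
    """
    contig, start, end = locus.region()
    records = []
    try:
        bam = pysam.AlignmentFile(os.fspath(bam_path), "rb")
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot open BAM {bam_path}: {exc}") from exc
    with bam:
        if contig not in bam.references:
            raise FormatError(f"contig {contig!r} absent from BAM {bam_path}")
        for aln in bam.fetch(contig, max(start - fetch_margin, 0), end + fetch_margin):
            if aln.is_secondary or aln.is_supplementary or aln.query_sequence is None:
                continue
            graph = None
            if aln.has_tag(GRAPH_TAG):
                graph = GraphAlignment.decode(aln.get_tag(GRAPH_TAG))
            linear = None
            if not aln.is_unmapped:
                linear = (aln.reference_name, aln.reference_start, aln.cigarstring)
            records.append(
                ReadRecord(
                    fragment_id=aln.query_name,
                    mate_index=2 if aln.is_read2 else 1,
                    bases=aln.query_sequence.upper(),
                    quals=list(aln.query_qualities) if aln.query_qualities is not None else None,
                    is_reverse=aln.is_reverse,
                    graph_alignment=graph,
                    linear_alignment=linear,
                )
            )
    return records


def group_fragments(records: Sequence[ReadRecord]) -> tuple:
    """Join mates by fragment id: ``(pairs, orphans)``.

    ``pairs`` maps fragment_id -> (mate1, mate2); ``orphans`` lists records
    whose mate is missing (kept out of all pairing stages).
    """
    by_frag: dict = {}
    for rec in records:
        slot = by_frag.setdefault(rec.fragment_id, {})
        if rec.mate_index in slot:
            raise FormatError(f"duplicate mate {rec.mate_index} for fragment {rec.fragment_id}")
        slot[rec.mate_index] = rec
    pairs, orphans = {}, []
    for fid in sorted(by_frag):
        slot = by_frag[fid]
        if len(slot) == 2:
            pairs[fid] = (slot[1], slot[2])
        else:
            orphans.extend(slot.values())
    if orphans:
        logger.warning("%d orphan mate(s) excluded from pairing stages", len(orphans))
    return pairs, orphans
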