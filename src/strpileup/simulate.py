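"""Paired-end read simulator for STR loci.

Fragments are drawn uniformly along each truth haplotype with lengths from a
truncated normal distribution; the two fragment ends become the mates, and
substitution errors are added per base. Reads carry both a linear placement
on a synthetic contig and an encoded graph-alignment path, so the projection
route and the de-novo realignment route can both be exercised from the same
fixture. PCR artifacts and GC bias are deliberately not modelled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pysam

from .catalog_io import (
    GRAPH_TAG,
    GraphAlignment,
    LocusSpec,
    ReadRecord,
    RepeatGenotype,
    StrSpec,
    write_genotypes_vcf,
    write_locus_catalog,
)
from .errors import SimulationError
from .haplotype_model import AlleleStructure, HaplotypePair, build_haplotype

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one simulated locus.

    Defaults reflect a typical short-read WGS run: 30x coverage, 150 bp
    reads, fragment lengths ~ Normal(450, 100) bp, and a 0.2% per-base
    substitution error rate.
    """

    truth: HaplotypePair
    coverage: float = 30.0
    read_len: int = 150
    frag_mean: float = 450.0
    frag_sd: float = 100.0
    base_error: float = 0.002
    seed: int = 42

    def __post_init__(self):
        if not 0 <= self.base_error < 0.1:
            raise SimulationError("base_error must lie in [0, 0.1)")
        if not self.read_len < self.frag_mean:
            raise SimulationError("read_len must be shorter than frag_mean")
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")


@dataclass(frozen=True)
class TruthRecord:
    hap_index: int
    start: int
    frag_len: int


def graph_path_for(hap, start: int, length: int) -> GraphAlignment:
    """Encode the segments a read interval [start, start+length) traverses."""
    path = []
    end = start + length
    for si, (a, b) in enumerate(hap.segment_map):
        lo, hi = max(start, a), min(end, b)
        if lo < hi:
            path.append((si, lo - a, hi - lo))
    return GraphAlignment(tuple(path))


def _mutate(bases: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hits.size == 0:
        return bases
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = alphabet[alphabet != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode("ascii")


def simulate_read_pairs(cfg: SimConfig) -> tuple:
    """Draw read pairs from the truth pair: ``(records, truth)``.

    ``truth`` maps fragment_id -> :class:`TruthRecord` (source haplotype
    index, fragment start on that haplotype, fragment length). Mate 1 is the
    leftmost (forward) end; bases are stored in haplotype-forward orientation
    with ``is_reverse`` marking the sequenced strand. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    truth = {}
    serial = 0
    for hi, hap in enumerate(cfg.truth.haplotypes):
        hap_len = len(hap.sequence)
        if hap_len < cfg.frag_mean + 4 * cfg.frag_sd:
            raise SimulationError(
                f"haplotype {hi} ({hap_len} bp) is shorter than frag_mean + 4*frag_sd; "
                "use longer flanks"
            )
        n_frags = int(round(cfg.coverage * hap_len / (2 * cfg.read_len)))
        lens = rng.normal(cfg.frag_mean, cfg.frag_sd, n_frags)
        lens = np.clip(np.rint(lens), cfg.read_len, hap_len).astype(int)
        for L in lens:
            start = int(rng.integers(0, hap_len - L + 1))
            frag = hap.sequence[start:start + L]
            fid = f"sim{serial:06d}"
            serial += 1
            truth[fid] = TruthRecord(hap_index=hi, start=start, frag_len=int(L))
            m1 = _mutate(frag[: cfg.read_len], rng, cfg.base_error)
            m2_start = start + L - cfg.read_len
            m2 = _mutate(frag[L - cfg.read_len:], rng, cfg.base_error)
            records.append(
                ReadRecord(
                    fragment_id=fid, mate_index=1, bases=m1, is_reverse=False,
                    graph_alignment=graph_path_for(hap, start, cfg.read_len),
                    linear_alignment=(hap.locus.contig, start, f"{cfg.read_len}M"),
                )
            )
            records.append(
                ReadRecord(
                    fragment_id=fid, mate_index=2, bases=m2, is_reverse=True,
                    graph_alignment=graph_path_for(hap, m2_start, cfg.read_len),
                    linear_alignment=(hap.locus.contig, m2_start, f"{cfg.read_len}M"),
                )
            )
    return records, truth


def make_locus(
    locus_id: str,
    repeat_units: Sequence[str],
    spacers: Optional[Sequence[str]] = None,
    flank_len: int = 700,
    ref_counts: Optional[Sequence[int]] = None,
    seed: int = 7,
) -> LocusSpec:
    """Build a synthetic locus with random flanks.

    Coordinates are laid out on a synthetic contig named after the locus so
    that haplotype coordinates and contig coordinates coincide (STR 0 starts
    at ``flank_len``); ``ref_counts`` sets the repeat sizes embedded in the
    contig coordinates (default 10 units each).
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def rand_seq(n):
        return "".join(bases[i] for i in rng.integers(0, 4, n))

    spacers = list(spacers) if spacers is not None else ["" for _ in repeat_units[1:]]
    if len(spacers) != len(repeat_units) - 1:
        raise SimulationError("need one spacer per adjacent STR pair")
    ref_counts = list(ref_counts) if ref_counts is not None else [10] * len(repeat_units)

    from .catalog_io import ConstantSegment  # local to avoid cycle at import time

    segments: list = [ConstantSegment(rand_seq(flank_len))]
    pos = flank_len
    for i, unit in enumerate(repeat_units):
        if i > 0:
            segments.append(ConstantSegment(spacers[i - 1]))
            pos += len(spacers[i - 1])
        tract = len(unit) * ref_counts[i]
        segments.append(
            StrSpec(
                str_id=f"{locus_id}_{i}" if len(repeat_units) > 1 else locus_id,
                repeat_unit=unit,
                contig=locus_id,
                start=pos,
                end=pos + tract,
                index_in_locus=i,
            )
        )
        pos += tract
    segments.append(ConstantSegment(rand_seq(flank_len)))
    return LocusSpec(locus_id=locus_id, segments=segments)


def write_fixture(
    reads: Sequence[ReadRecord],
    truth: Mapping[str, TruthRecord],
    locus: LocusSpec,
    genotypes: Mapping[str, RepeatGenotype],
    out_dir,
    pair: Optional[HaplotypePair] = None,
) -> dict:
    """Write a complete on-disk fixture; returns a dict of file paths.

    Files: sorted+indexed BAM on the synthetic contig, ExpansionHunter-style
    VCF, catalog JSON, 5-column wrapper TSV, reference FASTA (the contig
    realized at the catalog's reference repeat sizes), and a truth TSV.
    Assumes the locus was laid out with contig coordinates equal to haplotype
    coordinates (as :func:`make_locus` does).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bam": out / "reads.bam",
        "vcf": out / "genotypes.vcf",
        "catalog": out / "catalog.json",
        "tsv": out / "wrapper.tsv",
        "reference": out / "reference.fa",
        "truth": out / "truth.tsv",
    }
    # reference contig at the catalog's embedded repeat sizes
    ref_counts = {
        s.str_id: (s.end - s.start) // len(s.repeat_unit) for s in locus.strs
    }
    ref_seq = build_haplotype(locus, ref_counts).sequence
    contig_len = max(
        [len(ref_seq)]
        + ([len(h.sequence) for h in pair.haplotypes] if pair else [])
        + [t.start + t.frag_len for t in truth.values()]
        + [1]
    )

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": locus.contig, "LN": int(contig_len) + 1}],
    }
    by_frag: dict = {}
    for rec in reads:
        by_frag.setdefault(rec.fragment_id, {})[rec.mate_index] = rec
    unsorted = out / "reads.unsorted.bam"
    with pysam.AlignmentFile(os.fspath(unsorted), "wb", header=header) as bam:
        for fid in sorted(by_frag):
            mates = by_frag[fid]
            for mi, rec in sorted(mates.items()):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = fid
                a.query_sequence = rec.bases
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec.bases))
                a.flag = 0
                a.is_paired = True
                a.is_read1 = mi == 1
                a.is_read2 = mi == 2
                a.is_reverse = rec.is_reverse
                pos = rec.linear_alignment[1] if rec.linear_alignment else 0
                a.reference_id = 0
                a.reference_start = pos
                a.cigarstring = rec.linear_alignment[2] if rec.linear_alignment else f"{len(rec.bases)}M"
                other = mates.get(2 if mi == 1 else 1)
                if other is not None and other.linear_alignment:
                    a.next_reference_id = 0
                    a.next_reference_start = other.linear_alignment[1]
                    a.mate_is_reverse = other.is_reverse
                if rec.graph_alignment is not None:
                    a.set_tag(GRAPH_TAG, rec.graph_alignment.encode())
                bam.write(a)
    pysam.sort("-o", os.fspath(paths["bam"]), os.fspath(unsorted))
    unsorted.unlink()
    pysam.index(os.fspath(paths["bam"]))

    paths["vcf"].write_text(write_genotypes_vcf(locus, genotypes))
    paths["catalog"].write_text(write_locus_catalog([locus]))
    tsv_lines = []
    for s in locus.strs:
        g = genotypes[s.str_id]
        gt = "/".join(str(x) for x in g.allele_sizes)
        tsv_lines.append(f"{s.contig}\t{s.start}\t{s.end}\t{s.repeat_unit}\t{gt}")
    paths["tsv"].write_text("\n".join(tsv_lines) + "\n")
    paths["reference"].write_text(f">{locus.contig}\n{ref_seq}\n")
    truth_lines = ["fragment_id\thap_index\tstart\tfrag_len"]
    for fid in sorted(truth):
        t = truth[fid]
        truth_lines.append(f"{fid}\t{t.hap_index}\t{t.start}\t{t.frag_len}")
    paths["truth"].write_text("\n".join(truth_lines) + "\n")
    return {k: str(v) for k, v in paths.items()}
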