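"""Haplotype construction and diploid pair enumeration.

Given per-STR repeat genotypes (allele sizes in repeat units), a locus with k
heterozygous STRs admits 2^(k-1) distinct unordered phase configurations
(haplotype pairings) for k >= 1, and exactly one otherwise. Each haplotype is
a concrete DNA sequence: flanks and spacers verbatim, each STR expanded to
``unit x count`` (optionally overridden by an interrupted allele structure
such as ``(CGG)10AGG(CGG)9AGG(CGG)9``).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .catalog_io import ConstantSegment, LocusSpec, RepeatGenotype, StrSpec
from .errors import CatalogError, FormatError, GenotypeError

DEFAULT_PAIRING_CAP = 64

_RUN_RE = re.compile(r"\(([ACGT]+)\)(\d+)|([ACGT]+)")


@dataclass(frozen=True)
class AlleleStructure:
    """Run-length description of a repeat allele, e.g. (CGG)10AGG(CGG)9.

    ``runs`` is an ordered tuple of (motif, count) with counts >= 1 and
    adjacent motifs distinct (construction collapses equal neighbours).
    """

    runs: tuple

    def __post_init__(self):
        collapsed = []
        for motif, count in self.runs:
            motif = motif.upper()
            count = int(count)
            if count < 1:
                raise FormatError(f"run ({motif}){count}: counts must be >= 1")
            if not re.fullmatch(r"[ACGT]+", motif):
                raise FormatError(f"run motif {motif!r} is not plain ACGT")
            if collapsed and collapsed[-1][0] == motif:
                collapsed[-1] = (motif, collapsed[-1][1] + count)
            else:
                collapsed.append((motif, count))
        object.__setattr__(self, "runs", tuple(collapsed))

    @property
    def total_units(self) -> int:
        return sum(c for _, c in self.runs)

    def __str__(self) -> str:
        out = []
        for motif, count in self.runs:
            out.append(motif if count == 1 else f"({motif}){count}")
        return "".join(out)


def parse_structure_string(text: str) -> AlleleStructure:
    """Parse "(CGG)10AGG(CGG)9" style text; a bare motif means count 1."""
    if not isinstance(text, str) or not text:
        raise FormatError("empty allele-structure string")
    runs = []
    pos = 0
    for m in _RUN_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(f"cannot parse structure {text!r} at offset {pos}")
        if m.group(1) is not None:
            runs.append((m.group(1), int(m.group(2))))
        else:
            runs.append((m.group(3), 1))
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"cannot parse structure {text!r} at offset {pos}")
    return AlleleStructure(tuple(runs))


def count_repeat_units(s: AlleleStructure) -> int:
    """Total repeat units, counting every unit of every run (interruptions included)."""
    return s.total_units


def interruption_positions(s: AlleleStructure, canonical_motif: str) -> list:
    """1-based unit positions of every unit whose motif differs from the canonical one."""
    canonical = canonical_motif.upper()
    out = []
    pos = 1
    for motif, count in s.runs:
        if motif != canonical:
            out.extend(range(pos, pos + count))
        pos += count
    return out


def expand_structure(s: AlleleStructure) -> str:
    """Concatenate motif x count over the runs."""
    return "".join(motif * count for motif, count in s.runs)


@dataclass
class Haplotype:
    """One concrete locus sequence realized from per-STR allele sizes.

    ``segment_map`` holds one half-open interval on ``sequence`` per locus
    segment (same order as ``locus.segments``); the intervals tile the
    sequence without gaps.
    """

    locus: LocusSpec
    sequence: str
    str_counts: tuple  # per-STR units, ordered by index_in_locus
    segment_map: tuple  # per-segment (start, end)
    structures: Optional[dict] = None  # str_id -> AlleleStructure overrides

    def repeat_interval(self, str_id: str) -> tuple:
        for seg, interval in zip(self.locus.segments, self.segment_map):
            if isinstance(seg, StrSpec) and seg.str_id == str_id:
                return interval
        raise CatalogError(f"haplotype has no STR {str_id!r}")

    def repeat_intervals(self) -> dict:
        return {
            seg.str_id: interval
            for seg, interval in zip(self.locus.segments, self.segment_map)
            if isinstance(seg, StrSpec)
        }

    def count_for(self, str_id: str) -> int:
        for seg, count in zip(self.locus.strs, self.str_counts):
            if seg.str_id == str_id:
                return count
        raise CatalogError(f"haplotype has no STR {str_id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def build_haplotype(
    locus: LocusSpec,
    counts,
    structures: Optional[Mapping[str, AlleleStructure]] = None,
) -> Haplotype:
    """Realize one haplotype from per-STR unit counts.

    ``counts`` maps str_id -> units (or is a sequence ordered by STR index).
    A structure override must total exactly the given count for its STR.
    """
    strs = locus.strs
    if not isinstance(counts, Mapping):
        if len(counts) != len(strs):
            raise GenotypeError(f"expected {len(strs)} counts, got {len(counts)}")
        counts = {s.str_id: c for s, c in zip(strs, counts)}
    missing = {s.str_id for s in strs} - set(counts)
    if missing:
        raise GenotypeError(f"no allele size for STR(s) {sorted(missing)}")
    structures = dict(structures or {})
    parts = []
    segment_map = []
    pos = 0
    ordered_counts = []
    for seg in locus.segments:
        if isinstance(seg, ConstantSegment):
            piece = seg.sequence
        else:
            count = int(counts[seg.str_id])
            if count < 0:
                raise GenotypeError(f"{seg.str_id}: negative repeat count")
            struct = structures.get(seg.str_id)
            if struct is not None:
                if struct.total_units != count:
                    raise GenotypeError(
                        f"{seg.str_id}: structure totals {struct.total_units} units, "
                        f"genotype says {count}"
                    )
                piece = expand_structure(struct)
            else:
                piece = seg.repeat_unit * count
            ordered_counts.append(count)
        parts.append(piece)
        segment_map.append((pos, pos + len(piece)))
        pos += len(piece)
    return Haplotype(
        locus=locus,
        sequence="".join(parts),
        str_counts=tuple(ordered_counts),
        segment_map=tuple(segment_map),
        structures=structures or None,
    )


@dataclass
class HaplotypePair:
    """An unordered diploid candidate; ``hap2`` is None on haploid loci.

    Canonical form: ``hap1.sequence <= hap2.sequence``. ``cumulative_score``
    is set only after read-alignment scoring.
    """

    hap1: Haplotype
    hap2: Optional[Haplotype] = None
    cumulative_score: Optional[int] = None
    phase_id: str = ""

    def __post_init__(self):
        if self.hap2 is not None and self.hap2.sequence < self.hap1.sequence:
            self.hap1, self.hap2 = self.hap2, self.hap1
        if not self.phase_id:
            self.phase_id = self._default_phase_id()

    def _default_phase_id(self) -> str:
        def fmt(h):
            return ",".join(str(c) for c in h.str_counts)
        if self.hap2 is None:
            return fmt(self.hap1)
        return f"{fmt(self.hap1)}|{fmt(self.hap2)}"

    @property
    def haplotypes(self) -> tuple:
        return (self.hap1,) if self.hap2 is None else (self.hap1, self.hap2)

    @property
    def is_haploid(self) -> bool:
        return self.hap2 is None

    def sequence_key(self) -> tuple:
        return tuple(sorted(h.sequence for h in self.haplotypes))


def enumerate_haplotype_pairs(
    locus: LocusSpec,
    genotypes: Mapping[str, RepeatGenotype],
    max_pairings: int = DEFAULT_PAIRING_CAP,
) -> list:
    """All distinct unordered haplotype pairings consistent with the genotypes.

    With k heterozygous STRs a diploid locus yields 2^(k-1) pairings (one when
    k = 0); haploid loci yield a single one-haplotype "pair". Homozygous STRs
    contribute a single allele, so no duplicate pairings are produced.
    """
    strs = locus.strs
    missing = [s.str_id for s in strs if s.str_id not in genotypes]
    if missing:
        raise GenotypeError(f"locus {locus.locus_id!r}: missing genotype for {missing}")
    ploidies = {genotypes[s.str_id].ploidy for s in strs}
    if len(ploidies) != 1:
        raise GenotypeError(f"locus {locus.locus_id!r}: mixed ploidy across STRs")
    ploidy = ploidies.pop()

    if ploidy == 1:
        counts = {s.str_id: genotypes[s.str_id].allele_sizes[0] for s in strs}
        return [HaplotypePair(hap1=build_haplotype(locus, counts))]

    k = sum(1 for s in strs if genotypes[s.str_id].is_het)
    expected = 2 ** max(k - 1, 0)
    if expected > max_pairings:
        raise GenotypeError(
            f"locus {locus.locus_id!r}: {k} heterozygous STRs imply {expected} pairings "
            f"(cap {max_pairings}); split the locus"
        )

    # Brute-force orientation assignment with unordered-pair deduplication.
    per_str = [genotypes[s.str_id].allele_sizes for s in strs]
    seen = set()
    pairs = []
    for orient in itertools.product((0, 1), repeat=len(strs)):
        c1 = {s.str_id: alleles[o] for s, alleles, o in zip(strs, per_str, orient)}
        c2 = {s.str_id: alleles[1 - o] for s, alleles, o in zip(strs, per_str, orient)}
        h1 = build_haplotype(locus, c1)
        h2 = build_haplotype(locus, c2)
        key = tuple(sorted((h1.sequence, h2.sequence)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(HaplotypePair(hap1=h1, hap2=h2))
    pairs.sort(key=lambda p: p.sequence_key())
    return pairs
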