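"""Read classification, lane packing, and pileup quality metrics.

Reads are classified per STR as *spanning* (cover the whole tract with
anchor sequence in both flanks), *flanking* (cross exactly one tract
boundary), *in-repeat* (wholly inside the tract), or *flank-only*. Metrics
mirror the visual heuristics an analyst applies to a pileup: even coverage of
both alleles, spanning support for short alleles, in-repeat depth for
expanded alleles, and indel noise inside the repeat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .catalog_io import LocusSpec
from .errors import AlignmentError, CatalogError
from .fragment_assignment import FragmentStats
from .haplotype_model import Haplotype, HaplotypePair
from .realignment import ReadAlignment

MIN_ANCHOR = 5
EXPANSION_WEAK_FRAC = 0.3
NOISY_INDEL_PER_KB = 20.0
SPANNING_WEAK_MAX = 1
LANE_GAP = 5

CLASS_PRIORITY = ("spanning", "flanking", "in_repeat", "flank_only")


@dataclass
class PlacedRead:
    """A chosen alignment annotated for rendering."""

    aln: ReadAlignment
    read_class: str
    faint: bool = False
    lane: int = -1

    @property
    def hap_index(self) -> int:
        return self.aln.hap_index

    @property
    def fragment_id(self) -> str:
        return self.aln.fragment_id


@dataclass
class Pileup:
    """Final, render-ready state of one locus."""

    locus: LocusSpec
    pair: HaplotypePair
    placed: list  # list[PlacedRead]
    stats: Optional[FragmentStats] = None
    counters: Dict[str, int] = field(default_factory=dict)

    def by_hap(self, hap_index: int) -> list:
        return [p for p in self.placed if p.hap_index == hap_index]


def classify_read(
    aln: ReadAlignment,
    hap: Haplotype,
    str_id: str,
    min_anchor: int = MIN_ANCHOR,
) -> str:
    """Class of one alignment relative to one repeat tract.

    Spanning requires at least ``min_anchor`` aligned bases beyond each tract
    boundary so a 1 bp overhang never counts as a spanning call.
    """
    rs, re_ = hap.repeat_interval(str_id)
    s, e = aln.start, aln.end
    if e <= rs or s >= re_:
        return "flank_only"
    if s <= rs - min_anchor and e >= re_ + min_anchor:
        return "spanning"
    if s >= rs and e <= re_:
        return "in_repeat"
    return "flanking"


def classify_read_locus(aln: ReadAlignment, hap: Haplotype, min_anchor: int = MIN_ANCHOR) -> str:
    """Most informative class across all STRs of the locus."""
    classes = {
        classify_read(aln, hap, s.str_id, min_anchor) for s in hap.locus.strs
    }
    for cls in CLASS_PRIORITY:
        if cls in classes:
            return cls
    raise AlignmentError("classification produced no class")  # pragma: no cover


def assign_lanes(placed: Sequence[PlacedRead], gap: int = LANE_GAP) -> None:
    """Greedy interval packing per haplotype, mates sharing a lane.

    Mates of one fragment are packed as a single interval (their union) so
    they land in the same lane; mates that overlap each other are packed
    separately. Each interval takes the lowest lane whose previous occupant
    ends at least ``gap`` bp before it starts.
    """
    by_hap: dict = {}
    for p in placed:
        by_hap.setdefault(p.hap_index, {}).setdefault(p.fragment_id or id(p), []).append(p)
    for frags in by_hap.values():
        units = []  # (start, end, [PlacedRead,...])
        for members in frags.values():
            members.sort(key=lambda p: p.aln.start)
            if len(members) == 2 and members[0].aln.end > members[1].aln.start:
                for m in members:
                    units.append((m.aln.start, m.aln.end, [m]))
            else:
                units.append(
                    (members[0].aln.start, max(m.aln.end for m in members), members)
                )
        units.sort(key=lambda u: (u[0], u[1]))
        lane_ends: list = []
        for start, end, members in units:
            lane = None
            for li, le in enumerate(lane_ends):
                if le + gap <= start:
                    lane = li
                    break
            if lane is None:
                lane = len(lane_ends)
                lane_ends.append(end)
            else:
                lane_ends[lane] = end
            for m in members:
                m.lane = lane


@dataclass
class PileupMetrics:
    """Per-locus QC metrics and the flags behind the visual heuristics."""

    spanning_by_allele: dict  # (hap_index, str_id) -> count
    flanking_by_allele: dict
    in_repeat_by_allele: dict
    repeat_depth_by_allele: dict  # (hap_index, str_id) -> mean depth
    flank_depth_by_allele: dict  # hap_index -> mean depth over constant segments
    depth_evenness: dict  # hap_index -> coefficient of variation
    in_repeat_indel_per_kb: float
    flank_to_spanning_ratio: dict  # (hap_index, str_id) -> ratio (raw, no flag)
    short_allele_weak: bool
    expansion_weak: bool
    noisy_repeat: bool

    def to_dict(self) -> dict:
        def keyed(d):
            return {
                "|".join(str(x) for x in (k if isinstance(k, tuple) else (k,))): v
                for k, v in d.items()
            }
        return {
            "spanning_by_allele": keyed(self.spanning_by_allele),
            "flanking_by_allele": keyed(self.flanking_by_allele),
            "in_repeat_by_allele": keyed(self.in_repeat_by_allele),
            "repeat_depth_by_allele": keyed(self.repeat_depth_by_allele),
            "flank_depth_by_allele": keyed(self.flank_depth_by_allele),
            "depth_evenness": keyed(self.depth_evenness),
            "in_repeat_indel_per_kb": self.in_repeat_indel_per_kb,
            "flank_to_spanning_ratio": keyed(self.flank_to_spanning_ratio),
            "short_allele_weak": self.short_allele_weak,
            "expansion_weak": self.expansion_weak,
            "noisy_repeat": self.noisy_repeat,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def _depth_array(hap: Haplotype, placed: Sequence[PlacedRead]) -> np.ndarray:
    depth = np.zeros(len(hap.sequence), dtype=np.int32)
    for p in placed:
        pos = p.aln.start
        for op, ln, _ in p.aln.ops:
            if op in ("match", "mismatch"):
                depth[pos:pos + ln] += 1
                pos += ln
            elif op == "deletion":
                pos += ln
    return depth


def compute_metrics(
    pileup: Pileup,
    min_anchor: int = MIN_ANCHOR,
    expansion_weak_frac: float = EXPANSION_WEAK_FRAC,
    noisy_indel_per_kb: float = NOISY_INDEL_PER_KB,
    spanning_weak_max: int = SPANNING_WEAK_MAX,
) -> PileupMetrics:
    """QC metrics over a finalized pileup.

    ``short_allele_weak`` fires when a spannable allele (tract short enough
    for a single read to bridge with anchors) has <= ``spanning_weak_max``
    spanning reads; ``expansion_weak`` when a tract's depth falls below
    ``expansion_weak_frac`` of the same haplotype's flank depth;
    ``noisy_repeat`` when in-repeat alignments carry more than
    ``noisy_indel_per_kb`` indel events per aligned kb.
    """
    haps = pileup.pair.haplotypes
    spanning: dict = {}
    flanking: dict = {}
    in_repeat: dict = {}
    repeat_depth: dict = {}
    flank_depth: dict = {}
    evenness: dict = {}
    ratio: dict = {}
    max_read_len = max((p.aln.read_length for p in pileup.placed), default=0)
    indel_events = 0
    aligned_in_repeat = 0
    short_weak = False
    exp_weak = False

    for hi, hap in enumerate(haps):
        placed = pileup.by_hap(hi)
        depth = _depth_array(hap, placed)
        intervals = hap.repeat_intervals()
        for s in hap.locus.strs:
            key = (hi, s.str_id)
            spanning[key] = flanking[key] = in_repeat[key] = 0
            for p in placed:
                cls = classify_read(p.aln, hap, s.str_id, min_anchor)
                if cls == "spanning":
                    spanning[key] += 1
                elif cls == "flanking":
                    flanking[key] += 1
                elif cls == "in_repeat":
                    in_repeat[key] += 1
            rs, re_ = intervals[s.str_id]
            repeat_depth[key] = float(depth[rs:re_].mean()) if re_ > rs else 0.0
            ratio[key] = (
                flanking[key] / spanning[key] if spanning[key] else float("inf")
            )
        const_mask = np.ones(len(hap.sequence), dtype=bool)
        for rs, re_ in intervals.values():
            const_mask[rs:re_] = False
        flank_depth[hi] = float(depth[const_mask].mean()) if const_mask.any() else 0.0
        # trim coverage ramp zones at the haplotype ends before the CV; the
        # ramp extends roughly one fragment length when fragments are local
        trim = max_read_len
        if pileup.stats is not None and pileup.stats.n_pairs > 0:
            trim = max(trim, int(pileup.stats.mean_len + 2 * pileup.stats.sd_len))
        trim = min(trim, (len(depth) - 1) // 2)
        interior = depth[trim:len(depth) - trim]
        if interior.size and interior.mean() > 0:
            evenness[hi] = float(interior.std() / interior.mean())
        else:
            evenness[hi] = float("inf") if interior.size else 0.0
        for s in hap.locus.strs:
            key = (hi, s.str_id)
            rs, re_ = intervals[s.str_id]
            tract_len = re_ - rs
            spannable = tract_len + 2 * min_anchor <= max_read_len
            if spannable and tract_len > 0 and spanning[key] <= spanning_weak_max:
                short_weak = True
            if tract_len > 0 and flank_depth[hi] > 0 and (
                repeat_depth[key] < expansion_weak_frac * flank_depth[hi]
            ):
                exp_weak = True
        # indel noise inside repeat tracts
        for p in placed:
            pos = p.aln.start
            for op, ln, _ in p.aln.ops:
                if op in ("match", "mismatch", "deletion"):
                    for rs, re_ in intervals.values():
                        lo, hi_ = max(pos, rs), min(pos + ln, re_)
                        if lo < hi_:
                            aligned_in_repeat += hi_ - lo
                            if op == "deletion":
                                indel_events += 1
                    pos += ln
                elif op == "insertion":
                    for rs, re_ in intervals.values():
                        if rs <= pos < re_:
                            indel_events += 1

    indel_rate = 1000.0 * indel_events / aligned_in_repeat if aligned_in_repeat else 0.0
    return PileupMetrics(
        spanning_by_allele=spanning,
        flanking_by_allele=flanking,
        in_repeat_by_allele=in_repeat,
        repeat_depth_by_allele=repeat_depth,
        flank_depth_by_allele=flank_depth,
        depth_evenness=evenness,
        in_repeat_indel_per_kb=indel_rate,
        flank_to_spanning_ratio=ratio,
        short_allele_weak=short_weak,
        expansion_weak=exp_weak,
        noisy_repeat=indel_rate > noisy_indel_per_kb,
    )
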