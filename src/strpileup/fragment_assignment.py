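"""Fragment-length based assignment of read pairs to haplotype positions.

The mean fragment (insert) length is estimated from pairs that map uniquely
and entirely within the constant flanking sequence. For every read pair the
joint placements on each haplotype are enumerated (Cartesian product of the
mates' placements), gated on orientation and a maximum length, and the
placements whose implied fragment length is closest to the flank mean are
kept; one of those is then drawn uniformly at random. A draw is *ambiguous* —
and rendered faint — when the tied candidates live on more than one
haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog_io import ConstantSegment, ReadRecord
from .haplotype_model import Haplotype, HaplotypePair
from .realignment import ReadAlignment

logger = logging.getLogger(__name__)

DEFAULT_FRAG_MEAN = 450.0
DEFAULT_FRAG_SD = 100.0
MIN_FLANK_PAIRS = 10
FRAG_GATE_SD = 4.0


@dataclass(frozen=True)
class FragmentStats:
    """Fragment-length distribution summary; ``n_pairs`` = 0 marks the
    configured fallback (no usable flank pairs)."""

    mean_len: float
    sd_len: float
    n_pairs: int


@dataclass(frozen=True)
class AlignmentPairCandidate:
    """One joint placement of both mates on the same haplotype."""

    aln1: ReadAlignment
    aln2: ReadAlignment
    fragment_len: int
    distance: float

    @property
    def hap_index(self) -> int:
        return self.aln1.hap_index


def _interval_in_constant_segments(s: int, e: int, hap: Haplotype) -> bool:
    """True when [s, e) overlaps no repeat tract."""
    for seg, (a, b) in zip(hap.locus.segments, hap.segment_map):
        if isinstance(seg, ConstantSegment):
            continue
        if not (e <= a or s >= b):
            return False
    return True


def _span(a1: ReadAlignment, a2: ReadAlignment) -> int:
    return max(a1.end, a2.end) - min(a1.start, a2.start)


def _orientation_ok(a1, a2, rev1, rev2) -> bool:
    if rev1 is None or rev2 is None:
        return True
    if rev1 == rev2:
        return False
    left_rev = rev1 if a1.start <= a2.start else rev2
    return left_rev is False


def estimate_fragment_stats(
    placements: Mapping[str, tuple],
    pair: HaplotypePair,
    min_flank_pairs: int = MIN_FLANK_PAIRS,
    default_mean: float = DEFAULT_FRAG_MEAN,
    default_sd: float = DEFAULT_FRAG_SD,
) -> FragmentStats:
    """Mean/sd of fragment length over uniquely placed all-flank pairs.

    ``placements`` maps fragment_id -> (placements_mate1, placements_mate2)
    where each element is the mate's list of alignments on the selected pair
    (hap_index set). A pair qualifies when both mates share a haplotype with
    exactly one placement each and the whole fragment interval lies in
    constant sequence (a pair bridging a repeat has a haplotype-dependent
    span and would bias the estimate). Falls back to (default_mean,
    default_sd) with a warning below ``min_flank_pairs``.
    """
    spans = []
    haps = pair.haplotypes
    for fid in sorted(placements):
        p1, p2 = placements[fid]
        if not p1 or not p2:
            continue
        by_hap1 = _group_by_hap(p1)
        by_hap2 = _group_by_hap(p2)
        shared = sorted(set(by_hap1) & set(by_hap2))
        if not shared:
            continue
        hi = shared[0]
        if len(by_hap1[hi]) != 1 or len(by_hap2[hi]) != 1:
            continue
        a1, a2 = by_hap1[hi][0], by_hap2[hi][0]
        hap = haps[hi]
        # the whole fragment interval must avoid the repeats: a pair bridging
        # a repeat has a haplotype-dependent span and would bias the estimate
        lo = min(a1.start, a2.start)
        hi_end = max(a1.end, a2.end)
        if not _interval_in_constant_segments(lo, hi_end, hap):
            continue
        spans.append(_span(a1, a2))
    if len(spans) < min_flank_pairs:
        logger.warning(
            "only %d flank-mapped pair(s) (< %d); falling back to fragment length %.0f +- %.0f",
            len(spans), min_flank_pairs, default_mean, default_sd,
        )
        return FragmentStats(mean_len=default_mean, sd_len=default_sd, n_pairs=0)
    arr = np.asarray(spans, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return FragmentStats(mean_len=float(arr.mean()), sd_len=sd, n_pairs=len(arr))


def _group_by_hap(alns: Sequence[ReadAlignment]) -> dict:
    out: dict = {}
    for a in alns:
        out.setdefault(a.hap_index, []).append(a)
    return out


def enumerate_pair_candidates(
    placements1: Sequence[ReadAlignment],
    placements2: Sequence[ReadAlignment],
    stats: FragmentStats,
    rev1: Optional[bool] = None,
    rev2: Optional[bool] = None,
    gate_sd: float = FRAG_GATE_SD,
) -> list:
    """Joint placements per shared haplotype, orientation- and length-gated.

    The gate keeps fragment_len <= mean + gate_sd * sd and
    fragment_len >= the longer mate, pruning the quadratic in-repeat candidate
    space without touching plausible placements. Returns [] when the mates
    share no haplotype (the caller counts the dropped fragment).
    """
    by1, by2 = _group_by_hap(placements1), _group_by_hap(placements2)
    max_len = stats.mean_len + gate_sd * stats.sd_len
    out = []
    for hi in sorted(set(by1) & set(by2)):
        for a1 in by1[hi]:
            for a2 in by2[hi]:
                if not _orientation_ok(a1, a2, rev1, rev2):
                    continue
                span = _span(a1, a2)
                if span < max(a1.read_length, a2.read_length):
                    continue
                if span > max_len:
                    continue
                out.append(
                    AlignmentPairCandidate(
                        aln1=a1, aln2=a2, fragment_len=span,
                        distance=abs(span - stats.mean_len),
                    )
                )
    out.sort(key=lambda c: (c.hap_index, c.aln1.start, c.aln2.start))
    return out


def select_pair_alignment(
    candidates: Sequence[AlignmentPairCandidate],
    rng: np.random.Generator,
) -> tuple:
    """Keep min-distance candidates, draw one uniformly: (choice, ambiguous).

    ``ambiguous`` is True when the tied candidates span more than one
    haplotype — the read pair cannot be attributed to a single haplotype and
    is rendered faint.
    """
    if not candidates:
        raise ValueError("select_pair_alignment requires at least one candidate")
    dmin = min(c.distance for c in candidates)
    tied = [c for c in candidates if c.distance == dmin]
    choice = tied[int(rng.integers(len(tied)))]
    ambiguous = len({c.hap_index for c in tied}) > 1
    return choice, ambiguous


def assign_fragments(
    placements: Mapping[str, tuple],
    reads_by_fragment: Mapping[str, tuple],
    stats: FragmentStats,
    rng: np.random.Generator,
    gate_sd: float = FRAG_GATE_SD,
) -> tuple:
    """Assign every pair: ``(assignments, counters)``.

    ``assignments`` maps fragment_id -> (AlignmentPairCandidate, ambiguous);
    fragments are processed in sorted id order so a fixed seed reproduces the
    pileup byte for byte. ``counters`` tallies dropped fragments.
    """
    assignments = {}
    counters = {"no_shared_haplotype": 0, "no_candidates": 0}
    for fid in sorted(placements):
        p1, p2 = placements[fid]
        rec1, rec2 = reads_by_fragment[fid]
        cands = enumerate_pair_candidates(
            p1, p2, stats, rev1=rec1.is_reverse, rev2=rec2.is_reverse, gate_sd=gate_sd
        )
        if not cands:
            if set(_group_by_hap(p1)) & set(_group_by_hap(p2)):
                counters["no_candidates"] += 1
            else:
                counters["no_shared_haplotype"] += 1
            continue
        assignments[fid] = select_pair_alignment(cands, rng)
    if counters["no_shared_haplotype"] or counters["no_candidates"]:
        logger.info("dropped fragments: %s", counters)
    return assignments, counters
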