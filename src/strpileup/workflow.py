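"""End-to-end pileup construction: the glue between the stage modules.

``run_locus`` takes a locus, its genotypes and the loaded reads and executes
the full pipeline: candidate haplotype-pair enumeration, read placement
(graph projection or de-novo alignment), pair selection by cumulative score,
fragment-length estimation, per-fragment placement assignment, read
classification, lane packing, and metric computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog_io import LocusSpec, ReadRecord, RepeatGenotype, group_fragments
from .config import DEFAULT_CONFIG, PipelineConfig
from .fragment_assignment import FragmentStats, assign_fragments, estimate_fragment_stats
from .haplotype_model import HaplotypePair, enumerate_haplotype_pairs
from .interruption_annotation import ConsensusResult, call_consensus_structure
from .pileup import Pileup, PileupMetrics, PlacedRead, assign_lanes, classify_read_locus, compute_metrics
from .realignment import read_placements, select_haplotype_pair

logger = logging.getLogger(__name__)


@dataclass
class LocusResult:
    pileup: Pileup
    pair: HaplotypePair
    metrics: PileupMetrics
    stats: FragmentStats
    counters: dict

    def consensus_structures(
        self, min_depth: Optional[int] = None, min_frac: Optional[float] = None,
        config: PipelineConfig = DEFAULT_CONFIG,
    ) -> dict:
        """(hap_index, str_id) -> ConsensusResult over the selected pair."""
        out = {}
        for hi, hap in enumerate(self.pair.haplotypes):
            for s in hap.locus.strs:
                out[(hi, s.str_id)] = call_consensus_structure(
                    self.pileup, hap, s.str_id,
                    min_depth=config.min_depth if min_depth is None else min_depth,
                    min_frac=config.min_frac if min_frac is None else min_frac,
                )
        return out


def _placements_on_pair(rec: ReadRecord, pair: HaplotypePair, scheme, cache: dict) -> list:
    """Top-scoring placements of one read across BOTH haplotypes of the pair.

    Placements are first computed per haplotype, then filtered to the global
    maximum score over the pair — a read that fits one allele strictly better
    is only ever placed there; equally good placements on both alleles are
    all kept (that is the ambiguity the fragment stage may resolve).
    """
    alns = []
    for hi, hap in enumerate(pair.haplotypes):
        key = (rec.fragment_id, rec.mate_index, hap.sequence)
        if key not in cache:
            cache[key] = read_placements(rec, hap, scheme, hap_index=hi)
        alns.extend(
            a if a.hap_index == hi else replace(a, hap_index=hi) for a in cache[key]
        )
    if not alns:
        return []
    best = max(a.score for a in alns)
    return [a for a in alns if a.score == best]


def run_locus(
    locus: LocusSpec,
    genotypes: Mapping[str, RepeatGenotype],
    reads: Sequence[ReadRecord],
    config: PipelineConfig = DEFAULT_CONFIG,
    seed: Optional[int] = None,
) -> LocusResult:
    """Run the whole pipeline for one locus and return its result bundle."""
    seed = config.seed if seed is None else seed
    scheme = config.scheme
    candidates = enumerate_haplotype_pairs(locus, genotypes, max_pairings=config.pairing_cap)
    pair = select_haplotype_pair(candidates, reads, scheme)
    logger.info("locus %s: selected pair %s from %d candidate(s)",
                locus.locus_id, pair.phase_id, len(candidates))

    pairs, orphans = group_fragments(reads)
    counters = {"orphans": len(orphans)}
    cache: dict = {}
    placements = {
        fid: (
            _placements_on_pair(r1, pair, scheme, cache),
            _placements_on_pair(r2, pair, scheme, cache),
        )
        for fid, (r1, r2) in pairs.items()
    }
    stats = estimate_fragment_stats(
        placements, pair,
        min_flank_pairs=config.min_flank_pairs,
        default_mean=config.default_frag_mean,
        default_sd=config.default_frag_sd,
    )
    rng = np.random.default_rng(seed)
    assignments, drop_counters = assign_fragments(
        placements, pairs, stats, rng, gate_sd=config.frag_gate_sd
    )
    counters.update(drop_counters)

    placed = []
    haps = pair.haplotypes
    for fid in sorted(assignments):
        cand, ambiguous = assignments[fid]
        hap = haps[cand.hap_index]
        for aln in (cand.aln1, cand.aln2):
            placed.append(
                PlacedRead(
                    aln=aln,
                    read_class=classify_read_locus(aln, hap, config.min_anchor),
                    faint=ambiguous,
                )
            )
    assign_lanes(placed, gap=config.lane_gap)
    pileup = Pileup(locus=locus, pair=pair, placed=placed, stats=stats, counters=counters)
    metrics = compute_metrics(
        pileup,
        min_anchor=config.min_anchor,
        expansion_weak_frac=config.expansion_weak_frac,
        noisy_indel_per_kb=config.noisy_indel_per_kb,
        spanning_weak_max=config.spanning_weak_max,
    )
    return LocusResult(pileup=pileup, pair=pair, metrics=metrics, stats=stats, counters=counters)
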