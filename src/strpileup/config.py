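"""All tunable thresholds in one place, loadable from a YAML/JSON mapping."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

from .realignment import ScoringScheme


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults for every stage.

    flank_len            bp of reference flank around the repeats; also the
                         BAM fetch margin. 1000 bp comfortably exceeds any
                         short-read fragment.
    min_flank_pairs      minimum uniquely-placed all-flank pairs before the
                         fragment-length fallback kicks in.
    default_frag_mean/sd fallback fragment-length distribution (bp).
    frag_gate_sd         joint placements longer than mean + k*sd are pruned.
    min_anchor           aligned bp required beyond each tract boundary for a
                         spanning call; avoids 1 bp-overhang spanning calls.
    expansion_weak_frac  tract depth below this fraction of flank depth flags
                         a possibly overestimated expansion.
    noisy_indel_per_kb   in-repeat indel events per aligned kb above which the
                         repeat is flagged noisy.
    spanning_weak_max    spannable alleles with <= this many spanning reads
                         are flagged weak.
    lane_gap             minimum bp between reads sharing a lane.
    pairing_cap          maximum haplotype pairings before refusing a locus.
    min_depth, min_frac  consensus thresholds for interruption calling.
    seed                 locus RNG seed (all randomness flows from it).
    """

    flank_len: int = 1000
    min_flank_pairs: int = 10
    default_frag_mean: float = 450.0
    default_frag_sd: float = 100.0
    frag_gate_sd: float = 4.0
    min_anchor: int = 5
    expansion_weak_frac: float = 0.3
    noisy_indel_per_kb: float = 20.0
    spanning_weak_max: int = 1
    lane_gap: int = 5
    pairing_cap: int = 64
    min_depth: int = 5
    min_frac: float = 0.8
    seed: int = 42
    match: int = 5
    mismatch: int = -4
    gap_open: int = -8
    gap_extend: int = -2

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            match=self.match, mismatch=self.mismatch,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
        )

    @classmethod
    def from_mapping(cls, mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)


DEFAULT_CONFIG = PipelineConfig()
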