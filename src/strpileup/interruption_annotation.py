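"""Consensus allele structures (interruption maps) from a finished pileup.

The repeat tract of the selected haplotype is framed into unit-length
columns anchored at the tract start. Each boundary-anchored read (spanning
or flanking, unambiguously assigned) votes with the unit-length word its
alignment places on a column; a column is called as an alternative motif
(an interruption, e.g. AGG inside a CGG tract) when enough reads agree.
In-repeat reads are excluded from the vote: their placement inside the tract
is ambiguous up to unit shifts, so their words would smear interruptions
across columns rather than sharpen them — deep expansions therefore resolve
near the tract ends and report unresolved columns in the middle, which is
exactly what the assignment ambiguity warrants. 5' and 3' ends are treated
symmetrically.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import CatalogError
from .haplotype_model import AlleleStructure, Haplotype, count_repeat_units
from .pileup import Pileup

MIN_DEPTH = 5
MIN_FRAC = 0.8
CONSENSUS_CLASSES = ("spanning", "flanking")


@dataclass
class ConsensusResult:
    """Outcome of structure calling for one allele of one STR."""

    structure: AlleleStructure
    support: list  # per unit column: Counter of words (empty below coverage)
    unresolved_units: list  # 0-based unit indices below min_depth
    resolved: bool  # False when no column met min_depth

    @property
    def depths(self) -> list:
        return [sum(c.values()) for c in self.support]


def _read_word(aln, col_start: int, col_end: int) -> Optional[str]:
    """Read bases gaplessly covering hap interval [col_start, col_end), else None."""
    pos = aln.start
    out = []
    need = col_end - col_start
    for op, ln, payload in aln.ops:
        if op in ("match", "mismatch"):
            lo, hi = max(pos, col_start), min(pos + ln, col_end)
            if lo < hi:
                if op == "match":
                    # match payload is None; bases equal the haplotype's, which
                    # the caller reconstructs — store a placeholder resolved later
                    out.append((lo, hi, None))
                else:
                    off = lo - pos
                    out.append((lo, hi, payload[off:off + (hi - lo)]))
            pos += ln
        elif op == "deletion":
            if not (pos + ln <= col_start or pos >= col_end):
                return None  # gap inside the column: no clean word
            pos += ln
        elif op == "insertion":
            if col_start < pos < col_end:
                return None
        # softclips consume no haplotype positions
    covered = sum(hi - lo for lo, hi, _ in out)
    if covered != need:
        return None
    return out  # list of pieces; caller substitutes hap bases for match pieces


def call_consensus_structure(
    pileup: Pileup,
    hap: Haplotype,
    str_id: str,
    min_depth: int = MIN_DEPTH,
    min_frac: float = MIN_FRAC,
) -> ConsensusResult:
    """Per-unit-column consensus over anchored reads for one allele.

    A column keeps the canonical unit unless at least ``min_frac`` of at
    least ``min_depth`` covering reads agree on one alternative unit-length
    word. Columns below ``min_depth`` are reported unresolved (and kept
    canonical in the emitted structure); if every column is unresolved the
    result carries an empty structure and ``resolved=False``.
    """
    seg = hap.locus.get_str(str_id)
    unit = seg.repeat_unit
    ulen = len(unit)
    rs, re_ = hap.repeat_interval(str_id)
    n_units = (re_ - rs) // ulen
    try:
        hap_index = next(
            i for i, h in enumerate(pileup.pair.haplotypes) if h is hap
        )
    except StopIteration:
        raise CatalogError("haplotype is not part of the pileup's selected pair") from None

    support = [Counter() for _ in range(n_units)]
    for placed in pileup.placed:
        if placed.hap_index != hap_index or placed.faint:
            continue
        if placed.read_class not in CONSENSUS_CLASSES:
            continue
        aln = placed.aln
        first_u = max((aln.start - rs + ulen - 1) // ulen, 0)
        last_u = min((aln.end - rs) // ulen, n_units)
        for u in range(first_u, last_u):
            c0, c1 = rs + u * ulen, rs + (u + 1) * ulen
            pieces = _read_word(aln, c0, c1)
            if pieces is None:
                continue
            word = "".join(
                hap.sequence[lo:hi] if sub is None else sub for lo, hi, sub in pieces
            )
            support[u][word] += 1

    runs = []
    unresolved = []
    any_resolved = False
    for u in range(n_units):
        counts = support[u]
        depth = sum(counts.values())
        if depth < min_depth:
            unresolved.append(u)
            motif = unit
        else:
            any_resolved = True
            motif = unit
            alt, alt_n = None, 0
            for word, n in counts.items():
                if word != unit and n > alt_n:
                    alt, alt_n = word, n
            if alt is not None and "N" not in alt and alt_n / depth >= min_frac:
                motif = alt
        runs.append((motif, 1))
    if not any_resolved:
        return ConsensusResult(
            structure=AlleleStructure(()), support=support,
            unresolved_units=unresolved, resolved=False,
        )
    return ConsensusResult(
        structure=AlleleStructure(tuple(runs)),
        support=support,
        unresolved_units=unresolved,
        resolved=True,
    )


@dataclass
class StructureDiff:
    equal: bool
    unit_count_delta: int
    run_diffs: list  # (run_a or None, run_b or None) aligned by index


def compare_structures(a: AlleleStructure, b: AlleleStructure) -> StructureDiff:
    """Run-by-run comparison; delta = units(a) - units(b)."""
    diffs = []
    for i in range(max(len(a.runs), len(b.runs))):
        ra = a.runs[i] if i < len(a.runs) else None
        rb = b.runs[i] if i < len(b.runs) else None
        if ra != rb:
            diffs.append((ra, rb))
    return StructureDiff(
        equal=a.runs == b.runs,
        unit_count_delta=count_repeat_units(a) - count_repeat_units(b),
        run_diffs=diffs,
    )
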