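"""Read-to-haplotype alignment and haplotype-pair selection.

Two placement routes feed the pileup:

* **projection** — reads that already carry a graph-alignment path through the
  locus segments are laid onto each candidate haplotype; a path anchored in
  any constant segment has one placement, while a path wholly inside a repeat
  slides in repeat-unit steps (U - u + 1 placements on a U-unit tract).
* **de novo** — reads without a path are aligned with an affine-gap
  (Gotoh) local dynamic program over the full haplotype; *all* placements
  tied at the maximum score are reported, which is what makes in-repeat
  placement ambiguity explicit downstream.

Candidate diploid pairs are ranked by cumulative score: for every read, the
best score on either haplotype of the pair, summed over reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

from .catalog_io import ConstantSegment, ReadRecord
from .errors import AlignmentError
from .haplotype_model import Haplotype, HaplotypePair

logger = logging.getLogger(__name__)

NEG_INF = np.int32(-(10 ** 8))

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_seq(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring. A gap of length L scores gap_open + L * gap_extend;
    soft-clipped bases score 0; N matches nothing (always the mismatch score)."""

    match: int = 5
    mismatch: int = -4
    gap_open: int = -8
    gap_extend: int = -2

    def __post_init__(self):
        if self.match <= 0:
            raise AlignmentError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise AlignmentError("penalties must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class ReadAlignment:
    """One placement of one read on one haplotype.

    ``ops`` is a tuple of (op, length, payload) with op in {"match",
    "mismatch", "insertion", "deletion", "softclip"}; mismatch / insertion /
    softclip payloads carry the read bases consumed by the op.
    """

    hap_index: int
    start: int
    ops: tuple
    score: int
    fragment_id: str = ""
    mate_index: int = 0

    @property
    def end(self) -> int:
        return self.start + sum(
            ln for op, ln, _ in self.ops if op in ("match", "mismatch", "deletion")
        )

    @property
    def read_length(self) -> int:
        return sum(ln for op, ln, _ in self.ops if op in ("match", "mismatch", "insertion", "softclip"))

    def read_bases(self) -> str:
        return "".join(p for op, ln, p in self.ops if p is not None and op != "deletion")


def score_ops(ops: Sequence[tuple], scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    total = 0
    for op, ln, _ in ops:
        if op == "match":
            total += scheme.match * ln
        elif op == "mismatch":
            total += scheme.mismatch * ln
        elif op in ("insertion", "deletion"):
            total += scheme.gap_open + scheme.gap_extend * ln
        elif op == "softclip":
            pass
        else:
            raise AlignmentError(f"unknown alignment op {op!r}")
    return total


def ops_from_gapless(read: str, hap_seq: str, start: int) -> tuple:
    """Match/mismatch run-length ops for a gapless placement of ``read`` at ``start``."""
    if start < 0 or start + len(read) > len(hap_seq):
        raise AlignmentError("gapless placement runs off the haplotype")
    ref = hap_seq[start:start + len(read)]
    ops = []
    run_op, run_start = None, 0
    for i, (a, b) in enumerate(zip(read, ref)):
        op = "match" if (a == b and a != "N" and b != "N") else "mismatch"
        if op != run_op:
            if run_op is not None:
                payload = read[run_start:i] if run_op == "mismatch" else None
                ops.append((run_op, i - run_start, payload))
            run_op, run_start = op, i
    payload = read[run_start:] if run_op == "mismatch" else None
    ops.append((run_op, len(read) - run_start, payload))
    return tuple(ops)


# ---------------------------------------------------------------------------
# affine local DP (Gotoh), numba-compiled


@njit(cache=True)
def _affine_local_matrices(read, hap, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.shape[0]
    m = hap.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            e = H[i, j - 1] + gap_open + gap_extend
            e2 = E[i, j - 1] + gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] + gap_open + gap_extend
            f2 = F[i - 1, j] + gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            s = match if (ri == hap[j - 1] and ri < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def _traceback(read: str, hap_seq: str, H, E, F, i, j, scheme: ScoringScheme):
    """One deterministic path from end cell (i, j) back to an H=0 cell.

    Preference order diagonal > deletion > insertion. Returns (start, ops).
    """
    end_i = i
    raw = []  # (op, read_char or None), collected backwards
    state = "H"
    go, ge = scheme.gap_open, scheme.gap_extend
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            took_diag = False
            if i > 0 and j > 0:
                a, b = read[i - 1], hap_seq[j - 1]
                is_match = a == b and a != "N" and b != "N"
                diag_s = scheme.match if is_match else scheme.mismatch
                if H[i, j] == H[i - 1, j - 1] + diag_s:
                    raw.append(("match" if is_match else "mismatch", a))
                    i -= 1
                    j -= 1
                    took_diag = True
            if took_diag:
                continue
            if H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - matrices inconsistent
                raise AlignmentError("traceback failed: inconsistent DP matrices")
        elif state == "E":
            raw.append(("deletion", None))
            if E[i, j] == H[i, j - 1] + go + ge:
                state = "H"
            j -= 1
        else:  # F
            raw.append(("insertion", read[i - 1]))
            if F[i, j] == H[i - 1, j] + go + ge:
                state = "H"
            i -= 1
    start, read_from = j, i
    raw.reverse()
    ops = []
    if read_from > 0:
        ops.append(("softclip", read_from, read[:read_from]))
    idx = 0
    while idx < len(raw):
        op = raw[idx][0]
        k = idx
        chars = []
        while k < len(raw) and raw[k][0] == op:
            if raw[k][1] is not None:
                chars.append(raw[k][1])
            k += 1
        payload = "".join(chars) if op in ("mismatch", "insertion") else None
        ops.append((op, k - idx, payload))
        idx = k
    if end_i < len(read):
        ops.append(("softclip", len(read) - end_i, read[end_i:]))
    return start, tuple(ops)


def align_read(
    bases: str,
    hap: Haplotype,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    band: Optional[tuple] = None,
    hap_index: int = 0,
) -> list:
    """All maximum-score local placements of ``bases`` on ``hap``.

    Read bases outside the aligned core become zero-scoring soft-clips, so
    reads hanging off a haplotype end stay comparable. Results are sorted by
    (start, end); every returned alignment scores exactly the DP maximum.
    ``band``, when given as (lo, hi), restricts the search to that haplotype
    window.
    """
    if not bases:
        raise AlignmentError("cannot align an empty read")
    lo, hi = (0, len(hap.sequence)) if band is None else (max(band[0], 0), min(band[1], len(hap.sequence)))
    hap_seq = hap.sequence[lo:hi]
    H, E, F = _affine_local_matrices(
        encode_seq(bases),
        encode_seq(hap_seq),
        np.int32(scheme.match),
        np.int32(scheme.mismatch),
        np.int32(scheme.gap_open),
        np.int32(scheme.gap_extend),
    )
    best = int(H.max())
    if best <= 0:
        # nothing aligns: the whole read is one soft-clip with score 0
        aln = ReadAlignment(hap_index=hap_index, start=lo, score=0,
                            ops=(("softclip", len(bases), bases),))
        return [aln]
    out = {}
    ii, jj = np.nonzero(H == best)
    for i, j in zip(ii.tolist(), jj.tolist()):
        start, ops = _traceback(bases, hap_seq, H, E, F, i, j, scheme)
        key = (start + lo, ops)
        if key not in out:
            out[key] = ReadAlignment(
                hap_index=hap_index, start=start + lo, ops=ops, score=best
            )
    return sorted(out.values(), key=lambda a: (a.start, a.end))


# ---------------------------------------------------------------------------
# graph-path projection


def project_graph_alignment(
    rec: ReadRecord,
    hap: Haplotype,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    hap_index: int = 0,
) -> list:
    """Project a read's graph path onto one haplotype.

    A path touching two or more segments is anchored (one placement, provided
    every traversed repeat fits the haplotype's allele); a path inside a
    single repeat segment slides in unit steps. Scores and per-base ops are
    recomputed against the haplotype sequence, so sequencing errors surface
    as mismatch ops regardless of the source alignment. Returns [] when the
    path needs more repeat units than this haplotype has.
    """
    if rec.graph_alignment is None:
        raise AlignmentError(f"read {rec.fragment_id}/{rec.mate_index} has no graph alignment")
    path = rec.graph_alignment.path
    segs = hap.locus.segments
    smap = hap.segment_map
    for si, _, _ in path:
        if not 0 <= si < len(segs):
            raise AlignmentError(f"graph path references segment {si}, locus has {len(segs)}")
    for (a, _, _), (b, _, _) in zip(path, path[1:]):
        if b != a + 1:
            raise AlignmentError("graph path segments must be consecutive")
    total_len = sum(ln for _, _, ln in path)
    if total_len != len(rec.bases):
        raise AlignmentError(
            f"graph path consumes {total_len} bp but read has {len(rec.bases)}"
        )

    starts = []
    if len(path) == 1:
        si, off, ln = path[0]
        s0, s1 = smap[si]
        avail = s1 - s0
        seg = segs[si]
        if isinstance(seg, ConstantSegment):
            if off + ln <= avail:
                starts.append(s0 + off)
        else:
            unit = len(seg.repeat_unit)
            phase = off % unit
            o = phase
            while o + ln <= avail:
                starts.append(s0 + o)
                o += unit
    else:
        ok = True
        first_si, _, first_ln = path[0]
        if first_ln > smap[first_si][1] - smap[first_si][0]:
            ok = False
        for si, _, ln in path[1:-1]:
            if ln != smap[si][1] - smap[si][0]:
                ok = False
        last_si, last_off, last_ln = path[-1]
        if last_ln > smap[last_si][1] - smap[last_si][0]:
            ok = False
        if ok:
            starts.append(smap[path[1][0]][0] - first_ln)
    out = []
    for start in starts:
        if start < 0 or start + len(rec.bases) > len(hap.sequence):
            continue
        ops = ops_from_gapless(rec.bases, hap.sequence, start)
        out.append(
            ReadAlignment(
                hap_index=hap_index,
                start=start,
                ops=ops,
                score=score_ops(ops, scheme),
                fragment_id=rec.fragment_id,
                mate_index=rec.mate_index,
            )
        )
    out.sort(key=lambda a: (a.start, a.end))
    return out


def read_placements(
    rec: ReadRecord,
    hap: Haplotype,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    hap_index: int = 0,
) -> list:
    """Placements via graph projection when a path is present, de novo otherwise."""
    if rec.graph_alignment is not None:
        alns = project_graph_alignment(rec, hap, scheme, hap_index=hap_index)
        return alns
    alns = align_read(rec.bases, hap, scheme, hap_index=hap_index)
    return [replace(a, fragment_id=rec.fragment_id, mate_index=rec.mate_index) for a in alns]


# ---------------------------------------------------------------------------
# pair scoring / selection


def _best_on_hap(rec, hap, scheme, hap_index, cache):
    key = (rec.fragment_id, rec.mate_index, hap.sequence)
    if key not in cache:
        cache[key] = read_placements(rec, hap, scheme, hap_index=hap_index)
    alns = cache[key]
    return max((a.score for a in alns), default=0)


def score_haplotype_pair(
    pair: HaplotypePair,
    reads: Sequence[ReadRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    cache: Optional[dict] = None,
) -> int:
    """Cumulative score: sum over reads of the best score on either haplotype."""
    cache = cache if cache is not None else {}
    total = 0
    for rec in reads:
        scores = [
            _best_on_hap(rec, hap, scheme, hi, cache)
            for hi, hap in enumerate(pair.haplotypes)
        ]
        total += max(scores)
    pair.cumulative_score = total
    return total


def select_haplotype_pair(
    candidates: Sequence[HaplotypePair],
    reads: Sequence[ReadRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> HaplotypePair:
    """Pick the candidate with the highest cumulative read-alignment score.

    A single candidate is returned unscored (selection is skipped). Ties are
    broken by canonical sequence order and logged.
    """
    if not candidates:
        raise AlignmentError("no candidate haplotype pairs")
    if len(candidates) == 1:
        return candidates[0]
    cache: dict = {}
    ranked = sorted(candidates, key=lambda p: p.sequence_key())
    scores = [score_haplotype_pair(p, reads, scheme, cache=cache) for p in ranked]
    best = max(scores)
    winners = [p for p, s in zip(ranked, scores) if s == best]
    if len(winners) > 1:
        logger.info(
            "haplotype-pair score tie (%d candidates at %d); keeping canonical order",
            len(winners), best,
        )
    return winners[0]
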