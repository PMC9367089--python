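"""Independent reference implementations used only to check the package.

These are deliberately naive: a textbook O(n*m) affine-gap local aligner, a
sliding-window placement counter, an exhaustive haplotype-pairing enumerator,
and a first-fit interval coloring. They share no code with the package.
"""

from itertools import product


def affine_local_max_score(read, ref, match=5, mismatch=-4, gap_open=-8, gap_extend=-2):
    """Textbook Gotoh local alignment; returns the maximum H value."""
    n, m = len(read), len(ref)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend)
            a, b = read[i - 1], ref[j - 1]
            s = match if (a == b and a != "N" and b != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def gapless_placements(read, ref):
    """All offsets where read matches ref exactly (sliding window)."""
    return [
        i for i in range(len(ref) - len(read) + 1) if ref[i:i + len(read)] == read
    ]


def enumerate_pairings_bruteforce(allele_sizes_per_str):
    """All distinct unordered pairings over 2^n ordered assignments.

    ``allele_sizes_per_str``: list of (a, b) per STR. Returns a set of
    frozenset-like canonical pairs of count tuples.
    """
    n = len(allele_sizes_per_str)
    seen = set()
    for orient in product((0, 1), repeat=n):
        h1 = tuple(alleles[o] for alleles, o in zip(allele_sizes_per_str, orient))
        h2 = tuple(alleles[1 - o] for alleles, o in zip(allele_sizes_per_str, orient))
        seen.add(tuple(sorted((h1, h2))))
    return seen


def greedy_interval_coloring(intervals, gap=0):
    """First-fit coloring of (start, end) intervals sorted by start; returns color count."""
    lane_ends = []
    for start, end in sorted(intervals):
        for li, le in enumerate(lane_ends):
            if le + gap <= start:
                lane_ends[li] = end
                break
        else:
            lane_ends.append(end)
    return len(lane_ends)
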