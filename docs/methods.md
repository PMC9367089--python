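# Methods

This note documents the model behind `strpileup`, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the design
choices made where the problem left the design open.

## Locus model

A locus is an ordered alternation of constant segments and STR segments,
flattened from left flank to right flank: `C0 S0 C1 S1 ... Cn` (2n+1 segments
for n STRs; inter-repeat constant segments may be empty). All coordinates are
0-based half-open; VCF positions are converted on ingest. A haplotype is one
concrete realization: constant segments verbatim, each STR expanded to
`unit^count`, with an optional run-length structure override (e.g.
`(CGG)10AGG(CGG)9AGG(CGG)9`) used by the simulator and the annotation layer.
Phase enumeration deliberately operates on sizes alone — at run time on real
data the genotyper provides sizes, not interruption maps — so candidate
haplotypes are always pure-motif expansions.

With k heterozygous STRs at a diploid locus there are `2^(k-1)` distinct
unordered pairings (homozygous STRs contribute one allele, so no phantom
duplicates arise). Enumeration is brute force over `2^n` orientation
assignments with sequence-level deduplication, capped at 64 pairings
(`pairing_cap`); real catalogs rarely exceed three STRs per locus, so the cap
only guards pathological inputs. Pairs are canonicalized with the
lexicographically smaller sequence first, which makes deduplication, tie
breaking and output deterministic.

## Read placement

Two routes produce, per read and haplotype, the set of *all* placements tied
at the maximum alignment score:

* **Graph-path projection.** Reads realigned by the genotyper carry a path
  through the locus segments (decoded from a BAM tag; the decoder is
  pluggable because tag dialects vary). A path that touches a constant
  segment is anchored and projects to exactly one placement; a path wholly
  inside one repeat slides in unit steps, giving `U − u + 1` placements on a
  U-unit tract — the placement-count law that makes in-repeat ambiguity
  explicit. A path whose repeat traversal needs more units than a candidate
  haplotype has projects to nothing: that read is evidence against the
  haplotype. Projected alignments are rescored base-by-base against the
  haplotype, so sequencing errors surface as mismatch ops; the projection
  route assumes gapless reads (substitution errors only), which matches the
  simulator and the dominant error mode of the target platform.

* **De-novo affine alignment.** Reads without a path (the wrapper route for
  linear-reference BAMs) are aligned with a Gotoh affine-gap local DP over
  the full haplotype, compiled with numba. The full matrix at locus scale
  (a few kb × 150 bp) costs well under a millisecond per read, so no
  banding or seeding heuristic is used. Soft-clipped bases score 0, keeping
  reads that run off a haplotype end comparable. All cells achieving the
  maximum H value are traced back (preference diagonal > deletion >
  insertion), yielding every score-tied placement. Scoring defaults are
  match +5, mismatch −4, gap open −8, gap extend −2 (a gap of length L costs
  open + L·extend); `N` never matches. The scheme is configurable; the exact
  values are not critical because selection and assignment compare scores of
  the same read across haplotypes.

The haplotype pair maximizing `Σ_reads max(best on hap1, best on hap2)` is
selected; with a single candidate, selection is skipped. Score ties are
broken canonically and logged. Cumulative scoring is per read, not per
fragment: phase signal then comes from single reads that overlap two
heterozygous positions, which is the regime where phasing is trustworthy
anyway.

## Fragment-length assignment

The fragment-length distribution is estimated from pairs in which both mates
place uniquely on a shared haplotype and the *whole fragment interval* lies
in constant sequence. The interval condition matters: a pair with one mate in
each flank brackets the repeat, so its span depends on which haplotype it is
projected onto, and admitting such pairs inflates the estimate. Requiring the
fragment to fit inside a flank does impose a mild length bias (long fragments
have fewer admissible positions in a finite flank; about −40 bp at 700 bp
flanks with 450 ± 100 bp fragments), which is acceptable because the mean is
only used as a proximity target. Below `min_flank_pairs` (10) qualifying
pairs, a configured default (450 ± 100 bp) is used with a loud warning.

Per read pair, joint placements are enumerated per shared haplotype —
placements are first pooled across both haplotypes and filtered to the
global maximum score, so a read that fits one allele strictly better is only
ever considered there. Candidates must be forward–reverse with the leftmost
mate forward (when strand is known) and shorter than `mean + 4·sd`
(`frag_gate_sd`), which prunes the quadratic in-repeat candidate space
without touching plausible placements. Candidates at the minimum
`|span − mean|` are kept and one is drawn uniformly with the per-locus RNG,
consumed in sorted fragment-id order so a fixed seed reproduces the pileup
byte for byte. A draw is *ambiguous* when the tied set spans both haplotypes
(typical for pairs wholly inside shared flank sequence, or any pair at a
homozygous locus); ambiguous pairs are still placed — coverage stays even —
but are rendered faint and excluded from consensus voting. The distance
metric is the absolute deviation from the mean, not a z-score: "closest to
the mean" is the operational definition.

## Classification, lanes, metrics

Relative to one repeat tract, an alignment is *spanning* if it covers the
tract with at least `min_anchor` (5 bp) aligned beyond each boundary (so a
1 bp overhang never counts), *in-repeat* if contained in the tract,
*flanking* if it crosses exactly one boundary, *flank-only* otherwise; the
partition is exhaustive. Lane packing is greedy first-fit per haplotype with
mates sharing a lane (their union interval is packed as one unit; mates that
overlap each other are packed separately), a 5 bp gap, and matches a
first-fit interval-coloring oracle by construction.

Metrics per locus: per-allele spanning/flanking/in-repeat counts, mean depth
over each repeat tract and over constant sequence, a coefficient-of-variation
evenness score over the interior (one fragment length is trimmed from each
end before the CV, because confining fragments to a finite region creates
coverage ramps there), the in-repeat indel rate (indel events per aligned kb
inside tracts), and a raw flanking/spanning ratio. Three flags operationalize
the visual QC heuristics, with thresholds that are explicit config because
the heuristics are qualitative:

* `short_allele_weak` — a spannable allele (tract + 2·anchor ≤ read length)
  with ≤ 1 spanning read; such an allele may not be real.
* `expansion_weak` — tract depth < 0.3 × flank depth on the same haplotype;
  the expansion's size may be overestimated.
* `noisy_repeat` — in-repeat indel rate > 20/kb; in-repeat reads may be
  misaligned.

No normal/intermediate/full verdicts are produced: category thresholds are
gene-specific and belong to the reviewer, not the tool.

## Interruption annotation

The repeat tract of a selected haplotype is framed into unit-length columns
anchored at the tract start. Votes come from spanning and flanking reads
whose assignment is unambiguous; for each column a read contributes the
unit-length word its alignment places there, provided the column is covered
gaplessly. A column is called as an alternative motif when ≥ `min_frac`
(0.8) of ≥ `min_depth` (5) covering reads agree on one alternative word;
otherwise it stays canonical, and columns under `min_depth` are reported
unresolved (an entirely unresolved tract yields an empty structure and
`resolved=False`). Raising `min_frac` can only remove calls (monotone by
construction). 5′ and 3′ ends are treated symmetrically, so a 5′ interruption
is as visible as a 3′ one.

In-repeat reads are deliberately excluded from voting: their placement is
ambiguous up to unit shifts, so their words would smear an interruption
across neighbouring columns instead of sharpening it. The consequence is
honest and visible in the output: alleles short enough for anchored reads to
tile (up to roughly `2·(read_len − anchor)` ≈ 290 bp ≈ 96 CGG units at
150 bp reads) resolve completely, while deep expansions resolve near their
ends and report unresolved interiors.

## Synthetic data generator

The simulator draws fragments uniformly along each truth haplotype, lengths
from Normal(`frag_mean`, `frag_sd`) truncated to [read length, haplotype
length]; the fragment ends become the mates, and substitutions are applied
per base. Defaults model a contemporary WGS run: 30× coverage, 150 bp reads,
450 ± 100 bp fragments, 0.2% substitution error. Reads are emitted with both
linear coordinates on a synthetic contig and an encoded graph path, so the
projection route and the wrapper route are exercised by the same fixture;
`write_fixture` also emits the catalog JSON, genotype VCF, wrapper TSV,
reference FASTA and a truth table.

Two properties of real data are *not* emulated, and tests passing on
simulated data say nothing about them: PCR/optical duplicates and GC coverage
bias (severe at GC-rich repeats like FMR1, where real in-repeat depth dips),
and indel sequencing errors (the simulator is substitution-only). One
artifact of the generator is worth knowing: because fragments are confined
to the haplotype, interior depth exceeds nominal coverage by a factor
N/(N − L̄) while total bases equal coverage × haplotype length exactly; the
evenness metric trims the end ramps before computing its CV.

## Numerical and policy choices

* Flank length defaults to 1000 bp (test fixtures use 600–700 bp), which
  exceeds any short-read fragment; the BAM fetch margin adds the longest
  allele so mates on an expanded allele are never dropped.
* Ambiguity requires exact distance ties; no tolerance window is applied.
* The locus RNG (default seed 42, CLI `--seed`) is the single source of
  randomness; identical inputs and seed give byte-identical SVG and metrics.
* Rendering compresses only repeat intervals when a locus exceeds the page
  width (piecewise-linear x-map, annotated scale), falling back to a global
  scale when the flanks alone overflow. Mate connector lines exist behind an
  option and default off.
* Reads containing `N` align with `N` as a universal mismatch.
* Haploid loci skip pair enumeration and selection entirely.

## Known limitations

* **Diploid interruption maps at similar allele sizes.** Fragment length is
  the only evidence assigning repeat-bridging pairs, so when the two alleles
  differ by much less than the fragment-length sd, a substantial fraction of
  bridging pairs is assigned to the wrong haplotype and allele-specific
  interruptions are diluted below the consensus threshold (simulations at
  31 vs 46 CGG units recover only ~65% of alleles exactly). Haploid loci and
  alleles resolvable by spanning reads do not suffer from this. The
  annotation layer reports what the reads support; it does not attempt to
  phase interruptions through ambiguous assignments.
* Underestimated expansions are undetectable from a pileup: a longer repeat
  missing its in-repeat reads looks like a shorter repeat.
* The projection route assumes gapless graph alignments; reads with true
  indels inside the repeat take the de-novo route only on the wrapper path.
* Genotyping is out of scope: repeat sizes are inputs, and a poor fit is
  reported through metrics and flags rather than by re-genotyping.
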