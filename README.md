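# strpileup

Haplotype-resolved read pileups for short tandem repeat (STR) loci from
short-read sequencing data.

Expanded STR alleles — the cause of fragile X syndrome, Huntington disease,
C9orf72-linked ALS/FTD and many other neurogenetic disorders — are large
insertions relative to the reference genome. Around such loci, generic genome
browsers show a wall of misaligned and ambiguously placed reads, because a
read that lies inside a long repeat tract fits the tract at many positions.
`strpileup` consumes the outputs of an STR genotyper (repeat sizes per allele,
plus reads realigned to the repeat region) and reconstructs what a genome
browser cannot: the two local haplotype sequences, each read pair assigned to
one haplotype at one position, and an SVG pileup in which allele sizes,
repeat interruptions, and genotype-quality problems are visible at a glance.
It is aimed at scientists who review repeat-expansion calls — in clinical
sign-out or in methods development — and at pipelines that want machine-
readable quality flags next to each call.

## The algorithm

For a locus with STRs genotyped as allele sizes (in repeat units):

1. **Haplotype pairs.** Every distinct unordered phase configuration is
   realized as a pair of concrete sequences: flanks and spacers verbatim,
   each STR as `unit^count`. With *k* heterozygous STRs there are `2^(k-1)`
   pairings (one haplotype for haploid loci).
2. **Pair selection.** Each read is aligned to every candidate haplotype —
   by projecting its graph-alignment path when the BAM provides one, or by an
   affine-gap (Gotoh) local alignment otherwise — and the pair maximizing the
   cumulative score `Σ_reads max(best on hap1, best on hap2)` is selected.
   *All* placements tied at the maximum score are kept, so a read inside a
   U-unit tract contributes its full set of `U − u + 1` placements.
3. **Fragment assignment.** The fragment-length distribution is estimated
   from uniquely placed pairs lying wholly in constant sequence. For each
   read pair, joint placements on a shared haplotype are enumerated
   (orientation- and length-gated), those whose implied fragment length is
   closest to the mean are kept, and one is drawn uniformly at random.
   Draws whose ties span both haplotypes are flagged ambiguous and rendered
   faint.
4. **Pileup, metrics, annotation.** Reads are classified (spanning /
   flanking / in-repeat / flank-only), packed into lanes, and rendered as
   SVG with per-base mismatch, deletion and insertion glyphs. QC metrics
   mirror the visual heuristics: per-allele spanning support, repeat-vs-flank
   depth, coverage evenness, and in-repeat indel noise. A per-unit-column
   consensus over anchored reads yields each allele's structure string, e.g.
   `(CGG)10AGG(CGG)9AGG(CGG)9` — the AGG-interruption map of an FMR1 allele.

A built-in paired-end simulator generates reads from known haplotypes
(configurable coverage, fragment-length distribution, and base-error rate)
and writes complete fixtures (BAM, VCF, catalog JSON, wrapper TSV, reference
FASTA, truth table), so the whole pipeline is testable without external data.

## Worked example

Simulate a heterozygous CGG locus (20 vs 150 repeat units, 30× coverage,
150 bp reads, 450 ± 100 bp fragments, 0.2% base error) and plot it:

```sh
strpileup simulate --preset short-expanded --out-dir demo --seed 7
strpileup plot --reads demo/reads.bam --catalog demo/catalog.json \
    --vcf demo/genotypes.vcf --locus-id sim --out demo/sim.svg \
    --metrics-out demo/metrics.json --structure-out demo/structures.json \
    --seed 7 --flank-len 700
```

Key numbers from `demo/metrics.json` (hap 0 is the 150-unit allele):

```json
{
 "spanning_by_allele":  {"0|sim": 0,  "1|sim": 21},
 "in_repeat_by_allele": {"0|sim": 74, "1|sim": 0},
 "repeat_depth_by_allele": {"0|sim": 38.04, "1|sim": 43.55},
 "short_allele_weak": false, "expansion_weak": false, "noisy_repeat": false
}
```

Read this as a quality reviewer would: the 20-unit allele (60 bp, shorter
than a read) is directly sized by 21 spanning reads; the 150-unit expansion
(450 bp) cannot be spanned and is instead supported by 74 wholly-in-repeat
reads; depth inside both repeat tracts matches the flanks, so none of the
warning flags fire. `demo/structures.json` reports `(CGG)20` for the short
allele with every unit column resolved, and `(CGG)150` for the expansion
with the middle 62 columns marked unresolved — anchored reads cannot reach
the interior of a 450 bp tract, and the tool says so rather than guessing.
`demo/sim.svg` shows the two haplotype tracks with reads in lanes;
ambiguously assignable pairs (e.g. fully flank-mapped ones) are faint.

The same pipeline runs on real genotyper output (`--catalog` + `--vcf` with
the realigned BAMlet), or on a plain linear-reference BAM through the
self-sufficient wrapper format (`--tsv` + `--reference`). `strpileup batch`
renders one SVG per row of a sample manifest; `annotate` and `metrics`
expose the structure-calling and QC stages individually.

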