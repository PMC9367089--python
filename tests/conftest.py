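import numpy as np
import pytest

import strpileup as sp


def make_genotype(str_id, *sizes):
    return sp.RepeatGenotype(str_id=str_id, allele_sizes=tuple(sizes))


def simulate_locus(
    locus, allele_counts, structures=None, base_error=0.002, seed=11, **sim_kwargs
):
    """Build a truth pair for ``locus`` and simulate reads from it.

    ``allele_counts``: list of per-STR counts for hap1 (and hap2 when diploid),
    e.g. [{"sid": 20}, {"sid": 150}]. Returns (genotypes, truth_pair, reads, truth).
    """
    strs = locus.strs
    genotypes = {}
    for s in strs:
        sizes = tuple(c[s.str_id] for c in allele_counts)
        genotypes[s.str_id] = sp.RepeatGenotype(str_id=s.str_id, allele_sizes=sizes)
    structures = structures or [None] * len(allele_counts)
    haps = [
        sp.build_haplotype(locus, counts, structures=struct)
        for counts, struct in zip(allele_counts, structures)
    ]
    pair = sp.HaplotypePair(hap1=haps[0], hap2=haps[1] if len(haps) > 1 else None)
    cfg = sp.SimConfig(truth=pair, base_error=base_error, seed=seed, **sim_kwargs)
    reads, truth = sp.simulate_read_pairs(cfg)
    return genotypes, pair, reads, truth


@pytest.fixture(scope="session")
def cgg_locus():
    return sp.make_locus("fmr1like", ["CGG"], flank_len=700, ref_counts=[20], seed=7)


@pytest.fixture(scope="session")
def het_expansion(cgg_locus):
    """A clean heterozygous expansion (20/150 CGG units) run end to end."""
    sid = cgg_locus.strs[0].str_id
    genotypes, pair, reads, truth = simulate_locus(
        cgg_locus, [{sid: 20}, {sid: 150}], base_error=0.002, seed=11
    )
    result = sp.run_locus(cgg_locus, genotypes, reads, seed=11)
    return {
        "locus": cgg_locus,
        "str_id": sid,
        "genotypes": genotypes,
        "truth_pair": pair,
        "reads": reads,
        "truth": truth,
        "result": result,
    }
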