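"""Test-only helpers: independent microsatellite population samples
generated with msprime's stepwise mutation model (used as the external
oracle for the heterozygosity-excess calibration)."""

import msprime
import numpy as np

from xhap.core import DiploidGenotype, Locus, MarkerPanel, SampleRecord


def sample_locus(mu, n_copies, seed, demography=None):
    """Allele states (repeat numbers) for n haploid copies at one locus."""
    kw = dict(demography=demography) if demography is not None else dict(population_size=1.0)
    anc = msprime.sim_ancestry(samples=n_copies, ploidy=1, random_seed=seed, **kw)
    mts = msprime.sim_mutations(
        anc, rate=mu, model=msprime.SMM(lo=1, hi=200), random_seed=seed + 1
    )
    for var in mts.variants():
        return np.array([int(var.alleles[g]) for g in var.genotypes])
    return np.full(n_copies, 50)


def equilibrium_records(mu, n_loci, n_copies, seed, demography=None):
    """A male (haploid) population sample of unlinked microsatellite loci."""
    panel = MarkerPanel(
        tuple(Locus(f"L{i}", "s", 100 + i, "AAA", frozenset({1})) for i in range(n_loci))
    )
    per_locus = [
        sample_locus(mu, n_copies, seed * 10_007 + 7 * i + 1, demography)
        for i in range(n_loci)
    ]
    records = [
        SampleRecord(
            f"m{j}",
            "male",
            "P1",
            "R1",
            DiploidGenotype(tuple((int(per_locus[i][j]),) for i in range(n_loci))),
        )
        for j in range(n_copies)
    ]
    return records, panel


def crash_demography(fold=100.0, t=0.2):
    """Population of size 1 (coalescent units) that was ``fold`` times
    larger until ``t`` time units ago: a recent crash."""
    dem = msprime.Demography()
    dem.add_population(initial_size=1.0)
    dem.add_population_parameters_change(time=t, initial_size=fold)
    return dem
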