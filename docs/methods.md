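# Methods

This note documents the models, algorithms and numerical choices behind
`xhap`, what the built-in simulator does and does not emulate, and the
known limitations of each inference step.

## 1. Inheritance model

The package assumes X0 sex determination: females are XX, males carry a
single maternally inherited X and transmit it to daughters unchanged
(there is no male meiotic partner for the X, so paternal X haplotypes
cannot recombine in male meiosis).  Consequences used throughout:

* a male's multilocus genotype at X-linked loci is his haplotype, and two
  distinct alleles at any locus in a male are treated as a data error
  (`validate_male_hemizygosity`);
* the maternal gamete of every larva is one of the mother's two X
  haplotypes, possibly altered by meiotic crossover;
* a female larva's genotype is the unordered union of one maternal gamete
  and her father's haplotype.

Alleles are integer fragment lengths in base pairs, as sized by capillary
electrophoresis; sequence-level differences between equal-length alleles
are outside the model.  Missing data is an explicit sentinel (empty cell
in files, `None` in memory); a missing locus is simply uninformative for
that individual.

## 2. The marker panel

A `MarkerPanel` is an ordered list of loci with strictly increasing
chromosome-X positions; position order — not scaffold grouping — defines
the coordinate system for crossover classification.  Scaffold membership
is retained only for per-scaffold summaries (the N_hm counts of maternally
heterozygous loci).  Allele sets are configuration, not constants: alleles
observed in data but absent from the panel definition extend the *working*
allele set with a logged notice.  "Polymorphic" always means >= 2 alleles
in the working set.  The default panel has 10 loci on two scaffolds, six
of them polymorphic with allele-set sizes 2, 4, 2, 2, 2 and 3, so the
potential haplotype space is 2·4·2·2·2·3 = 192.

## 3. Haplotype calling and grouping

`call_male_haplotypes` collapses male records into a catalogue.  Males
missing a call at any polymorphic locus are excluded (imputation would
fabricate haplotypes); a missing call at a monomorphic locus is filled
with the locus's single allele.  Labels `Xhap_01..` are assigned by
descending count with lexicographic tie-break, making the catalogue
deterministic and invariant to record order.

The frequency spectrum uses fixed count classes — common (> 10 copies),
mid (2–10), singleton — and reports the share of males carried by each
class to 0.1%.

Dissimilarity between haplotypes is simple matching over polymorphic
loci: (# mismatching loci) / (# jointly non-missing polymorphic loci).
Neighbour joining is the classic Q-criterion agglomeration, implemented
in-package with a fixed tie-break (the lowest-index pair is joined first)
so output is deterministic; negative branch lengths, a known NJ artefact,
are clamped to zero with a log notice.  Group delimitation on the tree is
visual in practice; `cut_groups` provides a single-linkage threshold cut
as a descriptive utility, not a tested claim.

## 4. Family inference

### Maternal phasing

All 2^(h−1) phasings of a mother heterozygous at h loci are scored
against the male larvae: first by the number of males explained with zero
crossovers, then by total crossovers over all consistent males, with a
lexicographic tie-break.  With h <= 6 in realistic panels the search is
exhaustive and exact.  A fully homozygous mother yields a trivial phase
(recombination undetectable, warned).  If no phasing explains any male
larva within the crossover budget, phasing fails loudly.

### Crossover classification

Over informative loci ordered by position, each observed allele is
labelled H1 or H2; the crossover count is the number of label switches
(0 parental, 1 SCO, 2 DCO, > 2 complex).  Missing loci are skipped.  Any
allele matching neither maternal haplotype marks the whole observation
`inconsistent` (possible mutation or non-maternal origin) — it is
reported, never silently reclassified, because mutation and recombination
cannot be distinguished from a single offspring.

### Paternal reconstruction and the uniqueness margin

For a female larva, every maternal gamete derivable from (H1, H2) with at
most `budget` crossovers (default 2, matching the largest crossover class
observed in such data) is tested against the genotype; each consistent
gamete determines the paternal vector as the other pair member.  The
reported paternal vector and crossover count always come from the
minimal-crossover explanations, and ties among them are reported as
ambiguity.

Uniqueness for *father counting* is stricter.  A recombinant maternal
gamete combined with a father who happens to carry maternal alleles at
the switched loci admits a spurious zero-crossover explanation whose
"paternal" vector is partly the recombinant gamete; minimal parsimony
alone therefore invents rare fathers at roughly the recombination rate.
`family_report` counts a larva toward the father tally only when all
explanations within **one extra crossover** of the minimum agree
(`margin=1`).  With per-interval crossover probabilities well below the
allele-sharing probabilities of real populations, a one-crossover
alternative is not decisively less plausible than the minimal
explanation, whereas demanding agreement across the whole budget
(margin = budget) discards most informative larvae.  In simulation at the
default rates this margin removed every wrong unique-status assignment
(0 of ~6,500 across 100 replicate families) while retaining roughly a
third of female larvae as countable, and the father-count bound then
equals the true father number whenever every father has at least one
countable daughter.  `infer_paternal` exposes `margin` directly
(default 0: pure minimal-parsimony status).

The father count is always a **minimum** bound: fathers sharing a
haplotype are indistinguishable, as are fathers whose haplotype collides
with a maternal one.  Ambiguity-adjusted count bounds (min = unique-status
count, max = plus compatible ambiguous larvae) are reported per paternal
haplotype.

### Sub-clutch homogeneity and novel paternal haplotypes

Paternal-haplotype-by-sub-clutch counts (unique-status larvae) are tested
with a chi-square statistic and a permutation p-value (sub-clutch labels
permuted among larvae; p = (b+1)/(B+1)), avoiding asymptotic assumptions
on sparse tables.  Paternal haplotypes absent from a supplied adult
catalogue are searched for a minimal SCO/DCO derivation as a mosaic of two
catalogue haplotypes over loci in position order; the best pair and switch
count are reported descriptively.

Maternal recombinant frequencies are reported with *both* denominators
(all larvae, and male larvae only), since either convention appears in
practice; `complex` (> 2 crossovers) and `inconsistent` gametes are
excluded from the frequency lines but tallied.

## 5. Population statistics

Copy counting is X-aware: one allele copy per male, two per female.

Diversity descriptors per locus and population: Na; Ne = 1/Σp²;
I = −Σp ln p; h = He = 1 − Σp² (the plain estimator by default — an
unbiased n/(n−1) variant sits behind `unbiased=True`); Ho = fraction of
heterozygous typed females; PIC = 1 − Σp² − Σᵢ<ⱼ 2pᵢ²pⱼ²;
F = 1 − Ho/He.  Ho/He/PIC/F are NaN for the haploid (male) partition and
monomorphic loci — the descriptor range genuinely defined in each case.
P% counts a locus polymorphic within a population if >= 2 alleles are
observed there.

AMOVA uses the sums-of-squared-pairwise-distances construction.  Haploid
model: units are male haplotypes, squared distance = number of
mismatching loci.  Diploid codominant model: units are allele copies (two
per female), distance summed per locus, adding among-/within-individual
levels; because distances are additive over loci, the decomposition is
independent of the arbitrary cross-locus phase of the two copies.
Variance components come from the standard nested moment equations with
unequal-size coefficients; with exactly two copies per individual the
within-individual coefficient is exactly 2.  Components are reported even
when negative (standard AMOVA behaviour); percentages are computed from
non-negativity-truncated components.  Fixation indices are the usual
ratios (Φ_RT, Φ_PR, Φ_PT; F_RT, F_SR, F_ST, F_IS, F_IT).  Permutation
p-values (default B = 999, p = (b+1)/(B+1)) permute units at the level
appropriate to each component: samples among populations (globally, or
within regions), whole populations among regions, and allele copies among
individuals (within populations for F_IS, globally for F_IT).  Records
with any missing call are dropped from AMOVA with a notice so all
pairwise distances span the same loci, and units are ordered canonically
by sample id so p-values are invariant to input row order.

The type-I error of the Φ_PT permutation test is verified by simulation:
under panmixia (4 demes × 8 haploid samples, 4 triallelic loci, 999
permutations, 500 replicates) the rejection rate at α = 0.05 must fall in
[0.03, 0.07].

## 6. Bottleneck (heterozygosity-excess) test

A recently bottlenecked population loses rare alleles faster than gene
diversity, so observed He exceeds the equilibrium heterozygosity Heq
expected for the observed allele count k and sample size n.  For each
polymorphic locus the package simulates Kingman genealogies (time scaled
so mutations arrive at rate θ/2 per lineage) with two-phase mutations:
one-step with probability `smm_proportion` (default 0.95; 1.0 is strict
SMM), otherwise a multi-step change of geometric magnitude with variance
`tpm_variance` (default 12, giving geometric success probability 0.25)
and random sign.  θ is adapted in a burn-in phase until the mean
simulated allele count brackets k, then frozen; genealogies yielding
exactly k alleles contribute one Heq value each (rejection sampling).
Loci whose conditioning fails within the simulation cap are dropped with
a notice.  Per locus the standardized difference (He − mean Heq)/sd Heq
is reported; the per-population p-value is a one-tailed Wilcoxon
signed-rank across loci on these standardized differences, using the
exact null distribution for <= 25 loci (the relevant regime here is ~6
polymorphic loci, where the smallest attainable p is 1/64).  This follows
the *concept* of the classical testing procedure, not its code; numerical
agreement with any particular program is not claimed — calibration is the
acceptance surface.  Calibration and directional power are checked
against an independent coalescent simulator (msprime's SMM microsatellite
model): under equilibrium the 5% rejection rate must lie in [0.02, 0.09]
(the exact-Wilcoxon null rejection at 6 loci is 3/64 ≈ 0.047), and a
100-fold recent crash must shift the median p-value downward.

## 7. The simulator

`simulate_adults` draws males as *linked* haplotype vectors from a pool
of distinct haplotypes with geometrically decaying weights (decay 0.85
over a pool of 36), reproducing the skewed spectrum of real samples —
few common haplotypes, many rare; females draw two pool haplotypes.  An
independence mode (`linked_pool=False`) draws loci independently for null
experiments, and an optional cline reweights one pool haplotype linearly
across localities for migration-gradient scenarios.  The default scenario
is 14 localities × 30 adults in 6 regions with P(female) = 0.55.

`simulate_family` draws, per larva: a starting maternal haplotype (fair
coin), independent per-interval Bernoulli crossovers (no interference;
default 0.005 per interval, giving ~4–5% of gametes with at least one
crossover over a 10-locus panel), sex (P(female) = 0.55), and — for
females — a father by sperm-use share, the default giving the last
father a dominant share of 0.55 and splitting the rest equally
(last-male precedence).  Larvae are partitioned sequentially into
sub-clutches, so father shares are homogeneous across sub-clutches by
construction; a heterogeneity knob exists for power studies.  Five
default family specifications (75–253 larvae, 6–13 fathers) mirror a
realistic clutch series.  Every larva's true gamete origin, crossover
intervals and father index are retained (`truth_report`) for
parameter-recovery testing.

What the simulator does **not** emulate: meiotic mutation (single-locus
changes are surfaced as `inconsistent`, never auto-called), crossover
interference, sperm stratification over time within the spermatheca,
autumn-sperm carryover, selection or sex-linked lethality, and genotyping
error/allelic dropout.  Passing the recovery tests therefore shows that
the inference is correct under clean X0 Mendelian transmission with
independent crossovers — not that it is robust to genotyping artefacts.

## 8. Numerical and design choices

* Every stochastic operation takes an explicit seed; there is no hidden
  global RNG state.  Identical scenario + seed gives byte-identical
  output files.
* Permutation p-values use p = (b+1)/(B+1) with ties counted toward b
  (conservative); statistic comparisons use a 1e-12 slack against
  floating-point noise.
* Frequency-vector sanity is enforced at 1e-9; AMOVA SS identities hold
  to 1e-9 in tests; closed-form diversity values to 1e-12.
* The crossover budget is capped at 2 because larger classes are not
  identifiable with ~6 informative loci — a `complex` class is reported
  but excluded from frequency summaries.
* Problem sizes in the statistical tests (replicate counts, deme sizes,
  coalescent replicates) are chosen as the smallest designs that give the
  binomial/Monte-Carlo resolution the asserted tolerance needs.

## 9. Known limitations

* Father counts are minimum bounds; no probabilistic sibship
  reconstruction (COLONY/CERVUS-style likelihoods) is attempted.
* The NJ tree is a descriptive grouping device; with heavily tied
  dissimilarities (values are multiples of 1/#loci) the topology among
  tied joins is implementation-defined.
* The bottleneck test's conditioning-on-k is approximate (adaptive-θ
  rejection sampling), and the Wilcoxon across ~6 loci has coarse p-value
  granularity; interpret per-population results accordingly.
* The diploid AMOVA drops individuals with missing calls rather than
  rescaling distances, which can bias components if missingness is
  structured.
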