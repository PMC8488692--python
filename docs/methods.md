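# Methods

This package models how genetic drift in a small, isolated population can
carry a rare recessive allele to high frequency, and provides the
supporting machinery for estimating that frequency from noisy noninvasive
samples.  The concrete system it is built around is the pseudomelanism
allele Taqpep p.H454Y in the Similipal tiger population (allele frequency
0.58 among 12 genetically identified individuals), but every component is
parametric and reusable.

## Drift model

Generations are discrete and non-overlapping.  A population of N
individuals contributes a gamete pool of `copies_per_individual * N` gene
copies; the next generation's pool is a binomial draw from the current
mutant frequency (Wright–Fisher resampling).  Census size follows the
deterministic logistic map

    N' = round(N + r * N * (1 - N / K)),

rounded half-away-from-zero with a floor of one individual.  K is a fixed
point of the exact map; under rounding the trajectory settles at the
largest integer whose unit step rounds to zero (102 for r = 0.15,
K = 104), which has no practical effect on drift.

**Bottleneck grids.**  A founding population of N0 individuals contains
exactly one heterozygote (`forced_het`, p0 = 1/(2 N0) with a diploid
pool), or founder copies are sampled binomially from a source frequency
(`sampled`).  After G generations of recovery the final frequency is
compared with a threshold (default 0.5); the grid cell reports the
fraction of replicates at or above it.  Crossing is evaluated on the
*final* generation, not as a running maximum: the running-maximum variant
nearly doubles the headline probability and is inconsistent with storing
only the last generation's frequency.

**Fixation runs.**  Replicates start from a supplied p0 (default 0.5) and
run until an allele absorbs.  Defaults follow the study conditions this
package reproduces: a starting population of 10 with
`copies_per_individual = 1` (a 10-copy pool), optional logistic growth
(r = 0.15) toward K = 35 or 104, and 2,000 replicates.  Genetic rescue is
modelled as `migrant_copies_per_gen` wild-type copies (2 = one wild-type
homozygous immigrant) joining the *parental* gamete pool each generation,
so the effective sampling frequency is p·c/(c+m) for pool size c.  With
migration the mutant can only be lost; a 100,000-generation cap guards
non-termination and capped replicates are reported separately (none occur
at the default settings).

**Validation oracles.**  For pools of ≤ 200 copies the simulator is
checked against exact absorbing-Markov-chain solutions: the binomial
transition matrix over copy counts gives fixation probabilities and
expected absorption times by solving the standard linear systems.  Because
the census trajectory is deterministic, the growth scenarios admit an
exact *time-inhomogeneous* oracle: solve the homogeneous chain at the
final pool size, then back-propagate expected times and fixation
probabilities through the growth generations.  Simulated means agree with
these oracles within Monte-Carlo error in every scenario (tested at 3
standard errors), and the neutral martingale property P(fix) = p0 holds
exactly in the oracle and statistically in the simulator.

These oracles are also why the package reports some reference values it
cannot match: the constant 10-copy pool has an exact expected absorption
time of 12.59 generations from p0 = 0.5 (20-copy diploid pool: 26.2),
while the reference analysis prints 10.6; the growth and rescue scenarios
differ similarly (about 30 vs 43.8, 82 vs 102.3, 8.6 vs 9.1, 16 vs 33.7,
36 vs 76.9).  No resampling convention we tried (haploid vs diploid pools,
start sizes 2–20, growth applied per year vs per generation, migrant
copies added before vs after sampling, medians vs means, random binomial
starts) reproduces the printed set jointly, so the conventions above are
fixed as documented, exposed as parameters, and the exact chains — not the
printed times — are the correctness standard for the simulator.  The
bottleneck headline value behaves the same way: the faithful simulation
gives P(p ≥ 0.5) ≈ 0.249 at (N0 = 2, G = 44), the martingale bound
p0 = 0.25 plus a little segregating mass, and 0.28 is most plausibly the
upward-biased maximum of a 1,000-replicate grid scan.

**RNG.**  All simulations take a seed; grid cells use dedicated
`SeedSequence(seed, spawn_key=(n0, G))` substreams so any sub-grid is
reproducible independently of evaluation order.

## Consensus genotyping

Calls at the variant site arrive per sample from up to three methods
(Sanger, amplicon NGS, allele-specific PCR).  The consensus rule is
deliberately conservative: unanimous non-missing calls win; a
disagreement is resolved only by a unanimous AS-PCR triplicate (the
multiple-tubes rule) and flagged; otherwise the sample is reported
missing.  Majority voting across two-of-three methods is *not* used —
observed conflict resolutions in the reference call table always went
through replication or recaptures, and the per-individual modal rule
recovers the final genotypes without it.  Ties at the individual level
are reported missing (no tie occurs in practice).  Genotype strings parse
case-insensitively and `m/+` normalizes to `+/m`.

## Individual identification

Filtering runs locus filters first (missingness > 10%, minor allele count
< 2, monomorphic, out of HWE at α = 0.05 in ≥ 2 populations — raw α, no
multiple-testing correction, mirroring the reference cascade), then drops
samples called at < 50 loci, and repeats until stable since sample removal
changes locus statistics.

Relatedness is the PLINK-style genome-wide method-of-moments estimator:
per pair, observed identity-by-state counts over co-called loci are
combined with their expected probabilities under IBD states 0/1/2 to
solve for the IBD distribution; PI-HAT = P(IBD=2) + P(IBD=1)/2, bounded
to the probability simplex.  With a finite reference panel the plain
moment terms (powers of p) are replaced by unbiased falling-factorial
ratios of allele counts.  Reference frequencies should come from an
external panel; the within-sample default warns, because frequencies
estimated from a small, related sample bias PI-HAT.  The estimator is
validated against pedigree expectations (duplicates 1.0,
parent–offspring and full sibs 0.5, unrelated 0), not against numeric
equality with any external program.

Clustering marks pairs with PI-HAT > 0.78 as recaptures and merges them
by single linkage (chained recaptures merge, as the pairwise marking
implies).  Cross-cluster pairs in (0.6, 0.78] are ambiguous: the member
with more missing data is dropped (least informative), ties broken toward
the lexicographically later id, deterministically.  The 0.78 threshold
came from technical replicates in the reference data and is exposed as a
parameter; no auto-calibration is attempted.  On synthetic surveys with
44 informative loci and ≤ 0.1 dropout, the true number of individuals is
recovered in ≥ 95% of seeded runs.

PID and PID-sibs use the standard biallelic closed forms and multiply
across loci; fixed loci contribute 1.

## Population statistics

* Wright's F_ST uses unweighted population means (this reproduces the
  closed form 1/3 for p = 0.5 against a fixed population, matching the
  reference tool's convention).
* Weir & Cockerham's θ (1984) computes the a/b/c variance components per
  locus from sample sizes, frequencies and observed heterozygote
  frequencies; the global value is the ratio of summed components.
  Populations with one called individual at a locus are excluded there; a
  worked 2×4 instance is frozen in the tests from exact rational
  arithmetic, and an island-model simulation with true F_ST = 0.1 is
  recovered within 0.03.
* The HWE test is the exact conditional test on genotype counts (log-space
  enumeration of heterozygote counts of matching parity); no mid-p
  variant.  The enumeration distribution sums to 1 within 1e-12.
* The inbreeding coefficient is F = (O_hom − E_hom)/(L − E_hom) with the
  2n/(2n−1) small-sample correction on expected homozygosity; F is not
  clamped, so heterozygosity excess gives negative values.
* The Mantel test correlates lower-triangle distances with one-sided
  (greater) permutation p-values under joint row/column permutation;
  p ≥ 1/(permutations+1) by construction.  Permutations default to 999,
  enough to resolve p = 0.001.  The correlogram tests each geographic
  distance class against its binary membership matrix under the same
  scheme, so a class's r is positive when within-class genetic distances
  are atypically large; classes whose membership matrix is constant are
  reported with NaN.  The implementation is cross-checked against
  scikit-bio's Mantel on random instances in the tests.

## Synthetic data

The generator emulates the statistical structure of a noninvasive SNP
survey, not any real dataset: HWE populations at specified frequencies;
pedigrees with Mendelian transmission and known kinship classes (founder
matings only — deeper generations are not needed to validate the
relatedness thresholds); per-method call failure (defaults 0.48/0.40/0.32,
one minus the three assays' empirical success rates) and symmetric allelic
dropout (either allele lost with equal probability — no direction is
documented for the real assays, so the symmetric null is used; the 0.1
default rate is a round placeholder typical of fecal panels, not an
estimate).  Dropout acts only on heterozygotes; homozygotes are never
mis-reported as heterozygotes.  Spatial structure uses logit-scale
population frequency deviates with covariance σ²·exp(−d/decay), which
produces the monotone distance–divergence relationship a Mantel analysis
assumes without committing to a particular demographic model.

What passing tests on these data do *not* show: robustness to
reference-panel misspecification, locus-specific error rates,
null alleles, contamination or linkage between loci, none of which the
generator produces.

## Problem sizes

Defaults mirror the study conditions: 1,000 replicates per grid cell
(bottleneck sizes 2–20, 10–50 generations), 2,000 replicates per fixation
scenario, 44-locus identification panels, 999 Mantel permutations.  Test
calibration runs use 100–300 seeded repetitions where a distributional
property (uniform null p-values, recovery rates) is asserted.
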