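# Methods

This note records the models implemented in `breedmap`, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical decisions a maintainer would otherwise have to reverse-
engineer from the code.

## The breed-mapping setting

The analysis unit is the breed. Breeds are small closed populations formed
from a shared ancestral pool; founder sampling and a few generations of
drift leave them internally uniform and mutually differentiated. Traits
that breeders selected (size, skull shape, ear position) are governed by a
few large-effect loci whose allele frequencies were driven apart between
breeds, so regressing breed-mean phenotypes on breed allele frequencies has
high power at a sample size equal to the number of breeds — provided shared
ancestry among breeds is controlled.

## Autozygosity HMM

Two hidden states along each chromosome of one individual: *autozygous*
(the two homologs coalesce in a recent ancestor) and *non-autozygous*.

* **Emissions.** Non-autozygous: Hardy–Weinberg genotype probabilities at
  the cohort allele frequency p (computed complete-case over all
  individuals). Autozygous: a mixture — with probability 1−ε the IBD
  genotype (homozygote for an allele drawn at its frequency), with
  probability ε an erroneous Hardy–Weinberg call. A heterozygote therefore
  has autozygous likelihood ε·2p(1−p). Missing genotypes and monomorphic
  markers contribute likelihood 1 in both states.
* **Transitions.** Over a gap of d bp the switch probability is the
  stationary-weighted 1 − exp(−k·d·ρ), ρ the recombination rate in
  Morgans/bp, k a rate multiplier (default 1). This makes the stationary
  distribution exactly the configured (prior_auto, prior_non) and leaves
  posteriors invariant to genome-wide position shifts; only inter-marker
  distances matter.
* **Defaults.** prior 0.20/0.80, ε = 0.005, ρ = 1.0 cM/Mb — the standard
  purebred-dog setting. Posterior decoding (forward–backward with
  per-marker scaling) rather than Viterbi; runs of posterior > 0.5 are
  segments if they span > 100 kb and ≥ 25 SNPs. The 0.5 threshold is our
  choice; the span/SNP filters are the field's convention for this panel
  density.
* **Edge behavior.** A single heterozygote near the *edge* of a true tract
  can truncate the called segment's leading markers: with weak one-sided
  evidence the posterior crosses 0.5 only after the error. Mid-tract
  errors are absorbed (the two flanks dominate). This matters when
  interpreting the het-in-autozygosity QC filter: a marker that is an
  artifact hotspot may be *uncovered* (hence "untested") if it truncates
  segments rather than sitting inside them.

The SNP-QC rule: per marker, among individuals whose called segments cover
it and whose call is non-missing, the heterozygous fraction; markers above
10% are excluded, markers covered by no segment are kept but flagged
`untested`.

## Diversity statistics

* **LD decay**: squared Pearson correlation of dosage vectors over
  complete cases, for same-chromosome pairs within a distance cap, averaged
  in 25-kb bins (binning is our choice; nothing downstream depends on it).
  Ten dogs are sampled per population and the MAF ≥ 15% / missing < 10%
  filters are re-applied *inside* the sample, so different pairs of SNPs
  enter for different breeds — deliberate, to compare breeds at equal
  sample size.
* **Haplotype diversity**: 500-kb windows anchored at position 1,
  half-open; a random subset of 15 SNPs (5 for windows with 5–14 SNPs;
  fewer than 5, dropped) fixed once and reused for every breed, so marker
  density does not drive the count; 2 × 10 sampled chromosomes per breed,
  so counts lie in 1..20.
* **F_ST**: Weir & Cockerham (1984) θ̂ per marker from the variance
  components a (between populations), b (between individuals within), c
  (within individuals), with heterozygosity terms from observed genotype
  counts. Breeds contribute only where they have ≥ 2 non-missing
  genotypes; negative estimates are reported as computed (clipping would
  distort the percentile used by the region rule). Genome-wide pairwise
  breed F_ST offers ratio-of-averages (default; standard for multi-locus
  summaries) and average-of-ratios.
* **Outlier regions**: peaks at θ̂ ≥ 0.55 and MAF ≥ 0.15, extended over
  consecutive retained markers while each stays at or above the
  genome-wide 95th-percentile θ̂; the configured quantile governs, not a
  hard-coded constant. Overlapping regions merge keeping the highest peak;
  isolated peaks are singletons.

## Breed-average association

Breed phenotype = mean over measured dogs strictly older than 1 year
(records without an age pass; they are assumed adult), requiring ≥ 2 dogs
per breed. Log-transformed traits are transformed before averaging
(mean of logs); the alternative ordering is one flag away.

**Kinship.** IBS(i,j) = mean over shared non-missing markers of
(2 − |g_i − g_j|)/2. The breed-level matrix averages all cross-breed pairs;
diagonals average distinct within-breed pairs (self-similarity excluded,
since including the IBS-with-self of 1 would inflate within-breed
relatedness). If the smallest eigenvalue is < 1e-8, 1e-6 is added to the
diagonal.

**Continuous traits.** Per marker, exact REML for
y = μ + β·freq + Cγ + u + ε, u ~ MVN(0, σ_g²K), ε ~ MVN(0, σ_e²I). One
eigendecomposition of K serves all markers; the profiled restricted
likelihood in the variance ratio δ = σ_e²/σ_g² is maximized per marker by a
41-point grid on log δ ∈ [−10, 10] followed by 30 golden-section
iterations (final bracket ≈ 5e-7 in log δ, comfortably beyond the 1e-4
relative tolerance we verify against a dense-grid oracle). p-values are
two-sided t tests on β with n − q degrees of freedom. Degenerate cases are
resolved on the weighted response scale: residual variance at relative
floating-point zero means a perfect fit (p → 0 if β explains variance,
p = 1 if the response is constant). Estimating δ per marker (rather than
once) follows the exact-REML variant of the mixed-model scan.

A calibration caveat found while testing: if the kinship matrix is
estimated from the *same* markers being tested, the simulated null trait
(drawn from that estimated K) shares sampling noise with every predictor
and the scan inflates mildly (λ ≈ 1.1–1.2 at 5,000 markers from a 50-breed
panel). The calibration tests therefore estimate K from a disjoint marker
half — the analogue of the standard practice of building the relatedness
matrix from markers excluded from testing. With 60k markers the effect
would be negligible.

**Dichotomous traits.** Statistic: |Pearson r| between the per-individual
0/1 phenotype and the breed allele frequency assigned to each individual.
Each bootstrap replicate re-draws individual i's phenotype from donor j
with probability K(i,j)/Σ_j′K(i,j′); the empirical p-value is
(1 + #{replicates ≥ observed})/(B + 1) — the +1 correction avoids zero
p-values and is removable by flag. "Bigger than" is implemented as ≥ on
the absolute statistic (two-sided). The same routine with uniform
permutation of phenotypes provides the structure-ignorant baseline.
Calibration of the weighted test depends on how strongly the similarity
rows concentrate within blocks: it is exact under exchangeable K, and
contains breed-confounded nulls only when within-breed similarity dominates
the row mass — with realistic IBS contrasts (within ≈ 0.85 vs between
≈ 0.7) the correction is partial.

## Predictive models

Forward stepwise over association-ranked candidates; response is the
breed-average value repeated for every dog of the breed (the stated
design — it overweights well-sampled breeds; a one-row-per-breed mode is
provided), design matrix is individual minor-allele dosages with mean
imputation. The step criterion is adjusted R², ties broken by association
rank then marker index; candidates that leave the design rank-deficient
are skipped; selection stops at max_k (default 6) or when adjusted R²
stops improving. The plain-R² trajectory of the nested top-1..k fits is
non-decreasing by construction and is validated as such. Prediction is the
linear predictor; validation reports the Pearson correlation between
observed and predicted individual phenotypes.

## The synthetic cohort

Defaults describe the emulated study: 50 breeds × 10 dogs, 5,000 markers
on five 50-Mb autosomes (≈ 50-kb spacing), ancestral frequencies
Uniform(0.05, 0.95) (array ascertainment toward common variants).

* **Frequency drift**: Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) per
  breed; alleles already fixed stay fixed. Optionally two-tier
  (ancestral → clade → breed) to give breed families correlated drift;
  total differentiation is then 1−(1−F_clade)(1−F_breed).
* **Haplotypes**: per breed, 8 founder haplotypes drawn at the breed's
  drifted frequencies with a first-order along-chromosome correlation
  (latent-uniform copying, scale 100 kb), then 5 generations of random
  mating at 50 diploids with Poisson crossovers at 1 cM/Mb. The defaults
  were calibrated analytically before any testing: total differentiation ≈
  breed_F + (1−breed_F)·[1/founders + g/(2N)] ≈ 0.28 with breed_F = 0.13,
  matching the cohort's mean per-SNP F_ST. The founder bottleneck, not the
  Beta drift, generates the long within-breed LD and the emergent long
  ROHs. Village dogs are direct draws from the ancestral pool — short LD,
  few long ROHs, no bottleneck.
* **QTLs**: a QTL with `sweep_fraction` set models diversifying selection:
  that fraction of breeds (at least one) is swept toward high trait-allele
  frequency (Beta(38,2), ≈ 0.95) while the rest sit near absence
  (Beta(1,49)); neighbors within an exponential hitchhiking scale (default
  300 kb) are dragged toward the swept haplotype's allele in the swept
  breeds only. The swept haplotype carries the "1" allele at neighbors —
  allele labels are arbitrary, and this phase matches the positive
  short-range allele association of the ancestral pool, so a tag that is
  informative at the breed level remains phase-consistent in the village
  population. The default three-QTL architecture (effects 4:2:1, sweep
  fractions 0.04/0.10/0.28) spreads realized variance shares
  (≈ 50/30/20%) so each locus carries appreciable breed-level signal —
  the few-loci-of-large-effect architecture of breed-divergent traits;
  with equal allele-frequency variance at all three loci the weakest
  would contribute ≈ 5% of variance and be undetectable at 50 breeds.
* **Phenotypes**: additive score plus Gaussian noise; binary traits
  threshold the noisy liability. `noise_sd_for_heritability` sets the
  noise so the planted loci explain a target fraction of the realized
  cohort-level variance. All simulated dogs are adults (age 5 y).
* **Planted autozygosity**: inside planted segments every heterozygote
  duplicates a random allele, then each marker flips to heterozygous with
  the configured error rate — the test harness for the HMM.

What the simulator does **not** emulate: mutation, X-chromosome dosage,
selection during propagation (sweeps are imposed on frequencies, not
simulated dynamically), array ascertainment bias beyond the common-allele
frequency law, genotype-calling error outside planted segments, and
linkage between the kinship noise and phenotypes present in real cohorts.
Passing tests on this cohort show the statistics are implemented correctly
and behave as expected under the stated population structure; they do not
show robustness to real-data artifacts such as batch effects, call-rate
structure or pedigree substructure within breeds.

## Problem sizes and determinism

The test suite and the acceptance script run the simulator at the default
cohort scale (50 breeds × 10 dogs × 5,000 markers) or below; calibration
runs pool independent null traits over marker blocks (10 × 500 markers for
the mixed model, 40 × 50 at B = 2,000 for the bootstrap) so that the
pooled rejection rate concentrates — p-values from a single shared trait
are jointly correlated and their empirical size is unstable by design, not
by bug. Every stage draws from `numpy.random.default_rng` seeded with
(seed, stage) pairs, so one integer reproduces the full pipeline
byte-for-byte.
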