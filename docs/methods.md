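# Methods

This note documents the models, decision rules, and numerical choices
behind `poolcross`, and what the synthetic experiments do and do not show
about real data.

## The experimental design being modelled

A composite, multi-resistant founder population (F0) is exposed, per
insecticide line, to a dose killing 80% of females; 100 surviving females
are mass-crossed with 100 males of a fully susceptible strain; F1
reproduce freely; F2 females are exposed to doses killing 25% and 75% of
F2. Thirteen pools of 100 females are sequenced by targeted capture: the
shared unexposed F0 and, per line (deltamethrin, bendiocarb, fenitrothion),
F0_LD80 survivors, unexposed F2, F2_LD25 survivors, F2_LD75 survivors.
The cross halves resistance-allele frequencies and randomizes backgrounds,
so dose-graded re-selection in F2 isolates the alleles actually driving
each resistance phenotype.

## Phenotype model

Individual log10-tolerance is Normal(μ₀ + Σ c(g)·β, σ): an individual
survives dose d with probability Φ((μ₀ + Σ c(g)·β − log₁₀ d)/σ). This is
the individual-level counterpart of the probit dose–mortality analysis used
to calibrate LD doses in bioassays. The genotype code c(g) is {0, 2h, 2}
for allele dosage g ∈ {0,1,2}; effects are additive across loci with
dominance h = 0.5 by default.

- **μ₀ = 0** sets the susceptible LD₅₀ to 1 dose unit (doses are relative).
- **σ = 0.15 log₁₀-dose units** (residual, within-genotype). The residual
  component reflects micro-environmental variation within one genotype and
  is sharp in tube bioassays; the shallow slopes of field populations arise
  from genetic heterogeneity, which the model generates explicitly.
- **β** per allele copy: log₁₀ 3 (≈ 3-fold LD₅₀ shift) for causal SNPs, 1.0
  (≈ 10-fold) for gene-amplification alleles — consistent with the
  several-hundred-fold resistance ratios reported for field pyrethroid
  resistance.

LD doses are found by monotone root-finding (Brent) of the expected
population mortality on the log₁₀-dose axis (xtol 1e-9), exactly as the
design derives its LD₈₀/LD₂₅/LD₇₅ from bioassays on the population at hand.

## Genetics

Populations are arrays of haplotypes (n, L, 2). Founders are drawn at
Hardy–Weinberg and linkage equilibrium, except within declared *haplotype
groups*: loci in a group co-occur on a single founder haplotype, emulating
co-segregating resistance mutations (the three *kdr* mutations of the
sodium channel; co-amplified detoxification gene clusters). Gametes are
generated by a crossover Markov chain along the locus list with per-pair
recombination fractions (default 0.5 = unlinked; 0 within clusters).
Amplification alleles segregate as single Mendelian alleles of k gene
copies, so a genotype with dosage g has copy number 2 + g(k−1); pool mean
copy number drives capture coverage (gene-dosage effect).

A design decision that matters for validation: **each line's causal loci
form one linked cluster on one founder haplotype**. With independent causal
loci, truncation selection spreads a fixed selection differential across
loci, capping the per-locus LD₂₅ enrichment near the pool+read noise floor;
clustered resistance haplotypes — what field data actually show — make the
per-locus signal equal to the haplotype signal.

## Sequencing model

Per locus and pool, read depth is negative binomial (mean 100, dispersion
30) and alt reads are binomial(depth, f(1−e) + (1−f)e) with error rate
e = 0.001. Region coverage is a negative-binomial read count over the
region (dispersion 400, ≈5% residual CV between same-batch capture
libraries) scaled by shared library and region capture factors; the
common-reference normalization removes both factors by construction.
Not modelled: mapping bias, strand bias, batch differences between pools,
index hopping — so passing tests bound statistical, not technical, error.

## Decision rules

The three rules are implemented exactly as printed, with these conventions
(each verified against an independently coded transcription in the tests):

- Region QC: length strictly > 45 bp; depth bounds 30 and 800 inclusive.
- CNV condition: strict inequalities; thresholds 0.3/0.2 applied by default
  on the **normalized copy-number (ratio) scale**, where 0.3 means a 15%
  copy gain over the diploid baseline. Applying them to the centre-reduced
  (z) values is supported but not the default: a copy-neutral gene's z
  profile is standardized noise with unit spread, so fixed thresholds lose
  all specificity there (~20% chance passes per line in simulation).
  Centre-reduction uses the population sd (denominator n) across all 13
  conditions jointly; genes with spread < 1e-12 are degenerate and never
  pass.
- Trajectory bands are left-closed right-open, the top band [0.95, 1]
  closed; band minima compare with ≥; "increase"/"decrease" without a
  printed magnitude are strict signs; the band's minimum applies to both
  the F0→F0_LD80 and F2→F2_LD75 rises; stages with depth < 30 disqualify a
  locus rather than being imputed; deleterious = the exact complement
  trajectory passes. The two verdicts are mutually exclusive by
  construction.
- Variant QC: depth > 30 in all 13 conditions, minor allele ≥ 4% of reads
  in at least one condition, and ≥ 5% frequency difference between some
  pair of conditions.

## Bayesian outlier scan

The scan re-implements the classic logistic F_ST decomposition:
counts are beta-binomial around an ancestral frequency p_i with
overdispersion θ_ij = (1−F_ST)/F_ST = exp(−(α_i+β_j)); a reversible-jump
MCMC toggles each α_i with prior odds 10 for neutrality (inclusion
proposals draw α* from its Normal(0,1) prior, so the acceptance ratio is
the likelihood ratio over the prior odds); β_j has a Normal(−1, 1.8²)
prior; ancestral frequencies are uniform. Pooled reads are rescaled to
effective haploid samples of size min(2·pool, depth) — the standard
pool-seq compromise. Pilot runs (20 × 2,000 iterations) adapt proposal
widths into the 0.25–0.45 acceptance window; the published schedule
(burn-in 100,000; 500,000 iterations thinned by 50) is the default, and a
*desk preset* divides all chain lengths by 10 for tests and synthetic runs.
q-values average the posterior error probabilities (1 − posterior) down the
ranking and are monotone by construction. The exponent of θ is clipped to
±50 to keep the likelihood finite in degenerate corners. A split-chain
disagreement of β beyond 0.5 logs a warning; results are still emitted.

The descriptive per-locus F_ST is a haploid analysis-of-variance
(moment) estimator on the same effective counts, clipped to [0,1]; on
beta-binomial island-model data at F_ST = 0.1 its mean is within ±0.02.

**A property worth knowing:** at the study's depth (~100×) and pool size
(100), a true causal locus whose F2/LD₂₅/LD₇₅ frequencies span ~0.25 gives
an F2-contrast likelihood ratio of only e^1–e^3, so the dual-contrast
region rule (q < 0.05 in both contrasts at the hit locus itself) fires
only for the strongest haplotypes. Selection regions are therefore a
high-precision, low-recall output at these conditions; the trajectory
filter carries most of the sensitivity.

## Synthetic study conditions

The canonical scenario (`poolcross.scenarios`) uses founder frequencies of
0.4 for causal SNP clusters and 0.3 for amplified clusters (k = 3 copies),
neutral SNP frequencies uniform on (0.05, 0.95), pools of 100, 100× depth,
F0 census 4,000 and F1/F2 censuses of 2,000 (the real census sizes are not
knowable from the design; 2,000 is a modest cage population and keeps
drift realistic). The pipeline default uses 400 neutral SNPs and 200
neutral genes so a full `run-all` (six MCMC scans at the desk preset)
finishes in minutes; the validation suite uses 5,000 neutral SNPs for the
recovery experiments.

## Known limitations

- The simulator tracks sex but all loci are autosomal; fecundity is equal.
- Amplifications are single alleles of fixed copy number; tandem-array
  expansion/contraction dynamics are out of scope.
- The effective-size rescaling of pooled counts (min(2·pool, depth)) is a
  compromise, slightly anticonservative at depth ≈ 2·pool.
- Effect annotation supports single-exon CDS models only.
- Real-data result counts from the deposited study accession are not
  reproduced; all validation is against simulator ground truth.
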