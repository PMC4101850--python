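# Methods

This note documents the statistical model behind `csscan`, the choices
made where the design was genuinely open, what the synthetic data do and
do not emulate, and known limitations.

## Model and pipeline

The scan contrasts a SELECTED group of diploid samples against a
REFERENCE group on phased biallelic haplotypes (0 = REF, 1 = ALT, no
missing data; phasing and imputation are upstream). Positions are
1-based and all window arithmetic uses closed bp intervals. SNPs with
pooled minor-allele frequency ≤ 0.01 are removed before anything else;
the filter pools both groups deliberately, because a SNP monomorphic in
one group but segregating in the other is exactly the differentiation
signal being sought.

Three constituent statistics are computed per SNP:

- **FST** — unweighted two-population Wright/Nei form: with
  p̄ = (f_sel + f_ref)/2, H_T = 2p̄(1−p̄) and H_S the mean within-group
  expected heterozygosity, FST = (H_T − H_S)/H_T (0 when H_T = 0). It is
  a pure frequency contrast in [0, 1], symmetric in the groups and
  independent of sample sizes — preferable when group sizes are very
  unbalanced. The haploid Weir–Cockerham ANOVA estimator (sample-size
  weighted, can go slightly negative) is available behind
  `fst_estimator="weir-cockerham"`.
- **ΔDAF / ΔSAF** — derived-allele frequency difference D_S − D_NS when
  every SNP carries an ancestral-allele annotation (a REF/ALT flag, so
  no sequence context is needed); otherwise ΔSAF, the difference in
  frequency of the SELECTED group's major allele (tie at 0.5 polarized
  to ALT — arbitrary but deterministic). Where the derived allele is
  major in the selected group the two statistics coincide exactly.
  Either is standardized genome-wide to zero mean, unit variance
  (population SD).
- **XP-EHH** — ln(I_sel/I_ref), where I is the trapezoid integral of
  extended haplotype homozygosity against physical distance on both
  sides of the core SNP. EHH of an interval is the probability that two
  randomly drawn haplotypes of a population are identical over the whole
  interval (core included). EHH is unconditional — each population is
  summarized by one decay curve from all of its haplotypes, with no
  conditioning on a core allele — matching the cross-population
  construction (per-allele conditioning belongs to iHS-style scans, not
  here). Both integrals share stopping boundaries determined on the
  pooled two-population panel: a side stops at the chromosome end, past
  1 Mb of extension, or after including the first SNP where pooled EHH
  drops below 0.05 (EHH clamped to 0 beyond). Truncation and maximum
  extension are configuration keys; the defaults are de-facto community
  practice and bound runtime, chosen because no principled value exists
  without a genetic map. Scores are standardized genome-wide; a zero
  integral on either side makes the score undefined (NaN).

Composite: per test, genome-wide fractional ranks R/(n+1) with
average-rank ties (keeps the fractional-rank multiset symmetric and the
null calibrated); undefined scores receive the median rank 0.5 so n is
identical across tests. Ranks use the signed statistics as-is — large
values mean selection in the SELECTED group; FST is unsigned, so large
means differentiation in either direction. Then Z = Φ⁻¹(R′), Z̄ the mean
over the m tests, p = 1 − Φ(√m·Z̄) and CSS = −log₁₀ p. Fractional ranks
never touch 0 or 1, so Φ⁻¹ is always finite.

Windows: smoothed CSS at SNP j is the mean over all same-chromosome SNPs
within ±500 kb (closed, including j); windows with fewer than 5
contributing SNPs are pruned and excluded from every downstream basis.
Each constituent's (standardized) statistic is smoothed the same way for
the per-region concordance counts. Significance is the top
⌈0.001·n_retained⌉ smoothed values, ties at the cutoff broken by genome
order so the count is exact; small panels keep at least one SNP (with a
warning). Clusters are seeded greedily from the most extreme unassigned
significant SNP (deterministic and matching how peaks are annotated in
practice), absorb unassigned significant SNPs within ±500 kb on the same
chromosome, are merged while same-chromosome boundary gaps are < 1 Mb
(the merged core is the more extreme one), and are dropped below 3
members — merging happens before the minimum-member filter. Regions are
cluster bounds ± 500 kb, floored at 1 bp.

FDR: computed from the raw (never smoothed) composite p-values. They
are first recalibrated: a concave monotone CDF model
F(p) = Σ c_k p^{a_k} (c_k ≥ 0, Σ c_k = 1, fixed exponent grid
0.02 … 1.0) is fitted to the empirical CDF by non-negative least squares
with relative weights, and each p is replaced by F⁻¹(ecdf(p)). This is a
simplified, extrapolative form of constrained-regression recalibration:
an exactly uniform sample is a fixed point, rank order is always
preserved, a mis-shaped null bulk is pulled toward uniformity, and a
genuine spike of tiny p-values steepens F near the origin so the
extreme tail keeps (or extends) its magnitude instead of being
flattened to ranks. The empirical CDF uses Weibull plotting positions
rank/(n+1); fewer than 100 p-values skip calibration. q-values are
tail-area FDRs q(p) = min over p′ ≥ p of η₀·n·p′/#{p ≤ p′}, clipped to
(0, 1], with η₀ = min(1, 0.25/(1 − q₇₅)) estimated from the p-value mass
above the 75th percentile (the null-dominated range; an exactly uniform
sample gives η₀ = 1, and with η₀ fixed at 1 the procedure is exactly
Benjamini–Hochberg step-up). Small samples (< 100) pin η₀ = 1. Region
summaries report the percentage of SNPs at q ≤ 0.05 inside each called
region and outside all of them.

## Synthetic data

`SweepScenario` generates the package's reference study conditions:
20,000 SNPs on five 100 Mb chromosomes (uniform random distinct
positions), 100 + 100 diploid samples, ancestral-allele frequencies
drawn from Beta(0.5, 0.5) with the derived (ALT) base frequency their
complement, and independent N(0, 0.05) per-population jitter clipped to
[0, 1]. REF is ancestral at every SNP, so the derived-frequency contrast
is symmetric around zero under the null and statistically decoupled from
the homozygosity contrast. Haplotypes are independent Bernoulli draws
per SNP (linkage equilibrium), except that a single fixed haplotype
string spanning ±300 kb of the sweep locus — carrying the derived allele
at the focal SNP — is assigned to each SELECTED haplotype with
probability 0.9 (the sweep carrier frequency). A truth table records the
locus, interval and realized carrier frequencies.

The chromosome length was chosen once so that a 1 Mb window holds ~35
post-filter SNPs — a dense-chip density that gives the EHH integral
useful bp-resolution at desk scale — and the structural sweep encoding
(shared haplotype + elevated derived frequency) was chosen over forward
simulation because it is deterministic, fast, and produces exactly the
two footprints the constituents detect. What the generator does **not**
emulate: background LD (the null genome is at linkage equilibrium),
demography, recombination maps, variable SNP ascertainment, or partial
soft sweeps. Consequences worth knowing:

- Passing sweep-recovery tests show the pipeline localizes a hard sweep
  against an LE background; they do not certify performance under
  realistic LD, where smoothing windows contain correlated scores.
- Under the null, the three constituent ranks are linearly uncorrelated
  but **not independent**: all three tests are most informative at
  mid-frequency SNPs, so |z| values are positively associated and the
  composite p distribution has a heavier-than-uniform joint tail (and
  visible steps from rank ties — group frequencies are multiples of
  1/(2·n_samples)). Null composite p-values are therefore *not* exactly
  uniform at genome scale; this mirrors the behaviour the method shows
  on real panels and is precisely why the FDR stage recalibrates
  p-values instead of trusting them. Genome scans should read q-values
  and region calls, not raw composite p, as the inferential output.
- Genome-wide correlation between standardized ΔDAF and ΔSAF is ≈ 0
  under the symmetric derived-frequency base (the ΔSAF polarization
  flips sign wherever the derived allele is minor in the selected
  group); the two agree strongly — identically, in fact — exactly where
  sweeps have pushed derived alleles to major status, which is the
  regime that matters for detection.

## Numerical choices

- EHH equality of haplotype strings is decided by prefix-summed random
  64-bit hashes (collision probability ~2⁻⁶⁴ per comparison); the fast
  scan is required by tests to agree exactly with a direct
  pair-enumeration implementation.
- Smoothing uses cumulative sums with `searchsorted` window edges; NaN
  inputs (undefined XP-EHH) are excluded from both numerator and count.
- The composite p uses the normal survival function, keeping precision
  for extreme scores (p ~ 1e−300 rather than underflowing to 0).
- Standardization is population-SD, genome-wide (all chromosomes
  pooled), applied before smoothing; zero-variance input is an error.
- Degenerate inputs: a panel with < 2 post-filter SNPs is an error; < 2
  haplotypes in a population makes EHH undefined (integral 0, XP-EHH
  NaN, median rank downstream); a single p-value gets q = p.

## Limitations

- Two populations only; no hierarchical F-statistics, no k > 2 scans.
- Physical distance only (no cM support); autosome-style chromosomes.
- The recalibration is a simplified stand-in for full
  constrained-regression recalibration — it honours the contract that
  matters downstream (order preservation, uniform nulls, preserved
  signal tails) but is not a faithful port of the original fitting
  procedure, and its tail extrapolation can *overshoot* (a p of 1e−11
  may calibrate to 1e−15); q-value rankings are unaffected.
- Region calling on smoothed scores will, by construction, group
  neighbouring top SNPs even on null panels (two spurious regions on a
  typical 20,000-SNP null genome); the FDR contrast, not the existence
  of a region, carries the evidence.
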