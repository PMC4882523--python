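# Methods

## Scope and model

The package implements a two-group selective-sweep scan for diploid
SNP-array data.  The contrast is between an "observed" group (G1, highland)
and a "reference" group (G2, lowland), each composed of one or more breeds.
Two complementary statistics are computed per SNP: the Weir–Cockerham
variance-component estimator of F_ST (allele-frequency differentiation) and
XP-EHH (differential haplotype homozygosity), and their upper tails are
intersected.  The two statistics fail in different ways — F_ST is noisy at
small sample sizes, XP-EHH is undefined where haplotype homozygosity never
decays within the scan limits — which motivates the rescue rule: a SNP in
the F_ST tail whose XP-EHH is undefined still enters the candidate set.

## Estimators and conventions

**Weir–Cockerham components (r = 2).**  Per locus, from diploid sample
sizes nᵢ, alt frequencies pᵢ and observed heterozygote proportions hᵢ:

    n̄ = (n₁+n₂)/2              n_c = (2n̄ − (n₁²+n₂²)/(2n̄))
    p̄ = Σnᵢpᵢ/(2n̄)             s² = Σnᵢ(pᵢ−p̄)²/n̄
    h̄ = Σnᵢhᵢ/(2n̄)
    a  = (n̄/n_c)[s² − (p̄(1−p̄) − s²/2 − h̄/4)/(n̄−1)]
    b  = (n̄/(n̄−1))[p̄(1−p̄) − s²/2 − h̄(2n̄−1)/(4n̄)]
    c  = h̄/2                    θ̂ = a/(a+b+c)

θ̂ is undefined when a+b+c = 0 (monomorphic locus) or when either group has
fewer than two called individuals; undefined loci are excluded from
quantiles and from multi-locus sums.  Per-SNP θ̂ may be negative and is
*not* clipped for ranking; clipping to 0 happens only when multi-locus
values enter a distance matrix.  Multi-locus θ̂ between breed pairs is
Σa / Σ(a+b+c) over defined loci.

**EHH.**  For a core SNP, haplotypes are partitioned by identity of the
segment [core..current] as the scan extends outward one SNP at a time;
EHH = Σ_k C(m_k,2)/C(n,2) over partition class sizes.  The curve starts at
the conventional point (0, 1) and is truncated when EHH < 0.05 (cutoff),
the span exceeds 1 Mb, an inter-SNP gap exceeds 200 kb, or the chromosome
ends; the truncation reason is recorded.  All haplotypes of a population
are pooled at the core (homozygosity is compared between whole populations,
not between core-allele classes).  Distances are physical bp — appropriate
for array data without a genetic map.

**iHH and XP-EHH.**  iHH is the trapezoidal integral of max(EHH − cutoff, 0)
over distance, summed over both sides.  A score is defined only when both
sides of both populations decayed below the cutoff and both iHH values are
positive; otherwise the SNP carries a null score.  raw = ln(iHH_obs/iHH_ref)
is standardized by the mean and (population) standard deviation of all
defined raw scores, so standardized scores have mean 0 and sd 1 exactly.
Null scores at this data scale arise mainly near chromosome ends and inside
very long swept regions.

**Quantile rule.**  The upper tail of M defined values selects the
ceil(q·M) largest; ties at the boundary are all included, and the reported
threshold is the smallest selected value.  With 46,355 distinct scores and
q = 0.01 this selects exactly 464.

**Structure stage.**  LD pruning follows sliding-window `indep-pairwise`
semantics: 25-SNP windows advanced by 5 SNPs; within a window, pairs with
squared Pearson correlation of mean-imputed dosages above 0.05 are broken
by dropping the member with more missing calls (tie: the later position).
IBS similarity between samples is the mean shared-allele fraction over
jointly called SNPs; MDS is classical (Torgerson) scaling of 1−IBS, used
directly without a square-root transform, with a deterministic sign
convention (first nonzero loading of each axis positive).  Neighbor joining
uses the Saitou–Nei Q-criterion with ties broken toward the smallest sorted
label pair; negative branch lengths are clipped to 0 with the residual
moved to the sister edge so the joined pair's path length is preserved.
The NJ input is the pairwise F_ST matrix itself (linearized F_ST/(1−F_ST)
is available via `multilocus_theta` but is not the default).

**Nucleotide diversity.**  π per breed is Σ 2p̂(1−p̂)·n/(n−1) over sites,
divided by `total_sites`.  The surveyed-length denominator behind
chip-based absolute π values is generally unknowable from the chip alone,
so `total_sites` defaults to the SNP count, making the reported value a
per-SNP average heterozygosity; only comparisons between breeds are
meaningful.

**Association.**  Allele-count chi-squared uses the plain Pearson 2×2 form
(no Yates correction) so the statistic has the textbook closed form.  The
trait model is OLS of trait on genotype class (unordered factor — the
contrast of interest is between homozygote classes) plus sex; the genotype
test is the F-comparison of the full against the sex-only model, and
adjusted means average predictions over sex levels with equal weight.
Fisher's LSD reuses the model covariance and residual df for unadjusted
pairwise contrasts.  Missing trait values are dropped listwise per trait.

## Synthetic data

The generator emulates the statistical structure the scan assumes, not any
particular genome:

- **Frequencies.**  Balding–Nichols: ancestral p ~ U(0.05, 0.95) per SNP;
  each group draws Beta(p(1−F)/F, (1−p)(1−F)/F) independently.  Default
  F = 0.08, matching moderate between-group differentiation.
- **Haplotypes and LD.**  A latent uniform is copied from the previous SNP
  with probability ρ = 0.3 (reset at chromosome starts) and thresholded at
  the SNP's group frequency, giving marginally correct frequencies with
  short-range LD.
- **Sweep.**  The core SNP's G1 frequency is overridden to the sweep's
  final frequency (default 0.9).  Haplotypes that drew the alt allele at
  the core all receive the first such haplotype's alleles across the sweep
  span (default 400 kb), so the realized core frequency matches the draw
  while the span carries one long shared haplotype — the signature XP-EHH
  must detect.  This is a mechanical sweep, not a forward simulation: it
  guarantees the property under test but has no recombination breakpoints
  within carriers and no soft-sweep structure.
- **Scale.**  Defaults are 2 × 40 diploids (split into 3 highland and 4
  lowland breeds), 10,000 SNPs on three 50-Mb chromosomes, 2% genotype
  missingness (haplotypes stay complete, as phased input requires).
- **Phenotypes.**  Six haematological traits with sheep-scale baselines and
  nominal within-group sds (RBC 9.5 ± 1.2 ×10¹²/L, HGB 110 ± 8 g/L, HCT
  0.33 ± 0.03, MCV 34 ± 2.5 fL, MCH 11 ± 0.9 pg, MCHC 330 ± 9 g/L).
  Effects are expressed in units of the trait sd: the causal genotype adds
  +1 sd per alt copy to RBC and −1 sd to MCV and MCH; highland membership
  adds +1 sd to every trait except MCHC; males get +0.5 sd; residual noise
  is 1 sd.  The genotype and group effects deliberately pull MCV/MCH in
  opposite directions within highlanders, mirroring the situation where a
  selected allele modulates a trait that is also shifted at the group
  level.  Sexes alternate for balance.

All generators are pure functions of the config including its seed;
regenerating a fixture bundle is byte-identical.

What passing on these data does *not* show: robustness to phasing error
(haplotypes are simulated error-free), to array ascertainment bias, to
population substructure within groups beyond breed labels, or to soft or
incomplete sweeps.

## Numerical and design choices

- MAF and missingness filters use strict inequalities (keep MAF > 0.01,
  missing rate < 0.05); QC removal counts attribute each SNP to the first
  failing criterion in the order MAF, missingness, chromosome, and a SNP
  with no calls at all is attributed to missingness (its MAF is undefined).
- Dosages count the globally minor allele fixed once at load (or an
  explicit allele table); per-group re-orientation would corrupt
  differentiation estimates.
- r² of a zero-variance dosage vector is defined as 0 (such SNPs never
  trigger pruning).
- The XP-EHH fast path is a numba kernel; `ehh`/`ihh` remain the reference
  implementation and the test suite asserts their agreement.
- Standardization uses the population (ddof 0) standard deviation.
- Chi-squared tables with an absent allele column return a flagged
  undefined statistic rather than raising.
- Degenerate Welch comparisons (both groups constant and equal) report
  p = 1 by convention.
- The gene-assignment flank (25 kb) is a configurable convention, not an
  inferred value; scan limits (cutoff 0.05, 1 Mb span, 200 kb gap) follow
  common haplotype-scan practice and are all configurable.

## Problem sizes used by the test suite

The sweep-recovery check runs 20 sweep and 20 null replicates at the
default conditions above (2 × 40 diploids, 10k SNPs, F = 0.08, sweep to
0.9) and requires a candidate within 100 kb of the core in at least 18/20
sweep replicates with no such enrichment under the null.  Smaller fixtures
(2 × 20 diploids, 400 SNPs on two 5-Mb chromosomes) drive the per-module
tests; at that scale the 1% F_ST tail holds only four SNPs, so end-to-end
CLI checks widen the tail to 5% rather than asserting through noise.

## Known limitations

- EHH includes the core allele in the compared segment and pools all
  haplotypes; scans conditioning on core alleles (iHS-style) are out of
  scope.
- No genetic-map support beyond physical distance unless positions are
  supplied in map units.
- Binary PLINK (BED), imputation, phasing and admixture inference are out
  of scope; phased input is consumed as-is.
- Absolute π values depend on an external surveyed-length denominator and
  are not comparable across datasets with different denominators.
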