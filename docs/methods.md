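# Methods

## Model and assumptions

The package targets association panels of fully homozygous (inbred) lines.
Each line carries one of two homozygous genotypes at a biallelic marker, so
a marker defines at most K = 2 phenotype groups; heterozygous calls are
treated as genotyping noise (masked by default, or the marker dropped).
One phenotype value per line per trait is assumed — within-line replicate
structure, and hence within-genotype variance heterogeneity between
repeated measurements, is outside the model.

At a single locus the phenotype is modeled per genotype g as
y = mu_g + sigma_g * eps with eps of mean 0 and variance 1 ("standard
deviation model": the genotype acts additively on the SD scale). The
phenotypic variance then decomposes exactly as

    sigma2_P = p*q*d_mu^2  +  p*q*d_sigma^2  +  (p*sigma_2 + q*sigma_1)^2
               [sigma2_m]     [sigma2_d]        [sigma2_eps]

with p the low-variance allele frequency (LAF), q = 1-p, d_mu and d_sigma
the between-genotype differences in mean and SD, and sigma_1 >= sigma_2
the high/low genotype SDs. The first term is the additive variance (no
dominance in inbreds), the second the variance of the per-genotype SD
across the population, the third the squared mean per-genotype SD. The
residual term is defined as (p*sigma_2 + q*sigma_1)^2 precisely so that
the three terms sum to the mixture variance
p*q*d_mu^2 + p*sigma_2^2 + q*sigma_1^2 exactly; the identity is algebraic
and is enforced to machine precision by tests. h2_m and h2_d are the first
two terms as fractions of sigma2_P. Both are maximized in p at
sigma_1/(sigma_1+sigma_2), independent of d_mu (verified against grid
maximization at 1e-4 resolution).

Estimation is plug-in: sample means, sample SDs (n-1 denominator) and
sample genotype frequencies replace population quantities, with no
small-sample bias correction. The genotype with the larger sample SD is
labeled high-variance; an exact SD tie keeps the allele-A homozygote as
the low-variance class, making the labeling deterministic.

## Tests

The variance scan uses the Brown–Forsythe test: a one-way ANOVA on
absolute deviations from per-genotype medians (midpoint convention for
even group sizes). F follows F(K-1, N-K); since panel sizes put N around
200, (K-1)F is treated as a chi-square(1) score, and the chi-square
p-value is the one used downstream (genomic control operates on chi-square
scores); the F-based p-value is also reported. Degenerate markers follow
fixed conventions chosen so that zero-dispersion markers are never
spuriously significant: within-group SS = 0 with between-group SS = 0
gives F = 0, p = 1; within = 0 with between > 0 gives p equal to the
smallest positive double and a degeneracy flag (such scores are excluded
from lambda estimation, where one infinity would swamp the regression).

The mean scan is the two-sided Wilcoxon rank-sum test: average ranks for
ties, tie-corrected variance, 0.5 continuity correction by default, exact
enumeration available for N <= 20. Whether continuity correction or exact
p-values are used is a declared convention of this implementation, not an
inference from prior practice. The squared normal deviate is the
chi-square(1) score used for genomic control.

Markers are skipped (with reason codes, never exceptions, in scan context)
when monomorphic or when a genotype class is below min_group_size
(default 2 — a singleton class contributes no within-group dispersion).

## Scan pipeline

Per trait: complete-case alignment in genotype-matrix order; MAF filter
(default: minor allele frequency < 0.10 removed, computed on the analyzed
complete-case sample, the conservative reading of the filter); both tests
per surviving marker; lambda estimated per test family over surviving
markers; GC-corrected p-values; Bonferroni threshold alpha / (markers
tested for the trait) — a fixed denominator (e.g. a chip-wide count) is
available via `bonferroni_m`; variance decomposition at every tested
marker (not only significant ones, so mean- and variance-explained
fractions can be compared genome-wide); traits with Brown–Forsythe
lambda strictly greater than 1.5 are flagged (strict inequality chosen;
configurable). No adjustment across traits is made.

## Genomic control

Lambda is estimated either by zero-intercept regression of the sorted
observed scores on chi-square(1) quantiles at plotting positions
(i - 0.5)/n (the symmetric convention; the paper-trail choice here was
open) or by the median ratio. The regression estimator is exactly
scale-equivariant and, on heavy-upper-tailed score sets, at least as large
as the median ratio — i.e. the more conservative correction. Correction
divides scores by max(lambda, 1) by default; clamping can be disabled, as
whether deflated traits should be amplified is a policy question the
estimator cannot settle.

## Simulator

`simulate_dataset` draws independent biallelic markers (no linkage
disequilibrium) on n_lines homozygous lines; one designated causal marker
sets mu_g and sigma_g. Defaults emulate the target panel scale: 200 lines,
normal noise, intermediate allele frequency. With n_subpops > 1, marker
frequencies differentiate via Balding–Nichols beta draws with parameter
Fst and subpopulations receive evenly spaced additive mean offsets of
scale subpop_shift; this induces genome-wide inflation of both scans
because genotype classes at differentiated markers are different mixtures
of shifted subpopulations. A unit-variance Student-t noise option (df = 3
by default) probes robustness to heavy tails. What the generator does
*not* emulate: linkage disequilibrium, multi-locus architectures,
genotyping error, within-line replicates, and real ascertainment of chip
SNPs — so passing simulations demonstrate calibration and power under the
generating model, not performance on any particular real panel.

Study drivers report empirical rejection rates with binomial Monte-Carlo
standard errors. The Monte-Carlo Brown–Forsythe path batches replicates by
genotype-class size (exchangeability makes a fixed block layout
distributionally equivalent to random assignment) so the studies vectorize;
a test pins the batched statistic to the scalar implementation.

Problem sizes used by the shipped studies and the acceptance script —
10,000 single-marker replicates for error calibration, 1,000 datasets of
n = 500 for decomposition recovery, 100 replicates of 300-marker genomes
on 200 lines for the structure study — were chosen as the smallest sizes
at which the Monte-Carlo standard errors are comfortably below the
tolerances being checked.

## Enrichment

SNPs are ranked by ascending GC-corrected p; tied p-values share the
floored average of their positions (deterministic). A gene's rank is the
best rank among SNPs within a window (default 20 kb, configurable — the
assignment window is a declared choice) of its interval; BED half-open
start coordinates are respected at the boundary. Merging GWAS and vGWAS
rank lists takes the element-wise minimum; "improved" means the combined
rank is strictly smaller than the GWAS-only rank.

## Numerical and design notes

- Genotype calls are int8 with -1 as the out-of-band MISSING sentinel
  (never a valid code); phenotypes use NaN.
- MAF for inbreds equals minor genotype frequency; it is invariant to
  allele-label swaps and returns 0 for monomorphic markers.
- All randomness flows from explicit integer seeds through
  numpy Generator objects; scans are fully deterministic given inputs
  and config.
- p-values are floored at the smallest positive double so that -log10
  transforms stay finite.
- The decomposition canonicalizes reversed labels (sd_low > sd_high) by
  swapping genotypes and replacing p with 1-p, making it invariant to
  label exchange.

## Known limitations

- K = 3 (heterozygous) populations, covariates, kinship/mixed-model
  correction and double generalized linear models are out of scope; the
  genomic-control scalar is the only structure correction.
- The variance decomposition is single-locus; no epistatic or multi-locus
  partitioning.
- Regression-based lambda is sensitive to a handful of very strong true
  signals when the marker set is small (visible in the packaged toy
  example); with genome-scale marker counts the null bulk dominates.
- The inflation-triage threshold (1.5) is a reporting convention, not an
  estimated quantity.
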