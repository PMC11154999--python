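# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of the
package. It describes what the code computes; every empirical number it
mentions is produced by the test suite or by `scripts/acceptance.py`.

## Mixed linear model association

Phenotypes (fertility traits and expression features alike) are analysed
under y = Xb + gβ + u + e, u ~ N(0, σ²_g G), e ~ N(0, σ²_e I). The GRM
uses centred, frequency-standardised dosages,
G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)); missing
dosages are mean-imputed per variant and monomorphic variants are
skipped. Under Hardy–Weinberg genotypes the average diagonal is ≈ 1.

REML maximises the restricted likelihood through the spectral
decomposition of G: after rotating by the eigenvectors the likelihood is
profiled to a scalar function of γ = σ²_g/σ²_e and maximised by bounded
Brent search on log γ over e^[−12, 12] with tolerance 1e-8; γ = 0 is
evaluated explicitly so the no-genetic-variance boundary is exact rather
than approached asymptotically.

Variance components are estimated once on the null model (covariates
only) and reused for every variant — the standard single-fit MLMA
economy. Each variant is then tested by generalised least squares in the
whitened space (Frisch–Waugh residualisation against the fixed effects),
with a two-sided p from the normal approximation to the Wald statistic.
No small-sample t correction is applied; consequently the package's
"collapse to ordinary least squares" property at σ²_g = 0 holds exactly
against an OLS computation that uses the same two conventions
(null-model residual variance, normal p), and the test suite's
independent lstsq oracle is written that way. Variants with zero dosage
variance after imputation are emitted with p = 1 and a `zero_variance`
flag.

Genome-wide trait scans use leave-one-chromosome-out (LOCO) GRMs with
variance components re-estimated per left-out chromosome, removing
proximal contamination. Expression cis scans use the whole-genome GRM
(one REML fit per feature) with age as a covariate; the cis window is
the feature span ± 1 Mb, bounds inclusive, 1-based coordinates
throughout. Binary fertility traits go through the same linear mixed
model — direction of effect is all that downstream stages consume from
them, and a linear model estimates that direction consistently.

## Meta-analysis

Per-stratum scans are first allele-aligned (effects re-signed so the
tested allele is always ALT; ref/alt-swapped records are not silently
merged) and combined by the sample-size-weighted Z-score,
z_meta = Σ √n_s z_s / √(Σ n_s). Variants missing from some strata are
combined over the strata that carry them. Inverse-variance weighting and
heterogeneity statistics are deliberately out of scope.

## Discovery: thresholds, FDR, clumping

Significance is p ≤ 1e-6 (inclusive); the enrichment stages also run a
grid of 1e-4/1e-6/1e-8. The expected FDR of a fixed-threshold call set
is Q_e = (n_tests × threshold)/R; values above 1 are reported as-is and
an empty call set leaves Q_e undefined.

Clumping uses single-linkage chaining: on each chromosome, significant
variants whose consecutive gaps are ≤ 1 Mb form one region, which is
exactly the connected components of the "within 1 Mb" graph (regions may
therefore span several Mb, and neighbouring regions are separated by
more than the window). The region's top variant is its smallest-p member
with ties broken by position then alleles, making the output invariant
to input order. A stricter `top` mode (greedy capture within 1 Mb of
each successive top variant) is available where single peaks are wanted.
BED export converts to 0-based half-open coordinates at the boundary.

## Allele-specific expression

The allele-count phenotype is the natural log of (nRef+10)/(nAlt+10);
the log base is a scale choice that only rescales the linear-model
effect. QC removes rows with allele-count sum < 10, rows where read
depth exceeds the allele-count sum by more than 20% of depth, and rows
whose two most prevalent alleles do not match REF/ALT.

Both ASE tests use only individuals heterozygous and phased at both the
tSNP and the dSNP, and both variants must have MAF ≥ 0.05 (the
double-heterozygote restriction shrinks the sample, so rare variants are
uninformative). The phase coding is x = +1 when the dSNP alternate
allele lies on the same haplotype as the tSNP reference allele; the
opposite convention would only flip the sign of b. The linear test
regresses the phenotype on x with an intercept (with balanced ±1 coding
the slope is identical with or without one; the intercept makes the test
robust to a mean shift) and uses a t p-value on n−2 df; fewer than three
double-heterozygotes or constant coding yields an undefined (never
significant) result. The Z-test statistic (A/T − 0.5)√(4T) is the score
statistic of Binomial(T, ½) — the tests verify the identity
Z = (A − T/2)/√(T/4) exactly. A tSNP/dSNP pair is called significant
only when both tests reach the threshold; an undefined test blocks the
call. Both p-values are two-sided. Read-level reference-bias correction
and beta-binomial overdispersion are out of scope.

## Differential expression

Gene counts are TMM-normalised (trim 0.30 on M, 0.05 on A — the
method's published defaults; reference column by 75th-percentile count
fraction closest to the mean; factors scaled to geometric mean 1; the
implementation agrees with the Bioconductor reference to 1e-6 in the
test suite). Genes need ≥ 3 CPM (effective library sizes) in ≥ 50% of
individuals; the per-sample fraction is a parameter since only the CPM
cutoff itself is canonical. Introns must be present in ≥ 60% of
individuals and show usage variance above var_eps = 1e-8 (the "almost no
variation" cut, exposed as a parameter); intron phenotypes are
within-cluster usage proportions.

The exact test conditions on the total of the two group sums of
quantile-adjusted pseudo-counts (counts mapped to the geometric-mean
library size by NB quantile matching, averaging normal and gamma
approximations). With common dispersion φ estimated by conditional
maximum likelihood (two alternating rounds of pseudo-count update and
1-D likelihood maximisation on log φ ∈ [log 1e-6, log 5]), the two-sided
p sums the probabilities of all splits as or less likely than the
observed one under Y_g ~ NB(n_g μ, size n_g/φ). As φ → 0 this reduces
exactly to the conditional binomial exact test (verified against
scipy's binomial test to 1e-6). log2 fold changes use prior-damped
(0.5 count) normalised group means, positive = up-regulated in the POS
line; BH adjustment at FDR < 0.05. Tagwise dispersion is out of scope.

## Enrichment and concordance

Enrichment folds are ratios of percentages as defined in the README; the
2×2 chi-square of independence has no continuity correction by default
(cell counts in the intended applications are large; a flag restores
it). Direction concordance uses signs only: each trait carries a
polarity (+1 if a positive effect is favourable; for a calving-interval
trait the polarity is −1), and a variant is consistent when its
polarity-adjusted signs agree across the two scans. Variants missing
from either scan are excluded and counted.

The overlap report implements the all-directions rule: for a variant
significant for the trait and an eQTL kind, the trait-favourable allele
is determined from the meta-analysis sign and the trait polarity, and
the flag requires (i) the favourable allele's expression direction to
match the sign of the gene's between-line differential expression,
(ii) the favourable allele to be more frequent in the POS line, and
(iii) its direction on every supplied secondary-trait scan to be
favourable. Any undefined component (missing scan, zero effect, gene
absent from the DE table) leaves the flag undetermined (None) rather
than False; the flag is invariant to globally relabelling ref/alt.

## Synthetic data

The generator reproduces the statistical structure each downstream stage
consumes, not cattle-genome realism: no real map, no breed LD panels, no
pedigree, no coalescent model.

* **Genotypes.** Founder haplotypes carry alleles thresholded from an
  AR(1) latent Gaussian along each chromosome (decay length 200 kb), so
  LD decays with distance; individuals are founder mosaics with Poisson
  switch points (1e-6 per bp). Allele frequencies follow a Beta(0.8,
  0.8) spectrum floored at 0.02. Defaults: two strata of 300 individuals
  from a shared pool of 30 founder haplotypes, two 10 Mb chromosomes of
  500 variants each — small enough for minute-scale test suites, large
  enough for the planted-recovery experiments.
* **Lines.** POS/NEG labels by truncation on true genetic merit
  (favourable sign × genetic value, default −1: lower calving interval
  is better) within stratum; the tail fraction is configurable (default
  0.5, a two-line partition; smaller fractions leave an OTHER class).
  Allele-frequency shifts at causal variants arise from the selection
  itself and are recorded in the ground truth.
* **Traits.** Continuous trait = causal effects + GRM-consistent
  polygenic term + Gaussian noise scaled to heritability 0.25 by default
  (fertility traits are lowly heritable; experiments that need more
  power set 0.5 explicitly). Binary traits threshold an independent
  liability at a configured prevalence with a configured favourable
  direction. Calving age, calving month and (for post-six-week traits)
  synchronisation enter with known nuisance effects.
* **Expression.** NB counts (dispersion 0.1) with log-mean = gene
  baseline (log-normal around 100) + cis effect × dosage + line effect
  for DE genes + log library offset; library sizes span ≥ 2-fold. Exon
  counts are multinomial partitions of the gene count (eeQTL shift one
  exon's logit proportion per dosage); intron clusters likewise (sQTL
  shift usage). Planted cis variants may be given as −1, resolving to
  the variant nearest the feature.
* **Allele counts.** Depth ~ Poisson(30); reference reads ~
  Binomial(depth, π) with logit(π) = θ·s, s the ±1 phase coding defined
  exactly as in the ASE module, so θ = 0 is the exact null of both
  tests. Homozygous individuals are emitted monoallelic, exercising the
  double-heterozygote filter.

Every stage draws from its own child generator of the seed, so outputs
are bit-reproducible and stages can be re-run independently. Fixture
files written twice with one config are byte-identical.

What the generator does **not** emulate — and hence what passing tests
do not certify about real data: reference alignment bias in allele
counts, tagwise dispersion heterogeneity, population structure beyond
the shared-founder design, genotyping/imputation error correlated with
MAF, and LD panels matching any real breed.

## Experiment sizes

The validation experiments run at desk scale by design: null
calibrations use 2 000 replicates (ASE) or 2 000–5 000 variants (scan
uniformity, genomic-control lambda); parameter recovery uses 10
replicates at n = 300 (planted cis effect, 20% of phenotype variance —
planted directly on the normalised phenotype scale so the variance share
is exact) and one n = 500 heritability fit; enrichment calibration
permutes labels 1 000 times over a 100 000-variant universe; the DE
experiment plants 20 of 200 genes at |log2FC| = 2 with 150 individuals
per line over 10 seeds; the concordance experiment runs 5 end-to-end
replicates.

In the concordance experiment the non-concordant counterpart is
constructed from the replicate's own outputs (the DE evidence reversed)
rather than by flipping the planted line effect: under truncation
selection on the causal variant, line membership is nearly collinear
with dosage, so a flipped planted line effect also flips the marginal
cis-effect estimate and the variant becomes genuinely — and correctly —
concordant again. The constructed counterpart isolates what the check is
about: the flag must respond to a reversed direction.

## Known limitations

* The normal-approximation Wald p is anti-conservative in very small
  samples; at the package's intended n (hundreds) the genomic-control
  lambda sits within [0.9, 1.1].
* The common-dispersion exact test ignores gene-specific dispersion;
  genes far more variable than the common estimate can reach small p
  spuriously in real data.
* The expected-FDR estimator assumes all tests are null in expectation
  (E(V) = n × threshold), so it overstates V when many tests are
  non-null.
* Single-linkage clumping can chain distinct signals into one region in
  dense significance landscapes; `top` mode is the conservative
  alternative. No LD-based clumping or conditional analysis is provided.
* No colocalisation: trait and expression evidence are combined by
  direction concordance only.
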