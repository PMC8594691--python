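# Methods

## The statistical model

All three scans are mass-univariate ordinary least-squares fits with a
two-sided *t* test on one coefficient. For methylation row *M_i* (a
vector of fractions over samples), environment *E*, genotype dosage
*G_j* ∈ {1, 2, 3} and covariate design *X* (intercept plus encoded
covariates):

| scan   | model                          | tested term |
|--------|--------------------------------|-------------|
| Emodel | M_i = Xα + βE + ε              | β           |
| Gmodel | M_i = Xα + βG_j + ε            | β           |
| GxE    | M_i = Xα + γG_j + δE + β(G_j·E) + ε | β      |

Categorical covariates are one-hot encoded with the first level dropped,
mirroring `lm` factor handling in R; numeric covariates enter as-is. The
design must be full rank with at least one residual degree of freedom
left for the tested term. Degrees of freedom are those of the full
fitted model (n − rank − 1 for E/G, n − rank − 3 for GxE with the
genotype and environment main effects in the nuisance block).

The scans are computed by the Frisch–Waugh–Lovell device: the
methylation row and the tested regressor are both residualized against
the nuisance columns (via a QR basis), and the simple regression between
the residuals reproduces the full-model coefficient, *t* statistic and
p-value exactly. The test suite verifies agreement with naive per-row
`statsmodels` OLS refits to 1e-8 relative on 50 samples × 3 covariates.

Genotype is an additive numeric dosage in the regression. In the GxE
*visualisation* the environment relationship is instead shown per
genotype class (AA/AB/BB trend panels); a categorical-interaction
regression would be the alternative reading, and the interaction
coefficient was chosen because it is the hypothesis the additive coding
actually tests.

Rows whose *t* statistic is non-finite are dropped before FDR. These
arise when the residual sum of squares underflows (an exact linear fit —
e.g. a bisulfite artefact tracking the environment perfectly) or when
the tested regressor is collinear with the nuisance block. RSS below
1e-12 of the row's residualized total sum of squares is treated as an
exact fit; without that clamp, floating-point dust would turn infinite
statistics into astronomically large finite ones and defeat the filter.

## Multiple testing and chunked execution

q-values are Benjamini–Hochberg step-up, computed once per scan over all
retained rows: q_(i) = min_{j≥i} p_(j)·m/j, capped at 1. Running FDR
inside subsets (per chromosome, per chunk) changes every q-value because
m and the ranks change; the package therefore exposes `merge_chunked`,
which pools the per-row statistics first and corrects once. For this to
be *bitwise* exact, every per-row statistic must be bit-identical no
matter which other rows share the batch. Two implementation details
guarantee that:

- row projections and dot products use per-row 1-D kernels rather than
  batched matrix products (BLAS gemm rounding depends on batch shape);
- the imputation stream is keyed per cell (below), not drawn
  sequentially.

## Missing data

Uniting independently sequenced methylomes leaves cells missing wherever
a sample lacks coverage. Rows are first filtered by missing fraction
(`filter_NA`, default 0 — only complete rows; any fraction up to 1 is
accepted). Each remaining missing cell is imputed from a beta
distribution moment-fitted to the row's observed values: with sample
mean m and variance v, c = m(1−m)/v − 1, α = mc, β = (1−m)c. The fit is
degenerate when v < 1e-12 or c ≤ 0 (a spread no beta distribution with
that mean can produce, e.g. observed values {0, 1}); degenerate rows
impute the row mean. Method of moments was chosen over maximum
likelihood because it is closed-form, robust at the small per-row sample
sizes involved, and matches established practice for this distribution
in methylation tooling.

The random draw for a cell is generated by a counter-based generator
(Philox) keyed by a hash of (chromosome, start, sample id, seed). This
buys the locality property stated above: adding or removing rows —
or splitting the matrix by scaffold — cannot change any imputed value. A
sequential generator would break it. Tests verify the draws' first two
Monte-Carlo moments against the fitted beta within 3 standard errors.

Genotype missingness is handled by a frequency imputer: variants over a
missing-fraction threshold are dropped, remaining missing codes take the
variant's modal code (ties resolve toward the code nearest the variant
mean, then the smaller code). This is deliberately simple — it is not a
haplotype-aware imputer — and with the default VCF filters (complete
genotyping required) it never actually fires.

## Matrix assembly and input types

Per-sample bedGraph calls (6-column dialect: percent methylation plus
methylated/unmethylated counts; 4-column accepted with unknown coverage)
are united into one matrix with `bedtools unionbedg` semantics (verified
against bedtools itself in the tests). Calls below the coverage
threshold (default 5 reads) are treated as missing. Contexts never mix
within one matrix; the CLI runs each enabled context independently.

DMP input intersects the matrix with the union of 1-bp intervals across
comparisons. DMR input either keeps the per-position rows inside the
regions or averages them: union DMRs are built by splitting all interval
boundaries into elementary intervals and keeping those covered by at
least a fraction X of the distinct comparisons (a comparison counts once
however many of its intervals overlap). Kept adjacent intervals merge by
default (`--udmr-independent` keeps them separate). With X → 0 this is
the union, with X = 1 the intersection; a single comparison passes
through unchanged. Region averaging takes the mean of each sample's
non-missing values over covered positions, and a region cell is missing
only when the sample is missing everywhere in the region — this
maximises retained data ahead of the NA filter, at the cost of averaging
over different position subsets per sample.

The per-position variation filter keeps rows with sample standard
deviation (n−1 denominator) and/or max−min range above thresholds on the
fraction scale (0.10 = 10 percentage points).

## Genotypes

VCF sites are used when biallelic SNPs with QUAL ≥ 30, completely
genotyped (missing fraction threshold 0 by default) and with minor
allele count ≥ 3; all three filters are flags. Codes are 1/2/3 for major
homozygote / heterozygote / minor homozygote, the major allele being the
more frequent among non-missing calls at the site, ties resolving to
REF. Multiallelic records and indels are skipped. The cis pairing for
the genetic models takes pairs on the same chromosome with
|SNP − cytosine| ≤ `--distance` (default 2000 bp); `--all-pairs` exists
for tiny datasets.

## The synthetic-data generator

`simulate_dataset` emulates what the upstream callers would hand the
tool: per-sample per-context bedGraphs with read counts, a biallelic
HWE VCF, a headerless sample sheet and a truth table of planted effects.
Per position *i* and sample *s*:

    logit p_is = logit(base_i) + site_s + effect_is + N(0, σ²)
    coverage_is ~ NegBin(mean 20, dispersion 5)
    counts_is ~ Binomial(coverage_is, p_is),  value = counts/coverage

with base_i ~ Beta(2, 2) clipped to [0.02, 0.98], a small planting-site
covariate shift (0.2 logits per site), residual noise σ = 0.3 logits,
10% random dropout (missing calls), environment ~ N(0, 1), and 28
samples over three sites by default — a small targeted-bisulfite cohort.
Effects are planted on the logit scale so fractions stay bounded at any
size: E effects add size·E, G effects size·(G−2), GxE effects
size·(G−2)·E, with G the major-allele-oriented code the pipeline's own
encoder will reproduce from the written VCF (so recovered signs match
the truth table). Two generator choices support identifiability and are
worth stating: planted positions draw their baseline from U(0.35, 0.65),
because a logit-scale effect at a near-0/1 baseline barely moves the
fraction; and effect-carrier SNPs are resampled until every genotype
class has ≥ 3 samples, since an interaction with an empty class is not
estimable. Background SNPs have neither constraint.

What the generator does **not** emulate: linkage disequilibrium
(variants are independent), spatial correlation of methylation along the
genome, bisulfite conversion error, mapping bias, and batch effects.
Passing tests therefore demonstrate the statistical machinery —
calibration, power at a stated effect size, invariances — not
performance on real cohorts with correlated markers.

`make_worked_example` writes a fixed 4-sample bundle with hand-checkable
numbers (values in exact tenths at coverage 10) used in the README and
the golden-output test. With 4 samples the interaction model has zero
residual degrees of freedom, so the pipeline logs a warning and skips
GxE on it; skipping rather than erroring is deliberate.

## Experiment sizes used by the checks

The acceptance checks run at sizes chosen to finish in seconds while
keeping Monte-Carlo error well inside the asserted bands: null
calibration pools p-values from two simulated cohorts of 2 × 2500
positions, n = 50, 60 variants (≈ 4.8k Emodel and 22k pair p-values;
binomial SE at α = 0.05 is ≈ 0.003); effect recovery uses 100 replicates
of a 40-position, 6-variant cohort with one planted E and one planted
GxE effect of 1.0 logits at n = 50, complete data (missingness is
exercised by the calibration and imputation checks, so the recovery
number measures scan power, not imputation dilution); the interval and
BH oracles use 100 random instances ≤ 10 kb and 1000 random vectors.

## Post-hoc separation of genetic and environmental signal

A position significant in the Emodel *and* in the Gmodel or GxE cannot
be attributed to the environment alone — genetic variation can create or
destroy cytosines and masquerade as methylation signal. `exclude_genetic`
removes from the Emodel table every id significant in either genetic
model at the q cutoff, plus (optional rule, on by default) any row whose
cytosine coordinate coincides with a SNP position, the C/T-at-the-base
confound. Removal counts are reported by reason. `membership_counts`
gives upset-plot-style exact-membership counts across any family of
significant-id sets; counts sum to the size of the union.

## Numerical and degenerate-input conventions

- Methylation is a fraction in [0, 1] internally; I/O converts from and
  to the percentage scale.
- Coordinates are 0-based half-open in memory (BED convention); VCF
  positions convert on ingest (pos − 1).
- Sample order everywhere is the sample-sheet order; scans refuse
  matrices whose sample order disagrees.
- Empty results are legal and warn rather than raise (empty
  intersection, no pairs in the cis window, no variants after filters);
  malformed input raises.
- Output floats are written at 6 significant digits; association tables
  round-trip to 1e-6 relative, and the worked-example output tree is
  byte-reproducible for a fixed seed.

## Known limitations

- No kinship or population-structure correction (no mixed models); the
  covariates are the only confounder control.
- Additive genotype coding only; dominance is not modelled.
- The genotype imputer is frequency-based, not haplotype-aware.
- Plots are rendered deterministically but only their data layers are
  tested numerically.
- Per-position OLS on fractions ignores the binomial precision
  differences between samples (no coverage weighting), matching the
  regression-on-values convention of the tools this package follows.
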