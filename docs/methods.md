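# Methods

## Data model

The pipeline operates on four objects: a `GenotypeMatrix` (sample × variant
A1-dosages in {0,1,2,missing}, A1 = VCF ALT, positions 1-based), an
`ExpressionDataset` (sample × probe raw intensities plus detection
p-values plus probe annotation with probe start and TSS), a sample table
(stage ∈ {M, EP, MP, LP, ES, MS, LS}, disease, quality), and GWAS summary
statistics in the COJO `.ma` layout (SNP A1 A2 freq b se p N).

## Detection, tracks and normalisation

A probe is expressed in a sample iff detection p ≤ 0.05 (equality counts as
expressed; the contrapositive "> 0.05 ⇒ not expressed" is the same rule).
Probes split three ways by the fraction of samples expressing them:
quantitative (≥ 0.90), variable ((0, 0.90)), excluded (0). The per-sample
quality covariate is the proportion of *all* probes expressed, computed
before any partition.

Normalisation applies a quantile adjustment across individuals — each
sample's sorted intensities are replaced by the across-sample rank means,
ties receiving the average of their rank means — followed by log2. All
probes participate by default (a flag restricts to detected probes); the
raw generator emits positive raw intensities so the log2 step is always
defined. Quantile normalisation compresses per-probe genetic effects when
the probe panel is small; at the pipeline's 2,000-probe scale the
attenuation is mild, but single-probe analyses of generator output should
use the log2 raw scale (the truth model's scale).

## Cycle-stage tests

Differential expression uses a two-group linear model per probe with an
empirical-Bayes moderated t. The prior (d₀, s₀²) is estimated by
moment-matching the log sample variances against their scaled-F
distribution: with e_g = log s²_g − ψ(d/2) + log(d/2), set
ψ′(d₀/2) = var(e) − ψ′(d/2) (Newton inversion of the trigamma) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)); when var(e) ≤ ψ′(d/2) the prior
df is infinite and all variances shrink to s₀². Moderated t uses
s̃² = (d₀s₀² + d s²)/(d₀+d) on d₀+d df. One test compares this estimator
against R limma's `eBayes` on the same matrix as an independent oracle.
A probe is significant when |log2FC| ≥ log2(1.5) (the conventional reading
of a 1.5-fold change; an alternative criterion of 1.5 residual SDs is
available by flag, since the two readings cannot be reconciled on the
normalised scale) and BH q < 0.05.

The activation/repression test fits, per variable-track probe, a logistic
regression of expressed status on a binary stage indicator plus disease and
quality, with a Wald test on the stage coefficient (matching the per-SNP
output convention used by the scans) and BH across probes. Stage enters as
a binary indicator because only successive pairs of stages are ever
contrasted. Probes expressed in all or no samples within a contrast are
excluded and logged (the intercept separates completely). The disease
covariate is included by default even in pooled case/control contrasts.

## Genotype QC and LD

Filters replicate PLINK flag semantics with strict boundaries: remove when
missingness > 0.05, MAF < threshold (1e-4 pre-imputation, 0.05
post-imputation; both are configuration, neither hard-coded), or HWE
p < 1e-6 from the 1-df chi-square goodness-of-fit (chosen over the exact
test for closed-form testability; monomorphic variants fit exactly and are
retained). A variant is attributed to the first filter it fails, so QC
accounting reconciles exactly. LD is the signed Pearson correlation of
dosages over pairwise-complete samples; zero-variance requests raise a
distinct error rather than returning 0. LD matrices destined for inversion
(HEIDI) receive a 1e-6 diagonal ridge.

## Scans

The linear eQTL scan residualises both expression and mean-imputed dosages
on the covariates (intercept, disease, stage dummies over the merged
5-level vocabulary by default; 7-level by flag) and forms per-pair Wald t
statistics on n − k − 1 df — algebraically identical to the full-model OLS
t-test (verified against statsmodels). Pairs whose dosage is collinear
with the covariates are skipped and reported as missing. Mean imputation
of missing dosages (rather than pairwise-complete fits) keeps the scan
vectorised; inputs are expected post-QC (≤ 5% missing).

The eBTL scan fits per-pair logistic regressions by IRLS vectorised over
variants; non-converged or separated fits (|β| > 8 or SE > 50) are refit
with Firth's Jeffreys-prior penalisation, which keeps estimates finite
under complete separation. For genome-wide runs the scan optionally
screens pairs with a vectorised Rao score test against the covariate-only
null — a valid per-pair p-value — and performs the exact Wald/Firth refit
only for pairs passing the screen (`screen_p`, 1e-3 in the pipeline
config); effect and SE remain unreported for pairs below the screen. The
default path (no screen) is exact everywhere.

Classification: cis iff same chromosome and |SNP pos − probe start| ≤
250,000 (boundary inclusive); trans iff different chromosome;
same-chromosome pairs beyond the window are "other" and excluded from both
result sets. Sentinels are per-probe, per-class minimum-p records with
ties broken by larger |effect| then variant id. Bonferroni thresholds are
always α/m for the actual test count m, and the FDR cutoff is the largest
p-value accepted by the BH step-up — reported per class in the stage
summaries, never copied from elsewhere.

Conditional analysis is forward stepwise: starting from the covariate
model, repeatedly admit the minimum-p region variant while its conditional
p is below the threshold, skipping candidates with r² > 0.99 to an already
selected signal; reported effects come from the final joint model. The
genotype × stage interaction test is a Gaussian likelihood-ratio test of
stage × dosage terms (df = stages − 1); designs with a stage level holding
fewer than two samples or no genotype variation return a distinct
"untestable" outcome rather than a p-value.

## GWAS integration

GWAS records are harmonised to the eQTL A1 before use: swapped-allele
records flip sign and frequency, strand-ambiguous (A/T, C/G) SNPs are
dropped by default. SMR uses the top cis-eSNP as instrument, requiring
|z_zx| ≥ 5.45 (≈ genome-wide instrument significance); T_SMR =
z²_zx z²_zy/(z²_zx + z²_zy) referred to χ²(1), with the study-wise
threshold 0.05/(probes tested). HEIDI takes the SNPs with eQTL
p ≤ 1.57e-3, r² to the top SNP within [0.05, 0.9] (near-perfect proxies
carry no independent information; unlinked SNPs none at all), capped at 20,
minimum 3 — the cited software's conventions, all configurable. For each
eligible SNP, d_i = b_xy(i) − b_xy(top); the covariance of d comes from the
delta method with cross-SNP correlations equal to LD r, and the statistic
d'Σ⁻¹d (Cholesky whitening after the ridge) is referred to χ² with
n_snps − 1 df. Singular covariances and too-small regions return
"untestable".

**Limitation.** The HEIDI null distribution relies on precise per-SNP
instrument effects. At eQTL cohorts of a few hundred samples the
ratio-estimate errors and the LD sampling mismatch between the eQTL and
GWAS cohorts are not captured by the delta-method covariance, and the test
becomes anti-conservative. The SMR/HEIDI simulation studies therefore use
an eQTL cohort of 2,000 (the scale of the consortium panels the test was
designed for) with a 50,000-sample GWAS; at those sizes the null rejection
rate is mildly conservative (~2% at nominal 5%). Applying HEIDI to
small-cohort eQTL data should be interpreted with this in mind.

## Synthetic-data generator

Genotypes: per-variant allele frequencies drawn from the configured MAF
range; two independent haplotype layers, each a blockwise equicorrelated
Gaussian copula (latent correlation `ld_rho`, default 0.8) thresholded at
the allele-frequency quantile — Hardy-Weinberg holds exactly per variant
and LD is tunable per block. Note dosage correlation is below the latent
correlation and decreases as the two variants' MAFs diverge. Variants in
different blocks are independent. No attempt is made to model realistic
genome-wide LD maps, imputation uncertainty, or array chemistry.

Samples follow the emulated study's composition: stage counts
M 11 / EP 5 / MP 69 / LP 20 / ES 50 / MS 51 / LS 23 per 229 (largest-
remainder rounding at other sizes) and a 133/229 case fraction. The
disease effect on expression defaults to 0 (configurable), reflecting the
absence of case/control expression differences in the emulated study.

Probes come in three classes: always-expressed (32.3%, baseline log-odds
+6, expression probability ≥ 0.9975 in every stage), variably expressed
(20.4%, baseline log-odds truncated-normal over roughly (−2.5, 1.6)), and
silent array probes (the remainder, −6). This yields ~43% of probes
detected per sample — the study-level detection rate — while the
between-sample variance of that rate is larger than the real array's
(matching it would require correlated probe states across samples, which
the generator does not model). Detection p-values are uniform on (0, 0.05]
when expressed and (0.05, 1] when not, making the 0.05 call threshold
exactly invertible; non-expressed intensities come from a background
normal (log2 mean 5) with the same SD as the foreground. Stage effects add
±1 (log2 mean) or ±2 (log-odds) to the secretory stages for a fraction of
each class; genetic effects plant β = 0.8 per allele (cis or trans) on
log2 level for quantitative probes and α = 2.0 per allele on the silencing
log-odds for variable probes, with cis probes placed within 100 kb of
their causal variant.

GWAS summary statistics come from an independently drawn cohort under the
same population model: pleiotropy (trait depends on the eQTL causal SNP
through expression, so b_zy ≈ b_zx·b_xy), linkage (trait depends on a
distinct SNP in LD), or null; effects are per-SNP OLS.

## Problem sizes and numerical choices

The bundled pipeline fixture is 200 samples × 2,000 probes × 20,000 SNPs
(~3 minutes end to end); calibration studies use 500 replicates at n = 200,
recovery studies 200 replicates at n = 229 (the emulated cohort size), and
SMR/HEIDI studies 200 replicates at the sizes above. All randomness flows
from one seed through fixed per-stage offsets; reruns are byte-identical
(no timestamps in outputs, deterministic BLAS paths at these sizes).
Numerical guards: a 1e-8 ridge inside batched IRLS solves, damped Firth
steps, p-values from survival functions (never 1 − cdf), and BH via the
standard step-up with q capped at 1.
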