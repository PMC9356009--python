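# Methods

This note documents the statistical models implemented in `cytoarch`, the
design choices made where the analysis description left the design open,
the calibration of the synthetic cohort generator, and the numerical
conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

The primary object is a child × cytokine × stimulus tensor of supernatant
concentrations in pg/mL with an explicit missing mask (`ResponseTensor`).
All analysis happens on the log₂ scale; the media well of each child and
cytokine is the reference, and the *fold matrix* of log₂ fold inductions
(child × (cytokine, stimulus) pairs, media column absent) is the working
representation for testing, imputation, unfolding and genetics.

**Left-censoring.** Wells below the per-cytokine per-batch lower detection
limit are stored as exactly ½·LOD. A consequence used by the tests: a
stimulus/media pair that is censored on both sides carries a fold induction
of exactly 0.

**Sample QC.** Children with viability < 5% on thawing are excluded; a
child is an *inadequate responder* only when viability < 20% **and** all
four sentinel responses (IL-2×PHA < 5, IFN-α2×RSV < 5, IFN-γ×RV16 < 7,
IL-6×Hin < 5 pg/mL) jointly fail; missing sentinel wells count as failing
since they carry no evidence of response. Free-text exclusions (e.g. a
non-responder with adequate viability) are passed explicitly so the QC
report partitions the cohort. All thresholds are keyword arguments
defaulting to the study values.

**Batch adjustment.** The two shipment batches are reconciled per
(cytokine, stimulus) pair by the regression of log₂ concentration on a
batch indicator with batch 2 (the larger batch) as baseline; with no
covariates this is the difference of batch means, and its pooled two-sample
standard error is reported. The coefficient is subtracted from batch-1
log₂ values only; adjusted concentrations below the batch-2 LOD re-floor to
½·(batch-2 LOD). Adjustment operates on log₂ values because a
multiplicative assay shift is additive in log; a plain indicator model is
used (no further covariates were described). Pairs with fewer than two
observations in either batch are flagged undefined and pass through
unadjusted with a warning.

**Induction testing.** Each pair's mean log₂ fold is tested against zero
with a right one-sided one-sample *t*-test at α = 0.05/(28·15). "Mean fold
induction" is reported as 2^(mean log₂ fold) — the geometric mean on the
ratio scale, matching a test defined on log-scale folds. Zero-variance or
n < 2 pairs are flagged untestable, not significant.

## PPCA imputation

Missing folds are completed under probabilistic PCA, x = Wz + μ + ε with
z ~ N(0, I_k) and isotropic ε ~ N(0, σ²I). The EM algorithm handles
arbitrary missingness: the E-step computes per-row posterior latent moments
from the observed coordinates (batched k×k solves assembled by masked
tensor contractions, O(n·d·k²) per iteration independent of the number of
missingness patterns); the M-step jointly re-estimates (W, μ) by a
per-feature regression on the augmented latent [z, 1] and then σ² — an ECM
scheme whose observed-data log-likelihood is non-decreasing, asserted each
iteration within 1e-8 (relative). Initialization: μ from observed means, W
from the SVD of the mean-filled data, σ² from the residual spectrum; 3
restarts (later ones perturbed, seeded), best final likelihood kept.
Convergence: relative log-likelihood change < 1e-6, max 1000 iterations.
Imputed cells are conditional expectations μ_M + W_M⟨z|x_O⟩; observed cells
are never touched.

The latent dimension is chosen by maximizing Minka's Laplace approximation
of the PCA model evidence, evaluated on the eigenspectrum of the
mean-filled, column-centered sample covariance (MLE normalization) — so
selection requires no EM runs and the full evidence curve is returned for
audit. Imputation runs on the media-normalized fold matrix (media wells
are the reference and are never imputed); children with no observed folds
(no media reference) cannot enter the imputation/clustering path and are
dropped there with a log line. Whether the original analysis imputed
normalized or raw log₂ values is not stated; normalized is used here and
the raw path remains computable for sensitivity analysis.

The simulated-missingness validation masks a fresh random subset of
observed cells at the study missing rate per replicate (restoring a cell if
masking would empty a row or column), imputes by PPCA and by per-feature
observed means, and scores RMSE on the same masked cells for both methods.

## Unfoldings, PCA and multiscale-bootstrap clustering

Three unfoldings of the fold tensor are provided: Child-Stimulus × Cytokine
(cluster cytokines), Child-Cytokine × Stimulus (cluster stimuli), and
Child × Cytokine-Stimulus (within-group correlation analysis). Unfolding
is a bijection (refold inverts it) and preserves the value multiset.
PCA is a column-centered SVD; columns are *not* standardized by default
because all entries share the log₂-fold scale (a flag enables scaling).
Pairwise Pearson correlations use pairwise-complete observations with p
from the t transform of r.

Columns are clustered with correlation distance d = 1 − r and average
linkage (UPGMA via scipy; deterministic tie handling). Cluster support
follows the multiscale bootstrap: at each scale r ∈ {0.5, 0.6, …, 1.4}
(ten scales — the standard multiscale design; the stated 1000 replicates
are applied per scale), ⌈r·n⌉ rows are resampled with replacement 1000
times and the columns re-clustered; a node's BP at that scale is the
fraction of replicate trees containing its exact leaf set (no
topology-aware matching). Per-replicate covariances are accumulated via
row-multiplicity counts and BLAS matmuls, algebraically identical to direct
resampling. With τ = √(n/n′), the signed-distance/curvature model
z(τ) = Φ⁻¹(1 − BP(τ)) = v·τ + c/τ is fit by weighted least squares with
weights n_boot·φ(z)²/(BP(1−BP)) — equivalent to first order to the maximum
likelihood fit and simpler to verify against an oracle; the weighted
residual sum of squares is exposed to flag poor fits. AU = 1 − Φ(v − c);
AU > 0.95 marks a node highly supported. Frequencies are clipped to
[1/(B+1), 1 − 1/(B+1)] so boundary scales remain usable; all-0/all-1
curves short-circuit to AU 0/1 with a degeneracy flag; fewer than three
scales leaves AU undefined. Trees export as Newick with "AU|BP" percent
labels and as flat TSV.

The contaminated-stimulus exclusion (polyIC by default) is a configuration
list, not hard-coded.

## cQTL association

Genotypes are minor-allele dosages in [0, 2] (VCF DS field preferred, GT
converted otherwise), so betas share the "allele associated with lower
release" orientation. SNP QC: typed SNPs need call rate ≥ 0.95, exact HWE
p > 5.9×10⁻⁷ and MAF > 0.005; imputation-derived SNPs need info ≥ 0.75 and
MAF ≥ 0.05. The HWE test is the exact conditional test (probability
ordering), correct at the low counts desk-scale simulations produce; an
exhaustive rational enumeration serves as its oracle in tests. Trait
normality is screened with a Kolmogorov–Smirnov test of the standardized
trait against N(0, 1).

The association test is the classical additive score test:
U = Σ(g−ḡ)(y−ȳ), V = σ̂₀²·Σ(g−ḡ)² with σ̂₀² the null MLE variance,
p from χ²₁ of U²/V, β = U/Σ(g−ḡ)², SE = √(σ̂₀²/Σ(g−ḡ)²). Binary
phenotypes use the logistic-null score test with a one-step log-odds
approximation for β. Analyses are complete-case on non-imputed folds; no
covariates enter (none were described; the function signatures leave room
for them). The variance used by GWAS software under dosage uncertainty is
not reproduced — the classical score form is implemented, a documented
divergence. Genome scans vectorize the statistic across SNPs and flag
p < 5×10⁻⁸. Specificity profiling tests one SNP against every pair in six
configured groups (IL-6×other-bacterial n=7, IL-6×viral n=4,
pro-inflammatory×bacterial n=56, virus-induced×viral n=16,
pro-inflammatory×PHA n=7, virus-induced×PHA n=4) at nominal 0.05 with no
multiplicity correction. Which four viral stimuli form the IL-6×viral
group is config-driven (the four strongly-correlated ones — R848, RV16,
RSV, CpGA — by default, since five viral stimuli remain after the polyIC
exclusion).

GINA treatment steps derive from per-year drug classes: step 5 for oral
corticosteroids or anti-IgE; 4 for medium/high-dose ICS plus LABA or a
leukotriene modifier; 3 for low-dose ICS plus LABA, medium/high ICS alone,
low ICS plus LTRA or sustained-release theophylline, or a combination
inhaler; 2 for low-dose ICS or LTRA alone; else 1. The rule set is
monotone: adding a medication never lowers the step (property-tested).
Cases are step ≥ 2, controls step 1.

## Synthetic cohort generator: what it emulates, and how it is calibrated

The generator draws, for child c, cytokine k, stimulus s:

log₂x = baseline(k) + δ(k,s) + a_{c,g(k)}·1[s≠media] + shift(k,s)·1[batch=1]
        + Σ β·(dosage − 2·MAF) + ε,  ε ~ N(0, σ_e²)

with one child-reactivity scalar a per cytokine functional group — the
simplest structure that produces both enormous between-child ranges and
near-unity correlations between one cytokine's responses to same-group
stimuli. Censoring to ½·LOD is applied after the batch shift (measurement
happens per batch). Defaults are the study conditions:

- **Cohort**: 340 children in batches of 54 and 286; 13 planted
  low-viability children, 19 inadequate responders and 1 adequate-viability
  non-responder, so QC reproduces the 340 → 307 flow.
- **Panels**: the 16-row stimulus table (media + 5 viral, 8 bacterial,
  PHA, polyIC) in its published rank order with its published mean missing
  rates, and 28 cytokines in four functional groups. The rates are not
  perfectly monotone in rank, while a rank-truncation mechanism can only
  realize monotone rates; the nearest monotone rates (isotonic regression)
  define the per-child available-count distribution, whose induced
  per-stimulus rates stay within 3 percentage points of the printed
  targets. polyIC has no printed rate and is interpolated as the midpoint
  of its rank neighbours (9.6%). The joint distribution of counts is not
  identified by per-stimulus rates; rank truncation is the assumed
  mechanism.
- **Signature block δ**: anchored at the printed means — IL-6×Hin =
  log₂ 280, IL-17×PHA = log₂ 67, ~1000-fold IFN-α2 under live viruses,
  strong Gram-negative (Hin, LPS) IFN-γ — with the remaining entries set to
  the narrative's strong/moderate/weak levels. polyIC carries a
  bacterial-like signature, emulating its endotoxin contamination.
- **Variance components**: with reactivity sd σ_a = 2.6 (anti-viral and
  pro-inflammatory groups), total genetic variance g ≈ 5.4 on IL-6 and
  noise σ_e = 0.82, the correlation between IL-6 folds to two bacterial
  stimuli — which share a, the genetic burden and the media well — is
  (σ_a² + g + σ_e²)/(σ_a² + g + 2σ_e²) ≈ 0.95, and the 2.5th–97.5th
  percentile fold ratio 2^(3.92·sd) far exceeds 1000.
- **Genetics**: 20 causal SNPs acting on IL-6 across all eight bacterial
  stimuli (the discovered loci associated across stimuli, not singly),
  18 weak (β from −0.1 to −0.58) plus two strong loci (β = −2.2, −2.5)
  whose variance share makes them discoverable at 5×10⁻⁸ at cohort scale;
  2000 null SNPs with MAF ~ U(0.05, 0.5) in Hardy–Weinberg proportions, a
  2% fraction given info scores below 0.75 to exercise SNP QC. Effects are
  mean-centered (β·(dosage − 2·MAF)) so δ remains the marginal mean fold
  induction; score tests are invariant to this centering.
- **Batch shift**: −0.7 log₂ applied to batch 1 everywhere (batch 2
  tended higher).
- **Clinical records**: four binary phenotypes drawn from
  logit = b₀ + Σ log-OR·dosage with b₀ solved so prevalence is 18% (near
  the observed control rates); two causal SNPs carry links (log-OR 0.32 for
  unscheduled visits; 0.56 and 0.73 for steroid receipt and GINA step ≥ 2).
  Medication histories in year 8 are sampled consistently with the latent
  GINA case flag, so `derive_gina_step` recovers it.

Not emulated: plate layout, PBMC cell-type composition, cryopreservation
effects, linkage disequilibrium between SNPs, covariate structure
(age/sex/ancestry), and any relationship between viability and responses
beyond independence. Passing tests therefore demonstrate correctness of
the statistical machinery under the assumed generative structure, not
robustness to those real-data features.

## Problem sizes and determinism

Test and acceptance runs use the cohort at its design size (340 children,
28×16 panel, 1000 bootstrap replicates per scale, 10⁴ null simulations for
calibration, 100 imputation-validation replicates at 307×100, 2000-SNP
scans at n = 2000); Monte-Carlo claims use 20–50 seeds with success
thresholds stated per test. One master seed drives everything;
per-stage generators derive from it via fixed counters
(`default_rng([seed, counter])`), so stages re-run identically in
isolation. Bootstrap index draws are consumed scale by scale from a single
seeded stream, letting an independently coded loop reproduce BP counts
exactly.

## Known limitations

- AU support relies on the asymptotic signed-distance/curvature model;
  nodes whose BP curves sit at the Monte-Carlo boundary on every scale are
  reported as degenerate (AU exactly 0/1) rather than fitted.
- Minka evidence is evaluated on the mean-filled spectrum; with very high
  missing fractions the selected dimension can drift from the EM-optimal
  one.
- The score test's null-variance estimate ignores dosage uncertainty, so p
  values can differ slightly from GWAS software that models it.
- A single completed matrix feeds clustering (no multiple imputation /
  uncertainty propagation), matching the described analysis.
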