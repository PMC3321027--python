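# Methods

This note records the statistical model, the estimators, the generator, the
numerical choices, and the judgment calls a reader should know about.

## 1. Mixed-model decomposition of bilateral variation

For one trait, the measurement of individual *i* on side *j* (x = −½ left,
+½ right) in session *k* is

    y_ijk = μ + δ·x_j + b_i + s_i·x_j + ε_ijk,
    b_i ~ N(0, σ²_ind),   s_i ~ N(0, σ²_FA),   ε_ijk ~ N(0, σ²_ME),

all mutually independent. Interpretation:

- δ — directional asymmetry (DA), the population mean right−left difference;
- σ²_ind — between-individual size variation;
- σ²_FA — variance of individual signed asymmetry, the "real FA" signal and
  the quantity of interest;
- σ²_ME — digitization error, identified only when sessions are replicated
  (K ≥ 2). With K = 1 the within-cell variance is zero by construction and
  σ²_ME is reported as 0; the fitted σ²_FA then absorbs measurement error.
  This convention is deliberate and documented rather than hidden: a K = 1
  design cannot separate the two, and the real-FA test refuses to run on it.

### Estimation

Variance components are estimated by REML (fixed effects μ, δ profiled out;
restricted log-likelihood exposed as `restricted_loglik(theta, measurements)`)
under the constraints σ² ≥ 0. Two paths:

- **Balanced designs** (every individual measured on both sides in all K
  sessions — the common case, including after the generator): the marginal
  covariance of an individual's 2K measurements,
  V = σ²_ind·J + σ²_FA·xxᵀ + σ²_ME·I, is simultaneously diagonalized by the
  ones vector (eigenvalue 2K·σ²_ind + σ²_ME), the side contrast
  (eigenvalue (K/2)·σ²_FA + σ²_ME), and 2K−2 residual directions (σ²_ME).
  The likelihood therefore factorizes into three independent Gaussian
  variance problems with sufficient statistics: between-individual sums of
  squares of the scaled means and of the scaled side differences, and the
  pooled within-cell sum of squares. The constrained maximum is found
  exactly by enumerating the interior solution and all boundary-pinned
  subsets (a pinned component pools its sum of squares and degrees of
  freedom into σ²_ME). This is exact and ~1000× faster than iterative
  fitting, which is what makes the simulation-calibration tests affordable.
- **Unbalanced designs**: per-individual-pattern Cholesky evaluation of the
  profiled (restricted) likelihood, maximized by multi-start L-BFGS-B with a
  Nelder–Mead polish and explicit refits on each boundary face.

Degenerate-data conventions (all exercised in tests): data with zero total
variance yield all-zero components with a warning; identical replicate
sessions (zero within-cell variance with K ≥ 2) are collapsed to K = 1 so
that the likelihood stays finite and comparable across nested fits; when a
variance candidate pins a component whose sum of squares is exactly zero the
likelihood supremum (+∞) is attained at the boundary and that candidate wins,
which makes e.g. pure-DA data return δ̂ = d, σ_FA = σ_ME = 0 exactly.

### Tests

- **DA**: likelihood-ratio test of δ = 0 using full ML (not REML, since the
  fixed-effects structure changes), referred to χ²₁.
- **Real FA**: REML likelihood-ratio test of σ²_FA = 0. Because the null is
  on the boundary, the statistic's null distribution is the 50:50 mixture
  ½χ²₀ + ½χ²₁, so p = ½·P(χ²₁ > c) and p = 1 at c = 0.

Both tests return χ² = 0, p = 1 when the two likelihood suprema are both
infinite (fully degenerate data).

### Signed FA

Per individual: raw_i = (mean right) − (mean left) − δ̂, and the shrunken
BLUP = w·raw_i with w = σ²_FA / (σ²_FA + σ²_ME·(1/K_L + 1/K_R)). Individuals
missing a side get no estimate. BLUPs are the default for downstream indices;
the *raw* values must be used for the repeatability moment estimator, since
shrinkage already encodes the variance components.

## 2. Hypothetical repeatability

Modelling signed FA of individual *i* as N(0, σ_i²) with σ_i varying among
individuals, the fraction of between-individual variance in |FA| that
reflects real DI variation is

    R = (2/π)·cv² / (1 + cv² − 2/π),   cv = CV(σ_i),

bounded by 2/π ≈ 0.637 (folded-normal moments; verified in tests against
numerical integration over a gamma mixing density). The moment estimator
removes measurement noise τ² = 2σ²_ME/K from the observed side differences:

    M2 = mean(d²) − τ²,
    Êσ = sqrt(max((mean|d|·sqrt(π/2))² − τ², 0)),
    V̂σ = M2 − Êσ²,
    R̂  = (2/π)·V̂σ / (M2 − (2/π)·Êσ²).

Negative estimates are reported, not truncated — they are informative about
sampling noise dominating the DI signal. The estimate is flagged undefined
when the denominator is not positive. This estimator is *one defensible
reading* of the moment-based approach in the DI literature; alternatives
(e.g. distribution-specific ML under a named mixing law) would differ at
higher moments. At least 10 individuals are required.

## 3. Integration and composite indices

Integration: pairwise-complete Pearson correlations of per-individual signed
FA between traits, t-distribution p-values with df = n_pair − 2, minimum 3
complete pairs, zero-variance traits flagged undefined.

Composite FA: per trait u = |signed FA|, z = (u − mean u)/SD(u); the score is
the mean of available z-values, reported only when at least `min_traits`
(default: half the subset, rounded up) are present. Zero-SD traits are
excluded with a warning. The "non-DA" index restricts to traits whose DA test
has p ≥ α (default 0.05), the conventional guard against handedness
contaminating the FA signal.

## 4. Multivariate association

Seven responses (BMI, age at first/last reproduction, number of offspring,
age at menarche, proportion of sons, offspring survival; optionally BMI²) are
z-standardized and regressed jointly on standardized composite FA plus
dummy-coded education, birth cohort and birth area (first level reference;
results are invariant to the reference choice — tested). Complete-case
analysis; n_complete always reported. Each predictor block is tested with
Pillai's trace V = tr[H(H+E)⁻¹] and the standard F approximation with
s = min(q, b), m = (|q−b|−1)/2, n★ = (df_e−q−1)/2,
df1 = s(2m+s+1), df2 = s(2n★+s+1). For a 1-df block this reduces to the
Hotelling T² form, and the per-response t statistics satisfy t² = F of the
univariate test (verified). FA × cohort and FA × education interactions add
product columns and test that block, after checking every factor cell
contains FA variation. Rank deficiency is reported with the offending
columns (QR with pivoting). Treating proportions and counts as Gaussian
responses is a deliberate simplification, matching standard practice for
this design.

`statsmodels` (MixedLM, MANOVA) is used in the test suite as an independent
oracle only; all estimators above are implemented in this package.

## 5. Synthetic cohort generator

Defaults describe a cohort of 209 post-menopausal women measured on 21 hand
distances per side in 2 sessions, in cm. Structure:

- **Latent DI**: one gamma multiplier g_i with mean 1 and CV `di_cv_sigma`
  (default 0.25) scales every trait's asymmetry SD σ_it = g_i·σ̄_t, so DI is
  a single shared factor; the latent DI z-score is the standardized log g_i.
  The default CV puts the analytic repeatability near the low values typical
  of empirical FA studies (R < 0.1).
- **Integration**: given g_i, the per-trait signed asymmetries are
  multivariate normal with correlation `integration_corr`; the default blends
  an AR-1 kernel over digit position with the identity (α = 0.5, ρ = 0.55),
  positive semi-definite by construction. Because g_i scales all traits
  jointly and cancels in correlations, signed-FA correlations consistently
  estimate `integration_corr` (acceptance criterion 6).
- **Sides**: side values are size_it ∓ (δ_t + s_it)/2 plus independent
  session-level N(0, σ²_ME,t) noise.
- **Life history**: categorical covariates (education, cohort, area) with
  configurable level probabilities and per-response effects; optional linear
  effects of the latent DI z-score on any response (default 0 — the null
  world); offspring counts rounded and floored at 0, proportions clipped to
  [0, 1]; childless women get missing reproduction-dependent fields,
  which is what drives complete-case n below the cohort size.

### Units and scale

The generator's trait scale (sizes ~1–8, DA ~0.01–0.08) reads the published
per-trait asymmetry columns as *standard deviations* in cm. Reading them as
variances would shrink DA χ² statistics but implies FA several percent of
trait size, contradicting the ~1%-of-size magnitude the same reports state;
the SD reading is used and documented here as an open interpretive decision.
No acceptance quantity depends on it.

## 6. Landmark fixtures

The default scheme shares landmarks within a digit (tip, base, two creases
serve the four length traits of that digit), so a synthetic landmark
configuration cannot give every trait its own independent segment. The
fixture generator instead solves each digit's 4-point chain by circle–circle
intersection, exact to machine precision whenever the targets are
geometrically consistent (|total − sum of phalanges| realizable), and rejects
inconsistent targets with a diagnostic. Palm width and joint widths get
dedicated segments. Distances are rigid-motion invariant and homogeneous
under scaling (property-tested).

## 7. Reproducibility and limitations

All stochastic code takes explicit seeds; the pipeline is byte-reproducible
for a fixed seed and writes a manifest with config, seed and version. Outputs
are written to a temporary directory and only published on success.

Limitations: Gaussian FA (no antisymmetry or kurtosis options); single shared
DI factor (rank-1 log-σ structure); proportions/counts as Gaussian responses;
the ME correction in the repeatability estimator is first-order; complete-case
association analysis (no imputation); 2-D landmarks only.
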