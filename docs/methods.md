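# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Dose-response summarization

Ex vivo drug screens expose patient-derived cells to a dose series and
read out viability; the package works throughout in percent inhibition
(viability inputs are converted as `100 − viability`), so an active drug
produces a response that increases with dose. Each series is fitted with
the 4-parameter log-logistic curve

    f(x) = c + (d − c) / (1 + exp(b · (ln x − ln e)))

(slope `b`, lower asymptote `c`, upper asymptote `d`, inflection
concentration `e`; `b < 0` gives an increasing curve) and with the
3-parameter variant that constrains the response to zero at vanishing
concentration (`c = 0`). Fitting is damped least squares from a
deterministic multi-start grid (slopes ±{0.3, 1, 2, 4} crossed with an
inflection guess at every tested dose), so fits are reproducible and
robust to local optima; flat series are reported as degenerate flat fits
rather than errors. Response is summarized as AUC: the fitted curve,
clipped to [0, 100], integrated over log10 concentration across the
drug's tested range and normalized by 100 times the log10 width, giving
a value in [0, 1] where higher means more sensitive. AUC is preferred to
single-parameter summaries (EC50/IC50) because it is stable when the
curve only partially traverses its dynamic range within the tested
window. Integration uses composite Simpson on a dense grid (4097
points), which agrees with a 10^5-point trapezoid reference to < 1e-4;
the clipping makes a closed form unavailable.

Screen-level QC mirrors large-screen practice:

* per drug, series whose (min, max, n_points) concentration design
  differs from the modal design are excluded (ties break to the
  lexicographically smaller tuple);
* one sample per patient is kept — the one assayed across the most
  drugs, ties broken by lexicographic sample id;
* three outlier criteria annotate (not remove) fits: a non-monotone
  dose-response trend; divergence between the zero-anchored (LL3) and
  free (LL4) fits, measured as |AUC_LL3 − AUC_LL4| > 0.2; and replicate
  discordance, |ΔAUC| between replicates > 0.3. A fitted log-logistic
  curve is monotone by construction, so the monotonicity criterion
  checks both the fitted trend direction and gross point-level
  violations in the data (an observed point more than 10 response units
  below the running maximum). All three thresholds are configuration
  parameters; the defaults are package choices on the normalized-AUC
  scale, not community standards.

## General response across drugs (GRD)

Patient samples often respond strongly (or weakly) to nearly every drug
on a panel, independent of target. GRD quantifies this: a sample's mean
raw AUC over a drug panel. MRP (mean response across patients) is the
per-drug analogue, and standardized AUCs are per-drug z-scores across
patients. When GRD enters a model of a particular drug's response, that
drug is excluded from the mean (leave-drug-out), so a drug never
explains itself through its own covariate.

Cross-study concordance statistics: drug-drug correlation matrices over
samples (pairwise-complete; cells with fewer than 5 overlapping samples
are dropped); the "correlation of correlations" (Pearson r between the
upper triangles of two studies' drug-drug correlation matrices on
shared drugs); per-drug concordance of a drug's correlation-vector
representation across studies; and bootstrap stability of GRD under
random drug subsets (percentile 2.5/97.5 interval over 100 draws). GRD
requires at least 10 observed drugs per sample by default.

## Multi-source sparse regression

The core model couples D studies that measured the same response (one
drug's AUC, or GRD) on different samples:

    y⁽ᵈ⁾   ~ N(X⁽ᵈ⁾β⁽ᵈ⁾, σ_d² I)
    β⁽ᵈ⁾  ~ N(β, s² I),            s = 0.5
    β_g    ~ N(0, λ_g² τ²)
    λ_g    ~ C⁺(0, 1)
    τ      ~ C⁺(0, τ₀),            τ₀ = p0/(N_G − p0) · Σ_d σ_d/√N_d
    σ_d    ~ IG(1, 1)

The shared coefficient vector β carries a horseshoe-type prior whose
global scale is anchored at τ₀, encoding an a-priori number of active
genes `p0` (default 10, always exposed); the per-study coefficients are
small perturbations of the shared vector, which is how information is
shared across studies without forcing identical effects. The multi-task
variant couples a set of drugs through a per-drug scalar weight,
y⁽ᵈ·ⁱ⁾ ~ N(X⁽ᵈ⁾β⁽ᵈ⁾ w_i, σ_d² I) with w_i ~ N(0.5, 0.5), so the shared
β becomes the common biomarker profile of the drug set and w_i its
per-drug loading. The β·w product is scale-non-identifiable up to a
reciprocal rescaling; the informative w prior resolves this only
softly, which is why the reported w should be read as relative loadings.

Open choices, and how they were resolved:

* **Scale convention.** All fixed scales (the 0.5s, IG parameters) are
  interpreted as standard deviations, the convention of the statistical
  platforms this model family is usually written in; a variance
  interpretation is available (`interpret_scale_as="variance"`) for
  sensitivity analysis. The grouping of the τ₀ formula is per-source,
  Σ_d [σ_d/√N_d]; the pooled alternative is selectable.
* **Data scale.** Genes are z-scored within study. Responses are
  centered within study and scaled to sd 100 — a percent-like scale
  matching the 0–100 units of inhibition/AUC-style readouts. This
  matters: the perturbation scale s = 0.5 is fixed, and on a
  unit-variance response it would be as large as the coefficients
  themselves (standardized effects are ~0.2 in realistic regimes),
  decoupling the studies and disabling both the cross-study coupling
  and the transmission of the sparsity prior to the per-study
  coefficients. On the percent scale, coefficients dwarf s and the
  hierarchy behaves as intended: a tight near-zero coefficient bulk
  with a small set of well-separated biomarkers.
* **p0.** Never estimated; a modeling prior. Default 10.
* **Slab.** The plain horseshoe is the default, matching the model as
  written. An optional regularized slab (`slab_scale = c`) replaces each
  coefficient's prior variance with c²λ²τ²/(c² + λ²τ²), bounding even
  strongly supported coefficients near c — a sensitivity-analysis knob,
  off by default.

### Inference

No gradient-based probabilistic-programming sampler is used; inference
is a partially collapsed Gibbs sampler with exact conditional updates,
written for this model's structure:

1. **Shrinkage scales.** λ_g and τ are updated with the shared β
   integrated out: given the per-study coefficients, their cross-source
   mean satisfies m_g ~ N(0, λ_g²τ² + s²/D) analytically. A direct
   conditional-on-β update cannot cross the horseshoe funnel (λ cannot
   grow while β is pinned at zero); the collapsed likelihood lets the
   local scales jump between the shrunk and active regimes in one move.
   λ updates use Metropolis steps mixing half-Cauchy prior proposals
   with log-scale random walks; τ uses slice sampling. τ₀ is recomputed
   from the current σ draws at every sweep.
2. **Shared β.** Drawn with the per-study coefficients collapsed out via
   the Woodbury identity (marginally y⁽ᵈ⁾ ~ N(X⁽ᵈ⁾β, σ_d²I + s²XXᵀ)).
   Plain alternation between β and β⁽ᵈ⁾ mixes pathologically slowly in
   the tight-coupling regime (split-R̂ up to 2.6 observed); the
   collapsed draw sees the data directly. Each X⁽ᵈ⁾ᵀX⁽ᵈ⁾ is
   eigendecomposed once per fit, making the per-study updates O(N_G²)
   per sweep.
3. **Per-study β⁽ᵈ⁾** and **w_i** are conjugate Gaussian blocks; **σ_d**
   uses univariate slice sampling on log σ (the IG prior on an sd is
   non-conjugate).

Defaults follow a 2-chain × (500 warm-up + 500 kept) budget, enough for
split-R̂ and effective-sample-size diagnostics (via ArviZ); R̂ > 1.1 on
the shared coefficients raises a warning on the results object, not an
error.

**Reported posterior means of the shared β are Rao-Blackwellized**: at
each sweep the analytic conditional mean of β_g is computed with the
per-study coefficient draw integrated out (its cross-source mean is
Gaussian given β, σ) and the local scale integrated out by 1-D
quadrature over its half-Cauchy posterior; averaging these per-sweep
conditional means estimates the same posterior mean as averaging raw
draws (tower rule) but without the heavy-tailed Monte-Carlo noise of
sampled shrinkage factors, which otherwise dominates gene rankings at
practical draw budgets. Raw draws are kept alongside for diagnostics
and intervals.

### Prediction, cross-validation, prioritization

Prediction is the posterior-mean linear predictor, using a named study's
β⁽ᵈ⁾ or the shared β. Cross-validation is source-stratified k-fold
(default 5): each study's samples are dealt into folds, the model is
refitted per fold, held-out samples are predicted with their own study's
coefficients, and the median-performing fold is reported alongside all
folds. Biomarker prioritization standardizes each study's posterior-mean
coefficients across genes (z_g = (b_g − mean)/sd), combines them by
Stouffer's method (Σ_d z_g⁽ᵈ⁾/√D), and flags genes with two-sided
normal p < 0.01 — the "extremal combined coefficients" rule. Whether to
standardize empirically across genes was an open choice; it makes the
combined score location/scale-free across studies with different
coefficient scales.

## Ridge baselines and the GRD covariate design

The cross-study evaluation trains a ridge model of one drug's response
on one study and tests on another, under four covariate modes: genes
only; genes plus GRD predicted from expression (the GRD model itself is
ridge, trained on the training study, leave-drug-out); genes plus the
test study's own observed leave-drug-out GRD; or the GRD covariate
alone. Ridge is the closed-form normal-equations solution with the
penalty chosen by inner 10-fold CV over a 13-point grid 10^{−3..3}; y is
centered (the intercept is unpenalized), covariate columns are
standardized like genes and penalized identically. Model comparisons
across drugs use the one-sided paired Wilcoxon signed-rank test (exact
for ≤ 25 non-zero pairs, normal approximation with continuity correction
above; zeros dropped). Drug specificity is Δr = r(expr+GRD) −
r(GRD-only), ranked descending; the top drugs are the most
GRD-independent. The leave-drug-out discipline is structural: the
evaluated drug's row is removed before any GRD computation.

## Single-sample enrichment and the monocytic signature

The enrichment score follows the GSVA recipe for continuous log
expression: per gene, a Gaussian-kernel CDF across the cohort
(bandwidth sd/4) converts expression to within-cohort quantile-like
statistics; within each sample, genes are ranked by decreasing statistic
and the rank is symmetrized about the list midpoint; a weighted
Kolmogorov-Smirnov-like walk runs down the list (in-set steps weighted
by the symmetrized rank to the power τ = 1, out-of-set steps by
1/(N_G − |set|)); the score is the maximum positive plus maximum
negative excursion (signed-sum convention). Kernel, τ and the score
convention are configuration knobs. Scores are invariant to per-gene
affine increasing transforms applied uniformly across samples. Genes
absent from a dataset are dropped with a warning rather than imputed,
since the signature is applied across heterogeneous platforms.

The built-in monocytic signature compresses BCL3, CD14, LILRB1, LRP1,
MAFB, PSAP, SLC15A3 and SLC7A7 into one score per sample; a higher
score marks a more monocytic sample and predicts resistance to BCL-2
inhibition (negative correlation with AUC is the resistance
convention).

## Synthetic data: what it emulates, and what it does not

* `simulate_multisource` mirrors the regression model's generative
  process: block-equicorrelated standard-normal expression (a shared
  latent factor per block of 10 genes, within-block correlation 0.3 by
  default — mimicking co-expressed pathway modules), a sparse shared
  coefficient vector whose nonzero entries have magnitude `effect_sd`
  with random signs (magnitudes bounded away from zero keep
  sign-recovery oracles well defined), small Gaussian study-specific
  perturbations (sd 0.1), and Gaussian noise. `target_r2` computes the
  noise sd from the realized coefficients and the block covariance so
  the in-sample signal fraction hits the target (default 0.5).
* `simulate_grd_structure` generates AUC(s, d) = clamp01(μ + g_s + m_d +
  ε) with Gaussian sample effects g_s, drug effects m_d and noise, plus
  missing-completely-at-random cells; clamping reflects the normalized
  AUC scale.
* `simulate_dose_response` evaluates an LL4 curve with iid replicate
  noise; optional artifact injection swaps the two responses bracketing
  the inflection, the canonical non-monotone technical artifact.
* `simulate_signature_cohort` gives signature genes a shared latent
  "monocyticity" loading; all other genes are noise.
* `simulate_cross_study_pair` combines per-drug sparse gene effects with
  a latent sample-level general-response component shared across drugs
  — the structure behind the GRD-covariate evaluation design.

All generators are pure functions of (configuration, seed). None of
them attempts to match the marginal distributions of real AML screens
(library-size effects, heteroscedastic counts, plate effects,
informative missingness); passing tests on these fixtures demonstrates
correctness of the algorithms under their assumed structure, not
performance on real cohorts.

## Known limitations and observed bounds

* Under the default correlated-block generator at its stated study
  conditions (two sources of 120 + 60 samples, 300 genes, 8 active
  genes at standardized effect ≈ 0.2, signal fraction 0.5), full
  support recovery is information-limited: the sparse multi-source
  posterior typically places most, but not all, of the 8 active genes in
  the top 20 of the shared-coefficient ranking, and median
  cross-validated held-out correlation sits near 0.4-0.5 against a
  noise ceiling of √0.5 ≈ 0.71. Pooled cross-validated lasso and tuned
  ridge perform no better on the same data (lasso leaves actives ranked
  > 200 on hard draws; ridge held-out r ≈ 0.4), so these are bounds of
  the conditions, not of the implementation; the package's comparative
  claims (sparser and better-ranked than ridge) hold.
* The Gibbs sampler's λ updates are Metropolis moves on a collapsed
  target; their acceptance is not tuned adaptively, and split-R̂ on raw
  β draws can sit slightly above 1.1 at the default budget. The
  Rao-Blackwellized summaries are far less sensitive to this than raw
  draws.
* QC thresholds (0.2 LL3/LL4 AUC gap, 0.3 replicate gap) are package
  defaults on the normalized-AUC scale; real screens should calibrate
  them against replicate distributions.
* BMSMTR's β·w scale indeterminacy means w values are comparable within
  a fit, not across fits.
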