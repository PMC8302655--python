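# bmsr — multi-source Bayesian biomarker discovery for ex vivo drug screens

Functional precision-oncology studies expose primary patient samples
(e.g., AML mononuclear cells) to drug panels ex vivo and profile the
same samples by RNA-seq. Two obstacles make biomarker discovery from
such data fragile: each study is small and technically idiosyncratic, so
coefficients learned in one study rarely replicate in another; and
samples exhibit a *general response across drugs* (GRD) — a
target-agnostic tendency to respond strongly or weakly to everything —
that confounds drug-specific signals. This package addresses both, for
computational biologists analyzing multi-study pharmacotranscriptomic
data.

It implements, end to end:

* **Dose-response processing** — 3-/4-parameter log-logistic fits
  (`f(x) = c + (d−c)/(1+exp(b(ln x − ln e)))`), normalized AUC over the
  tested log-concentration range, modal-concentration-range and
  one-sample-per-patient filters, and three outlier flags
  (non-monotone trend, LL3/LL4 divergence, replicate discordance).
* **Response metrics** — GRD (per-sample mean AUC, with leave-drug-out
  support), MRP (per-drug mean), standardized AUCs, drug-drug
  correlations, the "correlation of correlations" interstudy
  consistency measure, per-drug cross-study concordance, and GRD
  bootstrap stability.
* **BMSR / BMSMTR** — Bayesian multi-source sparse regression: each
  study's coefficients β⁽ᵈ⁾ ~ N(β, 0.5) perturb a shared vector β whose
  components carry a horseshoe-type prior β_g ~ N(0, λ_g²τ²),
  λ_g ~ C⁺(0,1), τ ~ C⁺(0, τ₀) with τ₀ = p0/(N_G−p0)·Σ_d σ_d/√N_d
  encoding an a-priori number of active genes p0. The multi-task
  variant couples a drug set through per-drug weights w_i ~ N(0.5, 0.5).
  Inference is a partially collapsed Gibbs sampler (see
  `docs/methods.md`); fits return a results object with draws,
  split-R̂/ESS diagnostics, `summary()`, `predict()`,
  source-stratified cross-validation and Stouffer-combined biomarker
  prioritization (selected at combined p < 0.01).
* **Baselines & evaluation** — closed-form ridge with inner-CV penalty
  selection, cross-study train/test evaluation with GRD covariates
  (observed or expression-predicted, always leave-drug-out), one-sided
  paired Wilcoxon signed-rank model comparison, and drug-specificity
  ranking.
* **Signature scoring** — a GSVA-style single-sample enrichment score
  (Gaussian-kernel CDF → in-sample ranks → weighted KS-like walk) and
  the built-in 8-gene monocytic signature (BCL3, CD14, LILRB1, LRP1,
  MAFB, PSAP, SLC15A3, SLC7A7) whose high values predict BCL-2
  inhibitor resistance.
* **Synthetic data** — generators for every structure above, with truth
  records, so the full pipeline is testable without any restricted
  clinical dataset.

## Worked example

Two simulated expression studies (60 + 40 samples, 80 genes) share four
true biomarkers; the joint fit recovers them:

```python
from bmsr import (SimConfig, simulate_multisource, fit_bmsr, BmsrModelSpec,
                  McmcConfig, ExpressionMatrix, harmonize_sources)

cfg = SimConfig(n_sources=2, n_samples_per_source=(60, 40), n_genes=80,
                n_active=4, effect_sd=1.0, target_r2=0.5, seed=42)
sources, truth = simulate_multisource(cfg)
print("true biomarkers:", truth.active_genes)

harm = harmonize_sources(
    [ExpressionMatrix(s.X.T, dataset_id=s.source_id) for s in sources],
    [s.y for s in sources],
)
result = fit_bmsr(harm, BmsrModelSpec(p0=4),
                  McmcConfig(n_samples=500, n_burnin=500, n_chains=2, seed=0))
print(result.summary(top=6))
print(result.prioritize_biomarkers(alpha=0.01).head(6).round(3))
```

```
true biomarkers: ['G0006', 'G0035', 'G0051', 'G0060']
BMSR results
========================================
sources: source0, source1
genes (N_G): 80   p0: 4
chains x draws: 2 x 500 (burn-in 500)
noise sd posterior means: source0=68.144, source1=72.987
max split-Rhat(beta): 1.036   min ESS(beta): 67
top 6 genes by |posterior-mean shared beta|:
  G0051        -28.0632
  G0006        +26.4262
  G0001        +15.8476
  G0035        -14.2961
  G0060        +10.7440
  G0048        +8.3156
       z_source0  z_source1  combined_z      p  selected
gene
G0051     -5.118     -5.115      -7.236  0.000      True
G0006      4.632      4.637       6.554  0.000      True
G0001      2.741      2.750       3.883  0.000      True
G0035     -2.650     -2.647      -3.746  0.000      True
G0060      1.835      1.832       2.593  0.010      True
G0048      1.402      1.393       1.976  0.048     False
```

All four planted genes rank in the top five by |posterior-mean shared
coefficient| with correct signs, and the Stouffer-combined selection at
p < 0.01 keeps them (responses are standardized to a percent-like scale,
hence the coefficient magnitudes; one correlated-block neighbor, G0001,
is also picked up — the usual behavior on co-expressed modules). The
noise-sd posteriors sit near the generating value (≈ 70.7 on that
scale).

A command-line interface mirrors the library
(`bmsr simulate|fit-curves|grd|fit|cv|prioritize|predict|score-signature|eval|bmsmtr`);
every stochastic command takes an explicit `--seed`.

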