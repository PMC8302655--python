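"""Synthetic data generators emulating the statistical structure of
multi-study ex vivo drug screens.

Four generators cover the structures the downstream analyses assume:

* :func:`simulate_multisource` — several expression studies sharing one
  sparse coefficient vector with small study-specific perturbations and
  block-correlated genes (co-expressed pathway modules).
* :func:`simulate_dose_response` — sigmoidal dose-response series with
  replicate noise and optional non-monotone artifacts.
* :func:`simulate_grd_structure` — an additive sample-effect + drug-effect
  AUC matrix (the structure behind a "general response across drugs").
* :func:`simulate_signature_cohort` — a cohort whose signature genes load
  on a latent monocytic-differentiation gradient.

Every generator is a pure function of its configuration and seed, and
returns a truth record so tests can score recovery against the generating
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DoseResponseSeries,
    ExpressionMatrix,
    LogLogisticFit,
    ResponseMatrix,
    SourceDataset,
    ll4,
)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_multisource",
    "simulate_dose_response",
    "simulate_grd_structure",
    "simulate_signature_cohort",
    "simulate_cross_study_pair",
]


class ConfigurationError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Configuration of the multi-source generative process.

    The fields mirror the generative counterparts of the regression model:
    ``n_samples_per_source`` are the per-study sample sizes N_d, ``n_genes``
    is N_G, ``n_active`` the number of truly nonzero shared coefficients
    (the a-priori p0), ``effect_sd`` the magnitude of nonzero shared
    coefficients, ``source_perturb_sd`` the sd of the study-specific
    coefficient perturbation around the shared vector, and
    ``noise_sd_per_source`` the per-study residual sd sigma^(d).

    If ``target_r2`` is set and ``noise_sd_per_source`` is None, the noise
    sd of each source is computed from the realized coefficients and the
    block-equicorrelated gene covariance so that the in-sample signal
    fraction equals the target.
    """

    n_sources: int = 2
    n_samples_per_source: Sequence[int] = (120, 60)
    n_genes: int = 300
    n_active: int = 8
    effect_sd: float = 1.0
    source_perturb_sd: float = 0.1
    block_size: int = 10
    block_rho: float = 0.3
    noise_sd_per_source: Optional[Sequence[float]] = None
    target_r2: Optional[float] = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ConfigurationError("n_sources must be >= 1")
        if len(self.n_samples_per_source) != self.n_sources:
            raise ConfigurationError(
                "n_samples_per_source length must equal n_sources"
            )
        if any(n < 2 for n in self.n_samples_per_source):
            raise ConfigurationError("each source needs >= 2 samples")
        if not 0 <= self.n_active <= self.n_genes:
            raise ConfigurationError("need 0 <= n_active <= n_genes")
        if self.effect_sd < 0 or self.source_perturb_sd < 0:
            raise ConfigurationError("sds must be >= 0")
        if not 0 <= self.block_rho < 1:
            raise ConfigurationError("block_rho must be in [0, 1)")
        if self.block_size < 1:
            raise ConfigurationError("block_size must be >= 1")
        if self.noise_sd_per_source is not None:
            if len(self.noise_sd_per_source) != self.n_sources:
                raise ConfigurationError("need one noise sd per source")
            if any(s < 0 for s in self.noise_sd_per_source):
                raise ConfigurationError("noise sds must be >= 0")
        elif self.target_r2 is not None and not 0 < self.target_r2 < 1:
            raise ConfigurationError("target_r2 must be in (0, 1)")


@dataclass
class TruthRecord:
    """Generating parameters stored alongside simulated data."""

    beta_shared: Optional[np.ndarray] = None
    beta_source: Optional[dict] = None  # source_id -> vector
    active_genes: Optional[list] = None
    noise_sd: Optional[dict] = None
    sample_effects: Optional[pd.Series] = None  # GRD-like g_s
    drug_effects: Optional[pd.Series] = None  # m_d
    latent: Optional[pd.Series] = None  # per-sample latent monocyticity
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.beta_shared is not None:
            out["beta_shared"] = list(map(float, self.beta_shared))
        if self.beta_source is not None:
            out["beta_source"] = {
                k: list(map(float, v)) for k, v in self.beta_source.items()
            }
        if self.active_genes is not None:
            out["active_genes"] = list(self.active_genes)
        if self.noise_sd is not None:
            out["noise_sd"] = {k: float(v) for k, v in self.noise_sd.items()}
        for name in ("sample_effects", "drug_effects", "latent"):
            v = getattr(self, name)
            if v is not None:
                out[name] = {str(k): float(x) for k, x in v.items()}
        out.update(self.extra)
        return out


def _block_correlated_normals(
    rng: np.random.Generator, n: int, n_genes: int, block_size: int, rho: float
) -> np.ndarray:
    """n x n_genes matrix; genes within a block share a latent factor so the
    within-block correlation is ``rho`` (equicorrelated), marginal N(0, 1)."""
    eps = rng.standard_normal((n, n_genes))
    if rho == 0:
        return eps
    n_blocks = int(np.ceil(n_genes / block_size))
    factors = rng.standard_normal((n, n_blocks))
    block_of = np.minimum(np.arange(n_genes) // block_size, n_blocks - 1)
    return np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * eps


def _signal_variance(beta: np.ndarray, block_size: int, rho: float) -> float:
    """Var(x' beta) under the block-equicorrelated gene covariance."""
    var = float(np.sum(beta**2))
    if rho > 0:
        n_genes = len(beta)
        block_of = np.arange(n_genes) // block_size
        for b in np.unique(block_of):
            sub = beta[block_of == b]
            s = float(np.sum(sub))
            var += rho * (s * s - float(np.sum(sub**2)))
    return var


def simulate_multisource(
    config: SimConfig,
) -> tuple[list[SourceDataset], TruthRecord]:
    """Draw D studies sharing a sparse coefficient vector.

    For each source d: X^(d) has block-correlated standard-normal rows,
    beta^(d) = beta + N(0, source_perturb_sd^2), and
    y^(d) = X^(d) beta^(d) + N(0, sigma_d^2). The shared beta has
    ``n_active`` nonzero entries of magnitude ``effect_sd`` with random
    signs (magnitudes bounded away from zero keep sign-recovery oracles
    well defined).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]

    beta = np.zeros(cfg.n_genes)
    active = np.sort(rng.choice(cfg.n_genes, size=cfg.n_active, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_active)
    beta[active] = signs * cfg.effect_sd

    sources: list[SourceDataset] = []
    beta_source: dict[str, np.ndarray] = {}
    noise_used: dict[str, float] = {}
    for d in range(cfg.n_sources):
        n = cfg.n_samples_per_source[d]
        sid = f"source{d}"
        X = _block_correlated_normals(
            rng, n, cfg.n_genes, cfg.block_size, cfg.block_rho
        )
        beta_d = beta + rng.normal(0.0, cfg.source_perturb_sd, size=cfg.n_genes)
        if cfg.noise_sd_per_source is not None:
            sigma = float(cfg.noise_sd_per_source[d])
        elif cfg.target_r2 is not None:
            sig_var = _signal_variance(beta_d, cfg.block_size, cfg.block_rho)
            sigma = float(
                np.sqrt(sig_var * (1.0 - cfg.target_r2) / cfg.target_r2)
            )
        else:
            sigma = 1.0
        y = X @ beta_d + rng.normal(0.0, sigma, size=n)
        sample_ids = [f"{sid}_s{i:03d}" for i in range(n)]
        sources.append(
            SourceDataset(
                X=pd.DataFrame(X, index=sample_ids, columns=gene_ids),
                y=pd.Series(y, index=sample_ids, name="response"),
                source_id=sid,
            )
        )
        beta_source[sid] = beta_d
        noise_used[sid] = sigma

    truth = TruthRecord(
        beta_shared=beta,
        beta_source=beta_source,
        active_genes=[gene_ids[i] for i in active],
        noise_sd=noise_used,
        extra={"gene_ids": gene_ids},
    )
    return sources, truth


def simulate_dose_response(
    fit_params,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    inject_artifact: bool = False,
    sample_id: str = "S1",
    patient_id: str = "P1",
    drug_id: str = "drugA",
) -> list[DoseResponseSeries]:
    """Evaluate an LL4 curve at the given doses and add iid noise.

    ``fit_params`` is anything with attributes b, c, d, e (e.g. a
    :class:`~bmsr.datatypes.LogLogisticFit`). With ``inject_artifact``
    the two responses bracketing the inflection are swapped in every
    replicate, producing a non-monotone series for QC fixtures.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    curve = ll4(conc, fit_params.b, fit_params.c, fit_params.d, fit_params.e)
    out = []
    for r in range(n_replicates):
        resp = curve + rng.normal(0.0, noise_sd, size=len(conc))
        if inject_artifact and len(conc) >= 2:
            i = int(np.argmin(np.abs(np.log(conc) - np.log(fit_params.e))))
            j = min(i + 1, len(conc) - 1)
            if i == j:
                i -= 1
            resp[i], resp[j] = resp[j], resp[i]
        out.append(
            DoseResponseSeries(
                sample_id=sample_id,
                patient_id=patient_id,
                drug_id=drug_id,
                replicate_id=f"rep{r + 1}",
                concentrations=conc.copy(),
                responses=resp,
            )
        )
    return out


def simulate_grd_structure(
    n_samples: int = 100,
    n_drugs: int = 60,
    grd_sd: float = 0.1,
    drug_sd: float = 0.1,
    noise_sd: float = 0.02,
    missing_frac: float = 0.0,
    mu: float = 0.3,
    seed: int = 0,
    dataset_id: str = "sim",
) -> tuple[ResponseMatrix, TruthRecord]:
    """Additive AUC model: AUC(s, d) = clamp01(mu + g_s + m_d + eps).

    ``g_s`` is the per-sample general-response effect, ``m_d`` the
    per-drug mean-response effect; both Gaussian. Missingness is injected
    completely at random at the requested fraction.
    """
    for name, v in (("grd_sd", grd_sd), ("drug_sd", drug_sd), ("noise_sd", noise_sd)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if not 0 <= missing_frac <= 1:
        raise ValueError("missing_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    drug_ids = [f"drug{i:03d}" for i in range(n_drugs)]
    g = rng.normal(0.0, grd_sd, size=n_samples)
    m = rng.normal(0.0, drug_sd, size=n_drugs)
    eps = rng.normal(0.0, noise_sd, size=(n_drugs, n_samples))
    auc = np.clip(mu + g[None, :] + m[:, None] + eps, 0.0, 1.0)
    if missing_frac > 0:
        # exact-count injection so realized missingness never exceeds the
        # requested fraction by more than one cell
        n_cells = n_drugs * n_samples
        n_miss = int(round(missing_frac * n_cells))
        flat = rng.choice(n_cells, size=n_miss, replace=False)
        auc = auc.copy().reshape(-1)
        auc[flat] = np.nan
        auc = auc.reshape(n_drugs, n_samples)
    mat = ResponseMatrix(
        values=pd.DataFrame(auc, index=drug_ids, columns=sample_ids),
        dataset_id=dataset_id,
    )
    truth = TruthRecord(
        sample_effects=pd.Series(g, index=sample_ids, name="g"),
        drug_effects=pd.Series(m, index=drug_ids, name="m"),
        extra={"mu": mu},
    )
    return mat, truth


def simulate_signature_cohort(
    n_samples: int = 60,
    n_genes: int = 200,
    signature_genes: Optional[Sequence[str]] = None,
    gradient_sd: float = 1.0,
    loading: float = 1.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    dataset_id: str = "sim",
) -> tuple[ExpressionMatrix, pd.Series]:
    """Cohort with a latent per-sample monocyticity gradient.

    Signature genes' expression = latent score x loading + noise; all other
    genes are pure noise. Returns the expression matrix and the latent
    scores (the truth for rank-recovery tests).
    """
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    if signature_genes is None:
        signature_genes = gene_ids[:8]
    signature_genes = list(signature_genes)
    known = set(gene_ids)
    extra = [g for g in signature_genes if g not in known]
    if extra:
        # allow caller-supplied symbols (e.g. the 8 monocyte genes) by
        # renaming the first len(extra) background genes
        replace = [g for g in gene_ids if g not in set(signature_genes)][: len(extra)]
        if len(replace) < len(extra):
            raise ValueError("more signature genes than genes in the matrix")
        renames = dict(zip(replace, extra))
        gene_ids = [renames.get(g, g) for g in gene_ids]
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    latent = rng.normal(0.0, gradient_sd, size=n_samples)
    expr = rng.normal(0.0, 1.0, size=(len(gene_ids), n_samples))
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in signature_genes:
        expr[idx[g], :] = loading * latent + rng.normal(
            0.0, noise_sd, size=n_samples
        )
    mat = ExpressionMatrix(
        values=pd.DataFrame(expr, index=gene_ids, columns=sample_ids),
        dataset_id=dataset_id,
    )
    return mat, pd.Series(latent, index=sample_ids, name="latent_monocyticity")


def simulate_cross_study_pair(
    n_drugs: int = 20,
    n_train: int = 120,
    n_test: int = 60,
    n_genes: int = 100,
    genes_per_drug: int = 3,
    drug_effect_sd: float = 0.05,
    grd_effect_sd: float = 0.1,
    noise_sd: float = 0.03,
    mu: float = 0.3,
    grd_orthogonal_drugs: Sequence[str] = (),
    seed: int = 0,
) -> tuple[dict, dict, TruthRecord]:
    """Two studies sharing gene-driven drug effects plus a latent
    sample-level general-response component.

    Each study is returned as a dict with keys ``expression``
    (:class:`ExpressionMatrix`), ``response`` (:class:`ResponseMatrix`,
    drugs x samples), and ``grd_truth`` (pd.Series of the latent sample
    effect). Drug AUCs follow

        AUC(d, s) = clamp01(mu + x_s' beta_d + g_s + eps)

    where g_s is a latent general-response effect independent of
    expression. Drugs named in ``grd_orthogonal_drugs`` get g_s weight 0
    (drug-specific signal orthogonal to the general response).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    drug_ids = [f"drug{i:02d}" for i in range(n_drugs)]
    betas = {}
    for d in drug_ids:
        b = np.zeros(n_genes)
        idx = rng.choice(n_genes, size=genes_per_drug, replace=False)
        b[idx] = rng.choice([-1.0, 1.0], size=genes_per_drug) * drug_effect_sd
        betas[d] = b
    studies = []
    for study, n in (("train", n_train), ("test", n_test)):
        sample_ids = [f"{study}_s{i:03d}" for i in range(n)]
        X = rng.standard_normal((n, n_genes))
        g = rng.normal(0.0, grd_effect_sd, size=n)
        rows = []
        for d in drug_ids:
            w = 0.0 if d in set(grd_orthogonal_drugs) else 1.0
            rows.append(
                mu + X @ betas[d] + w * g + rng.normal(0.0, noise_sd, size=n)
            )
        auc = np.clip(np.asarray(rows), 0.0, 1.0)
        studies.append(
            {
                "expression": ExpressionMatrix(
                    pd.DataFrame(X.T, index=gene_ids, columns=sample_ids),
                    dataset_id=study,
                ),
                "response": ResponseMatrix(
                    pd.DataFrame(auc, index=drug_ids, columns=sample_ids),
                    dataset_id=study,
                ),
                "grd_truth": pd.Series(g, index=sample_ids, name="g"),
            }
        )
    truth = TruthRecord(
        beta_source={d: betas[d] for d in drug_ids},
        extra={
            "gene_ids": gene_ids,
            "drug_ids": drug_ids,
            "grd_orthogonal_drugs": list(grd_orthogonal_drugs),
        },
    )
    return studies[0], studies[1], truth
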