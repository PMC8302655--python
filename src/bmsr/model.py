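"""Bayesian multi-source (and multi-task) sparse regression.

The model couples several studies ("sources") that measured the same
response (one drug's AUC, or GRD) on different samples:

    y^(d)   ~ N(X^(d) beta^(d), sigma_d^2 I)        d = 1..D
    beta^(d) ~ N(beta, s^2 I)                        s = 0.5
    beta_g  ~ N(0, lambda_g^2 tau^2)
    lambda_g ~ C+(0, 1)
    tau     ~ C+(0, tau0)
    tau0    = p0 / (N_G - p0) * sum_d sigma_d / sqrt(N_d)
    sigma_d ~ IG(1, 1)    (prior on the noise sd)

The shared coefficient vector ``beta`` carries a horseshoe-type prior
whose global scale is anchored by ``tau0``, encoding an a-priori number
of active genes ``p0``; the per-study coefficients are small
perturbations of the shared vector. The multi-task variant additionally
couples a set of drugs I through a per-drug scalar weight:

    y^(d,i) ~ N(X^(d) beta^(d) w_i, sigma_d^2 I),   w_i ~ N(0.5, 0.5)

so the shared ``beta`` is the common biomarker profile across the drug
set, and ``w_i`` its per-drug loading.

Inference is a partially collapsed Gibbs sampler. The Gaussian blocks
(``beta^(d)``, ``beta``, ``w_i``) are conjugate. The shrinkage scales
``lambda_g`` and ``tau`` are updated with the shared coefficient
integrated out: given the per-source coefficients, their cross-source
mean satisfies mean_d beta_g^(d) ~ N(0, lambda_g^2 tau^2 + s^2/D), an
analytic marginal that lets the local scales jump directly between the
shrunk and the active regime (a plain conditional-on-beta update cannot
cross that funnel). Local scales use Metropolis steps mixing
half-Cauchy prior proposals with log-scale random walks; the global
scale and the noise sds use univariate slice sampling. ``tau0`` is
recomputed from the current sigma draws at every sweep.

All inputs are expected harmonized within source (see
:func:`bmsr.preprocess.harmonize_sources`): genes z-scored, responses on
a percent-like scale. The fixed perturbation scale s = 0.5 is small
relative to coefficients only on such a 0-100-style response scale; on a
unit-variance response it would rival the coefficients themselves and
decouple the studies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, solve_triangular

from .datatypes import SourceDataset

__all__ = [
    "BmsrModelSpec",
    "McmcConfig",
    "BMSR",
    "BMSMTR",
    "BMSRResults",
    "fit_bmsr",
    "fit_bmsmtr",
    "predict",
    "crossvalidate",
    "prioritize_biomarkers",
    "stouffer_combine",
]

_EPS = 1e-12
_BIG = 1e12


@dataclass
class BmsrModelSpec:
    """Model hyperparameters.

    ``p0`` — a-priori number of active genes (anchors the global scale).
    ``source_perturb_scale`` — the 0.5 of beta^(d) ~ N(beta, 0.5).
    ``noise_prior`` — (alpha, beta) of the IG prior on each noise sd.
    ``task_weight_prior`` — (location, scale) of the per-drug weight prior.
    ``interpret_scale_as`` — whether the two 0.5 scales are sds (the
    convention of the probabilistic-modeling platforms this family of
    models is usually written in) or variances (sensitivity mode).
    ``tau0_grouping`` — "per_source" sums sigma_d / sqrt(N_d) per source;
    "pooled" divides the summed sds by sqrt(mean N_d).
    ``slab_scale`` — optional regularized-slab scale c: each
    coefficient's prior variance becomes c^2 lam^2 tau^2 / (c^2 + lam^2
    tau^2), bounding even strongly supported coefficients at scale c.
    None (the default) is the plain horseshoe as the model is written.
    """

    p0: int = 10
    source_perturb_scale: float = 0.5
    noise_prior: tuple = (1.0, 1.0)
    task_weight_prior: tuple = (0.5, 0.5)
    interpret_scale_as: str = "sd"
    tau0_grouping: str = "per_source"
    slab_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p0 < 1:
            raise ValueError("p0 must be >= 1")
        if self.interpret_scale_as not in ("sd", "variance"):
            raise ValueError("interpret_scale_as must be 'sd' or 'variance'")
        if self.tau0_grouping not in ("per_source", "pooled"):
            raise ValueError("tau0_grouping must be 'per_source' or 'pooled'")

    @property
    def perturb_var(self) -> float:
        s = self.source_perturb_scale
        return s * s if self.interpret_scale_as == "sd" else s

    @property
    def weight_var(self) -> float:
        s = self.task_weight_prior[1]
        return s * s if self.interpret_scale_as == "sd" else s

    @property
    def slab_var(self) -> Optional[float]:
        if self.slab_scale is None:
            return None
        c = self.slab_scale
        return c * c if self.interpret_scale_as == "sd" else c


@dataclass
class McmcConfig:
    """Sampler budget: ``n_samples`` kept draws after ``n_burnin`` warmup
    sweeps, per chain. ``target_accept`` is accepted for interface
    compatibility with gradient-based samplers and is unused here."""

    n_samples: int = 500
    n_burnin: int = 500
    n_chains: int = 2
    seed: int = 0
    target_accept: float = 0.9

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_burnin, self.n_chains) < 1:
            raise ValueError("MCMC counts must be positive")


def _slice_sample(rng: np.random.Generator, logp, x0: float, w: float = 1.0,
                  max_steps: int = 50) -> float:
    """One univariate slice-sampling update (stepping out + shrinkage)."""
    logy = logp(x0) + np.log(rng.random() + _EPS)
    u = rng.random()
    lo, hi = x0 - u * w, x0 + (1.0 - u) * w
    for _ in range(max_steps):
        if logp(lo) <= logy:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) <= logy:
            break
        hi += w
    for _ in range(200):
        x1 = lo + rng.random() * (hi - lo)
        if logp(x1) >= logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


def _halfcauchy_logpdf_u(u: np.ndarray) -> np.ndarray:
    """Log-density (up to a constant) of u = log(scale^2) when the scale
    is standard half-Cauchy."""
    return 0.5 * u - np.logaddexp(0.0, u)


def _prior_var(lam2, tau2, slab2):
    """Per-coefficient prior variance: plain horseshoe lam2*tau2, or the
    regularized-slab form c^2 lam2 tau2 / (c^2 + lam2 tau2)."""
    v = lam2 * tau2
    if slab2 is None:
        return v
    return slab2 * v / (slab2 + v)


def _collapsed_loglik(m: np.ndarray, lam2, tau2, v0: float, slab2=None):
    """Log-likelihood of the cross-source coefficient means with the
    shared coefficient integrated out: m_g ~ N(0, prior_var + v0)."""
    V = _prior_var(lam2, tau2, slab2) + v0
    return -0.5 * np.log(V) - m * m / (2.0 * V)


_U_GRID = np.linspace(-30.0, 30.0, 121)  # quadrature grid in log(lambda^2)


_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(21)  # probabilists' GH


def _rb_cond_mean(mu: np.ndarray, sd: np.ndarray, tau2: float,
                  v0: float, slab2=None) -> np.ndarray:
    """Rao-Blackwellized conditional posterior mean of the shared beta.

    Computes E[beta_g | beta, sigma, tau^2, y] by integrating out both
    the per-source coefficient draw — whose cross-source mean m_g is
    Gaussian with moments (mu_g, sd_g^2) given (beta, sigma), and is
    independent of tau given beta — and the local scale lambda_g (1-D
    quadrature over its half-Cauchy posterior):

        E[beta_g | m, tau] = m * E_lambda[shrink | m, tau],
        shrink = lambda^2 tau^2 / (lambda^2 tau^2 + v0).

    Averaging this over sweeps estimates the same posterior mean as
    averaging the raw beta draws (tower rule), but without the
    heavy-tailed Monte-Carlo noise of sampled scales, which makes the
    raw-draw average useless for ranking genes at realistic budgets.
    """
    lam2g = np.exp(_U_GRID)[None, None, :]
    pv = _prior_var(lam2g, tau2, slab2)
    V = pv + v0                                             # 1 x 1 x L
    m = mu[:, None] + sd[:, None] * _GH_X[None, :]          # G x K
    logw = (
        _halfcauchy_logpdf_u(_U_GRID)[None, None, :]
        - 0.5 * np.log(V)
        - (m[:, :, None] ** 2) / (2.0 * V)
    )
    logw -= logw.max(axis=2, keepdims=True)
    wgt = np.exp(logw)
    shrink = pv / V
    f = m * (wgt * shrink).sum(axis=2) / wgt.sum(axis=2)    # G x K
    return f @ (_GH_W / _GH_W.sum())


def _update_scales(rng, m: np.ndarray, lam2: np.ndarray, tau2: float,
                   v0: float, t0: float, slab2=None, n_mh: int = 3):
    """Metropolis-within-Gibbs update of the local scales and slice
    update of the global scale, both collapsed over the shared beta."""
    G = len(m)
    u = np.log(lam2)
    for _ in range(n_mh):
        # independence proposals from the half-Cauchy prior (prior terms
        # cancel in the acceptance ratio)
        lam_prop = np.abs(rng.standard_cauchy(G))
        u_prop = 2.0 * np.log(np.maximum(lam_prop, 1e-150))
        logr = _collapsed_loglik(m, np.exp(u_prop), tau2, v0, slab2) - \
            _collapsed_loglik(m, np.exp(u), tau2, v0, slab2)
        acc = np.log(rng.random(G)) < logr
        u = np.where(acc, u_prop, u)
        # symmetric random walk on the log scale
        u_prop = u + rng.normal(0.0, 2.0, G)
        logr = (
            _halfcauchy_logpdf_u(u_prop)
            + _collapsed_loglik(m, np.exp(u_prop), tau2, v0, slab2)
            - _halfcauchy_logpdf_u(u)
            - _collapsed_loglik(m, np.exp(u), tau2, v0, slab2)
        )
        acc = np.log(rng.random(G)) < logr
        u = np.where(acc, u_prop, u)
    lam2 = np.clip(np.exp(u), _EPS, _BIG)

    def logp_tau(ut: float) -> float:
        if abs(ut) > 80:
            return -np.inf
        ll = float(
            np.sum(_collapsed_loglik(m, lam2, np.exp(ut), v0, slab2))
        )
        # tau ~ C+(0, t0) transformed to ut = log(tau^2)
        return ll + 0.5 * ut - float(np.logaddexp(0.0, ut - 2.0 * np.log(t0)))

    tau2 = float(
        np.clip(np.exp(_slice_sample(rng, logp_tau, float(np.log(tau2)),
                                     w=2.0)), _EPS, _BIG)
    )
    return lam2, tau2


def _tau0(spec: BmsrModelSpec, sigma: np.ndarray, n_per_source: np.ndarray,
          n_genes: int) -> float:
    ratio = spec.p0 / max(n_genes - spec.p0, 1)
    if spec.tau0_grouping == "per_source":
        return float(ratio * np.sum(sigma / np.sqrt(n_per_source)))
    return float(ratio * np.sum(sigma) / np.sqrt(np.mean(n_per_source)))


class BMSR:
    """Multi-source sparse regression model (statsmodels-style).

    Parameters
    ----------
    sources : list of SourceDataset
        Harmonized studies: identical gene order, standardized X and y.
    spec : BmsrModelSpec, optional
    """

    def __init__(self, sources: Sequence[SourceDataset],
                 spec: Optional[BmsrModelSpec] = None) -> None:
        sources = list(sources)
        if len(sources) < 1:
            raise ValueError("need >= 1 source")
        genes = sources[0].gene_ids
        for s in sources[1:]:
            if s.gene_ids != genes:
                raise ValueError(
                    "sources must share an identical gene order; run "
                    "harmonize_sources first"
                )
        self.sources = sources
        self.gene_ids = genes
        self.source_ids = [s.source_id for s in sources]
        self.spec = spec or BmsrModelSpec()
        if not self.spec.p0 < len(genes):
            raise ValueError("p0 must be < number of genes")

    # -- data blocks the sampler consumes ---------------------------------
    def _blocks(self):
        blocks = []
        for s in self.sources:
            X = s.X.to_numpy(dtype=float)
            y = s.y.to_numpy(dtype=float)
            blocks.append(
                {"X": X, "y": y, "XtX": X.T @ X, "Xty": X.T @ y, "n": len(y)}
            )
        return blocks

    def fit(self, mcmc: Optional[McmcConfig] = None, **kw) -> "BMSRResults":
        mcmc = mcmc or McmcConfig(**kw)
        blocks = self._blocks()
        G = len(self.gene_ids)
        D = len(blocks)
        n_per_source = np.array([b["n"] for b in blocks], dtype=float)
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        chains = {
            "beta": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "beta_cond_mean": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "beta_source": np.empty((mcmc.n_chains, mcmc.n_samples, D, G)),
            "sigma": np.empty((mcmc.n_chains, mcmc.n_samples, D)),
            "lam": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "tau": np.empty((mcmc.n_chains, mcmc.n_samples)),
            "tau0": np.empty((mcmc.n_chains, mcmc.n_samples)),
        }
        for c, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            self._run_chain(rng, blocks, mcmc, chains, c, n_per_source)
        return BMSRResults(
            draws=chains,
            gene_ids=self.gene_ids,
            source_ids=self.source_ids,
            spec=self.spec,
            mcmc=mcmc,
            model_kind="bmsr",
        )

    # -- Gibbs sweep -------------------------------------------------------
    def _run_chain(self, rng, blocks, mcmc, chains, c, n_per_source):
        G = len(self.gene_ids)
        D = len(blocks)
        s2 = self.spec.perturb_var
        slab2 = self.spec.slab_var
        a0, b0 = self.spec.noise_prior
        # eigendecompose each X'X once: every per-source operation becomes
        # diagonal in the eigenbasis (O(G^2) per sweep instead of O(G^3))
        eig = []
        for b in blocks:
            evals, Q = np.linalg.eigh(b["XtX"])
            evals = np.maximum(evals, 0.0)
            eig.append(
                {
                    "evals": evals,
                    "Q": Q,
                    "Q2": Q**2,
                    "Qt_Xty": Q.T @ b["Xty"],
                }
            )
        beta = np.zeros(G)
        beta_src = np.zeros((D, G))
        sigma = np.array(
            [max(0.5 * float(np.std(b["y"])), 1e-3) for b in blocks]
        )
        lam2 = np.ones(G)
        tau2 = max(_tau0(self.spec, sigma, n_per_source, G) ** 2, _EPS)
        total = mcmc.n_burnin + mcmc.n_samples
        for it in range(total):
            # 1. shrinkage scales | beta_src (collapsed over shared beta)
            t0 = max(_tau0(self.spec, sigma, n_per_source, G), _EPS)
            if it > 0:
                m = beta_src.mean(axis=0)
                lam2, tau2 = _update_scales(rng, m, lam2, tau2, s2 / D, t0,
                                            slab2)
            # 2. shared beta | scales, sigma, y (collapsed over beta_src):
            #    marginally y^(d) ~ N(X beta, sigma_d^2 I + s^2 X X'), so
            #    the Woodbury contribution of source d in the eigenbasis of
            #    X'X is diag(ev / (sigma_d^2 + s^2 ev))
            P = np.diag(1.0 / np.maximum(_prior_var(lam2, tau2, slab2), _EPS))
            rhs = np.zeros(G)
            for d, e in enumerate(eig):
                wd = 1.0 / (sigma[d] ** 2 + s2 * e["evals"])
                P += (e["Q"] * (e["evals"] * wd)) @ e["Q"].T
                rhs += e["Q"] @ (wd * e["Qt_Xty"])
            L = np.linalg.cholesky(P)
            mean = cho_solve((L, True), rhs)
            beta = mean + solve_triangular(
                L.T, rng.standard_normal(G), lower=False
            )
            # 3. per-source coefficients | shared beta, sigma, y
            #    precision (X'X + (sigma^2/s^2) I) / sigma^2, diagonal in
            #    the eigenbasis
            rb_mu = np.zeros(G)
            rb_var = np.zeros(G)
            for d, (b, e) in enumerate(zip(blocks, eig)):
                cpen = sigma[d] ** 2 / s2
                denom = e["evals"] + cpen
                rhs_d = e["Qt_Xty"] + (e["Q"].T @ beta) * cpen
                mean_d = e["Q"] @ (rhs_d / denom)
                z = rng.standard_normal(G)
                beta_src[d] = mean_d + sigma[d] * (
                    e["Q"] @ (z / np.sqrt(denom))
                )
                rb_mu += mean_d
                rb_var += sigma[d] ** 2 * (e["Q2"] @ (1.0 / denom))
            # 4. noise sds | beta_src (slice sampling on log sigma)
            for d, b in enumerate(blocks):
                rss = float(np.sum((b["y"] - b["X"] @ beta_src[d]) ** 2))
                n_d = b["n"]

                def logp(t, rss=rss, n_d=n_d):
                    if abs(t) > 40:
                        return -np.inf
                    return (
                        -(n_d + 2 * a0 - 1) * t
                        - b0 * np.exp(-t)
                        - rss / (2.0 * np.exp(2.0 * t))
                    )

                sigma[d] = float(
                    np.exp(_slice_sample(rng, logp, float(np.log(sigma[d]))))
                )
            if it >= mcmc.n_burnin:
                k = it - mcmc.n_burnin
                chains["beta"][c, k] = beta
                chains["beta_cond_mean"][c, k] = _rb_cond_mean(
                    rb_mu / D, np.sqrt(rb_var) / D, tau2, s2 / D, slab2
                )
                chains["beta_source"][c, k] = beta_src
                chains["sigma"][c, k] = sigma
                chains["lam"][c, k] = np.sqrt(lam2)
                chains["tau"][c, k] = np.sqrt(tau2)
                chains["tau0"][c, k] = _tau0(
                    self.spec, sigma, n_per_source, G
                )


class BMSMTR(BMSR):
    """Multi-task extension: a set of drugs I shares the coefficient
    profile; each drug gets a scalar weight w_i ~ N(0.5, 0.5).

    ``responses_per_drug`` maps drug id -> list of per-source response
    Series (indexed by sample id; samples missing that drug's response
    are dropped per drug). A single-drug set reduces to BMSR with w
    fixed at 1 (a warning advises the plain model in that case).
    """

    def __init__(
        self,
        sources: Sequence[SourceDataset],
        responses_per_drug: dict,
        spec: Optional[BmsrModelSpec] = None,
    ) -> None:
        super().__init__(sources, spec)
        if len(responses_per_drug) < 1:
            raise ValueError("need at least one drug in the task set")
        if len(responses_per_drug) == 1:
            warnings.warn(
                "single-drug task set: w is fixed at 1; fit_bmsr is the "
                "natural model for a single drug",
                UserWarning,
            )
        self.drug_ids = list(responses_per_drug)
        self.responses_per_drug = {
            drug: list(ys) for drug, ys in responses_per_drug.items()
        }
        for drug, ys in self.responses_per_drug.items():
            if len(ys) != len(self.sources):
                raise ValueError(
                    f"drug {drug!r}: need one response vector per source"
                )

    def _blocks(self):
        blocks = []
        for d, s in enumerate(self.sources):
            Xfull = s.X
            per_drug = []
            for drug in self.drug_ids:
                y = self.responses_per_drug[drug][d].dropna()
                samples = [i for i in Xfull.index if i in set(y.index)]
                if len(samples) < 3:
                    raise ValueError(
                        f"drug {drug!r} has < 3 samples in source "
                        f"{s.source_id!r}"
                    )
                X = Xfull.loc[samples].to_numpy(dtype=float)
                yv = y.loc[samples].to_numpy(dtype=float)
                per_drug.append(
                    {
                        "X": X,
                        "y": yv,
                        "XtX": X.T @ X,
                        "Xty": X.T @ yv,
                        "n": len(yv),
                    }
                )
            blocks.append(
                {"per_drug": per_drug, "n": Xfull.shape[0]}
            )
        return blocks

    def fit(self, mcmc: Optional[McmcConfig] = None, **kw) -> "BMSRResults":
        mcmc = mcmc or McmcConfig(**kw)
        blocks = self._blocks()
        G = len(self.gene_ids)
        D = len(blocks)
        n_drugs = len(self.drug_ids)
        n_per_source = np.array([b["n"] for b in blocks], dtype=float)
        seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
        chains = {
            "beta": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "beta_cond_mean": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "beta_source": np.empty((mcmc.n_chains, mcmc.n_samples, D, G)),
            "sigma": np.empty((mcmc.n_chains, mcmc.n_samples, D)),
            "lam": np.empty((mcmc.n_chains, mcmc.n_samples, G)),
            "tau": np.empty((mcmc.n_chains, mcmc.n_samples)),
            "tau0": np.empty((mcmc.n_chains, mcmc.n_samples)),
            "w": np.empty((mcmc.n_chains, mcmc.n_samples, n_drugs)),
        }
        for c, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            self._run_chain_mt(rng, blocks, mcmc, chains, c, n_per_source)
        return BMSRResults(
            draws=chains,
            gene_ids=self.gene_ids,
            source_ids=self.source_ids,
            spec=self.spec,
            mcmc=mcmc,
            model_kind="bmsmtr",
            drug_ids=self.drug_ids,
        )

    def _run_chain_mt(self, rng, blocks, mcmc, chains, c, n_per_source):
        G = len(self.gene_ids)
        D = len(blocks)
        nI = len(self.drug_ids)
        fixed_w = nI == 1
        s2 = self.spec.perturb_var
        slab2 = self.spec.slab_var
        a0, b0 = self.spec.noise_prior
        w_loc = self.spec.task_weight_prior[0]
        w_var = self.spec.weight_var
        beta = np.zeros(G)
        beta_src = np.zeros((D, G))
        w = np.ones(nI) if fixed_w else np.full(nI, max(w_loc, 0.5))
        sigma = np.array(
            [
                max(
                    0.5
                    * float(
                        np.std(np.concatenate([pd_["y"] for pd_ in b["per_drug"]]))
                    ),
                    1e-3,
                )
                for b in blocks
            ]
        )
        lam2 = np.ones(G)
        tau2 = max(_tau0(self.spec, sigma, n_per_source, G) ** 2, _EPS)
        eyeG = np.eye(G)
        total = mcmc.n_burnin + mcmc.n_samples
        for it in range(total):
            # 1. shrinkage scales | beta_src (collapsed over shared beta)
            t0 = max(_tau0(self.spec, sigma, n_per_source, G), _EPS)
            if it > 0:
                m = beta_src.mean(axis=0)
                lam2, tau2 = _update_scales(rng, m, lam2, tau2, s2 / D, t0,
                                            slab2)
            # per-source stacked sufficient statistics at current weights
            ZtZ = []
            Zty = []
            for b in blocks:
                ZtZ.append(
                    sum(
                        w[i] ** 2 * pd_["XtX"]
                        for i, pd_ in enumerate(b["per_drug"])
                    )
                )
                Zty.append(
                    sum(
                        w[i] * pd_["Xty"]
                        for i, pd_ in enumerate(b["per_drug"])
                    )
                )
            # 2. shared beta | scales, w, sigma, y (collapsed over beta_src)
            P = np.diag(1.0 / np.maximum(_prior_var(lam2, tau2, slab2), _EPS))
            rhs = np.zeros(G)
            for d in range(D):
                cpen = sigma[d] ** 2 / s2
                Lm = np.linalg.cholesky(ZtZ[d] + cpen * eyeG)
                T = cho_solve((Lm, True), ZtZ[d])
                P += (ZtZ[d] - ZtZ[d] @ T) / sigma[d] ** 2
                rhs += (Zty[d] - ZtZ[d] @ cho_solve((Lm, True), Zty[d])) / (
                    sigma[d] ** 2
                )
            L = np.linalg.cholesky(P)
            beta = cho_solve((L, True), rhs) + solve_triangular(
                L.T, rng.standard_normal(G), lower=False
            )
            # 3. per-source coefficients | shared beta, w, sigma, y
            rb_mu = np.zeros(G)
            rb_var = np.zeros(G)
            for d in range(D):
                cpen = sigma[d] ** 2 / s2
                Lm = np.linalg.cholesky(ZtZ[d] + cpen * eyeG)
                mean_d = cho_solve((Lm, True), Zty[d] + cpen * beta)
                beta_src[d] = mean_d + sigma[d] * solve_triangular(
                    Lm.T, rng.standard_normal(G), lower=False
                )
                rb_mu += mean_d
                Vinv = cho_solve((Lm, True), eyeG)
                rb_var += sigma[d] ** 2 * Vinv.diagonal()
            # 4. per-drug weights | beta_src, sigma (conjugate normal)
            if not fixed_w:
                for i in range(nI):
                    prec_w = 1.0 / w_var
                    num = w_loc / w_var
                    for d, b in enumerate(blocks):
                        mvec = b["per_drug"][i]["X"] @ beta_src[d]
                        prec_w += float(mvec @ mvec) / sigma[d] ** 2
                        num += float(mvec @ b["per_drug"][i]["y"]) / (
                            sigma[d] ** 2
                        )
                    w[i] = num / prec_w + rng.standard_normal() / np.sqrt(
                        prec_w
                    )
            # 5. noise sds | beta_src, w (slice sampling on log sigma)
            for d, b in enumerate(blocks):
                rss = 0.0
                n_d = 0
                for i, pd_ in enumerate(b["per_drug"]):
                    resid = pd_["y"] - w[i] * (pd_["X"] @ beta_src[d])
                    rss += float(resid @ resid)
                    n_d += pd_["n"]

                def logp(t, rss=rss, n_d=n_d):
                    if abs(t) > 40:
                        return -np.inf
                    return (
                        -(n_d + 2 * a0 - 1) * t
                        - b0 * np.exp(-t)
                        - rss / (2.0 * np.exp(2.0 * t))
                    )

                sigma[d] = float(
                    np.exp(_slice_sample(rng, logp, float(np.log(sigma[d]))))
                )
            if it >= mcmc.n_burnin:
                k = it - mcmc.n_burnin
                chains["beta"][c, k] = beta
                chains["beta_cond_mean"][c, k] = _rb_cond_mean(
                    rb_mu / D, np.sqrt(rb_var) / D, tau2, s2 / D, slab2
                )
                chains["beta_source"][c, k] = beta_src
                chains["sigma"][c, k] = sigma
                chains["lam"][c, k] = np.sqrt(lam2)
                chains["tau"][c, k] = np.sqrt(tau2)
                chains["tau0"][c, k] = _tau0(
                    self.spec, sigma, n_per_source, G
                )
                chains["w"][c, k] = w


class BMSRResults:
    """Posterior draws, diagnostics and reporting for a fitted model."""

    def __init__(self, draws: dict, gene_ids: list, source_ids: list,
                 spec: BmsrModelSpec, mcmc: McmcConfig,
                 model_kind: str = "bmsr",
                 drug_ids: Optional[list] = None) -> None:
        self.draws = draws
        self.gene_ids = list(gene_ids)
        self.source_ids = list(source_ids)
        self.spec = spec
        self.mcmc = mcmc
        self.model_kind = model_kind
        self.drug_ids = list(drug_ids) if drug_ids is not None else None
        self._idata = None
        self.warnings: list[str] = []
        rh = self.rhat_max
        if rh is not None and rh > 1.1:
            msg = f"max split-Rhat on shared beta = {rh:.3f} (> 1.1)"
            self.warnings.append(msg)
            warnings.warn(msg, UserWarning)

    # -- posterior summaries ----------------------------------------------
    @property
    def beta_shared_mean(self) -> pd.Series:
        """Posterior mean of the shared coefficients.

        Uses the Rao-Blackwellized estimator (the average over sweeps of
        the analytic conditional mean of beta given the scales and the
        per-source coefficients), which estimates the same posterior mean
        as averaging the raw draws but with far less Monte-Carlo noise —
        the raw draws are dominated by the shrinkage scales' heavy tails.
        """
        key = "beta_cond_mean" if "beta_cond_mean" in self.draws else "beta"
        m = self.draws[key].mean(axis=(0, 1))
        return pd.Series(m, index=self.gene_ids, name="beta_shared")

    def beta_source_mean(self, source: str) -> pd.Series:
        d = self.source_ids.index(source)
        m = self.draws["beta_source"][:, :, d, :].mean(axis=(0, 1))
        return pd.Series(m, index=self.gene_ids, name=f"beta_{source}")

    @property
    def sigma_mean(self) -> pd.Series:
        return pd.Series(
            self.draws["sigma"].mean(axis=(0, 1)),
            index=self.source_ids,
            name="sigma",
        )

    @property
    def w_mean(self) -> Optional[pd.Series]:
        if "w" not in self.draws:
            return None
        return pd.Series(
            self.draws["w"].mean(axis=(0, 1)), index=self.drug_ids, name="w"
        )

    def credible_interval(self, var: str = "beta", prob: float = 0.95):
        """Equal-tailed posterior interval per coordinate of ``var``."""
        arr = self.draws[var]
        flat = arr.reshape(-1, *arr.shape[2:])
        lo = np.percentile(flat, 100 * (1 - prob) / 2, axis=0)
        hi = np.percentile(flat, 100 * (1 + prob) / 2, axis=0)
        return lo, hi

    # -- diagnostics -------------------------------------------------------
    def _to_idata(self):
        if self._idata is None:
            self._idata = az.from_dict(posterior={"beta": self.draws["beta"]})
        return self._idata

    @property
    def rhat_max(self) -> Optional[float]:
        if self.draws["beta"].shape[0] < 2:
            return None
        r = az.rhat(self._to_idata())["beta"].to_numpy()
        return float(np.nanmax(r))

    @property
    def ess_min(self) -> float:
        e = az.ess(self._to_idata())["beta"].to_numpy()
        return float(np.nanmin(e))

    # -- prediction --------------------------------------------------------
    def predict(self, X, source: str = "shared",
                return_interval: bool = False, prob: float = 0.95):
        """Posterior-mean linear prediction y_hat = X @ beta.

        ``source`` names a study (its beta^(d) is used) or "shared".
        With ``return_interval`` the posterior distribution of X @ beta
        per sample is summarized by an equal-tailed interval as well.
        """
        idx = None
        if isinstance(X, pd.DataFrame):
            if list(X.columns) != self.gene_ids:
                raise ValueError("gene order of X must match training")
            idx = X.index
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.shape[1] != len(self.gene_ids):
                raise ValueError("gene dimension mismatch")
        if source == "shared":
            coef_draws = self.draws["beta"]
            coef = self.beta_shared_mean.to_numpy()
        elif source in self.source_ids:
            d = self.source_ids.index(source)
            coef_draws = self.draws["beta_source"][:, :, d, :]
            coef = coef_draws.mean(axis=(0, 1))
        else:
            raise ValueError(f"unknown source id {source!r}")
        yhat = Xv @ coef
        yhat = pd.Series(yhat, index=idx) if idx is not None else yhat
        if not return_interval:
            return yhat
        flat = coef_draws.reshape(-1, len(self.gene_ids))
        pred_draws = flat @ Xv.T
        lo = np.percentile(pred_draws, 100 * (1 - prob) / 2, axis=0)
        hi = np.percentile(pred_draws, 100 * (1 + prob) / 2, axis=0)
        return yhat, (lo, hi)

    # -- biomarker prioritization -----------------------------------------
    def prioritize_biomarkers(self, alpha: float = 0.01) -> pd.DataFrame:
        """Stouffer-combined ranking of per-source coefficients.

        Within each source, posterior-mean coefficients are standardized
        across genes (z_g = (b_g - mean)/sd); the combined score is
        sum_d z_g^(d) / sqrt(D) with a two-sided normal p-value. Genes
        with p < ``alpha`` are flagged selected (the "extremal combined
        coefficients" rule).
        """
        if len(self.source_ids) < 2:
            raise ValueError(
                "prioritization requires >= 2 sources; rank "
                "beta_source_mean directly for a single study"
            )
        zs = {}
        for s in self.source_ids:
            b = self.beta_source_mean(s).to_numpy()
            zs[f"z_{s}"] = (b - b.mean()) / b.std(ddof=1)
        table = pd.DataFrame(zs, index=self.gene_ids)
        combined = table.to_numpy().sum(axis=1) / np.sqrt(len(self.source_ids))
        pvals = 2.0 * stats.norm.sf(np.abs(combined))
        table["combined_z"] = combined
        table["p"] = pvals
        table["selected"] = pvals < alpha
        table.index.name = "gene"
        return table.sort_values("combined_z", key=np.abs, ascending=False)

    def plot_coefficients(self, source_x: Optional[str] = None,
                          source_y: Optional[str] = None,
                          alpha: float = 0.01, ax=None):
        """Scatter of per-source posterior-mean coefficients.

        The canonical two-study diagnostic: most genes cluster near the
        origin and prioritized biomarkers separate along the identity
        line. Genes selected by the Stouffer rule at ``alpha`` are
        highlighted and labeled.
        """
        import matplotlib.pyplot as plt

        if source_x is None or source_y is None:
            if len(self.source_ids) < 2:
                raise ValueError("need two sources to plot against")
            source_x, source_y = self.source_ids[:2]
        bx = self.beta_source_mean(source_x)
        by = self.beta_source_mean(source_y)
        table = self.prioritize_biomarkers(alpha=alpha)
        sel = table.index[table["selected"]]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(bx, by, s=8, c="0.6", label="genes")
        ax.scatter(bx[sel], by[sel], s=18, c="crimson",
                   label=f"selected (p < {alpha:g})")
        for g in sel:
            ax.annotate(g, (bx[g], by[g]), fontsize=7,
                        xytext=(2, 2), textcoords="offset points")
        lim = max(bx.abs().max(), by.abs().max()) * 1.1
        ax.plot([-lim, lim], [-lim, lim], ls="--", c="0.8", lw=1)
        ax.set_xlabel(f"coefficient ({source_x})")
        ax.set_ylabel(f"coefficient ({source_y})")
        ax.legend(frameon=False, fontsize=8)
        return ax

    # -- reporting / persistence ------------------------------------------
    def summary(self, top: int = 10) -> str:
        lines = [
            f"{'BMSMTR' if self.model_kind == 'bmsmtr' else 'BMSR'} results",
            "=" * 40,
            f"sources: {', '.join(self.source_ids)}",
            f"genes (N_G): {len(self.gene_ids)}   p0: {self.spec.p0}",
            f"chains x draws: {self.draws['beta'].shape[0]} x "
            f"{self.draws['beta'].shape[1]} (burn-in {self.mcmc.n_burnin})",
            f"noise sd posterior means: "
            + ", ".join(
                f"{s}={v:.3f}" for s, v in self.sigma_mean.items()
            ),
        ]
        rh = self.rhat_max
        if rh is not None:
            lines.append(f"max split-Rhat(beta): {rh:.3f}   "
                         f"min ESS(beta): {self.ess_min:.0f}")
        if self.w_mean is not None:
            lines.append(
                "task weights: "
                + ", ".join(f"{d}={v:.3f}" for d, v in self.w_mean.items())
            )
        bm = self.beta_shared_mean
        ranked = bm.reindex(bm.abs().sort_values(ascending=False).index)
        lines.append(f"top {top} genes by |posterior-mean shared beta|:")
        for g, v in ranked.head(top).items():
            lines.append(f"  {g:<12s} {v:+.4f}")
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)

    def save(self, path) -> None:
        """Portable archive: draws in .npz plus a JSON metadata entry."""
        meta = {
            "gene_ids": self.gene_ids,
            "source_ids": self.source_ids,
            "drug_ids": self.drug_ids,
            "model_kind": self.model_kind,
            "spec": asdict(self.spec),
            "mcmc": asdict(self.mcmc),
        }
        np.savez_compressed(
            path, __meta__=np.array(json.dumps(meta)), **self.draws
        )

    @classmethod
    def load(cls, path) -> "BMSRResults":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            draws = {k: z[k] for k in z.files if k != "__meta__"}
        return cls(
            draws=draws,
            gene_ids=meta["gene_ids"],
            source_ids=meta["source_ids"],
            spec=BmsrModelSpec(**{**meta["spec"],
                                  "noise_prior": tuple(meta["spec"]["noise_prior"]),
                                  "task_weight_prior": tuple(meta["spec"]["task_weight_prior"])}),
            mcmc=McmcConfig(**meta["mcmc"]),
            model_kind=meta["model_kind"],
            drug_ids=meta["drug_ids"],
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_bmsr(sources: Sequence[SourceDataset],
             spec: Optional[BmsrModelSpec] = None,
             mcmc: Optional[McmcConfig] = None) -> BMSRResults:
    """Fit the multi-source model; see :class:`BMSR`."""
    return BMSR(sources, spec).fit(mcmc)


def fit_bmsmtr(sources: Sequence[SourceDataset], responses_per_drug: dict,
               spec: Optional[BmsrModelSpec] = None,
               mcmc: Optional[McmcConfig] = None) -> BMSRResults:
    """Fit the multi-task model; see :class:`BMSMTR`."""
    return BMSMTR(sources, responses_per_drug, spec).fit(mcmc)


def predict(posterior: BMSRResults, X, source: str = "shared"):
    """Posterior-mean prediction from a stored posterior."""
    return posterior.predict(X, source=source)


def prioritize_biomarkers(posterior: BMSRResults,
                          alpha: float = 0.01) -> pd.DataFrame:
    return posterior.prioritize_biomarkers(alpha=alpha)


def stouffer_combine(z: np.ndarray, axis: int = -1):
    """Stouffer's method: combined z = sum(z)/sqrt(k), two-sided p."""
    z = np.asarray(z, dtype=float)
    k = z.shape[axis]
    zc = z.sum(axis=axis) / np.sqrt(k)
    return zc, 2.0 * stats.norm.sf(np.abs(zc))


def crossvalidate(sources: Sequence[SourceDataset],
                  spec: Optional[BmsrModelSpec] = None,
                  mcmc: Optional[McmcConfig] = None,
                  k: int = 5, seed: int = 0) -> dict:
    """Source-stratified k-fold cross-validation.

    Folds preserve source proportions: each source's samples are shuffled
    and dealt into k folds; fold f's test set is the union across sources.
    The model is refit on each training split and held-out samples are
    predicted with their own source's coefficients. Returns per-fold
    (r, p, n) and the median-performing fold (the reporting convention
    for a k-fold fit: quote the fold of median r).
    """
    rng = np.random.default_rng(seed)
    assign = []
    for s in sources:
        idx = rng.permutation(s.n_samples)
        folds = np.empty(s.n_samples, dtype=int)
        folds[idx] = np.arange(s.n_samples) % k
        assign.append(folds)
    per_fold = []
    for f in range(k):
        train_sources = []
        tests = []
        for s, folds in zip(sources, assign):
            tr = folds != f
            te = ~tr
            if te.sum() < 3:
                raise ValueError(f"fold {f} has < 3 test samples in "
                                 f"source {s.source_id!r}")
            train_sources.append(
                SourceDataset(X=s.X.iloc[tr], y=s.y.iloc[tr],
                              source_id=s.source_id)
            )
            tests.append((s.source_id, s.X.iloc[te], s.y.iloc[te]))
        res = BMSR(train_sources, spec).fit(mcmc)
        obs, pred = [], []
        for sid, Xte, yte in tests:
            obs.append(yte.to_numpy(dtype=float))
            pred.append(res.predict(Xte, source=sid).to_numpy(dtype=float))
        obs = np.concatenate(obs)
        pred = np.concatenate(pred)
        r, p = stats.pearsonr(obs, pred)
        per_fold.append({"fold": f, "r": float(r), "p": float(p),
                         "n_test": int(len(obs))})
    rs = np.array([d["r"] for d in per_fold])
    median_fold = int(np.argsort(rs)[len(rs) // 2])
    return {
        "folds": per_fold,
        "median_fold": per_fold[median_fold],
        "median_r": float(np.median(rs)),
    }
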