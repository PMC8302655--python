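"""General-response metrics and cross-study concordance statistics.

GRD ("general response across drugs") is a sample's mean raw AUC over a
drug panel — a per-patient, target-agnostic ex vivo sensitivity
statistic. MRP (mean response across patients) is the per-drug analogue.
Standardized AUCs are per-drug z-scores across patients.

Cross-study concordance is measured three ways: the "correlation of
correlations" (Pearson r between the two studies' drug-drug correlation
matrices over shared drugs), per-drug concordance of a drug's
correlation-vector representation across studies, and bootstrap stability
of GRD under random drug subsets.

All correlations use pairwise-complete observations, as AUC matrices have
structured missingness after QC.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ResponseMatrix

__all__ = [
    "compute_grd",
    "compute_mrp",
    "standardize_auc",
    "drug_drug_correlation",
    "correlation_of_correlations",
    "cross_dataset_drug_concordance",
    "grd_subset_stability",
]

#: minimum observed drugs for a sample's GRD to be defined
DEFAULT_MIN_DRUGS = 10
#: minimum pairwise-complete observations for a correlation cell
DEFAULT_MIN_PAIRS = 5


def compute_grd(
    matrix: ResponseMatrix,
    drug_subset: Optional[Sequence[str]] = None,
    exclude_drug: Optional[str] = None,
    min_drugs: int = DEFAULT_MIN_DRUGS,
) -> pd.Series:
    """Per-sample mean raw AUC over the (optionally restricted) drug panel.

    ``exclude_drug`` implements the leave-drug-out discipline used when
    GRD enters a model of that drug's own response. Samples observed on
    fewer than ``min_drugs`` drugs get NaN.
    """
    vals = matrix.values
    if drug_subset is not None:
        missing = set(drug_subset) - set(vals.index)
        if missing:
            raise ValueError(f"unknown drugs in subset: {sorted(missing)[:5]}")
        vals = vals.loc[list(drug_subset)]
    if exclude_drug is not None:
        vals = vals.drop(index=exclude_drug, errors="ignore")
    if vals.shape[0] == 0:
        raise ValueError("empty effective drug subset")
    counts = vals.notna().sum(axis=0)
    grd = vals.mean(axis=0, skipna=True)
    grd[counts < min_drugs] = np.nan
    grd.name = "GRD"
    return grd


def compute_mrp(matrix: ResponseMatrix, min_samples: int = 1) -> pd.Series:
    """Per-drug mean raw AUC over patients; NaN under ``min_samples``."""
    vals = matrix.values
    counts = vals.notna().sum(axis=1)
    mrp = vals.mean(axis=1, skipna=True)
    mrp[counts < min_samples] = np.nan
    mrp.name = "MRP"
    return mrp


def standardize_auc(matrix: ResponseMatrix) -> ResponseMatrix:
    """Per-drug z-scores across patients (mean 0, sd 1 over observed
    entries); missing entries preserved; zero-variance rows become 0 with
    a warning."""
    vals = matrix.values
    mean = vals.mean(axis=1, skipna=True)
    sd = vals.std(axis=1, ddof=1, skipna=True)
    flat = sd.fillna(0.0) < 1e-12
    if flat.any():
        warnings.warn(
            f"zero-variance drug rows set to 0: {list(vals.index[flat])[:5]}"
        )
    # flat rows: deviations are already 0 where observed; divide by 1 there
    z = vals.sub(mean, axis=0).div(sd.where(~flat, 1.0), axis=0)
    return ResponseMatrix(values=z, dataset_id=matrix.dataset_id)


def drug_drug_correlation(
    matrix: ResponseMatrix,
    method: str = "pearson",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.DataFrame:
    """Symmetric drug x drug correlation matrix over samples
    (pairwise-complete); cells with fewer than ``min_pairs`` overlapping
    samples are NaN, the diagonal is 1."""
    vals = matrix.values.T  # samples x drugs: pandas corr works columnwise
    corr = vals.corr(method=method, min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _upper_triangle(mat: pd.DataFrame) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat.to_numpy()[iu]


def correlation_of_correlations(
    mat_a: ResponseMatrix,
    mat_b: ResponseMatrix,
    method: str = "pearson",
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> tuple[float, float]:
    """Interstudy consistency: Pearson (r, p) between the upper triangles
    of the two studies' drug-drug correlation matrices over shared drugs."""
    shared = sorted(set(mat_a.drug_ids) & set(mat_b.drug_ids))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared drugs")
    ca = drug_drug_correlation(mat_a, method, min_pairs).loc[shared, shared]
    cb = drug_drug_correlation(mat_b, method, min_pairs).loc[shared, shared]
    xa, xb = _upper_triangle(ca), _upper_triangle(cb)
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete correlation pairs")
    r, p = stats.pearsonr(xa[ok], xb[ok])
    return float(r), float(p)


def cross_dataset_drug_concordance(
    mat_a: ResponseMatrix,
    mat_b: ResponseMatrix,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> pd.Series:
    """Per-drug cross-study concordance.

    Each shared drug is represented, within each study, by the vector of
    its correlations to all other shared drugs; the returned Series holds
    the Pearson r between those two vectors per drug."""
    shared = sorted(set(mat_a.drug_ids) & set(mat_b.drug_ids))
    if len(shared) < 3:
        raise ValueError("need >= 3 shared drugs")
    ca = drug_drug_correlation(mat_a, min_pairs=min_pairs).loc[shared, shared]
    cb = drug_drug_correlation(mat_b, min_pairs=min_pairs).loc[shared, shared]
    out = {}
    for drug in shared:
        others = [d for d in shared if d != drug]
        va = ca.loc[drug, others].to_numpy(dtype=float)
        vb = cb.loc[drug, others].to_numpy(dtype=float)
        ok = np.isfinite(va) & np.isfinite(vb)
        if ok.sum() >= 2 and np.std(va[ok]) > 0 and np.std(vb[ok]) > 0:
            out[drug] = float(np.corrcoef(va[ok], vb[ok])[0, 1])
        else:
            out[drug] = np.nan
    return pd.Series(out, name="cross_dataset_r")


def grd_subset_stability(
    matrix: ResponseMatrix,
    subset_size: int,
    n_boot: int = 100,
    seed: int = 0,
    min_drugs: int = 1,
) -> dict:
    """Concordance of GRD computed from random drug subsets with GRD from
    the full panel.

    For each bootstrap draw a random subset of ``subset_size`` drugs is
    taken (without replacement) and the Pearson r between subset GRD and
    full-panel GRD recorded. Returns the r list, its mean and the 2.5/97.5
    percentile interval.
    """
    n_drugs = len(matrix.drug_ids)
    if not 0 < subset_size <= n_drugs:
        raise ValueError("subset_size must be in 1..n_drugs")
    rng = np.random.default_rng(seed)
    full = compute_grd(matrix, min_drugs=min_drugs)
    rs = []
    for _ in range(n_boot):
        sub = list(
            np.asarray(matrix.drug_ids)[
                rng.choice(n_drugs, size=subset_size, replace=False)
            ]
        )
        g = compute_grd(matrix, drug_subset=sub, min_drugs=min_drugs)
        ok = full.notna() & g.notna()
        rs.append(float(np.corrcoef(full[ok], g[ok])[0, 1]))
    rs_arr = np.asarray(rs)
    return {
        "r": rs,
        "mean_r": float(np.mean(rs_arr)),
        "ci": (
            float(np.percentile(rs_arr, 2.5)),
            float(np.percentile(rs_arr, 97.5)),
        ),
    }
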