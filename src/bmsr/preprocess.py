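"""Gene filtering and cross-source harmonization.

Regression inputs are produced in two steps: per-study gene filtering
(drop low-expression and low-variance genes by dataset-specific quantile
cutoffs), then harmonization across studies — intersecting gene sets,
fixing a common gene order, and z-scoring every gene and every response
within each study. Within-study standardization is what makes the model's
fixed scales (the 0.5 coefficient-perturbation sd, the IG(1, 1) noise
prior) interpretable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SourceDataset

__all__ = ["filter_genes", "harmonize_sources"]


def filter_genes(
    expr: ExpressionMatrix,
    min_expression_quantile: float = 0.25,
    min_variance_quantile: float = 0.25,
    return_report: bool = False,
):
    """Keep genes whose mean expression AND variance exceed the
    dataset-specific quantile cutoffs.

    Quantiles are computed over this dataset's genes, so the thresholds
    adapt to each study's expression scale.
    """
    for q in (min_expression_quantile, min_variance_quantile):
        if not 0 <= q < 1:
            raise ValueError("quantiles must be in [0, 1)")
    vals = expr.values
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    q_e = float(np.quantile(mean, min_expression_quantile))
    q_v = float(np.quantile(var, min_variance_quantile))
    all_true = pd.Series(True, index=vals.index)
    # quantile 0 means "no cutoff on this axis" (identity), not "> min"
    keep_e = mean > q_e if min_expression_quantile > 0 else all_true
    keep_v = var > q_v if min_variance_quantile > 0 else all_true
    keep = keep_e & keep_v
    if not keep.any():
        raise ValueError("all genes filtered out")
    out = ExpressionMatrix(values=vals.loc[keep], dataset_id=expr.dataset_id)
    if return_report:
        report = pd.DataFrame(
            {
                "mean": mean,
                "variance": var,
                "retained": keep,
            }
        )
        report.attrs["mean_cutoff"] = q_e
        report.attrs["variance_cutoff"] = q_v
        return out, report
    return out


def _zscore_cols(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (df - df.mean(axis=0)) / sd


def harmonize_sources(
    exprs: Sequence[ExpressionMatrix],
    responses: Sequence[pd.Series],
    covariates: Optional[Sequence[Optional[pd.DataFrame]]] = None,
    response_scale: float = 100.0,
) -> list[SourceDataset]:
    """Align studies onto their common genes and standardize within study.

    Gene ids are intersected across studies and ordered identically
    (sorted); within each study every gene column is z-scored and the
    response is z-scored then rescaled to sd ``response_scale``. Each
    response Series must be indexed by that study's sample ids; samples
    missing a response are dropped.

    The percent-like default response scale matters for the downstream
    hierarchical regression: its fixed cross-study coefficient-
    perturbation scale (0.5) is calibrated against responses measured in
    0-100-style units (percent inhibition, AUC x 100). On a unit-variance
    response the perturbation would be as large as the coefficients
    themselves, decoupling the studies and disabling the information
    sharing the model exists for.
    """
    if len(exprs) < 2:
        raise ValueError("need >= 2 sources to harmonize")
    if len(responses) != len(exprs):
        raise ValueError("one response vector per source required")
    common = set(exprs[0].gene_ids)
    for e in exprs[1:]:
        common &= set(e.gene_ids)
    if not common:
        raise ValueError("no shared genes across sources")
    order = sorted(common)
    out = []
    for i, (e, y) in enumerate(zip(exprs, responses)):
        X = e.values.loc[order].T  # samples x genes
        y = y.dropna()
        samples = [s for s in X.index if s in set(y.index)]
        if len(samples) < 3:
            raise ValueError(
                f"source {e.dataset_id!r}: fewer than 3 samples with responses"
            )
        X = X.loc[samples]
        yv = y.loc[samples].astype(float)
        Xz = _zscore_cols(X)
        ysd = yv.std(ddof=1)
        yz = (yv - yv.mean()) / (ysd if ysd > 0 else 1.0) * response_scale
        cov = None
        if covariates is not None and covariates[i] is not None:
            cov = _zscore_cols(covariates[i].loc[samples].astype(float))
        out.append(
            SourceDataset(
                X=Xz, y=yz, source_id=e.dataset_id, covariates=cov
            )
        )
    return out
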