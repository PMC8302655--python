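"""Core data containers shared across the package.

Conventions
-----------
* Expression matrices are genes x samples on a log scale (log2 CPM/TPM or
  similar); regression design matrices are the transpose (samples x genes).
* Drug-response matrices are drugs x samples holding normalized AUC in
  [0, 1]; missing cells are NaN.
* Identifiers are opaque strings matched case-sensitively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ResponseMatrix",
    "SourceDataset",
    "DoseResponseSeries",
    "LogLogisticFit",
    "GeneSet",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with unique ids."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(list(self.values.index), "gene ids")
        _check_unique(list(self.values.columns), "sample ids")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ResponseMatrix:
    """Drugs x samples matrix of normalized AUC in [0, 1]; NaN = missing."""

    values: pd.DataFrame  # index = drug ids, columns = sample ids
    dataset_id: str = "dataset"
    exclusions: Optional[pd.DataFrame] = None  # provenance of QC exclusions

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(list(self.values.index), "drug ids")
        _check_unique(list(self.values.columns), "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("response values must be finite or missing (NaN)")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())


@dataclass
class SourceDataset:
    """Aligned design matrix + response for one study; the unit BMSR consumes.

    ``X`` is samples x genes (the regression orientation), ``y`` the
    per-sample response (one drug's AUC, or GRD). Sample alignment between
    the two is enforced; responses may not be missing after assembly.
    """

    X: pd.DataFrame  # samples x genes
    y: pd.Series  # indexed by sample id
    source_id: str = "source"
    covariates: Optional[pd.DataFrame] = None  # samples x covariates

    def __post_init__(self) -> None:
        if list(self.X.index) != list(self.y.index):
            raise ValueError(
                f"sample alignment mismatch in source {self.source_id!r}"
            )
        if self.y.isna().any():
            raise ValueError("missing responses after assembly")
        if not np.all(np.isfinite(self.X.to_numpy(dtype=float))):
            raise ValueError("non-finite expression values")
        if self.covariates is not None and list(self.covariates.index) != list(
            self.X.index
        ):
            raise ValueError("covariate rows must align with samples")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.X.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


@dataclass
class DoseResponseSeries:
    """One drug x sample x replicate dose-response series.

    ``responses`` are percent inhibition (nominally 0-100, increasing with
    dose for an active drug); viability inputs should be converted as
    ``100 - viability`` before construction.
    """

    sample_id: str
    patient_id: str
    drug_id: str
    replicate_id: str
    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    def __len__(self) -> int:
        return len(self.concentrations)

    @property
    def conc_range(self) -> tuple[float, float, int]:
        """(min, max, n_points) key used by the modal-range QC filter."""
        return (
            float(self.concentrations[0]),
            float(self.concentrations[-1]),
            len(self.concentrations),
        )


@dataclass
class LogLogisticFit:
    """Fitted 3- or 4-parameter log-logistic curve.

    The curve is ``f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))``;
    with b < 0 the response increases with dose. LL3 fixes c = 0 (zero
    response at vanishing concentration).
    """

    model: str  # "LL3" | "LL4"
    b: float
    c: float
    d: float
    e: float
    rss: float
    converged: bool
    series: Optional[DoseResponseSeries] = None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.model not in ("LL3", "LL4"):
            raise ValueError("model must be 'LL3' or 'LL4'")
        if self.model == "LL3" and self.c != 0.0:
            raise ValueError("LL3 requires c = 0")
        if self.e <= 0:
            raise ValueError("inflection concentration e must be positive")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return ll4(x, self.b, self.c, self.d, self.e)

    def replace(self, **kw) -> "LogLogisticFit":
        return dataclasses.replace(self, **kw)


def ll4(x, b: float, c: float, d: float, e: float) -> np.ndarray:
    """Four-parameter log-logistic curve evaluated at concentrations x."""
    x = np.asarray(x, dtype=float)
    z = np.clip(b * (np.log(x) - np.log(e)), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z))


@dataclass
class GeneSet:
    """Named gene set (as read from one GMT line)."""

    name: str
    gene_ids: tuple
    description: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        if len(self.gene_ids) == 0:
            raise ValueError("gene set must be non-empty")
        _check_unique(self.gene_ids, "gene ids in set")

    def __len__(self) -> int:
        return len(self.gene_ids)
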