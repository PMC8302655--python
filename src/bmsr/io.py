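"""Readers, writers and run configuration.

Formats
-------
* Expression TSV: first column the gene id, remaining columns samples;
  values log2-scale, '.' decimal, UTF-8, header row mandatory.
* Dose-response CSV (long): header
  ``sample_id,patient_id,drug_id,replicate_id,concentration,response``.
* AUC matrix CSV: rows drugs, columns samples; missing cells empty or
  "NA" (accepted both ways, written as "NA").
* GMT: one gene set per line, ``name<TAB>description<TAB>gene...``.
* Run configuration: YAML; every stochastic command requires a seed.

Malformed rows raise parse errors naming the offending line.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    DoseResponseSeries,
    ExpressionMatrix,
    GeneSet,
    ResponseMatrix,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_dose_response",
    "write_dose_response",
    "read_auc_matrix",
    "write_auc_matrix",
    "read_gmt",
    "write_gmt",
    "read_series_tsv",
    "write_series_tsv",
    "RunConfig",
    "run_pipeline",
]


class ParseError(ValueError):
    pass


def read_expression(path, dataset_id: Optional[str] = None) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        line = list(df.index).index(dup) + 3
        raise ParseError(f"{path}:{line}: duplicate gene id {dup!r}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell ({exc})") from exc
    df.index.name = None  # round-trip identity with in-memory matrices
    return ExpressionMatrix(values=df, dataset_id=dataset_id or path.stem)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


_DR_COLS = [
    "sample_id",
    "patient_id",
    "drug_id",
    "replicate_id",
    "concentration",
    "response",
]


def read_dose_response(path) -> list[DoseResponseSeries]:
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in _DR_COLS[:4]})
    missing = [c for c in _DR_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("concentration", "response"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ParseError(f"{path}:{line}: non-numeric {col}")
        df[col] = pd.to_numeric(df[col])
    key = ["sample_id", "drug_id", "replicate_id", "concentration"]
    dup = df.duplicated(subset=key)
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ParseError(
            f"{path}:{line}: duplicated (sample, drug, replicate, "
            "concentration) row"
        )
    series = []
    for (samp, pat, drug, rep), grp in df.groupby(
        ["sample_id", "patient_id", "drug_id", "replicate_id"], sort=True
    ):
        grp = grp.sort_values("concentration")
        series.append(
            DoseResponseSeries(
                sample_id=samp,
                patient_id=pat,
                drug_id=drug,
                replicate_id=rep,
                concentrations=grp["concentration"].to_numpy(float),
                responses=grp["response"].to_numpy(float),
            )
        )
    return series


def write_dose_response(series: list[DoseResponseSeries], path) -> None:
    rows = []
    for s in series:
        for c, r in zip(s.concentrations, s.responses):
            rows.append(
                [s.sample_id, s.patient_id, s.drug_id, s.replicate_id, c, r]
            )
    pd.DataFrame(rows, columns=_DR_COLS).to_csv(path, index=False)


def read_auc_matrix(path, dataset_id: Optional[str] = None) -> ResponseMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    if df.index.duplicated().any():
        raise ParseError(f"{path}: duplicate drug ids")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric AUC cell ({exc})") from exc
    df.index.name = None
    return ResponseMatrix(values=df, dataset_id=dataset_id or path.stem)


def write_auc_matrix(mat: ResponseMatrix, path) -> None:
    mat.values.to_csv(path, index_label="drug_id", na_rep="NA")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{i}: GMT line needs name, description and "
                    "at least one gene"
                )
            genes = [g for g in parts[2:] if g]
            try:
                sets.append(
                    GeneSet(name=parts[0], description=parts[1], gene_ids=genes)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.gene_ids]) + "\n")


def read_series_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    return df.iloc[:, 0]


def write_series_tsv(series: pd.Series, path, value_name: str = "value") -> None:
    series.rename(value_name).to_csv(
        path, sep="\t", index_label="sample_id", na_rep="NA"
    )


# ---------------------------------------------------------------------------
# run configuration + pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed)."""

    seed: int
    output_dir: Path
    datasets: dict = field(default_factory=dict)  # name -> {path, kind, ...}
    qc: dict = field(default_factory=dict)
    gene_filter: dict = field(default_factory=dict)
    bmsr: dict = field(default_factory=dict)
    mcmc: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config error: seed is mandatory")
        cfg = cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "bmsr_out")),
            datasets=raw.get("datasets", {}),
            qc=raw.get("qc", {}),
            gene_filter=raw.get("gene_filter", {}),
            bmsr=raw.get("bmsr", {}),
            mcmc=raw.get("mcmc", {}),
        )
        for name, decl in cfg.datasets.items():
            p = Path(decl["path"])
            if not p.exists():
                raise FileNotFoundError(
                    f"config error: dataset {name!r} path does not exist: {p}"
                )
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, command: str) -> dict:
    """Run a named pipeline command; artifacts land in ``output_dir``.

    Commands: ``simulate`` (write synthetic fixtures + truth JSON) and
    ``demo`` (simulate two sources, fit a small multi-source model, emit
    the biomarker table and the monocytic signature scores of a simulated
    cohort). Every run logs input hashes, the seed, and package versions;
    outputs are deterministic given the config.
    """
    from . import __version__
    from .model import BmsrModelSpec, McmcConfig, fit_bmsr
    from .signature import MONOCYTE_SIGNATURE_GENES, monocyte_signature
    from .simulate import (
        SimConfig,
        simulate_multisource,
        simulate_signature_cohort,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "command": command,
        "seed": config.seed,
        "versions": {
            "bmsr": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_hashes": {
            name: _sha256(Path(decl["path"]))
            for name, decl in config.datasets.items()
        },
        "config": {
            "gene_filter": config.gene_filter,
            "qc": config.qc,
            "bmsr": config.bmsr,
            "mcmc": config.mcmc,
        },
        "outputs": [],
    }
    written: list[Path] = []
    try:
        if command == "simulate":
            sim_cfg = SimConfig(seed=config.seed, **config.bmsr.get("sim", {}))
            sources, truth = simulate_multisource(sim_cfg)
            for s in sources:
                p = out / f"expression_{s.source_id}.tsv"
                write_expression(
                    ExpressionMatrix(s.X.T, dataset_id=s.source_id), p
                )
                written.append(p)
                p = out / f"response_{s.source_id}.tsv"
                write_series_tsv(s.y, p, value_name="response")
                written.append(p)
            p = out / "truth.json"
            p.write_text(json.dumps(truth.to_dict(), indent=1))
            written.append(p)
            # matching dose-response and AUC fixtures
            from .datatypes import LogLogisticFit
            from .simulate import (
                simulate_dose_response,
                simulate_grd_structure,
            )

            curve = LogLogisticFit("LL4", b=-1.5, c=0.0, d=95.0, e=0.1,
                                   rss=0.0, converged=True)
            doses = list(10.0 ** np.linspace(-3, 0, 7))
            dr_series = []
            for i, samp in enumerate(("S01", "S02", "S03")):
                for drug in ("drugA", "drugB"):
                    dr_series += simulate_dose_response(
                        curve, doses, noise_sd=2.0, n_replicates=2,
                        seed=config.seed + i, sample_id=samp,
                        patient_id=f"P{samp}", drug_id=drug,
                    )
            p = out / "dose_response.csv"
            write_dose_response(dr_series, p)
            written.append(p)
            auc_mat, auc_truth = simulate_grd_structure(
                n_samples=24, n_drugs=12, missing_frac=0.05,
                seed=config.seed,
            )
            p = out / "auc_matrix.csv"
            write_auc_matrix(auc_mat, p)
            written.append(p)
            p = out / "auc_truth.json"
            p.write_text(json.dumps(auc_truth.to_dict(), indent=1))
            written.append(p)
        elif command == "demo":
            sim_cfg = SimConfig(
                n_genes=int(config.bmsr.get("n_genes", 80)),
                n_samples_per_source=(60, 40),
                n_active=4,
                seed=config.seed,
            )
            sources, truth = simulate_multisource(sim_cfg)
            spec = BmsrModelSpec(p0=int(config.bmsr.get("p0", 4)))
            mcmc = McmcConfig(
                n_samples=int(config.mcmc.get("n_samples", 200)),
                n_burnin=int(config.mcmc.get("n_burnin", 200)),
                n_chains=int(config.mcmc.get("n_chains", 2)),
                seed=config.seed,
            )
            res = fit_bmsr(sources, spec, mcmc)
            table = res.prioritize_biomarkers()
            p = out / "biomarkers.tsv"
            table.to_csv(p, sep="\t")
            written.append(p)
            expr, latent = simulate_signature_cohort(
                signature_genes=list(MONOCYTE_SIGNATURE_GENES),
                seed=config.seed,
            )
            scores = monocyte_signature(expr)
            p = out / "signature_scores.tsv"
            write_series_tsv(scores, p, value_name="monocyte_signature")
            written.append(p)
        else:
            raise ValueError(f"unknown pipeline command {command!r}")
    except Exception:
        for p in written:  # no partial outputs on failure
            p.unlink(missing_ok=True)
        raise
    log["outputs"] = [
        {"path": str(p), "sha256": _sha256(p)} for p in written
    ]
    (out / f"{command}_log.json").write_text(json.dumps(log, indent=1))
    return log
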