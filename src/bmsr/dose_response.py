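"""Log-logistic dose-response fitting, AUC summarization and QC filters.

The curve model is the 4-parameter log-logistic

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with slope b (negative for a response that increases with dose), lower
asymptote c, upper asymptote d (percent inhibition), and inflection
concentration e. The 3-parameter variant (LL3) constrains the curve to
asymptote to zero response at vanishing concentration (c = 0).

Response is summarized as the normalized area under the fitted inhibition
curve over the drug's tested log10-concentration range (AUC in [0, 1];
higher = more sensitive), the summary generally preferred over single-
parameter EC50/IC50 readouts for multi-parameter fits.

QC follows ex vivo screen practice: series are excluded when their
concentration range differs from the drug's modal range or points are
missing; one sample is kept per patient (the one assayed across the most
drugs); and three outlier criteria annotate fits — a non-monotone
dose-response trend, divergence between the LL3 and LL4 AUCs, and
discordance between replicate screens.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.optimize import least_squares

from .datatypes import DoseResponseSeries, LogLogisticFit, ResponseMatrix, ll4

__all__ = [
    "QcThresholds",
    "fit_log_logistic",
    "compute_auc",
    "qc_concentration_range",
    "select_patient_sample",
    "flag_outliers",
    "build_response_matrix",
]


class FitError(ValueError):
    """Raised when a series cannot be fitted."""


@dataclass(frozen=True)
class QcThresholds:
    """Outlier-flagging thresholds, in normalized-AUC units.

    ``ll3_ll4_delta``: criterion (2) threshold on |AUC_LL3 - AUC_LL4|.
    ``replicate_rho``: criterion (3) threshold on |AUC_rep_i - AUC_rep_j|.
    ``monotone_tol``: tolerance for a decrease of the fitted curve.
    ``data_monotone_tol``: tolerated drop (response units) of an observed
    point below the running maximum before the series counts as
    non-monotone.
    """

    ll3_ll4_delta: float = 0.2
    replicate_rho: float = 0.3
    monotone_tol: float = 1e-6
    data_monotone_tol: float = 10.0


def _ll_residuals(params, logx, resp, model):
    if model == "LL3":
        b, d, loge = params
        c = 0.0
    else:
        b, c, d, loge = params
    z = np.clip(b * (logx - loge), -700, 700)
    return c + (d - c) / (1.0 + np.exp(z)) - resp


def fit_log_logistic(
    series: DoseResponseSeries, model: str = "LL4"
) -> LogLogisticFit:
    """Least-squares LL3/LL4 fit with a deterministic multi-start grid.

    Starts span slopes in {-0.3, -1, -2, -4} (and their positive mirrors,
    so decreasing series are representable) crossed with inflection
    guesses at each tested concentration; the best local optimum by RSS is
    returned. ``converged`` is False only if every start fails.
    """
    if model not in ("LL3", "LL4"):
        raise ValueError("model must be 'LL3' or 'LL4'")
    n_min = 3 if model == "LL3" else 4
    if len(series) < n_min:
        raise FitError(
            f"{model} requires >= {n_min} concentrations, got {len(series)}"
        )
    resp = series.responses
    if not np.all(np.isfinite(resp)):
        raise ValueError("non-finite responses")
    logx = np.log(series.concentrations)

    rmin, rmax = float(resp.min()), float(resp.max())
    if rmax - rmin < 1e-9:
        # flat series: slope is unidentifiable; report a degenerate flat fit
        c = 0.0 if model == "LL3" else rmin
        fit = LogLogisticFit(
            model=model,
            b=-1.0,
            c=c,
            d=rmin,
            e=float(np.exp(np.mean(logx))),
            rss=0.0,
            converged=True,
            series=series,
        )
        fit.rss = float(np.sum((resp - fit.predict(series.concentrations)) ** 2))
        fit.qc_flags.add("degenerate")
        return fit

    best = None
    slopes = [-0.3, -1.0, -2.0, -4.0, 0.3, 1.0, 2.0, 4.0]
    for b0 in slopes:
        for loge0 in logx:
            if model == "LL3":
                x0 = np.array([b0, rmax, loge0])
            else:
                x0 = np.array([b0, rmin, rmax, loge0])
            try:
                sol = least_squares(
                    _ll_residuals,
                    x0,
                    args=(logx, resp, model),
                    method="lm",
                    max_nfev=2000,
                )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if best is None or rss < best[0] - 1e-12:
                best = (rss, sol.x)
    if best is None:
        return LogLogisticFit(
            model=model,
            b=-1.0,
            c=0.0,
            d=rmax,
            e=float(np.exp(np.mean(logx))),
            rss=float("inf"),
            converged=False,
            series=series,
        )
    rss, params = best
    if model == "LL3":
        b, d, loge = params
        c = 0.0
    else:
        b, c, d, loge = params
    if model == "LL4" and b > 0 and d < c:
        # (b, c, d, e) and (-b, d, c, e) describe the same curve; normalize
        # so an increasing inhibition curve has b < 0 and d the high-dose
        # asymptote
        b, c, d = -b, d, c
    return LogLogisticFit(
        model=model,
        b=float(b),
        c=float(c),
        d=float(d),
        e=float(np.exp(loge)),
        rss=float(rss),
        converged=True,
        series=series,
    )


def compute_auc(
    fit: LogLogisticFit,
    conc_range: tuple[float, float],
    n_grid: int = 4097,
) -> float:
    """Normalized area under the fitted inhibition curve.

    Integrates the fitted response (clipped to [0, 100]) over
    log10-concentration across ``conc_range`` and divides by 100 times the
    log10 width, giving a value in [0, 1]. A curve pinned at 100%
    inhibition scores exactly 1; one pinned at 0% scores exactly 0.
    """
    if not fit.converged:
        raise ValueError("cannot compute AUC of an unconverged fit")
    low, high = conc_range
    if not 0 < low < high:
        raise ValueError("need 0 < low < high concentration range")
    t = np.linspace(np.log10(low), np.log10(high), n_grid)
    y = np.clip(fit.predict(10.0**t), 0.0, 100.0)
    width = t[-1] - t[0]
    return float(simpson(y, x=t) / (100.0 * width))


def qc_concentration_range(
    series_collection: Sequence[DoseResponseSeries],
) -> tuple[list[DoseResponseSeries], pd.DataFrame]:
    """Keep, per drug, only series matching the modal concentration range.

    The modal (min, max, n_points) tuple over a drug's series defines the
    expected design; series with a different range or missing points are
    excluded with reason ``incomplete_range``. Ties between equally common
    ranges break to the lexicographically smaller tuple.

    Returns (kept series, exclusion report).
    """
    if len(series_collection) == 0:
        raise ValueError("empty series collection")
    by_drug: dict[str, list[DoseResponseSeries]] = defaultdict(list)
    for s in series_collection:
        by_drug[s.drug_id].append(s)
    kept: list[DoseResponseSeries] = []
    records = []
    for drug, group in by_drug.items():
        counts = Counter(s.conc_range for s in group)
        top = max(counts.values())
        modal = min(k for k, v in counts.items() if v == top)
        for s in group:
            if s.conc_range == modal:
                kept.append(s)
            else:
                records.append(
                    {
                        "sample_id": s.sample_id,
                        "patient_id": s.patient_id,
                        "drug_id": drug,
                        "replicate_id": s.replicate_id,
                        "reason": "incomplete_range",
                        "observed_range": str(s.conc_range),
                        "modal_range": str(modal),
                    }
                )
    report = pd.DataFrame(
        records,
        columns=[
            "sample_id",
            "patient_id",
            "drug_id",
            "replicate_id",
            "reason",
            "observed_range",
            "modal_range",
        ],
    )
    return kept, report


def select_patient_sample(
    series_collection: Sequence[DoseResponseSeries],
) -> list[DoseResponseSeries]:
    """One sample per patient: keep the sample assayed across the most
    distinct drugs; ties break to the lexicographically first sample id."""
    drugs_per_sample: dict[tuple[str, str], set] = defaultdict(set)
    for s in series_collection:
        drugs_per_sample[(s.patient_id, s.sample_id)].add(s.drug_id)
    chosen: dict[str, str] = {}
    by_patient: dict[str, list[tuple[str, set]]] = defaultdict(list)
    for (pat, samp), drugs in drugs_per_sample.items():
        by_patient[pat].append((samp, drugs))
    for pat, entries in by_patient.items():
        entries.sort(key=lambda t: (-len(t[1]), t[0]))
        chosen[pat] = entries[0][0]
    return [s for s in series_collection if chosen[s.patient_id] == s.sample_id]


def _is_increasing(fit: LogLogisticFit, tol: float) -> bool:
    lo, hi = fit.series.concentrations[0], fit.series.concentrations[-1]
    x = np.geomspace(lo, hi, 101)
    y = fit.predict(x)
    return not np.any(np.diff(y) < -tol)


def _data_monotone(series: DoseResponseSeries, tol: float) -> bool:
    run_max = np.maximum.accumulate(series.responses)
    return not np.any(run_max - series.responses > tol)


def flag_outliers(
    fits_by_series: Iterable[tuple[LogLogisticFit, LogLogisticFit]],
    thresholds: QcThresholds = QcThresholds(),
) -> list[LogLogisticFit]:
    """Annotate fits with the three outlier criteria.

    ``fits_by_series`` yields (LL3 fit, LL4 fit) pairs for the same series.
    Flags set on the LL4 fit (returned):

    1. ``non_monotone`` — the fitted response decreases over the tested
       range by more than ``monotone_tol``, or an observed point falls more
       than ``data_monotone_tol`` response units below the running maximum
       (a fitted log-logistic is monotone by construction, so gross
       point-level violations are checked against the data).
    2. ``ll3_ll4_divergent`` — |AUC_LL3 - AUC_LL4| over the series' own
       range exceeds ``ll3_ll4_delta``.
    3. ``replicate_discordant`` — some replicate of the same
       (sample, drug) differs in LL4 AUC by more than ``replicate_rho``.

    Flags annotate; exclusion is the caller's choice. The operation is
    idempotent: flags are recomputed from scratch on each call.
    """
    pairs = list(fits_by_series)
    out: list[LogLogisticFit] = []
    auc_by_key: dict[tuple[str, str], list[tuple[str, float, LogLogisticFit]]] = (
        defaultdict(list)
    )
    for ll3, ll4_fit in pairs:
        if ll3.series is not ll4_fit.series and (
            ll3.series.sample_id != ll4_fit.series.sample_id
            or ll3.series.drug_id != ll4_fit.series.drug_id
            or ll3.series.replicate_id != ll4_fit.series.replicate_id
        ):
            raise ValueError("LL3/LL4 fits must refer to the same series")
        fit = ll4_fit.replace()
        fit.qc_flags = set(f for f in ll4_fit.qc_flags if f == "degenerate")
        series = fit.series
        rng_ = (series.concentrations[0], series.concentrations[-1])
        if not _is_increasing(fit, thresholds.monotone_tol) or not _data_monotone(
            series, thresholds.data_monotone_tol
        ):
            fit.qc_flags.add("non_monotone")
        if ll3.converged and fit.converged:
            a3 = compute_auc(ll3, rng_)
            a4 = compute_auc(fit, rng_)
            if abs(a3 - a4) > thresholds.ll3_ll4_delta:
                fit.qc_flags.add("ll3_ll4_divergent")
        else:
            a4 = compute_auc(fit, rng_) if fit.converged else np.nan
        auc_by_key[(series.sample_id, series.drug_id)].append(
            (series.replicate_id, a4, fit)
        )
        out.append(fit)
    for reps in auc_by_key.values():
        if len(reps) < 2:
            continue
        for i, (_, ai, fi) in enumerate(reps):
            for j, (_, aj, _) in enumerate(reps):
                if i != j and np.isfinite(ai) and np.isfinite(aj):
                    if abs(ai - aj) > thresholds.replicate_rho:
                        fi.qc_flags.add("replicate_discordant")
    return out


def build_response_matrix(
    fits: Sequence[LogLogisticFit],
    dataset_id: str = "dataset",
    conc_range_per_drug: Optional[dict] = None,
    exclude_flags: frozenset = frozenset(),
) -> ResponseMatrix:
    """Assemble a drugs x samples AUC matrix from fitted series.

    AUC is computed over each drug's modal tested range (or
    ``conc_range_per_drug`` if supplied). Replicate AUCs for the same
    (drug, sample) are averaged. Fits carrying any flag in
    ``exclude_flags`` become missing cells; exclusion provenance is kept
    on the returned matrix.
    """
    by_drug: dict[str, list[LogLogisticFit]] = defaultdict(list)
    for f in fits:
        if f.series is None:
            raise ValueError("fits must carry their series")
        by_drug[f.series.drug_id].append(f)
    ranges = {}
    for drug, group in by_drug.items():
        if conc_range_per_drug and drug in conc_range_per_drug:
            ranges[drug] = conc_range_per_drug[drug]
        else:
            counts = Counter(f.series.conc_range for f in group)
            top = max(counts.values())
            mn, mx, _ = min(k for k, v in counts.items() if v == top)
            ranges[drug] = (mn, mx)
    cells: dict[tuple[str, str], list[float]] = defaultdict(list)
    seen_rep: set = set()
    records = []
    for f in fits:
        s = f.series
        key = (s.drug_id, s.sample_id, s.replicate_id)
        if key in seen_rep:
            raise ValueError(f"duplicate (drug, sample, replicate): {key}")
        seen_rep.add(key)
        if f.qc_flags & exclude_flags or not f.converged:
            records.append(
                {
                    "drug_id": s.drug_id,
                    "sample_id": s.sample_id,
                    "replicate_id": s.replicate_id,
                    "reason": ";".join(sorted(f.qc_flags)) or "unconverged",
                }
            )
            continue
        cells[(s.drug_id, s.sample_id)].append(
            compute_auc(f, ranges[s.drug_id])
        )
    drugs = sorted(by_drug)
    samples = sorted({f.series.sample_id for f in fits})
    mat = pd.DataFrame(np.nan, index=drugs, columns=samples)
    for (drug, sample), aucs in cells.items():
        mat.loc[drug, sample] = float(np.mean(aucs))
    exclusions = pd.DataFrame(
        records, columns=["drug_id", "sample_id", "replicate_id", "reason"]
    )
    return ResponseMatrix(values=mat, dataset_id=dataset_id, exclusions=exclusions)
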