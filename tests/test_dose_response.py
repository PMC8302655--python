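"""Curve fitting, AUC and QC filters, checked against independent oracles."""

import itertools

import numpy as np
import pytest

from bmsr import (
    DoseResponseSeries,
    LogLogisticFit,
    QcThresholds,
    build_response_matrix,
    compute_auc,
    fit_log_logistic,
    flag_outliers,
    qc_concentration_range,
    select_patient_sample,
    simulate_dose_response,
)
from bmsr.datatypes import ll4
from bmsr.dose_response import FitError


def _series(conc, resp, **ids):
    base = dict(
        sample_id="S1", patient_id="P1", drug_id="drugA", replicate_id="r1"
    )
    base.update(ids)
    return DoseResponseSeries(
        concentrations=np.asarray(conc, float),
        responses=np.asarray(resp, float),
        **base,
    )


class TestFitLogLogistic:
    @pytest.mark.parametrize("b", [-0.7, -1.5, -3.0])
    @pytest.mark.parametrize("e", [0.03, 0.1, 0.5])
    def test_noiseless_ll4_recovery(self, b, e, seven_doses):
        d = 100.0
        conc = np.asarray(seven_doses)
        resp = ll4(conc, b, 0.0, d, e)
        fit = fit_log_logistic(_series(conc, resp), "LL4")
        assert fit.converged
        assert fit.b == pytest.approx(b, rel=1e-3)
        assert fit.d == pytest.approx(d, rel=1e-3)
        assert fit.e == pytest.approx(e, rel=1e-3)
        assert abs(fit.c) < 0.1

    def test_ll3_constrains_lower_asymptote(self, seven_doses):
        conc = np.asarray(seven_doses)
        resp = ll4(conc, -1.2, 0.0, 80.0, 0.1)
        fit = fit_log_logistic(_series(conc, resp), "LL3")
        assert fit.c == 0.0
        assert fit.d == pytest.approx(80.0, rel=1e-3)

    def test_ll3_equals_ll4_when_c_zero(self, seven_doses):
        conc = np.asarray(seven_doses)
        rng = np.random.default_rng(0)
        resp = ll4(conc, -1.0, 0.0, 90.0, 0.1) + rng.normal(0, 1.0, len(conc))
        f3 = fit_log_logistic(_series(conc, resp), "LL3")
        f4 = fit_log_logistic(_series(conc, resp), "LL4")
        a3 = compute_auc(f3, (conc[0], conc[-1]))
        a4 = compute_auc(f4, (conc[0], conc[-1]))
        assert a3 == pytest.approx(a4, abs=0.02)

    def test_rss_beats_brute_force_grid(self, seven_doses):
        conc = np.asarray(seven_doses)
        rng = np.random.default_rng(1)
        resp = ll4(conc, -1.3, 5.0, 85.0, 0.2) + rng.normal(0, 3, len(conc))
        fit = fit_log_logistic(_series(conc, resp), "LL4")
        grid_rss = min(
            float(np.sum((ll4(conc, b, c, d, e) - resp) ** 2))
            for b, c, d, e in itertools.product(
                np.linspace(-4, -0.2, 10),
                np.linspace(-10, 20, 10),
                np.linspace(50, 120, 10),
                np.geomspace(1e-3, 1.0, 10),
            )
        )
        assert fit.rss <= grid_rss + 1e-9

    def test_constant_zero_series_degenerate(self, seven_doses):
        fit = fit_log_logistic(_series(seven_doses, np.zeros(7)), "LL4")
        assert fit.converged
        assert abs(fit.d) < 1e-9 and abs(fit.c) < 1e-9
        assert "degenerate" in fit.qc_flags

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_log_logistic(_series([0.1, 1, 10], [1, 50, 99]), "LL4")


class TestComputeAuc:
    def test_constant_extremes(self, seven_doses):
        hi = LogLogisticFit("LL4", b=-1, c=100, d=100, e=0.1, rss=0,
                            converged=True)
        lo = LogLogisticFit("LL4", b=-1, c=0, d=0, e=0.1, rss=0,
                            converged=True)
        rng_ = (seven_doses[0], seven_doses[-1])
        assert compute_auc(hi, rng_) == pytest.approx(1.0, abs=1e-12)
        assert compute_auc(lo, rng_) == pytest.approx(0.0, abs=1e-12)

    def test_matches_dense_trapezoid_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            b = -rng.uniform(0.3, 3)
            c = rng.uniform(-20, 10)
            d = rng.uniform(60, 140)
            e = 10 ** rng.uniform(-2.5, -0.5)
            fit = LogLogisticFit("LL4", b=b, c=c, d=d, e=e, rss=0,
                                 converged=True)
            t = np.linspace(-3, 0, 100_001)
            oracle = np.trapezoid(
                np.clip(fit.predict(10.0**t), 0, 100), t
            ) / (100 * 3)
            assert compute_auc(fit, (1e-3, 1.0)) == pytest.approx(
                oracle, abs=1e-4
            )

    def test_monotone_in_upper_asymptote(self):
        aucs = [
            compute_auc(
                LogLogisticFit("LL4", b=-1, c=0, d=d, e=0.1, rss=0,
                               converged=True),
                (1e-3, 1.0),
            )
            for d in (40, 70, 100)
        ]
        assert aucs == sorted(aucs)

    def test_log_range_shift_invariance(self):
        # relabeling concentration units rescales e and the range together
        f1 = LogLogisticFit("LL4", b=-1, c=0, d=90, e=0.1, rss=0,
                            converged=True)
        f2 = LogLogisticFit("LL4", b=-1, c=0, d=90, e=100.0, rss=0,
                            converged=True)
        assert compute_auc(f1, (1e-3, 1.0)) == pytest.approx(
            compute_auc(f2, (1.0, 1e3)), abs=1e-9
        )

    def test_unconverged_rejected(self):
        bad = LogLogisticFit("LL4", b=-1, c=0, d=90, e=0.1, rss=np.inf,
                             converged=False)
        with pytest.raises(ValueError):
            compute_auc(bad, (1e-3, 1.0))


class TestQcFilters:
    def test_modal_range_exclusion(self, seven_doses):
        group = [
            _series(seven_doses, np.linspace(0, 90, 7), sample_id=f"S{i}")
            for i in range(9)
        ]
        odd = _series(seven_doses[:5], np.linspace(0, 60, 5), sample_id="S9")
        kept, report = qc_concentration_range(group + [odd])
        assert len(kept) == 9
        assert list(report["sample_id"]) == ["S9"]
        assert list(report["reason"]) == ["incomplete_range"]

    def test_missing_interior_point_excluded(self, seven_doses):
        full = [
            _series(seven_doses, np.linspace(0, 90, 7), sample_id=f"S{i}")
            for i in range(3)
        ]
        holed = _series(
            np.delete(np.asarray(seven_doses), 3),
            np.linspace(0, 90, 6),
            sample_id="S9",
        )
        kept, report = qc_concentration_range(full + [holed])
        assert all(s.sample_id != "S9" for s in kept)

    def test_tie_breaks_to_smaller_tuple(self, seven_doses):
        a = _series(seven_doses, np.linspace(0, 90, 7), sample_id="S1")
        b = _series(
            [c * 10 for c in seven_doses], np.linspace(0, 90, 7),
            sample_id="S2",
        )
        kept, _ = qc_concentration_range([a, b])
        assert [s.sample_id for s in kept] == ["S1"]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            qc_concentration_range([])

    def test_select_patient_sample(self, seven_doses):
        resp = np.linspace(0, 90, 7)
        series = []
        for drug in ("d1", "d2", "d3"):
            series.append(_series(seven_doses, resp, sample_id="SA",
                                  patient_id="P1", drug_id=drug))
        for drug in ("d1", "d2"):
            series.append(_series(seven_doses, resp, sample_id="SB",
                                  patient_id="P1", drug_id=drug))
        series.append(_series(seven_doses, resp, sample_id="SC",
                              patient_id="P2", drug_id="d1"))
        kept = select_patient_sample(series)
        assert {s.sample_id for s in kept} == {"SA", "SC"}

    def test_select_patient_sample_tie_lexicographic(self, seven_doses):
        resp = np.linspace(0, 90, 7)
        series = [
            _series(seven_doses, resp, sample_id=sid, patient_id="P1",
                    drug_id="d1")
            for sid in ("SB", "SA")
        ]
        kept = select_patient_sample(series)
        assert {s.sample_id for s in kept} == {"SA"}


class TestFlagOutliers:
    def _pair(self, series):
        return fit_log_logistic(series, "LL3"), fit_log_logistic(series, "LL4")

    def test_artifact_series_flagged_non_monotone(self, ll4_params,
                                                  seven_doses):
        (clean,) = simulate_dose_response(ll4_params, seven_doses, seed=1)
        (art,) = simulate_dose_response(
            ll4_params, seven_doses, seed=1, inject_artifact=True
        )
        fits = flag_outliers([self._pair(clean), self._pair(art)])
        assert "non_monotone" not in fits[0].qc_flags
        assert "non_monotone" in fits[1].qc_flags

    def test_identical_replicates_concordant(self, ll4_params, seven_doses):
        reps = simulate_dose_response(
            ll4_params, seven_doses, noise_sd=0, n_replicates=2, seed=0
        )
        fits = flag_outliers([self._pair(r) for r in reps])
        for f in fits:
            assert "replicate_discordant" not in f.qc_flags

    def test_discordant_replicates_flagged(self, seven_doses):
        conc = np.asarray(seven_doses)
        strong = _series(conc, ll4(conc, -2, 0, 100, 0.01), replicate_id="r1")
        weak = _series(conc, ll4(conc, -2, 0, 100, 10.0), replicate_id="r2")
        fits = flag_outliers([self._pair(strong), self._pair(weak)])
        assert all("replicate_discordant" in f.qc_flags for f in fits)

    def test_ll3_ll4_divergent_flag(self, seven_doses):
        # synthetic fit pair with a computed AUC gap of ~0.5: the flag must
        # fire exactly when the gap exceeds the default threshold of 0.2
        conc = np.asarray(seven_doses)
        series = _series(conc, ll4(conc, -1, 0, 100, 0.1))
        early = LogLogisticFit("LL4", b=-2.0, c=0.0, d=100.0, e=0.005,
                               rss=0.0, converged=True, series=series)
        late = LogLogisticFit("LL3", b=-2.0, c=0.0, d=100.0, e=0.5,
                              rss=0.0, converged=True, series=series)
        gap = abs(
            compute_auc(late, (conc[0], conc[-1]))
            - compute_auc(early, (conc[0], conc[-1]))
        )
        assert gap > 0.2
        fits = flag_outliers([(late, early)])
        assert "ll3_ll4_divergent" in fits[0].qc_flags
        # concordant pair stays unflagged
        fits2 = flag_outliers([self._pair(series)])
        assert "ll3_ll4_divergent" not in fits2[0].qc_flags

    def test_idempotent(self, ll4_params, seven_doses):
        (art,) = simulate_dose_response(
            ll4_params, seven_doses, seed=1, inject_artifact=True
        )
        once = flag_outliers([self._pair(art)])
        twice = flag_outliers([(self._pair(art)[0], once[0])])
        assert once[0].qc_flags == twice[0].qc_flags

    def test_threshold_config(self, ll4_params, seven_doses):
        reps = simulate_dose_response(
            ll4_params, seven_doses, noise_sd=0, n_replicates=2, seed=0
        )
        strict = QcThresholds(replicate_rho=-1.0)
        fits = flag_outliers([self._pair(r) for r in reps], strict)
        assert all("replicate_discordant" in f.qc_flags for f in fits)


class TestBuildResponseMatrix:
    def test_dense_matrix(self, ll4_params, seven_doses):
        fits = []
        for drug in ("d1", "d2", "d3"):
            for samp in ("S1", "S2"):
                (s,) = simulate_dose_response(
                    ll4_params, seven_doses, sample_id=samp, drug_id=drug
                )
                fits.append(fit_log_logistic(s, "LL4"))
        mat = build_response_matrix(fits)
        assert mat.values.shape == (3, 2)
        assert mat.n_missing == 0

    def test_excluded_cell_missing(self, ll4_params, seven_doses):
        (good,) = simulate_dose_response(
            ll4_params, seven_doses, sample_id="S1", drug_id="d1"
        )
        (bad,) = simulate_dose_response(
            ll4_params, seven_doses, sample_id="S2", drug_id="d1",
            inject_artifact=True,
        )
        pairs = [
            (fit_log_logistic(s, "LL3"), fit_log_logistic(s, "LL4"))
            for s in (good, bad)
        ]
        fits = flag_outliers(pairs)
        mat = build_response_matrix(
            fits, exclude_flags=frozenset({"non_monotone"})
        )
        assert mat.n_missing == 1
        assert np.isnan(mat.values.loc["d1", "S2"])
        assert mat.exclusions.shape[0] == 1

    def test_duplicate_cell_rejected(self, ll4_params, seven_doses):
        (s,) = simulate_dose_response(ll4_params, seven_doses)
        f = fit_log_logistic(s, "LL4")
        with pytest.raises(ValueError):
            build_response_matrix([f, f])

    def test_roundtrip_recovers_generating_auc(self, ll4_params, seven_doses):
        (s,) = simulate_dose_response(
            ll4_params, seven_doses, noise_sd=2.0, seed=4
        )
        fit = fit_log_logistic(s, "LL4")
        mat = build_response_matrix([fit])
        true_auc = compute_auc(
            ll4_params, (seven_doses[0], seven_doses[-1])
        )
        assert mat.values.iloc[0, 0] == pytest.approx(true_auc, abs=0.05)
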