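"""Multi-source regression model: shrinkage, recovery, prediction,
multi-task weights, prioritization and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmsr.datatypes import SourceDataset
from bmsr.model import (
    BMSR,
    BMSRResults,
    BmsrModelSpec,
    McmcConfig,
    crossvalidate,
    fit_bmsmtr,
    fit_bmsr,
    stouffer_combine,
)

FAST = McmcConfig(n_samples=200, n_burnin=200, n_chains=2, seed=0)


def _source(X, y, sid="S"):
    idx = [f"{sid}{i}" for i in range(len(y))]
    Xdf = pd.DataFrame(
        X, index=idx, columns=[f"g{j}" for j in range(X.shape[1])]
    )
    return SourceDataset(X=Xdf, y=pd.Series(y, index=idx), source_id=sid)


def _null_sources(seed=6, n_genes=50):
    rng = np.random.default_rng(seed)
    return [
        _source(rng.standard_normal((n, n_genes)), np.zeros(n), sid)
        for sid, n in (("A", 40), ("B", 30))
    ]


class TestFitBmsr:
    def test_null_data_shrinks_to_zero(self):
        res = fit_bmsr(_null_sources(), BmsrModelSpec(p0=5), FAST)
        assert res.beta_shared_mean.abs().max() < 0.05
        lo, hi = res.credible_interval("beta")
        assert np.mean((lo <= 0) & (0 <= hi)) >= 0.9

    def test_orthonormal_two_gene_matches_ols(self):
        rng = np.random.default_rng(0)
        n = 50
        Q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
        X = Q * np.sqrt(n)  # orthonormal directions at standardized scale
        y = X @ np.array([30.0, 0.0]) + rng.normal(0, 5, n)
        res = BMSR([_source(X, y, "one")], BmsrModelSpec(p0=1)).fit(FAST)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        draws = res.draws["beta"][..., 0]
        mcse = draws.std() / np.sqrt(max(res.ess_min, 1.0))
        bm = res.beta_shared_mean
        assert abs(bm.iloc[0] - ols[0]) < max(3 * mcse, 0.1)
        # the null gene stays pinned at zero (tiny against the 30-scale)
        assert abs(bm.iloc[1]) <= abs(ols[1]) + 0.05

    def test_recovery_on_small_simulation(self, small_multisource):
        harm, truth = small_multisource
        res = fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)
        rank = res.beta_shared_mean.abs().sort_values(ascending=False)
        top10 = set(rank.index[:10])
        assert set(truth.active_genes) <= top10
        gene_ids = truth.extra["gene_ids"]
        for g in truth.active_genes:
            true_sign = np.sign(truth.beta_shared[gene_ids.index(g)])
            assert np.sign(res.beta_shared_mean[g]) == true_sign

    def test_positivity_and_tau0_identity(self):
        res = fit_bmsr(_null_sources(), BmsrModelSpec(p0=5), FAST)
        for var in ("sigma", "lam", "tau"):
            assert np.all(res.draws[var] > 0)
        spec = res.spec
        G = len(res.gene_ids)
        n_per = np.array([40.0, 30.0])
        ratio = spec.p0 / (G - spec.p0)
        for c in range(res.draws["sigma"].shape[0]):
            for k in range(0, res.draws["sigma"].shape[1], 37):
                sig = res.draws["sigma"][c, k]
                expected = ratio * np.sum(sig / np.sqrt(n_per))
                assert res.draws["tau0"][c, k] == pytest.approx(
                    expected, abs=1e-10
                )

    def test_shrinkage_increases_as_p0_decreases(self):
        rng = np.random.default_rng(8)
        srcs = [
            _source(rng.standard_normal((n, 40)),
                    rng.normal(0, 100, n), sid)
            for sid, n in (("A", 40), ("B", 30))
        ]
        means = {}
        for p0 in (2, 20):
            res = fit_bmsr(srcs, BmsrModelSpec(p0=p0), FAST)
            means[p0] = float(res.beta_shared_mean.abs().mean())
        assert means[2] < means[20]

    def test_source_coupling_bounded(self, small_multisource):
        harm, _ = small_multisource
        res = fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)
        dev = 0.0
        for s in res.source_ids:
            dev = max(
                dev,
                float(
                    (res.beta_source_mean(s) - res.beta_shared_mean)
                    .abs()
                    .mean()
                ),
            )
        assert dev < 1.0

    def test_ridge_limit_single_source(self):
        # a diffuse global scale (p0 near N_G) reduces the fit to a
        # ridge-like estimate at penalty sigma^2 / s^2
        rng = np.random.default_rng(4)
        n, G = 100, 10
        X = rng.standard_normal((n, G))
        y = X @ rng.normal(0, 10, G) + rng.normal(0, 10, n)
        res = BMSR([_source(X, y, "one")], BmsrModelSpec(p0=9)).fit(
            McmcConfig(n_samples=300, n_burnin=300, n_chains=1, seed=5)
        )
        sig = float(res.sigma_mean.iloc[0])
        pen = sig**2 / res.spec.perturb_var
        ridge = np.linalg.solve(X.T @ X + pen * np.eye(G), X.T @ y)
        r = np.corrcoef(res.beta_source_mean("one"), ridge)[0, 1]
        assert r >= 0.95

    def test_gene_order_mismatch_rejected(self):
        a, b = _null_sources()
        b.X.columns = list(reversed(b.X.columns))
        with pytest.raises(ValueError):
            BMSR([a, b])

    def test_save_load_roundtrip(self, tmp_path):
        res = fit_bmsr(_null_sources(), BmsrModelSpec(p0=5), FAST)
        path = tmp_path / "posterior.npz"
        res.save(path)
        back = BMSRResults.load(path)
        np.testing.assert_array_equal(back.draws["beta"], res.draws["beta"])
        assert back.gene_ids == res.gene_ids
        assert back.spec.p0 == res.spec.p0

    def test_summary_mentions_sources_and_genes(self, small_multisource):
        harm, _ = small_multisource
        res = fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)
        text = res.summary()
        assert "source0" in text and "p0: 4" in text


class TestPredict:
    @pytest.fixture(scope="class")
    def fitted(self, small_multisource):
        harm, truth = small_multisource
        return harm, truth, fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)

    def test_zero_matrix_predicts_zero(self, fitted):
        harm, _, res = fitted
        yhat = res.predict(np.zeros((5, harm[0].n_genes)))
        np.testing.assert_allclose(yhat, 0.0)

    def test_deterministic_given_posterior(self, fitted):
        harm, _, res = fitted
        X = harm[0].X
        p1 = res.predict(X, source="source0")
        p2 = res.predict(X, source="source0")
        pd.testing.assert_series_equal(p1, p2)

    def test_unknown_source_rejected(self, fitted):
        harm, _, res = fitted
        with pytest.raises(ValueError):
            res.predict(harm[0].X, source="nope")

    def test_in_sample_beats_held_out(self, small_multisource):
        harm, _ = small_multisource
        s = harm[0]
        n_tr = 40
        train = SourceDataset(
            X=s.X.iloc[:n_tr], y=s.y.iloc[:n_tr], source_id=s.source_id
        )
        other = harm[1]
        res = fit_bmsr([train, other], BmsrModelSpec(p0=4), FAST)
        r_in = stats.pearsonr(
            train.y, res.predict(train.X, source=s.source_id)
        )[0]
        r_out = stats.pearsonr(
            s.y.iloc[n_tr:],
            res.predict(s.X.iloc[n_tr:], source=s.source_id),
        )[0]
        assert r_in >= r_out

    def test_interval_covers_point(self, fitted):
        harm, _, res = fitted
        yhat, (lo, hi) = res.predict(
            harm[0].X.iloc[:4], source="source0", return_interval=True
        )
        assert np.all(lo <= hi)


class TestCrossvalidate:
    def test_noiseless_prediction_near_perfect(self):
        rng = np.random.default_rng(3)
        beta = np.zeros(30)
        beta[[2, 11]] = [50.0, -40.0]
        srcs = []
        for sid, n in (("A", 50), ("B", 40)):
            X = rng.standard_normal((n, 30))
            srcs.append(_source(X, X @ beta, sid))
        rep = crossvalidate(srcs, BmsrModelSpec(p0=2), FAST, k=4, seed=0)
        assert all(f["r"] > 0.95 for f in rep["folds"])

    def test_fold_assignment_reproducible(self, small_multisource):
        harm, _ = small_multisource
        a = crossvalidate(harm, BmsrModelSpec(p0=4), FAST, k=4, seed=9)
        b = crossvalidate(harm, BmsrModelSpec(p0=4), FAST, k=4, seed=9)
        assert a["folds"] == b["folds"]

    def test_small_fold_rejected(self):
        srcs = _null_sources()
        tiny = SourceDataset(
            X=srcs[0].X.iloc[:4], y=srcs[0].y.iloc[:4], source_id="A"
        )
        with pytest.raises(ValueError):
            crossvalidate([tiny, srcs[1]], BmsrModelSpec(p0=5), FAST, k=3,
                          seed=0)


class TestBmsmtr:
    def _mt_data(self, w_true=(1.0, 0.7, 0.4), seed=1, sigma=20.0):
        rng = np.random.default_rng(seed)
        G = 60
        beta = np.zeros(G)
        beta[[3, 17, 40]] = [20.0, -25.0, 15.0]
        sources, responses = [], {f"drug{i}": [] for i in range(len(w_true))}
        for sid, n in (("A", 80), ("B", 50)):
            X = rng.standard_normal((n, G))
            src = _source(X, np.zeros(n), sid)
            sources.append(src)
            for i, w in enumerate(w_true):
                yv = w * (X @ beta) + rng.normal(0, sigma, n)
                responses[f"drug{i}"].append(
                    pd.Series(yv, index=src.X.index)
                )
        return sources, responses

    def test_weight_ordering_recovered(self):
        sources, responses = self._mt_data()
        res = fit_bmsmtr(sources, responses, BmsrModelSpec(p0=3),
                         McmcConfig(n_samples=300, n_burnin=300,
                                    n_chains=2, seed=2))
        w = res.w_mean
        assert w["drug0"] > w["drug1"] > w["drug2"]

    def test_single_drug_reduction_matches_bmsr(self):
        sources, responses = self._mt_data()
        single = {"drug0": responses["drug0"]}
        cfg = McmcConfig(n_samples=300, n_burnin=300, n_chains=2, seed=3)
        with pytest.warns(UserWarning, match="single-drug"):
            red = fit_bmsmtr(sources, single, BmsrModelSpec(p0=3), cfg)
        plain = fit_bmsr(
            [
                SourceDataset(X=s.X, y=responses["drug0"][d],
                              source_id=s.source_id)
                for d, s in enumerate(sources)
            ],
            BmsrModelSpec(p0=3),
            cfg,
        )
        a = red.beta_source_mean("A")
        b = plain.beta_source_mean("A")
        assert np.corrcoef(a, b)[0, 1] > 0.99
        assert np.all(red.draws["w"] == 1.0)

    def test_sign_flip_flips_weight_not_profile(self):
        sources, responses = self._mt_data()
        cfg = McmcConfig(n_samples=300, n_burnin=300, n_chains=1, seed=4)
        base = fit_bmsmtr(sources, responses, BmsrModelSpec(p0=3), cfg)
        flipped = {
            d: (ys if d != "drug2" else [-y for y in ys])
            for d, ys in responses.items()
        }
        alt = fit_bmsmtr(sources, flipped, BmsrModelSpec(p0=3), cfg)
        assert base.w_mean["drug2"] * alt.w_mean["drug2"] < 0
        a = base.beta_shared_mean.to_numpy()
        b = alt.beta_shared_mean.to_numpy()
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert cos >= 0.8

    def test_empty_task_set_rejected(self):
        sources, _ = self._mt_data()
        with pytest.raises(ValueError):
            fit_bmsmtr(sources, {}, BmsrModelSpec(p0=3), FAST)


class TestPrioritize:
    def test_stouffer_closed_forms(self):
        z, p = stouffer_combine(np.array([1.96, 1.96]))
        assert z == pytest.approx(2.772, abs=1e-3)
        assert p == pytest.approx(0.00556, abs=2e-4)
        z0, p0_ = stouffer_combine(np.array([2.0, -2.0]))
        assert z0 == pytest.approx(0.0, abs=1e-12)
        assert p0_ == pytest.approx(1.0)

    def test_table_selection_consistent(self, small_multisource):
        harm, truth = small_multisource
        res = fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)
        table = res.prioritize_biomarkers(alpha=0.01)
        assert set(table.columns) >= {"combined_z", "p", "selected"}
        np.testing.assert_array_equal(
            table["selected"].to_numpy(), (table["p"] < 0.01).to_numpy()
        )
        # recovery: the active genes dominate the combined ranking
        assert set(truth.active_genes) <= set(table.index[:10])

    def test_single_source_rejected(self):
        rng = np.random.default_rng(5)
        src = _source(rng.standard_normal((30, 20)), rng.normal(size=30))
        res = fit_bmsr([src], BmsrModelSpec(p0=3), FAST)
        with pytest.raises(ValueError):
            res.prioritize_biomarkers()


class TestPlotting:
    def test_coefficient_scatter_smoke(self, small_multisource, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        harm, _ = small_multisource
        res = fit_bmsr(harm, BmsrModelSpec(p0=4), FAST)
        ax = res.plot_coefficients()
        assert ax.get_xlabel().startswith("coefficient")
        ax.figure.savefig(tmp_path / "coef.png")


class TestRegularizedSlab:
    def test_slab_bounds_strong_coefficients(self):
        # the optional regularized slab caps even strongly supported
        # coefficients near its scale; the default plain horseshoe does not
        rng = np.random.default_rng(0)
        n = 50
        Q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
        X = Q * np.sqrt(n)
        y = X @ np.array([30.0, 0.0]) + rng.normal(0, 5, n)
        src = _source(X, y, "one")
        cfg = McmcConfig(n_samples=200, n_burnin=200, n_chains=1, seed=0)
        plain = BMSR([src], BmsrModelSpec(p0=1)).fit(cfg)
        slab = BMSR([src], BmsrModelSpec(p0=1, slab_scale=2.0)).fit(cfg)
        assert plain.beta_shared_mean.iloc[0] > 20
        assert slab.beta_shared_mean.iloc[0] < 15
        assert abs(slab.beta_shared_mean.iloc[1]) < 1.0
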