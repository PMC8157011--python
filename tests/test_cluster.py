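import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from milkscreen import simulate as sim
from milkscreen.cluster import (
    COV_RIDGE_ABS,
    COV_RIDGE_REL,
    ClusterModel,
    evaluate_clusters,
    fit_cluster_latent,
    fit_gmm,
    gmm_labels,
    gmm_log_density,
    max_window_fraction,
    merge_clusters,
    merge_map_from_pairs,
    responsibilities,
    split_train_test,
    suggest_instrument_merges,
    sweep_k,
)
from milkscreen.errors import DataError, FitError
from milkscreen.preprocess import apply_scaler, preprocess_pipeline

from .conftest import make_set


def _blobs(seed=0, centers=((0.0, 8.0)), n=30, d=6):
    rng = np.random.default_rng(seed)
    parts = [rng.normal(c, 0.3, size=(n, d)) for c in centers]
    X = np.vstack(parts)
    y = np.repeat(np.arange(len(centers)), n)
    return X, y


class TestClusterLatent:
    def test_robust_scaled_training_stats(self, deriv_200):
        scaler, basis = fit_cluster_latent(deriv_200)
        Z = apply_scaler(deriv_200.absorbance, scaler)
        np.testing.assert_allclose(np.median(Z, axis=0), 0.0, atol=1e-10)
        q25, q75 = np.percentile(Z, [25, 75], axis=0)
        np.testing.assert_allclose(q75 - q25, 1.0, atol=1e-10)

    def test_projection_inverse_in_span(self, deriv_200):
        scaler, basis = fit_cluster_latent(deriv_200)
        coeff = np.random.default_rng(0).normal(size=basis.n_components)
        x = basis.reconstruct(coeff)
        np.testing.assert_allclose(basis.reconstruct(basis.project(x)), x, atol=1e-10)

    def test_too_few_samples(self, deriv_200):
        with pytest.raises(FitError):
            fit_cluster_latent(deriv_200.take(np.arange(10)))

    def test_component_cap_by_rank(self, deriv_200):
        scaler, basis = fit_cluster_latent(deriv_200.take(np.arange(26)))
        assert basis.n_components <= 25


class TestFitGMM:
    def test_k1_closed_form_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 4))
        fit = fit_gmm(X, K=1, n_init=2, seed=0)
        np.testing.assert_allclose(fit.params.means[0], X.mean(axis=0), atol=1e-8)
        ml_cov = np.cov(X, rowvar=False, ddof=0)
        ridge = COV_RIDGE_REL * np.trace(ml_cov) / 4 + COV_RIDGE_ABS
        want_cov = ml_cov + ridge * np.eye(4)
        np.testing.assert_allclose(fit.params.covariances[0], want_cov, atol=1e-8)
        want_ll = multivariate_normal(X.mean(axis=0), want_cov).logpdf(X).sum()
        assert fit.log_likelihood == pytest.approx(want_ll, abs=1e-6)

    def test_two_blobs_ari_one(self):
        X, y = _blobs(seed=1, centers=(0.0, 8.0))
        fit = fit_gmm(X, K=2, n_init=5, seed=0)
        labels = gmm_labels(X, fit.params)
        assert adjusted_rand_score(y, labels) == 1.0

    def test_best_of_restarts_dominates(self):
        X, _ = _blobs(seed=2, centers=(0.0, 3.0, 6.0), n=20)
        best5 = fit_gmm(X, K=3, n_init=5, seed=7)
        single = fit_gmm(X, K=3, n_init=1, seed=7)  # restart 0 of the same schedule
        assert best5.log_likelihood >= single.log_likelihood - 1e-9

    def test_em_monotone_loglik(self):
        X, _ = _blobs(seed=4, centers=(0.0, 2.0), n=25)
        fit = fit_gmm(X, K=2, n_init=3, seed=1)
        trace = np.array(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_responsibilities_sum_to_one(self):
        X, _ = _blobs(seed=5, centers=(0.0, 5.0))
        fit = fit_gmm(X, K=2, n_init=2, seed=0)
        resp = responsibilities(X, fit.params)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)
        assert fit.params.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_more_components_than_samples(self):
        with pytest.raises(FitError):
            fit_gmm(np.zeros((5, 2)), K=5, n_init=1, seed=0)

    def test_determinism(self):
        X, _ = _blobs(seed=6, centers=(0.0, 4.0))
        a = fit_gmm(X, K=2, n_init=3, seed=9)
        b = fit_gmm(X, K=2, n_init=3, seed=9)
        np.testing.assert_array_equal(a.params.means, b.params.means)
        assert a.log_likelihood == b.log_likelihood


class TestSweepK:
    def test_entry_count_and_partition(self):
        X, _ = _blobs(seed=7, centers=(0.0, 4.0, 8.0, 12.0, 16.0), n=12, d=5)
        base = make_set(X.shape[0], n_points=5, seed=7)
        sset = base.with_absorbance(X)
        results = sweep_k(X, sset, k_min=4, k_max=6, n_init=3, seed=0)
        assert [K for K, _, _ in results] == [4, 5, 6]
        for _, _, diag in results:
            assert diag.sizes.sum() == X.shape[0]

    def test_reproducible(self):
        X, _ = _blobs(seed=8, centers=(0.0, 5.0, 10.0), n=12, d=4)
        sset = make_set(X.shape[0], n_points=4, seed=8).with_absorbance(X)
        r1 = sweep_k(X, sset, k_min=4, k_max=5, n_init=2, seed=3)
        r2 = sweep_k(X, sset, k_min=4, k_max=5, n_init=2, seed=3)
        for (_, f1, _), (_, f2, _) in zip(r1, r2):
            assert f1.log_likelihood == f2.log_likelihood

    def test_silhouette_peak_near_planted_k(self):
        # 10 well-separated planted groups in the cluster latent space
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(11)
        centers = rng.normal(0, 6.0, size=(10, 8))
        X = np.vstack([rng.normal(c, 0.3, size=(12, 8)) for c in centers])
        sset = make_set(120, n_points=8, seed=11).with_absorbance(X)
        results = sweep_k(X, sset, k_min=4, k_max=20, n_init=5, seed=2)
        sil = {}
        for K, fit, _ in results:
            labels = gmm_labels(X, fit.params)
            if np.unique(labels).size > 1:
                sil[K] = silhouette_score(X, labels)
        best_k = max(sil, key=sil.get)
        assert 8 <= best_k <= 12


class TestEvaluateClusters:
    def test_single_cluster_degenerate(self, deriv_200):
        sub = deriv_200.take(np.arange(30))
        latent = np.random.default_rng(0).normal(size=(30, 3))
        diag = evaluate_clusters(np.zeros(30, dtype=int), sub, latent)
        assert diag.degenerate
        assert np.isnan(diag.within_between.loc[0, "ratio"])

    def test_unique_farm_printed_case(self):
        labels = np.zeros(529, dtype=int)
        farms = [f"F{i % 227}" for i in range(529)]
        sset = make_set(529, n_points=4)
        sset.meta["farm_id"] = farms
        latent = np.random.default_rng(1).normal(size=(529, 3))
        diag = evaluate_clusters(labels, sset, latent)
        assert diag.unique_farm_pct[0] == pytest.approx(100 * 227 / 529, abs=1e-9)
        assert round(diag.unique_farm_pct[0], 1) == 42.9

    def test_fringe_instrument_entropy_near_zero(self, small_cfg):
        atyp = sim.generate_atypical(sim.Archetype.INSTRUMENT_FRINGE, 30, small_cfg, seed=5)
        deriv = preprocess_pipeline(atyp)
        latent = np.random.default_rng(2).normal(size=(30, 3))
        diag = evaluate_clusters(np.zeros(30, dtype=int), deriv, latent)
        counts = diag.instrument_counts.loc[0].to_numpy(dtype=float)
        assert counts.max() >= 28  # all but (up to) two on one instrument
        # entropy of the dominant-instrument distribution is near zero
        assert diag.instrument_entropy[0] < 0.3

    def test_permutation_invariance(self, deriv_200):
        sub = deriv_200.take(np.arange(40))
        latent = np.random.default_rng(3).normal(size=(40, 4))
        labels = np.random.default_rng(4).integers(0, 3, size=40)
        diag = evaluate_clusters(labels, sub, latent)
        perm = np.random.default_rng(5).permutation(40)
        diag_p = evaluate_clusters(labels[perm], sub.take(perm), latent[perm])
        pd.testing.assert_series_equal(diag.sizes, diag_p.sizes)
        pd.testing.assert_frame_equal(diag.within_between, diag_p.within_between)
        pd.testing.assert_series_equal(diag.unique_farm_pct, diag_p.unique_farm_pct)

    def test_14_day_concentration(self):
        ts = pd.to_datetime(
            ["2019-01-01", "2019-01-05", "2019-01-10", "2019-06-01"]
        )
        conc = max_window_fraction(ts, np.zeros(4, dtype=int), window_days=14)
        assert conc[0] == pytest.approx(0.75)


class TestMerging:
    def test_eleven_components_one_pair(self):
        mm = merge_map_from_pairs(11, [(3, 7)])
        assert np.unique(mm).size == 10
        assert mm[3] == mm[7]

    def test_empty_pairs_identity_sizes(self):
        sizes = [5, 10, 3]
        mm = merge_map_from_pairs(3, [], sizes=sizes)
        # renumbered by descending size: label 1 (10) -> 0, 0 (5) -> 1, 2 (3) -> 2
        np.testing.assert_array_equal(mm, [1, 0, 2])

    def test_chained_pairs_transitive(self):
        mm = merge_map_from_pairs(5, [(0, 1), (1, 2)])
        assert mm[0] == mm[1] == mm[2]
        assert np.unique(mm).size == 3

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            merge_map_from_pairs(3, [(0, 5)])

    def test_merge_clusters_uses_label_sizes(self):
        X, y = _blobs(seed=9, centers=(0.0, 6.0))
        fit = fit_gmm(X, K=2, n_init=2, seed=0)
        labels = gmm_labels(X, fit.params)
        mm = merge_clusters(fit.params, [(0, 1)], labels=labels)
        assert np.unique(mm).size == 1


class TestSuggestInstrumentMerges:
    def _diag(self, inst_rows, comp_medians):
        sizes = pd.Series({i: 10 for i in range(len(inst_rows))})
        inst = pd.DataFrame(inst_rows, columns=["I1", "I2", "I3", "I4"])
        recs = []
        analytes = ["fat", "protein", "lactose", "urea", "freezing_point", "milk_fat_acidity"]
        for c, med in enumerate(comp_medians):
            for a in analytes:
                recs.append(
                    {"cluster": c, "analyte": a, "median": med, "iqr": 1.0,
                     "q25": med - 0.5, "q75": med + 0.5}
                )
        comp = pd.DataFrame(recs).set_index(["cluster", "analyte"])
        from milkscreen.cluster import ClusterDiagnostics

        return ClusterDiagnostics(
            sizes=sizes, within_between=pd.DataFrame(), unique_farm_pct=None,
            temporal_concentration_14d=None, instrument_counts=inst,
            instrument_entropy=None, composition=comp,
        )

    def test_planted_split_scenario(self):
        diag = self._diag(
            inst_rows=[[5, 5, 0, 0], [0, 0, 5, 5], [2, 2, 3, 3]],
            comp_medians=[1.0, 1.1, 9.0],
        )
        assert suggest_instrument_merges(diag) == [(0, 1)]

    def test_identical_instrument_mix_no_proposal(self):
        diag = self._diag(
            inst_rows=[[5, 5, 5, 5], [5, 5, 5, 5]], comp_medians=[1.0, 1.1]
        )
        assert suggest_instrument_merges(diag) == []

    def test_single_cluster_empty(self):
        diag = self._diag(inst_rows=[[5, 5, 5, 5]], comp_medians=[1.0])
        assert suggest_instrument_merges(diag) == []

    def test_different_composition_no_proposal(self):
        diag = self._diag(
            inst_rows=[[5, 5, 0, 0], [0, 0, 5, 5]], comp_medians=[1.0, 9.0]
        )
        assert suggest_instrument_merges(diag) == []


class TestClusterModel:
    def test_merge_map_validation(self):
        X, _ = _blobs(seed=10, centers=(0.0, 6.0))
        scaler, basis = fit_cluster_latent(np.vstack([X, X]), n_components=3)
        fit = fit_gmm(basis.project(apply_scaler(X, scaler)), K=2, n_init=2, seed=0)
        with pytest.raises(FitError):
            ClusterModel(scaler=scaler, basis=basis, gmm=fit.params,
                         merge_map=np.array([0, 2]), best_loglik=0.0)

    def test_split_train_test_printed_case(self):
        tr, te = split_train_test(5671, 0.75, seed=0)
        assert len(tr) == 4253
        assert len(te) == 1418
        assert np.intersect1d(tr, te).size == 0

    def test_split_deterministic(self):
        a, _ = split_train_test(100, seed=4)
        b, _ = split_train_test(100, seed=4)
        np.testing.assert_array_equal(a, b)
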