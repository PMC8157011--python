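import numpy as np
import pandas as pd
import pytest

from milkscreen import simulate as sim
from milkscreen.errors import DataError, FitError, ShapeError
from milkscreen.preprocess import apply_scaler, preprocess_pipeline
from milkscreen.screen import (
    ScreeningModel,
    anomaly_scores,
    filter_freezing_point,
    fit_screening_model,
    flag_monthly,
    instrument_silhouette,
    mahalanobis_distance,
    reconstruction_residual,
)

from .conftest import make_set


class TestFreezingPointFilter:
    def test_oracle_count_1000_distinct(self):
        rng = np.random.default_rng(0)
        fp = rng.normal(-0.52, 0.01, 1000)
        assert np.unique(fp).size == 1000
        s = make_set(1000, n_points=6)
        s.meta["freezing_point"] = fp
        survivors = filter_freezing_point(s)
        # oracle: sort and count order statistics retained by the cuts
        srt = np.sort(fp)
        lo = srt[int(np.floor(0.01 * 999))]
        hi = srt[int(np.ceil(0.99 * 999))]
        expected = int(((fp >= lo) & (fp <= hi)).sum())
        assert survivors.n_samples == expected
        assert 978 <= survivors.n_samples <= 982

    def test_identical_values_all_survive(self):
        s = make_set(50, n_points=6)
        s.meta["freezing_point"] = -0.52
        assert filter_freezing_point(s).n_samples == 50

    def test_two_samples_survive(self):
        s = make_set(2, n_points=6)
        assert filter_freezing_point(s).n_samples == 2

    def test_order_preserved(self):
        s = make_set(100, n_points=6, seed=3)
        out = filter_freezing_point(s)
        ids = s.meta["sample_id"].tolist()
        kept = out.meta["sample_id"].tolist()
        assert kept == [i for i in ids if i in set(kept)]

    def test_missing_freezing_point(self):
        s = make_set(10, n_points=6)
        s.meta.loc[3, "freezing_point"] = np.nan
        with pytest.raises(DataError, match="T0003"):
            filter_freezing_point(s)


def _toy_model(k=16, seed=0):
    """Screening model with random orthonormal basis and random SPD latent
    covariance, for oracle checks."""
    rng = np.random.default_rng(seed)
    p = 40
    Q, _ = np.linalg.qr(rng.normal(size=(p, p)))
    components = Q[:, :k].T
    A = rng.normal(size=(k, k))
    cov = A @ A.T + 0.5 * np.eye(k)
    precision = np.linalg.inv(cov)
    precision = 0.5 * (precision + precision.T)
    from milkscreen.preprocess import PCABasis, ScalerParams

    return ScreeningModel(
        scaler=ScalerParams(kind="standard", center=np.zeros(p), scale=np.ones(p)),
        basis=PCABasis(
            components=components,
            mean=np.zeros(p),
            explained_variance_ratio=np.full(k, 1.0 / k),
        ),
        latent_mean=rng.normal(size=k),
        latent_precision=precision,
        maha_mean=1.0,
        maha_sd=0.5,
        resid_mean=0.1,
        resid_sd=0.05,
        n_train_final=100,
    ), cov


class TestMahalanobis:
    def test_zero_at_center(self):
        model, _ = _toy_model()
        assert mahalanobis_distance(model.latent_mean, model) == 0.0

    def test_pythagorean_with_identity_precision(self):
        model, _ = _toy_model()
        model.latent_precision = np.eye(16)
        x = model.latent_mean.copy()
        x[0] += 3.0
        x[1] += 4.0
        assert mahalanobis_distance(x, model) == pytest.approx(5.0)

    def test_dense_inverse_oracle(self):
        model, cov = _toy_model(seed=7)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 16))
        got = mahalanobis_distance(X, model)
        inv = np.linalg.inv(cov)
        want = np.array(
            [np.sqrt((x - model.latent_mean) @ inv @ (x - model.latent_mean)) for x in X]
        )
        np.testing.assert_allclose(got, want, atol=1e-8, rtol=1e-8)

    def test_non_finite_rejected(self):
        model, _ = _toy_model()
        x = model.latent_mean.copy()
        x[0] = np.inf
        with pytest.raises(DataError):
            mahalanobis_distance(x, model)

    def test_monotone_along_eigenvectors(self):
        model, cov = _toy_model(seed=3)
        w, V = np.linalg.eigh(np.linalg.inv(model.latent_precision))
        for j in range(0, 16, 5):
            ds = [
                mahalanobis_distance(model.latent_mean + t * V[:, j], model)
                for t in (0.0, 0.5, 1.0, 2.0, 5.0)
            ]
            assert np.all(np.diff(ds) >= -1e-12)


class TestReconstructionResidual:
    def test_zero_vector(self):
        model, _ = _toy_model()
        assert reconstruction_residual(np.zeros(40), model) == pytest.approx(0.0)

    def test_in_span_residual_tiny(self):
        model, _ = _toy_model()
        x = model.basis.components.T @ np.random.default_rng(2).normal(size=16)
        assert reconstruction_residual(x, model) < 1e-10

    def test_explicit_projection_oracle(self):
        model, _ = _toy_model()
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 40))
        got = reconstruction_residual(X, model)
        B = model.basis.components
        want = np.sqrt(np.mean((X - X @ B.T @ B) ** 2, axis=1))
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_shape_error(self):
        model, _ = _toy_model()
        with pytest.raises(ShapeError):
            reconstruction_residual(np.zeros(13), model)


class TestFitScreeningModel:
    def test_trim_arithmetic_1000(self, deriv_1000):
        model = fit_screening_model(deriv_1000)
        assert model.trim_history == [1, 1]
        assert model.n_train_final == 998

    def test_trim_zero_single_fit(self, deriv_1000):
        model = fit_screening_model(deriv_1000, trim_fraction=0.0)
        assert model.n_train_final == 1000
        assert sum(model.trim_history) == 0

    def test_too_few_samples(self, deriv_200):
        tiny = deriv_200.take(np.arange(10))
        with pytest.raises(FitError):
            fit_screening_model(tiny, n_components=16)

    def test_precision_spd(self, screening_model_1000):
        w = np.linalg.eigvalsh(screening_model_1000.latent_precision)
        assert np.all(w > 0)
        np.testing.assert_allclose(
            screening_model_1000.latent_precision,
            screening_model_1000.latent_precision.T,
        )


class TestAnomalyScores:
    def test_training_scores_center_near_zero(self, deriv_1000, screening_model_1000):
        res = anomaly_scores(deriv_1000, screening_model_1000)
        assert abs(res["anomaly_score"].mean()) < 0.05

    def test_duplicate_identical(self, deriv_200, screening_model_1000):
        res = anomaly_scores(deriv_200, screening_model_1000)
        dup = deriv_200.take(np.array([7, 7]))
        res_dup = anomaly_scores(dup, screening_model_1000)
        assert res_dup["anomaly_score"].iloc[0] == res_dup["anomaly_score"].iloc[1]
        assert res_dup["anomaly_score"].iloc[0] == pytest.approx(
            res["anomaly_score"].iloc[7], rel=1e-12
        )

    def test_score_decomposition(self, deriv_200, screening_model_1000):
        m = screening_model_1000
        res = anomaly_scores(deriv_200, m)
        recomposed = (res["mahalanobis"] - m.maha_mean) / m.maha_sd + (
            res["residual_rmse"] - m.resid_mean
        ) / m.resid_sd
        np.testing.assert_allclose(res["anomaly_score"], recomposed, rtol=1e-12)

    def test_fringe_outlier_scores_extreme(self, small_cfg, typical_1000, screening_model_1000):
        res_train = anomaly_scores(preprocess_pipeline(typical_1000), screening_model_1000)
        cut = np.percentile(res_train["anomaly_score"], 99.9)
        fringe = sim.generate_atypical(sim.Archetype.INSTRUMENT_FRINGE, 10, small_cfg, seed=3)
        # amplify the planted ripple 10x by regenerating with a bigger factor
        cfg10 = sim.SimConfig(
            n_farms=small_cfg.n_farms,
            monthly_volume=small_cfg.monthly_volume,
            fringe_amp_factor=10 * small_cfg.fringe_amp_factor,
        )
        fringe10 = sim.generate_atypical(sim.Archetype.INSTRUMENT_FRINGE, 10, cfg10, seed=3)
        res = anomaly_scores(preprocess_pipeline(fringe10), screening_model_1000)
        assert (res["anomaly_score"] > cut).all()

    def test_instrument_silhouette_low(self, deriv_1000, screening_model_1000):
        m = screening_model_1000
        Xs = apply_scaler(deriv_1000.absorbance, m.scaler)
        latent = m.basis.project(Xs)
        sil = instrument_silhouette(latent, deriv_1000.meta["instrument_id"])
        assert sil < 0.1


class TestFlagMonthly:
    def _results(self, sizes, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        for i, n in enumerate(sizes):
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": [f"M{i}_{j:05d}" for j in range(n)],
                        "anomaly_score": rng.normal(size=n),
                        "month": f"2019-{i + 1:02d}",
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_2000_scores_two_flagged(self):
        res = self._results([2000])
        out = flag_monthly(res, prevalence=0.001)
        assert out["flagged"].sum() == 2
        top2 = res.nlargest(2, "anomaly_score")["sample_id"]
        assert set(out.loc[out["flagged"], "sample_id"]) == set(top2)

    def test_400_scores_none_flagged(self):
        out = flag_monthly(self._results([400]), prevalence=0.001)
        assert out["flagged"].sum() == 0

    def test_equal_months_equal_flags(self):
        out = flag_monthly(self._results([1500] * 12), prevalence=0.001)
        per_month = out.groupby("month")["flagged"].sum()
        assert (per_month == 1).all()

    def test_tie_break_deterministic(self):
        res = pd.DataFrame(
            {
                "sample_id": ["b", "a", "c"],
                "anomaly_score": [1.0, 1.0, 0.0],
                "month": "2019-01",
            }
        )
        # k = floor(0.4 * 3) = 1; tie on score -> lowest sample_id wins
        out = flag_monthly(res, prevalence=0.4)
        assert out.loc[out["flagged"], "sample_id"].tolist() == ["a"]
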