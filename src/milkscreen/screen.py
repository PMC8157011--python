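"""Untargeted screening: normal-milk fingerprint and anomaly scores.

The model is a 16-component PCA of standard-scaled derivative spectra.
Each spectrum gets two deviation measures — the Mahalanobis distance of its
latent coordinates to the training distribution, and the RMSE between the
(scaled) spectrum and its PCA reconstruction — which are z-standardized
with frozen training statistics and summed into a single anomaly score.
Fitting performs two (fit -> trim top 0.1%) passes before the final fit.
Scores are thresholded per calendar month at a fixed prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FitError, ShapeError, StateError
from .preprocess import PCABasis, ScalerParams, apply_scaler, fit_pca, fit_scaler
from .spectra_io import SpectrumSet, register_model_class

logger = logging.getLogger(__name__)

#: Ridge added to the latent covariance diagonal, as a fraction of
#: trace/n_components (numerical safety for the precision matrix).
COV_RIDGE_FRACTION = 1e-10


def filter_freezing_point(
    sset: SpectrumSet, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> SpectrumSet:
    """Drop samples whose freezing point lies strictly outside the
    [lower_pct, upper_pct] percentile cuts of the input distribution.

    Cuts use order statistics ('lower' for the lower cut, 'higher' for the
    upper) so degenerate inputs — ties, or just two samples — survive
    intact.  Survivors keep their order.
    """
    fp = sset.meta["freezing_point"].to_numpy(dtype=float)
    bad = ~np.isfinite(fp)
    if bad.any():
        ids = sset.meta.loc[bad, "sample_id"].tolist()
        raise DataError(f"missing freezing point for samples: {ids[:10]}")
    lo = np.percentile(fp, lower_pct, method="lower")
    hi = np.percentile(fp, upper_pct, method="higher")
    keep = (fp >= lo) & (fp <= hi)
    logger.info(
        "freezing-point filter removed %d of %d samples", int((~keep).sum()), keep.size
    )
    return sset.take(np.flatnonzero(keep))


@register_model_class
@dataclass
class ScreeningModel:
    """Frozen normal-milk fingerprint (see module docstring)."""

    stage = "screen"

    scaler: ScalerParams
    basis: PCABasis
    latent_mean: np.ndarray
    latent_precision: np.ndarray
    maha_mean: float
    maha_sd: float
    resid_mean: float
    resid_sd: float
    trim_history: list = field(default_factory=list)
    n_train_final: int = 0
    composition_ref: pd.DataFrame | None = None  # analyte -> mean, sd, n

    @property
    def n_components(self) -> int:
        return self.basis.n_components

    # -- persistence ----------------------------------------------------
    def to_manifest(self) -> dict:
        return {
            "n_components": self.n_components,
            "maha_mean": self.maha_mean,
            "maha_sd": self.maha_sd,
            "resid_mean": self.resid_mean,
            "resid_sd": self.resid_sd,
            "trim_history": [int(k) for k in self.trim_history],
            "n_train_final": int(self.n_train_final),
            "scaler_kind": self.scaler.kind,
            "composition_analytes": (
                list(self.composition_ref.index) if self.composition_ref is not None else []
            ),
        }

    def to_arrays(self) -> dict:
        arrays = {
            "scaler_center": self.scaler.center,
            "scaler_scale": self.scaler.scale,
            "components": self.basis.components,
            "pca_mean": self.basis.mean,
            "explained_variance_ratio": self.basis.explained_variance_ratio,
            "latent_mean": self.latent_mean,
            "latent_precision": self.latent_precision,
        }
        if self.composition_ref is not None:
            arrays["composition_ref"] = self.composition_ref[["mean", "sd", "n"]].to_numpy()
        return arrays

    @classmethod
    def from_payload(cls, params: dict, arrays: dict) -> "ScreeningModel":
        comp = None
        if "composition_ref" in arrays:
            comp = pd.DataFrame(
                arrays["composition_ref"],
                index=params["composition_analytes"],
                columns=["mean", "sd", "n"],
            )
        return cls(
            scaler=ScalerParams(
                kind=params["scaler_kind"],
                center=arrays["scaler_center"],
                scale=arrays["scaler_scale"],
            ),
            basis=PCABasis(
                components=arrays["components"],
                mean=arrays["pca_mean"],
                explained_variance_ratio=arrays["explained_variance_ratio"],
            ),
            latent_mean=arrays["latent_mean"],
            latent_precision=arrays["latent_precision"],
            maha_mean=float(params["maha_mean"]),
            maha_sd=float(params["maha_sd"]),
            resid_mean=float(params["resid_mean"]),
            resid_sd=float(params["resid_sd"]),
            trim_history=list(params["trim_history"]),
            n_train_final=int(params["n_train_final"]),
            composition_ref=comp,
        )


def _latent_and_residual(X_deriv: np.ndarray, model: ScreeningModel):
    """Scaled projection + per-sample reconstruction RMSE (scaled space)."""
    Xs = apply_scaler(X_deriv, model.scaler)
    latent = model.basis.project(Xs)
    recon = model.basis.reconstruct(latent)
    resid = np.sqrt(np.mean((Xs - recon) ** 2, axis=1))
    return latent, resid


def mahalanobis_distance(latent, model: ScreeningModel):
    """sqrt((x - mu)^T P (x - mu)) for one latent vector or a batch."""
    x = np.asarray(latent, dtype=float)
    if not np.isfinite(x).all():
        raise DataError("non-finite latent coordinates")
    if x.shape[-1] != model.latent_mean.size:
        raise ShapeError(
            f"latent has {x.shape[-1]} dims, model has {model.latent_mean.size}"
        )
    diff = x - model.latent_mean
    q = np.einsum("...i,ij,...j->...", diff, model.latent_precision, diff)
    return np.sqrt(np.maximum(q, 0.0))


def reconstruction_residual(spectrum_scaled, model: ScreeningModel):
    """RMSE between a scaled spectrum and its 16-component reconstruction.

    ``spectrum_scaled`` must already be band-selected, differentiated and
    scaled with the model's scaler.
    """
    x = np.atleast_2d(np.asarray(spectrum_scaled, dtype=float))
    if x.shape[-1] != model.basis.n_points:
        raise ShapeError(
            f"spectrum has {x.shape[-1]} points, model expects {model.basis.n_points}"
        )
    latent = (x - model.basis.mean) @ model.basis.components.T
    recon = latent @ model.basis.components + model.basis.mean
    out = np.sqrt(np.mean((x - recon) ** 2, axis=1))
    return out[0] if np.ndim(spectrum_scaled) == 1 else out


def _month_key(timestamps) -> pd.Series:
    return pd.DatetimeIndex(timestamps).strftime("%Y-%m")


def anomaly_scores(sset: SpectrumSet, model: ScreeningModel) -> pd.DataFrame:
    """Per-sample anomaly results for a derivative-space spectrum set.

    Returns a DataFrame with columns ``sample_id, mahalanobis,
    residual_rmse, anomaly_score, month, flagged`` (flagged is False until
    :func:`flag_monthly` is applied).
    """
    if model.maha_sd <= 0 or model.resid_sd <= 0:
        raise StateError("screening model is not fitted")
    latent, resid = _latent_and_residual(sset.absorbance, model)
    maha = mahalanobis_distance(latent, model)
    score = (maha - model.maha_mean) / model.maha_sd + (
        resid - model.resid_mean
    ) / model.resid_sd
    return pd.DataFrame(
        {
            "sample_id": sset.meta["sample_id"].to_numpy(),
            "mahalanobis": maha,
            "residual_rmse": resid,
            "anomaly_score": score,
            "month": _month_key(sset.meta["timestamp"]),
            "flagged": False,
        }
    )


def _fit_pass(X: np.ndarray, n_components: int):
    scaler = fit_scaler(X, kind="standard")
    Xs = apply_scaler(X, scaler)
    basis = fit_pca(Xs, n_components)
    latent = basis.project(Xs)
    latent_mean = latent.mean(axis=0)
    cov = np.cov(latent, rowvar=False)
    cov = np.atleast_2d(cov)
    ridge = COV_RIDGE_FRACTION * np.trace(cov) / cov.shape[0]
    cov = cov + ridge * np.eye(cov.shape[0])
    precision = np.linalg.inv(cov)
    precision = 0.5 * (precision + precision.T)
    recon = basis.reconstruct(latent)
    resid = np.sqrt(np.mean((Xs - recon) ** 2, axis=1))
    diff = latent - latent_mean
    maha = np.sqrt(
        np.maximum(np.einsum("ni,ij,nj->n", diff, precision, diff), 0.0)
    )
    return scaler, basis, latent_mean, precision, maha, resid


def fit_screening_model(
    sset: SpectrumSet,
    n_components: int = 16,
    trim_fraction: float = 0.001,
    n_iterations: int = 2,
) -> ScreeningModel:
    """Fit the fingerprint on a derivative-space spectrum set.

    Performs ``n_iterations`` (fit -> remove ceil(trim_fraction * n)
    highest-scoring samples) passes, then a final fit on the survivors.
    The score standardization (maha/residual mean and SD) is frozen from
    the final pass.  Input must already be band-selected + differentiated;
    the freezing-point filter is the caller's responsibility.
    """
    n = sset.n_samples
    if n_components >= n:
        raise FitError(f"n_components={n_components} >= n_samples={n}")
    keep = np.arange(n)
    trim_history: list[int] = []
    if trim_fraction > 0:
        for _ in range(n_iterations):
            scaler, basis, mu, prec, maha, resid = _fit_pass(
                sset.absorbance[keep], n_components
            )
            score = (maha - maha.mean()) / maha.std() + (resid - resid.mean()) / resid.std()
            k = int(np.ceil(trim_fraction * keep.size))
            ids = sset.meta["sample_id"].to_numpy()[keep]
            order = np.lexsort((ids, -score))  # score desc, sample_id asc
            drop = set(order[:k].tolist())
            keep = np.array([keep[i] for i in range(keep.size) if i not in drop])
            trim_history.append(k)
    else:
        trim_history = [0] * n_iterations

    scaler, basis, mu, prec, maha, resid = _fit_pass(sset.absorbance[keep], n_components)
    if maha.std() <= 0 or resid.std() <= 0:
        raise FitError("degenerate training scores (zero spread)")

    analytes = ["fat", "protein", "lactose", "urea", "freezing_point", "milk_fat_acidity"]
    comp = sset.meta.iloc[keep][analytes]
    composition_ref = pd.DataFrame(
        {
            "mean": comp.mean(),
            "sd": comp.std(ddof=1),
            "n": comp.notna().sum().astype(float),
        }
    )

    model = ScreeningModel(
        scaler=scaler,
        basis=basis,
        latent_mean=mu,
        latent_precision=prec,
        maha_mean=float(maha.mean()),
        maha_sd=float(maha.std()),
        resid_mean=float(resid.mean()),
        resid_sd=float(resid.std()),
        trim_history=trim_history,
        n_train_final=int(keep.size),
        composition_ref=composition_ref,
    )
    logger.info(
        "screening model: %d components, EVR(sum)=%.4f, trims=%s, n_final=%d",
        model.n_components,
        float(basis.explained_variance_ratio.sum()),
        trim_history,
        keep.size,
    )
    return model


def flag_monthly(results: pd.DataFrame, prevalence: float = 0.001) -> pd.DataFrame:
    """Flag, per calendar month, the floor(prevalence * n_month) highest
    anomaly scores.  Ties break by (score desc, sample_id asc)."""
    out = results.copy()
    out["flagged"] = False
    for _, grp in out.groupby("month", sort=False):
        k = int(np.floor(prevalence * len(grp)))
        if k <= 0:
            continue
        order = grp.sort_values(
            ["anomaly_score", "sample_id"], ascending=[False, True], kind="mergesort"
        )
        out.loc[order.index[:k], "flagged"] = True
    return out


def instrument_silhouette(latent: np.ndarray, instrument_ids) -> float:
    """Silhouette of instrument labels in latent space (diagnostic only;
    values near 0 mean instruments do not form distinct clusters)."""
    from sklearn.metrics import silhouette_score

    labels = np.asarray(instrument_ids)
    if np.unique(labels).size < 2:
        return 0.0
    return float(silhouette_score(np.asarray(latent), labels))
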