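"""Assignment of new atypical spectra to the discovered clusters.

An RBF support-vector classifier is trained on the cluster latent
coordinates with the final cluster labels as classes; hyperparameters come
from a grid search under seeded stratified cross-validation scored by
weighted F1.  All transforms (robust scaler, eigenvectors) are frozen from
the clustering stage.  An optional typicality gate marks new spectra whose
GMM log-density falls below a training percentile as "unassignable"
without changing the primary label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .cluster import ClusterModel, GMMParams, gmm_log_density
from .errors import DataError, FitError, ShapeError
from .preprocess import PCABasis, ScalerParams
from .spectra_io import SpectrumSet, register_model_class

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_FACTORS = (0.1, 1.0, 10.0)


def weighted_f1(true_labels, predicted_labels) -> float:
    """Support-weighted mean of per-class F1 scores.

    Per-class F1 is the harmonic mean of precision and recall, defined as 0
    when precision + recall is 0; weights are proportional to true-class
    support.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.size != y_pred.size:
        raise DataError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size == 0:
        raise DataError("need at least one sample")
    classes = np.unique(y_true)
    total = 0.0
    for c in classes:
        tp = float(np.sum((y_true == c) & (y_pred == c)))
        fp = float(np.sum((y_true != c) & (y_pred == c)))
        fn = float(np.sum((y_true == c) & (y_pred != c)))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        total += f1 * np.sum(y_true == c)
    return total / y_true.size


def _default_grid(latent: np.ndarray) -> dict:
    var = float(np.asarray(latent).var())
    g0 = 1.0 / (latent.shape[1] * var) if var > 0 else 1.0
    return {
        "C": list(DEFAULT_C_GRID),
        "gamma": [g0 * f for f in DEFAULT_GAMMA_FACTORS],
    }


@register_model_class
@dataclass
class ClassifierModel:
    """Trained cluster-assignment classifier plus frozen transforms."""

    stage = "classifier"

    scaler: ScalerParams
    basis: PCABasis
    latent_train: np.ndarray
    labels_train: np.ndarray
    classes: np.ndarray
    C: float
    gamma: float
    cv_f1_weighted: float
    grid: dict
    n_folds: int
    gmm: GMMParams | None = None
    density_threshold: float | None = None

    def __post_init__(self):
        self.latent_train = np.asarray(self.latent_train, dtype=float)
        self.labels_train = np.asarray(self.labels_train, dtype=int)
        self.classes = np.asarray(self.classes, dtype=int)
        if not 0.0 <= self.cv_f1_weighted <= 1.0:
            raise FitError("cv_f1_weighted must lie in [0, 1]")
        self._svc = None

    def _fit_svc(self):
        from sklearn.svm import SVC

        svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        svc.fit(self.latent_train, self.labels_train)
        return svc

    @property
    def svc(self):
        if self._svc is None:
            self._svc = self._fit_svc()
        return self._svc

    def predict_latent(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=float)
        if latent.shape[-1] != self.latent_train.shape[1]:
            raise ShapeError(
                f"latent has {latent.shape[-1]} dims, classifier expects "
                f"{self.latent_train.shape[1]}"
            )
        return self.svc.predict(np.atleast_2d(latent))

    # -- persistence ----------------------------------------------------
    def to_manifest(self) -> dict:
        return {
            "C": self.C,
            "gamma": self.gamma,
            "cv_f1_weighted": self.cv_f1_weighted,
            "grid": {k: list(map(float, v)) for k, v in self.grid.items()},
            "n_folds": int(self.n_folds),
            "scaler_kind": self.scaler.kind,
            "has_gmm": self.gmm is not None,
            "density_threshold": self.density_threshold,
        }

    def to_arrays(self) -> dict:
        arrays = {
            "scaler_center": self.scaler.center,
            "scaler_scale": self.scaler.scale,
            "components": self.basis.components,
            "pca_mean": self.basis.mean,
            "explained_variance_ratio": self.basis.explained_variance_ratio,
            "latent_train": self.latent_train,
            "labels_train": self.labels_train,
            "classes": self.classes,
        }
        if self.gmm is not None:
            arrays["gmm_weights"] = self.gmm.weights
            arrays["gmm_means"] = self.gmm.means
            arrays["gmm_covariances"] = self.gmm.covariances
        return arrays

    @classmethod
    def from_payload(cls, params: dict, arrays: dict) -> "ClassifierModel":
        gmm = None
        if params.get("has_gmm"):
            gmm = GMMParams(
                weights=arrays["gmm_weights"],
                means=arrays["gmm_means"],
                covariances=arrays["gmm_covariances"],
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
            latent_train=arrays["latent_train"],
            labels_train=arrays["labels_train"],
            classes=arrays["classes"],
            C=float(params["C"]),
            gamma=float(params["gamma"]),
            cv_f1_weighted=float(params["cv_f1_weighted"]),
            grid=params["grid"],
            n_folds=int(params["n_folds"]),
            gmm=gmm,
            density_threshold=(
                float(params["density_threshold"])
                if params.get("density_threshold") is not None
                else None
            ),
        )


def fit_classifier(
    latent_train: np.ndarray,
    labels,
    grid: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    transforms: tuple[ScalerParams, PCABasis] | ClusterModel | None = None,
    density_gate_pct: float | None = None,
) -> ClassifierModel:
    """Grid-searched RBF-SVC on cluster latent coordinates.

    The best (C, gamma) by mean CV weighted F1 is refitted on all training
    data.  Classes with fewer members than ``cv_folds`` trigger a warning
    and a fold-count reduction to the minimum class size.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    X = np.asarray(latent_train, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.size:
        raise DataError("latent and labels must be aligned")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise FitError("need at least two classes to fit a classifier")
    min_count = int(counts.min())
    n_folds = cv_folds
    if min_count < cv_folds:
        n_folds = max(min_count, 2)
        warnings.warn(
            f"smallest class has {min_count} member(s); reducing CV folds "
            f"from {cv_folds} to {n_folds}",
            stacklevel=2,
        )
    grid = grid or _default_grid(X)

    # classes too small even for 2 folds are held out of CV scoring but kept
    # in the final refit
    cv_classes = classes[counts >= 2]
    cv_mask = np.isin(y, cv_classes)
    if cv_classes.size < 2:
        raise FitError("need at least two classes with >= 2 members for CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_idx = np.flatnonzero(cv_mask)
    folds = [
        (cv_idx[tr], cv_idx[te]) for tr, te in skf.split(X[cv_mask], y[cv_mask])
    ]
    best = None  # (score, C, gamma)
    for C in grid["C"]:
        for gamma in grid["gamma"]:
            scores = []
            for tr, te in folds:
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit(X[tr], y[tr])
                scores.append(weighted_f1(y[te], svc.predict(X[te])))
            mean_score = float(np.mean(scores))
            if best is None or mean_score > best[0]:
                best = (mean_score, float(C), float(gamma))
    cv_score, C, gamma = best
    logger.info("classifier grid search: C=%g gamma=%g cv_f1=%.4f", C, gamma, cv_score)

    scaler = basis = None
    gmm = None
    if isinstance(transforms, ClusterModel):
        scaler, basis, gmm = transforms.scaler, transforms.basis, transforms.gmm
    elif transforms is not None:
        scaler, basis = transforms
    if scaler is None:
        # transform-free classifier: identity placeholder over latent dims
        scaler = ScalerParams(kind="robust", center=np.zeros(X.shape[1]), scale=np.ones(X.shape[1]))
        basis = PCABasis(
            components=np.eye(X.shape[1]),
            mean=np.zeros(X.shape[1]),
            explained_variance_ratio=np.full(X.shape[1], 1.0 / X.shape[1]),
        )

    density_threshold = None
    if density_gate_pct is not None and gmm is not None:
        dens = gmm_log_density(X, gmm)
        density_threshold = float(np.percentile(dens, density_gate_pct))

    return ClassifierModel(
        scaler=scaler,
        basis=basis,
        latent_train=X,
        labels_train=y,
        classes=classes,
        C=C,
        gamma=gamma,
        cv_f1_weighted=cv_score,
        grid=grid,
        n_folds=n_folds,
        gmm=gmm,
        density_threshold=density_threshold,
    )


def classify(new_set, classifier: ClassifierModel):
    """Assign final cluster labels to new derivative-space spectra.

    Applies the frozen robust scaler and eigenvectors, then the decision
    model.  Returns a DataFrame with ``sample_id, final_label`` plus, when
    the density gate is configured, ``gmm_log_density`` and
    ``unassignable`` columns.
    """
    import pandas as pd

    if isinstance(new_set, SpectrumSet):
        X_deriv = new_set.absorbance
        ids = new_set.meta["sample_id"].to_numpy()
    else:
        X_deriv = np.asarray(new_set, dtype=float)
        ids = np.arange(X_deriv.shape[0])
    Xs = (X_deriv - classifier.scaler.center) / classifier.scaler.scale
    latent = classifier.basis.project(Xs)
    labels = classifier.predict_latent(latent)
    out = pd.DataFrame({"sample_id": ids, "final_label": labels})
    if classifier.gmm is not None:
        dens = gmm_log_density(latent, classifier.gmm)
        out["gmm_log_density"] = dens
        if classifier.density_threshold is not None:
            out["unassignable"] = dens < classifier.density_threshold
    return out
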