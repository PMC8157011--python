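"""Cluster discovery on flagged atypical spectra.

Robust scaling, a 24-component PCA latent space, and full-covariance
Gaussian mixture models fitted by EM with K-means initialization, 50
restarts per K (best final log-likelihood kept) and a sweep over K = 4..20.
Cluster quality is summarized by six diagnostics (within/between spectral
distance, sizes, unique-farm proportion, temporal concentration,
instrument distribution, composition summaries).  Final-K selection and
cluster merging are configuration decisions; an advisory helper proposes
merges of composition-identical clusters split by instrument support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.special import logsumexp

from .errors import DataError, FitError, StateError
from .preprocess import PCABasis, ScalerParams, apply_scaler, fit_pca, fit_scaler
from .spectra_io import SpectrumSet, register_model_class

logger = logging.getLogger(__name__)

#: Relative ridge added to each component covariance diagonal
#: (1e-6 x mean diagonal, with a tiny absolute floor).
COV_RIDGE_REL = 1e-6
COV_RIDGE_ABS = 1e-12


# ---------------------------------------------------------------------------
# Latent space
# ---------------------------------------------------------------------------


def fit_cluster_latent(sset_or_matrix, n_components: int = 24):
    """Robust scaler + PCA basis of min(n_components, rank) components."""
    X = sset_or_matrix.absorbance if isinstance(sset_or_matrix, SpectrumSet) else np.asarray(sset_or_matrix, dtype=float)
    if X.shape[0] < 25:
        raise FitError(f"need >= 25 samples to fit the cluster latent space, got {X.shape[0]}")
    scaler = fit_scaler(X, kind="robust")
    Xs = apply_scaler(X, scaler)
    if np.linalg.matrix_rank(Xs - Xs.mean(axis=0)) < 2:
        raise FitError("scaled data has rank < 2")
    basis = fit_pca(Xs, n_components)
    logger.info(
        "cluster latent: %d components, EVR(sum)=%.5f",
        basis.n_components,
        float(basis.explained_variance_ratio.sum()),
    )
    return scaler, basis


# ---------------------------------------------------------------------------
# Gaussian mixture via EM
# ---------------------------------------------------------------------------


@dataclass
class GMMParams:
    weights: np.ndarray       # (K,)
    means: np.ndarray         # (K, d)
    covariances: np.ndarray   # (K, d, d)

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise FitError("mixture weights must sum to 1")


@dataclass
class GMMFit:
    params: GMMParams
    log_likelihood: float          # total over samples, best restart
    ll_trace: list = field(default_factory=list)  # per-EM-iteration, best restart
    n_reinit: int = 0              # restarts re-initialized on empty components


def _component_log_density(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.size
    chol = cholesky(cov, lower=True)
    solved = np.linalg.solve(chol, (X - mean).T)
    quad = np.sum(solved**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + quad)


def gmm_log_density(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Per-sample mixture log density log sum_k w_k N(x; mu_k, S_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    parts = np.stack(
        [
            np.log(params.weights[k]) + _component_log_density(X, params.means[k], params.covariances[k])
            for k in range(params.n_components)
        ],
        axis=1,
    )
    return logsumexp(parts, axis=1)


def responsibilities(X: np.ndarray, params: GMMParams) -> np.ndarray:
    """Posterior component probabilities, rows summing to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    parts = np.stack(
        [
            np.log(params.weights[k]) + _component_log_density(X, params.means[k], params.covariances[k])
            for k in range(params.n_components)
        ],
        axis=1,
    )
    return np.exp(parts - logsumexp(parts, axis=1, keepdims=True))


def gmm_labels(X: np.ndarray, params: GMMParams) -> np.ndarray:
    return np.argmax(responsibilities(X, params), axis=1)


def _ridge(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    reg = COV_RIDGE_REL * float(np.trace(cov)) / d + COV_RIDGE_ABS
    return cov + reg * np.eye(d)


def _m_step(X: np.ndarray, resp: np.ndarray) -> GMMParams:
    n, d = X.shape
    nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for k in range(resp.shape[1]):
        diff = X - means[k]
        covs[k] = _ridge((resp[:, k][:, None] * diff).T @ diff / nk[k])
    return GMMParams(weights=weights, means=means, covariances=covs)


class _EmptyComponent(Exception):
    pass


def _em_run(X: np.ndarray, K: int, init_seed: int, max_iter: int, tol: float):
    """One EM run from a K-means initialization; returns (params, ll, trace)."""
    from sklearn.cluster import KMeans

    n = X.shape[0]
    km = KMeans(n_clusters=K, n_init=1, max_iter=10, random_state=init_seed).fit(X)
    resp = np.zeros((n, K))
    resp[np.arange(n), km.labels_] = 1.0
    if np.any(resp.sum(axis=0) < 1.0):
        raise _EmptyComponent
    params = _m_step(X, resp)

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        parts = np.stack(
            [
                np.log(params.weights[k])
                + _component_log_density(X, params.means[k], params.covariances[k])
                for k in range(K)
            ],
            axis=1,
        )
        log_norm = logsumexp(parts, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(parts - log_norm[:, None])
        if np.any(resp.sum(axis=0) < 1e-8):
            raise _EmptyComponent
        params = _m_step(X, resp)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            break
        prev_ll = ll
    return params, trace[-1], trace


def fit_gmm(
    latent: np.ndarray,
    K: int,
    n_init: int = 50,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> GMMFit:
    """Best-of-``n_init`` full-covariance GMM fit on latent coordinates.

    Each restart initializes component locations with K-means (10
    iterations, restart-specific seed derived deterministically from
    ``seed``) and runs EM with a per-component covariance ridge.  Restarts
    that collapse a component to (near) zero responsibility are
    re-initialized, up to 5 attempts each.
    """
    X = np.asarray(latent, dtype=float)
    if X.ndim != 2:
        raise DataError("latent must be a 2-d matrix")
    n = X.shape[0]
    if n <= K:
        raise FitError(f"need more samples ({n}) than components ({K})")
    seeds = np.random.SeedSequence(seed).generate_state(n_init * 8).astype(np.int64)
    best: tuple[float, GMMParams, list] | None = None
    n_reinit = 0
    for r in range(n_init):
        result = None
        for attempt in range(5):
            init_seed = int(seeds[r * 8 + attempt] % (2**31 - 1))
            try:
                result = _em_run(X, K, init_seed, max_iter, tol)
                break
            except _EmptyComponent:
                n_reinit += 1
                continue
        if result is None:
            logger.warning("restart %d abandoned after repeated empty components", r)
            continue
        params, ll, trace = result
        if best is None or ll > best[0]:
            best = (ll, params, trace)
    if best is None:
        raise FitError(f"all {n_init} GMM restarts failed for K={K}")
    if n_reinit:
        logger.info("K=%d: %d restart(s) re-initialized on empty components", K, n_reinit)
    return GMMFit(params=best[1], log_likelihood=best[0], ll_trace=best[2], n_reinit=n_reinit)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

_ANALYTES = ["fat", "protein", "lactose", "urea", "freezing_point", "milk_fat_acidity"]


@dataclass
class ClusterDiagnostics:
    """Per-cluster evaluation records (criteria i-vi)."""

    sizes: pd.Series
    within_between: pd.DataFrame          # within_mean, between_mean, ratio
    unique_farm_pct: pd.Series | None
    temporal_concentration_14d: pd.Series | None
    instrument_counts: pd.DataFrame | None
    instrument_entropy: pd.Series | None
    composition: pd.DataFrame | None      # (cluster, analyte) -> median, iqr
    degenerate: bool = False


def max_window_fraction(timestamps, labels, window_days: int) -> pd.Series:
    """Per cluster, max fraction of members inside any ``window_days``-day
    calendar window (windows anchored at member dates)."""
    ts = pd.DatetimeIndex(timestamps)
    labels = np.asarray(labels)
    out = {}
    for lab in np.unique(labels):
        days = ts[labels == lab].normalize()
        best = 0
        for d in days.unique():
            inside = ((days >= d) & (days < d + pd.Timedelta(days=window_days))).sum()
            best = max(best, int(inside))
        out[lab] = best / len(days)
    return pd.Series(out).sort_index()


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def evaluate_clusters(labels, sset: SpectrumSet, latent: np.ndarray) -> ClusterDiagnostics:
    """Compute the six evaluation criteria for a hard labeling.

    Metadata-dependent diagnostics degrade gracefully: a missing metadata
    column yields ``None`` for that diagnostic.
    """
    labels = np.asarray(labels)
    latent = np.asarray(latent, dtype=float)
    if labels.size != sset.n_samples or labels.size != latent.shape[0]:
        raise DataError("labels, spectra and latent must be aligned")
    uniq = np.unique(labels)
    sizes = pd.Series({lab: int((labels == lab).sum()) for lab in uniq}).sort_index()

    # (i) within/between mean pairwise latent distance
    from scipy.spatial.distance import pdist, squareform

    degenerate = uniq.size < 2
    if labels.size > 1:
        dm = squareform(pdist(latent))
        rows = {}
        same = labels[:, None] == labels[None, :]
        off_diag = ~np.eye(labels.size, dtype=bool)
        between_all = dm[(~same) & off_diag]
        between_mean = float(between_all.mean()) if between_all.size else np.nan
        for lab in uniq:
            mask = labels == lab
            sub = dm[np.ix_(mask, mask)]
            within = (
                float(sub[np.triu_indices(mask.sum(), k=1)].mean())
                if mask.sum() > 1
                else np.nan
            )
            ratio = within / between_mean if between_all.size and np.isfinite(within) else np.nan
            rows[lab] = {"within_mean": within, "between_mean": between_mean, "ratio": ratio}
        within_between = pd.DataFrame(rows).T.sort_index()
    else:
        within_between = pd.DataFrame(columns=["within_mean", "between_mean", "ratio"])

    meta = sset.meta
    farm = None
    if "farm_id" in meta and meta["farm_id"].notna().all():
        farm = pd.Series(
            {
                lab: 100.0 * meta.loc[labels == lab, "farm_id"].nunique() / max(int((labels == lab).sum()), 1)
                for lab in uniq
            }
        ).sort_index()

    temporal = None
    if "timestamp" in meta and meta["timestamp"].notna().all():
        temporal = max_window_fraction(meta["timestamp"], labels, window_days=14)

    inst_counts = inst_entropy = None
    if "instrument_id" in meta and meta["instrument_id"].notna().all():
        inst_counts = pd.crosstab(pd.Series(labels, name="cluster"), meta["instrument_id"])
        inst_entropy = inst_counts.apply(lambda row: _entropy(row.to_numpy(dtype=float)), axis=1)

    composition = None
    present = [a for a in _ANALYTES if a in meta.columns]
    if present:
        recs = []
        for lab in uniq:
            sub = meta.loc[labels == lab, present]
            for a in present:
                q25, med, q75 = np.percentile(sub[a].dropna(), [25, 50, 75]) if sub[a].notna().any() else (np.nan,) * 3
                recs.append({"cluster": lab, "analyte": a, "median": med, "iqr": q75 - q25,
                             "q25": q25, "q75": q75})
        composition = pd.DataFrame(recs).set_index(["cluster", "analyte"])

    return ClusterDiagnostics(
        sizes=sizes,
        within_between=within_between,
        unique_farm_pct=farm,
        temporal_concentration_14d=temporal,
        instrument_counts=inst_counts,
        instrument_entropy=inst_entropy,
        composition=composition,
        degenerate=degenerate,
    )


def sweep_k(
    latent: np.ndarray,
    sset: SpectrumSet,
    k_min: int = 4,
    k_max: int = 20,
    n_init: int = 50,
    seed: int = 0,
) -> list[tuple[int, GMMFit, ClusterDiagnostics]]:
    """Fit one GMM + diagnostics per K in [k_min, k_max]; per-K failures
    are logged and skipped rather than aborting the sweep."""
    X = np.asarray(latent, dtype=float)
    if X.shape[0] <= k_max:
        raise FitError(f"need more samples ({X.shape[0]}) than k_max ({k_max})")
    results = []
    for K in range(k_min, k_max + 1):
        try:
            fit = fit_gmm(X, K, n_init=n_init, seed=seed + K)
            diag = evaluate_clusters(gmm_labels(X, fit.params), sset, X)
            results.append((K, fit, diag))
        except (FitError, DataError) as exc:
            logger.warning("K=%d failed: %s", K, exc)
    return results


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_map_from_pairs(n_raw: int, pairs, sizes=None) -> np.ndarray:
    """Union-find over raw-label pairs; final labels renumbered 0..m-1 by
    descending merged size (``sizes`` defaults to equal sizes)."""
    parent = list(range(n_raw))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        a, b = int(a), int(b)
        if not (0 <= a < n_raw and 0 <= b < n_raw):
            raise DataError(f"merge pair ({a},{b}) references unknown raw label")
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    sizes = np.ones(n_raw) if sizes is None else np.asarray(sizes, dtype=float)
    roots = [find(i) for i in range(n_raw)]
    merged_size = {}
    for i, r in enumerate(roots):
        merged_size[r] = merged_size.get(r, 0.0) + sizes[i]
    order = sorted(merged_size, key=lambda r: (-merged_size[r], r))
    final_of_root = {r: j for j, r in enumerate(order)}
    return np.array([final_of_root[r] for r in roots], dtype=int)


def merge_clusters(gmm: GMMParams, pairs, labels=None) -> np.ndarray:
    """Merge map for a fitted mixture; sizes from hard ``labels`` when
    given, else from mixture weights."""
    K = gmm.n_components
    if labels is not None:
        labels = np.asarray(labels)
        sizes = np.array([(labels == k).sum() for k in range(K)], dtype=float)
    else:
        sizes = gmm.weights
    return merge_map_from_pairs(K, pairs, sizes=sizes)


def suggest_instrument_merges(diagnostics: ClusterDiagnostics) -> list[tuple]:
    """Advisory: propose merging cluster pairs whose composition summaries
    overlap (each median inside the other's IQR for all six analytes) and
    whose instrument supports are disjoint but jointly complete."""
    if diagnostics.instrument_counts is None or diagnostics.composition is None:
        return []
    counts = diagnostics.instrument_counts
    comp = diagnostics.composition
    clusters = list(counts.index)
    all_instruments = set(counts.columns[(counts.sum(axis=0) > 0)])
    proposals = []
    for i, a in enumerate(clusters):
        for b in clusters[i + 1 :]:
            sup_a = set(counts.columns[counts.loc[a] > 0])
            sup_b = set(counts.columns[counts.loc[b] > 0])
            if sup_a & sup_b or (sup_a | sup_b) != all_instruments:
                continue
            ok = True
            for analyte in _ANALYTES:
                if (a, analyte) not in comp.index or (b, analyte) not in comp.index:
                    ok = False
                    break
                ra, rb = comp.loc[(a, analyte)], comp.loc[(b, analyte)]
                if not (rb["q25"] <= ra["median"] <= rb["q75"] and ra["q25"] <= rb["median"] <= ra["q75"]):
                    ok = False
                    break
            if ok:
                proposals.append((a, b))
    return proposals


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------


@register_model_class
@dataclass
class ClusterModel:
    """Frozen clustering stage: robust scaler, PCA basis, GMM, merge map."""

    stage = "cluster"

    scaler: ScalerParams
    basis: PCABasis
    gmm: GMMParams
    merge_map: np.ndarray
    best_loglik: float

    def __post_init__(self):
        self.merge_map = np.asarray(self.merge_map, dtype=int)
        if self.merge_map.size != self.gmm.n_components:
            raise FitError("merge_map length must equal the number of raw components")
        final = np.unique(self.merge_map)
        if not np.array_equal(final, np.arange(final.size)):
            raise FitError("merge_map must be surjective onto 0..m-1")

    @property
    def n_final_clusters(self) -> int:
        return int(np.unique(self.merge_map).size)

    def transform(self, X_deriv: np.ndarray) -> np.ndarray:
        """Frozen robust scaling + projection of derivative-space spectra."""
        return self.basis.project(apply_scaler(np.asarray(X_deriv, dtype=float), self.scaler))

    def predict(self, X_deriv: np.ndarray) -> np.ndarray:
        """Final (merged) labels from GMM responsibilities."""
        raw = gmm_labels(self.transform(X_deriv), self.gmm)
        return self.merge_map[raw]

    # -- persistence ----------------------------------------------------
    def to_manifest(self) -> dict:
        return {
            "K": self.gmm.n_components,
            "n_final_clusters": self.n_final_clusters,
            "best_loglik": self.best_loglik,
            "scaler_kind": self.scaler.kind,
        }

    def to_arrays(self) -> dict:
        return {
            "scaler_center": self.scaler.center,
            "scaler_scale": self.scaler.scale,
            "components": self.basis.components,
            "pca_mean": self.basis.mean,
            "explained_variance_ratio": self.basis.explained_variance_ratio,
            "weights": self.gmm.weights,
            "means": self.gmm.means,
            "covariances": self.gmm.covariances,
            "merge_map": self.merge_map,
        }

    @classmethod
    def from_payload(cls, params: dict, arrays: dict) -> "ClusterModel":
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
            gmm=GMMParams(
                weights=arrays["weights"],
                means=arrays["means"],
                covariances=arrays["covariances"],
            ),
            merge_map=arrays["merge_map"],
            best_loglik=float(params["best_loglik"]),
        )


def split_train_test(n: int, train_fraction: float = 0.75, seed: int = 0):
    """Random 3:1-style split; training size is floor(train_fraction * n).

    Returns (train_idx, test_idx) positional index arrays.
    """
    if not 0 < train_fraction < 1:
        raise DataError("train_fraction must lie in (0, 1)")
    n_train = int(np.floor(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
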