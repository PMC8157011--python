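"""Spectral preprocessing: band selection, first derivative, scaling.

The default pipeline keeps three mid-IR windows (925-1600, 1690-1900 and
2700-2971 cm^-1, closed intervals), differentiates each contiguous band
independently with central finite differences (one-sided at band edges,
index units), and scales per grid point — standard (mean/SD) for the
screening stage, robust (median/IQR, linear-interpolation quartiles) for
the clustering stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PreprocessingError, SelectionError, ShapeError, FitError
from .spectra_io import SpectrumSet, WavenumberGrid

logger = logging.getLogger(__name__)

#: Default retained wavenumber windows (cm^-1), closed on both ends.
DEFAULT_BANDS = [(925.0, 1600.0), (1690.0, 1900.0), (2700.0, 2971.0)]


@dataclass(frozen=True)
class BandSelection:
    bands: tuple

    def __init__(self, bands=None):
        bands = DEFAULT_BANDS if bands is None else list(bands)
        norm = []
        for low, high in bands:
            low, high = float(low), float(high)
            if not low < high:
                raise SelectionError(f"band ({low}, {high}): low must be < high")
            norm.append((low, high))
        norm_sorted = sorted(norm)
        for (l1, h1), (l2, h2) in zip(norm_sorted, norm_sorted[1:]):
            if l2 <= h1:
                raise SelectionError(f"bands ({l1},{h1}) and ({l2},{h2}) overlap")
        object.__setattr__(self, "bands", tuple(norm))

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers, dtype=float)
        keep = np.zeros(w.shape, dtype=bool)
        for low, high in self.bands:
            keep |= (w >= low) & (w <= high)
        return keep


def select_bands(sset: SpectrumSet, selection: BandSelection | None = None) -> SpectrumSet:
    """Retain exactly the grid points inside any band (order preserved)."""
    selection = selection or BandSelection()
    keep = selection.mask(sset.grid.values)
    if not keep.any():
        raise SelectionError("band selection retains no grid points")
    idx = np.flatnonzero(keep)
    logger.info("band selection retained %d of %d grid points", idx.size, sset.n_points)
    return sset.with_absorbance(
        sset.absorbance[:, idx], grid=WavenumberGrid(sset.grid.values[idx])
    )


def band_segments(wavenumbers: np.ndarray) -> list[slice]:
    """Contiguous-band slices of a (possibly gappy) descending grid.

    A gap is any step larger than 1.5x the median absolute step.
    """
    w = np.asarray(wavenumbers, dtype=float)
    if w.size < 2:
        return [slice(0, w.size)]
    steps = np.abs(np.diff(w))
    threshold = 1.5 * np.median(steps)
    breaks = np.flatnonzero(steps > threshold) + 1
    edges = [0, *breaks.tolist(), w.size]
    return [slice(a, b) for a, b in zip(edges, edges[1:])]


def first_derivative(sset: SpectrumSet) -> SpectrumSet:
    """First derivative w.r.t. grid index, per contiguous band.

    Central differences on interior points, first-order one-sided at band
    edges; no differencing across band gaps.  Output has the same point
    count and grid as the input.
    """
    out = np.empty_like(sset.absorbance)
    for seg in band_segments(sset.grid.values):
        if seg.stop - seg.start < 3:
            raise PreprocessingError(
                f"band with {seg.stop - seg.start} point(s): need >= 3 to differentiate"
            )
        out[:, seg] = np.gradient(sset.absorbance[:, seg], axis=1)
    return sset.with_absorbance(out)


def savgol_derivative(sset: SpectrumSet, window: int = 7, polyorder: int = 2) -> SpectrumSet:
    """Optional Savitzky-Golay first derivative (config alternative)."""
    from scipy.signal import savgol_filter

    out = np.empty_like(sset.absorbance)
    for seg in band_segments(sset.grid.values):
        n = seg.stop - seg.start
        if n < window:
            raise PreprocessingError(f"band with {n} points shorter than SG window {window}")
        out[:, seg] = savgol_filter(
            sset.absorbance[:, seg], window_length=window, polyorder=polyorder,
            deriv=1, axis=1,
        )
    return sset.with_absorbance(out)


@dataclass
class ScalerParams:
    """Frozen per-point location/dispersion for (x - center) / scale."""

    kind: str  # {"standard", "robust"}
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.kind not in ("standard", "robust"):
            raise FitError(f"unknown scaler kind {self.kind!r}")
        if np.any(self.scale <= 0):
            raise FitError("scaler scale entries must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.center.size)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.absorbance
    return np.asarray(data, dtype=float)


def fit_scaler(data, kind: str = "standard") -> ScalerParams:
    """Fit per-point scaling statistics.

    ``standard`` uses mean/SD (population SD), ``robust`` uses median/IQR
    with linear-interpolation quartiles.  Points with zero dispersion get
    scale 1 (warning).
    """
    X = _as_matrix(data)
    if X.shape[0] < 2:
        raise FitError("scaler needs at least 2 samples")
    if kind == "standard":
        center = X.mean(axis=0)
        scale = X.std(axis=0)
    elif kind == "robust":
        q25, center, q75 = np.percentile(X, [25.0, 50.0, 75.0], axis=0)
        scale = q75 - q25
    else:
        raise FitError(f"unknown scaler kind {kind!r}")
    degenerate = scale <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} grid point(s) with zero dispersion; scale set to 1",
            stacklevel=2,
        )
        scale = np.where(degenerate, 1.0, scale)
    return ScalerParams(kind=kind, center=center, scale=scale)


def apply_scaler(data, params: ScalerParams):
    """(x - center) / scale pointwise; preserves the input container type."""
    X = _as_matrix(data)
    if X.shape[-1] != params.n_points:
        raise ShapeError(
            f"data has {X.shape[-1]} points, scaler expects {params.n_points}"
        )
    out = (X - params.center) / params.scale
    if isinstance(data, SpectrumSet):
        return data.with_absorbance(out)
    return out


def invert_scaler(data, params: ScalerParams):
    """Inverse of :func:`apply_scaler`: x * scale + center."""
    X = _as_matrix(data)
    if X.shape[-1] != params.n_points:
        raise ShapeError(
            f"data has {X.shape[-1]} points, scaler expects {params.n_points}"
        )
    out = X * params.scale + params.center
    if isinstance(data, SpectrumSet):
        return data.with_absorbance(out)
    return out


@dataclass
class PCABasis:
    """Frozen principal-component basis (components are rows)."""

    components: np.ndarray  # (k, p)
    mean: np.ndarray        # (p,)
    explained_variance_ratio: np.ndarray  # (k,)

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    @property
    def n_points(self) -> int:
        return int(self.components.shape[1])

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_points:
            raise ShapeError(f"data has {X.shape[-1]} points, basis expects {self.n_points}")
        return (X - self.mean) @ self.components.T

    def reconstruct(self, latent: np.ndarray) -> np.ndarray:
        latent = np.asarray(latent, dtype=float)
        if latent.shape[-1] != self.n_components:
            raise ShapeError(
                f"latent has {latent.shape[-1]} dims, basis has {self.n_components}"
            )
        return latent @ self.components + self.mean


def fit_pca(X: np.ndarray, n_components: int) -> PCABasis:
    """Fit a PCA basis with ``min(n_components, rank)`` components."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    if k < 1:
        raise FitError("not enough samples/points for PCA")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return PCABasis(
        components=pca.components_.copy(),
        mean=pca.mean_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def preprocess_pipeline(sset: SpectrumSet, bands=None, derivative: str = "finite_difference",
                        window: int = 7) -> SpectrumSet:
    """Band selection followed by the first derivative (no scaling)."""
    selected = select_bands(sset, BandSelection(bands))
    if derivative == "finite_difference":
        return first_derivative(selected)
    if derivative == "savitzky_golay":
        return savgol_derivative(selected, window=window)
    raise PreprocessingError(f"unknown derivative method {derivative!r}")
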