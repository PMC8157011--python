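"""Spectra and model I/O.

Defines the core in-memory containers (:class:`WavenumberGrid`,
:class:`SpectrumSet`) and the on-disk formats:

* spectra travel as a single wide, self-describing CSV file (UTF-8, comma
  separated, "." decimal) whose header holds ten reserved metadata columns
  followed by one column per grid point, named by the wavenumber printed
  with six significant digits;
* fitted models travel as a ZIP archive holding ``manifest.json`` (format
  version, stage name, scalar hyperparameters) plus ``arrays.npz`` with the
  numeric payload.  No executable serialization format is used.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    FormatError,
    IntegrityError,
    ModelVersionError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: Reserved metadata column names, in on-disk order.
META_COLUMNS = [
    "sample_id",
    "farm_id",
    "instrument_id",
    "timestamp",
    "fat",
    "protein",
    "lactose",
    "urea",
    "freezing_point",
    "milk_fat_acidity",
]

_STRING_META = ["sample_id", "farm_id", "instrument_id"]
_FLOAT_META = ["fat", "protein", "lactose", "urea", "freezing_point", "milk_fat_acidity"]

#: Acquisition grid constants: 1060 points descending from 5012 to 926 cm^-1.
GRID_HIGH = 5012.0
GRID_LOW = 926.0
GRID_N_POINTS = 1060

MODEL_FORMAT_VERSION = "1"


@dataclass(frozen=True)
class WavenumberGrid:
    """Ordered wavenumber axis in cm^-1, stored in descending order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise DataError("wavenumber grid must be a 1-d array with >= 2 points")
        diffs = np.diff(vals)
        if not (np.all(diffs < 0) or np.all(diffs > 0)):
            raise DataError("wavenumber grid must be strictly monotonic")

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def descending(self) -> bool:
        return bool(self.values[0] > self.values[-1])

    def __len__(self) -> int:
        return self.n_points


def default_grid() -> WavenumberGrid:
    """The standard 1060-point acquisition grid (5012 -> 926 cm^-1)."""
    return WavenumberGrid(np.linspace(GRID_HIGH, GRID_LOW, GRID_N_POINTS))


@dataclass
class SpectrumSet:
    """Absorbance matrix on a shared grid plus aligned per-sample metadata.

    ``meta`` is a DataFrame holding the reserved columns of
    :data:`META_COLUMNS`; its row order is aligned with the rows of
    ``absorbance``.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise DataError("absorbance must be a 2-d matrix")
        if self.absorbance.shape[1] != self.grid.n_points:
            raise DataError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {self.grid.n_points} points"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise DataError(
                f"metadata has {len(self.meta)} rows but the matrix has "
                f"{self.absorbance.shape[0]}"
            )
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise DataError(f"metadata missing reserved columns: {missing}")
        if not np.isfinite(self.absorbance).all():
            raise DataError("absorbance values must all be finite")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return int(self.absorbance.shape[0])

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def take(self, index) -> "SpectrumSet":
        """Row subset (positional), preserving order of ``index``."""
        idx = np.asarray(index)
        return SpectrumSet(
            grid=self.grid,
            absorbance=self.absorbance[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def with_absorbance(self, matrix: np.ndarray, grid: WavenumberGrid | None = None) -> "SpectrumSet":
        """Same metadata, replaced matrix (and optionally grid)."""
        return SpectrumSet(grid=grid or self.grid, absorbance=matrix, meta=self.meta.copy())


def _format_wavenumber(value: float) -> str:
    return format(value, ".6g")


def _format_float(value: float) -> str:
    if pd.isna(value):
        return ""
    return repr(float(value))


def write_spectra(sset: SpectrumSet, path) -> str:
    """Write ``sset`` to a wide CSV file; returns the path written.

    The output round-trips through :func:`read_spectra` bit-for-bit in
    values and row order (floats are printed with shortest round-trip
    representation).
    """
    path = str(path)
    cols = [_format_wavenumber(w) for w in sset.grid.values]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(META_COLUMNS + cols) + "\n")
        meta = sset.meta
        for i in range(sset.n_samples):
            row = meta.iloc[i]
            ts = row["timestamp"]
            ts_str = "" if pd.isna(ts) else pd.Timestamp(ts).strftime("%Y-%m-%dT%H:%M:%S")
            fields = [
                str(row["sample_id"]),
                str(row["farm_id"]),
                str(row["instrument_id"]),
                ts_str,
            ]
            fields += [_format_float(row[c]) for c in _FLOAT_META]
            fields += [repr(float(v)) for v in sset.absorbance[i]]
            fh.write(",".join(fields) + "\n")
    return path


def read_spectra(path) -> SpectrumSet:
    """Read a wide-CSV spectra file written in the package dialect.

    The grid is taken from the header; ascending grids are reordered to the
    internal descending convention (logged).  Raises :class:`FormatError`
    when reserved metadata columns are absent and :class:`ParseError`
    (naming row and column) for non-numeric or missing absorbance cells.
    """
    path = str(path)
    df = pd.read_csv(
        path,
        dtype={c: str for c in _STRING_META},
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {missing}")
    spectral_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not spectral_cols:
        raise FormatError(f"{path}: no spectral columns found")
    try:
        wavenumbers = np.array([float(c) for c in spectral_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric spectral column name: {exc}") from exc

    matrix = np.empty((len(df), len(spectral_cols)), dtype=float)
    for j, col in enumerate(spectral_cols):
        series = df[col]
        if series.dtype == object:
            coerced = pd.to_numeric(series, errors="coerce")
            bad = coerced.isna() & series.notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: non-numeric absorbance value at row {row}, column {col!r}"
                )
            series = coerced
        matrix[:, j] = series.to_numpy(dtype=float)
    if np.isnan(matrix).any():
        row, col = np.argwhere(np.isnan(matrix))[0]
        raise ParseError(
            f"{path}: missing absorbance value at row {int(row)}, "
            f"column {spectral_cols[int(col)]!r}"
        )

    if wavenumbers.size >= 2 and wavenumbers[0] < wavenumbers[-1]:
        logger.warning("%s: ascending wavenumber grid reordered to descending", path)
        order = np.argsort(-wavenumbers, kind="stable")
        wavenumbers = wavenumbers[order]
        matrix = matrix[:, order]

    meta = df[META_COLUMNS].copy()
    meta["timestamp"] = pd.to_datetime(meta["timestamp"], format="ISO8601")
    for c in _FLOAT_META:
        meta[c] = pd.to_numeric(meta[c], errors="raise")
    return SpectrumSet(grid=WavenumberGrid(wavenumbers), absorbance=matrix, meta=meta)


# ---------------------------------------------------------------------------
# Model archives
# ---------------------------------------------------------------------------

_MODEL_REGISTRY: dict[str, type] = {}


def register_model_class(cls) -> type:
    """Class decorator: register a model class by its ``stage`` attribute."""
    _MODEL_REGISTRY[cls.stage] = cls
    return cls


def save_model(model, path) -> str:
    """Serialize a fitted model to a ZIP archive (JSON manifest + npz)."""
    path = str(path)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "stage": model.stage,
        "params": model.to_manifest(),
    }
    arrays = model.to_arrays()
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1, sort_keys=True))
        zf.writestr("arrays.npz", buf.getvalue())
    return path


def load_model(path, expected_stage: str | None = None):
    """Load a model archive; dispatches on the manifest's stage name."""
    path = str(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            with io.BytesIO(zf.read("arrays.npz")) as buf:
                with np.load(buf, allow_pickle=False) as npz:
                    arrays = {k: npz[k] for k in npz.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, ValueError) as exc:
        raise IntegrityError(f"{path}: corrupt or truncated model archive ({exc})") from exc
    version = manifest.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"{path}: archive format version {version!r} does not match "
            f"code version {MODEL_FORMAT_VERSION!r}"
        )
    stage = manifest.get("stage")
    if stage not in _MODEL_REGISTRY:
        raise IntegrityError(f"{path}: unknown model stage {stage!r}")
    if expected_stage is not None and stage != expected_stage:
        raise FormatError(
            f"{path}: expected a {expected_stage!r} model, found {stage!r}"
        )
    cls = _MODEL_REGISTRY[stage]
    return cls.from_payload(manifest["params"], arrays)
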