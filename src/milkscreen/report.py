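"""Cluster characterization tables: sizes, farms, time, composition,
spectral deviation.

All operations emit plot-ready pandas tables; rendering (optional) is a
thin matplotlib layer over the tables and is never required by the
pipeline.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DataError, ShapeError

logger = logging.getLogger(__name__)

ANALYTES = ["fat", "protein", "lactose", "urea", "freezing_point", "milk_fat_acidity"]


def cluster_sizes(labels) -> pd.DataFrame:
    """Count and percentage (2 decimals) per cluster label."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DataError("need at least one label")
    uniq, counts = np.unique(labels, return_counts=True)
    return pd.DataFrame(
        {
            "cluster": uniq,
            "count": counts,
            "pct": np.round(100.0 * counts / labels.size, 2),
        }
    ).set_index("cluster")


def unique_farm_proportion(labels, farm_ids) -> pd.Series:
    """Per cluster: 100 * (distinct farms) / (cluster size)."""
    labels = np.asarray(labels)
    farms = pd.Series(np.asarray(farm_ids), name="farm")
    if labels.size != len(farms):
        raise DataError("labels and farm_ids must be aligned")
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[lab] = 100.0 * farms[mask].nunique() / int(mask.sum())
    return pd.Series(out, name="unique_farm_pct").sort_index()


def spectra_per_farm(labels, farm_ids) -> pd.Series:
    """Per cluster: cluster size / distinct farms (display rounds to 1 dp)."""
    labels = np.asarray(labels)
    farms = pd.Series(np.asarray(farm_ids), name="farm")
    if labels.size != len(farms):
        raise DataError("labels and farm_ids must be aligned")
    out = {}
    for lab in np.unique(labels):
        mask = labels == lab
        out[lab] = int(mask.sum()) / farms[mask].nunique()
    return pd.Series(out, name="spectra_per_farm").sort_index()


def two_day_concentration(labels, timestamps) -> pd.Series:
    """Per cluster, max fraction of members within two consecutive days."""
    from .cluster import max_window_fraction

    return max_window_fraction(timestamps, labels, window_days=2)


def temporal_profile(labels, timestamps, normalization: str = "max"):
    """Cluster x ISO-week matrix of member counts, each row normalized by
    its maximum (default; rows lie in [0, 1]) or by its sum
    (``normalization="sum"``); also returns the per-cluster
    two-consecutive-day concentration statistic.
    """
    labels = np.asarray(labels)
    ts = pd.DatetimeIndex(timestamps)
    if labels.size != ts.size:
        raise DataError("labels and timestamps must be aligned")
    if normalization not in ("max", "sum"):
        raise DataError(f"unknown normalization {normalization!r}")
    iso = ts.isocalendar()
    week_key = [f"{y}-W{w:02d}" for y, w in zip(iso["year"], iso["week"])]
    table = pd.crosstab(pd.Series(labels, name="cluster"), pd.Series(week_key, name="week"))
    table = table.reindex(sorted(table.columns), axis=1)
    denom = (table.max(axis=1) if normalization == "max" else table.sum(axis=1)).replace(0, 1)
    normalized = table.div(denom, axis=0)
    return normalized, two_day_concentration(labels, ts)


def composition_profile(labels, meta: pd.DataFrame, reference_population=None):
    """Per-cluster five-number composition summaries plus a reference band.

    ``reference_population`` is either a metadata DataFrame of the
    screening training population or a precomputed (analyte -> mean, sd, n)
    table; the band is mean +/- 1.96 * SD / sqrt(n).  Missing analyte
    columns are skipped with a warning.
    """
    labels = np.asarray(labels)
    if labels.size != len(meta):
        raise DataError("labels and metadata must be aligned")
    present = []
    for a in ANALYTES:
        if a in meta.columns:
            present.append(a)
        else:
            warnings.warn(f"analyte column {a!r} missing; skipped", stacklevel=2)
    recs = []
    for lab in np.unique(labels):
        sub = meta.loc[labels == lab, present]
        for a in present:
            vals = sub[a].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                mn = q25 = med = q75 = mx = np.nan
            else:
                mn, q25, med, q75, mx = np.percentile(vals, [0, 25, 50, 75, 100])
            recs.append(
                {
                    "cluster": lab,
                    "analyte": a,
                    "min": mn,
                    "q25": q25,
                    "median": med,
                    "q75": q75,
                    "max": mx,
                }
            )
    table = pd.DataFrame(recs).set_index(["cluster", "analyte"])

    reference = None
    if reference_population is not None:
        if isinstance(reference_population, pd.DataFrame) and "mean" in reference_population.columns:
            stats = reference_population
        else:
            pop = reference_population[[a for a in present if a in reference_population.columns]]
            stats = pd.DataFrame(
                {"mean": pop.mean(), "sd": pop.std(ddof=1), "n": pop.notna().sum().astype(float)}
            )
        half = 1.96 * stats["sd"] / np.sqrt(stats["n"])
        reference = pd.DataFrame(
            {"mean": stats["mean"], "lower": stats["mean"] - half, "upper": stats["mean"] + half}
        )
    return table, reference


def mean_spectral_deviation(labels, preprocessed: np.ndarray, typical_mean: np.ndarray) -> pd.DataFrame:
    """Per cluster: mean preprocessed spectrum minus the typical-population
    mean, per retained grid point."""
    labels = np.asarray(labels)
    X = np.asarray(preprocessed, dtype=float)
    typical_mean = np.asarray(typical_mean, dtype=float)
    if X.shape[1] != typical_mean.size:
        raise ShapeError(
            f"spectra have {X.shape[1]} points, typical mean has {typical_mean.size}"
        )
    if labels.size != X.shape[0]:
        raise DataError("labels and spectra must be aligned")
    rows = {lab: X[labels == lab].mean(axis=0) - typical_mean for lab in np.unique(labels)}
    return pd.DataFrame.from_dict(rows, orient="index")


def render_figures(out_dir, sizes=None, deviation=None, temporal=None, grid_values=None):
    """Optional PNG rendering of report tables (requires matplotlib)."""
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if sizes is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(sizes.index.astype(str), sizes["count"])
        ax.set_xlabel("cluster")
        ax.set_ylabel("spectra")
        fig.tight_layout()
        p = out_dir / "sizes.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    if deviation is not None:
        fig, ax = plt.subplots(figsize=(8, 4))
        x = grid_values if grid_values is not None else np.arange(deviation.shape[1])
        for lab, row in deviation.iterrows():
            ax.plot(x, row.to_numpy(), label=str(lab), lw=0.8)
        if grid_values is not None:
            ax.invert_xaxis()
            ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("mean deviation")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        p = out_dir / "deviation.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    if temporal is not None:
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.imshow(temporal.to_numpy(), aspect="auto", cmap="Greys")
        ax.set_xlabel("ISO week")
        ax.set_ylabel("cluster")
        fig.tight_layout()
        p = out_dir / "temporal.png"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)
    return written
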