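import numpy as np
import pandas as pd
import pytest

from milkscreen import simulate as sim
from milkscreen.preprocess import preprocess_pipeline
from milkscreen.spectra_io import META_COLUMNS, SpectrumSet, default_grid


@pytest.fixture(scope="session")
def small_cfg():
    return sim.SimConfig(n_farms=60, monthly_volume=200)


@pytest.fixture(scope="session")
def typical_200(small_cfg):
    return sim.generate_typical(200, small_cfg, seed=11)


@pytest.fixture(scope="session")
def deriv_200(typical_200):
    return preprocess_pipeline(typical_200)


@pytest.fixture(scope="session")
def typical_1000(small_cfg):
    return sim.generate_typical(1000, small_cfg, seed=5)


@pytest.fixture(scope="session")
def deriv_1000(typical_1000):
    return preprocess_pipeline(typical_1000)


@pytest.fixture(scope="session")
def screening_model_1000(deriv_1000):
    from milkscreen.screen import fit_screening_model

    return fit_screening_model(deriv_1000)


def make_set(n_samples: int, n_points: int = 8, seed: int = 0) -> SpectrumSet:
    """Tiny hand-rolled SpectrumSet on a descending uniform grid."""
    rng = np.random.default_rng(seed)
    grid = default_grid() if n_points == 1060 else None
    if grid is None:
        from milkscreen.spectra_io import WavenumberGrid

        grid = WavenumberGrid(np.linspace(2000.0, 1000.0, n_points))
    meta = pd.DataFrame(
        {
            "sample_id": [f"T{i:04d}" for i in range(n_samples)],
            "farm_id": [f"F{i % 5}" for i in range(n_samples)],
            "instrument_id": [f"I{i % 2 + 1}" for i in range(n_samples)],
            "timestamp": pd.to_datetime("2019-03-01")
            + pd.to_timedelta(rng.integers(0, 28 * 24 * 3600, n_samples), unit="s"),
            "fat": rng.normal(4.4, 0.2, n_samples),
            "protein": rng.normal(3.6, 0.1, n_samples),
            "lactose": rng.normal(4.5, 0.05, n_samples),
            "urea": rng.normal(23.0, 2.0, n_samples),
            "freezing_point": rng.normal(-0.52, 0.003, n_samples),
            "milk_fat_acidity": rng.normal(0.45, 0.05, n_samples),
        }
    )[META_COLUMNS]
    absorbance = rng.normal(0.5, 0.1, size=(n_samples, n_points))
    return SpectrumSet(grid=grid, absorbance=absorbance, meta=meta)
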