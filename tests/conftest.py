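import datetime as dt

import numpy as np
import pytest

from reefsense.bands import wavelengths
from reefsense.scene import Scene
from reefsense.synth import GeneratorConfig, simulate_timeseries


def make_scene(
    reflectance,
    date=dt.date(2023, 6, 1),
    valid_mask=None,
    pixel_size=3.0,
):
    """Build a Scene from a (bands, rows, cols) array with defaults."""
    reflectance = np.asarray(reflectance, dtype=float)
    if valid_mask is None:
        valid_mask = np.ones(reflectance.shape[1:], dtype=bool)
    wl = wavelengths()[: reflectance.shape[0]]
    return Scene(
        reflectance=reflectance,
        band_wavelengths=wl,
        valid_mask=valid_mask,
        acquisition_date=date,
        pixel_size=pixel_size,
    )


def flat_scene(value=0.02, n_bands=8, shape=(40, 40), **kwargs):
    return make_scene(np.full((n_bands,) + shape, value), **kwargs)


@pytest.fixture(scope="session")
def small_series():
    """A 6-date 64x64 simulated series with a 2-date bleaching window."""
    gen = GeneratorConfig(
        n_rows=64, n_cols=64, n_dates=6, coral_fraction=0.15,
        bleaching_window=(3, 4), severity=0.8,
    )
    scenes, truth = simulate_timeseries(gen, seed=123)
    return scenes, truth, gen
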