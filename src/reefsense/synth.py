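"""Synthetic shallow-reef scene generator with known ground truth.

Emulates multi-date SuperDove-like reflectance stacks over a patch reef:
a benthic mosaic of live coral, bleached coral, sand, algae and deep water;
a two-flow shallow-water observation model with two-way exponential
attenuation, R(lambda) = R_w(lambda) * (1 - exp(-2 K_d z)) +
R_bottom(lambda) * exp(-2 K_d z), where R_w is the asymptotic water-column
reflectance (the deep-water endmember); per-date multiplicative /
additive scene distortions standing in for atmospheric and illumination
residuals; a smooth additive sun-glint field shared across bands (so it is
fully expressed in the NIR); Gaussian sensor noise; bright cloud blobs;
and a bleaching event during which live-coral spectra move linearly toward
the bleached-coral endmember by a severity fraction.

Every stage of the detection pipeline can be validated against the
:class:`SyntheticTruth` the generator records.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt

import numpy as np
from scipy import ndimage

from .bands import N_BANDS, wavelengths
from .scene import Scene

CLASS_NAMES = ("live_coral", "bleached_coral", "sand", "algae", "deep_water")
LIVE, BLEACHED, SAND, ALGAE, DEEP = range(5)

#: Cloud pixels are painted with this reflectance in every band (sr^-1),
#: far above any water-leaving signal.
CLOUD_REFLECTANCE = 0.15

#: Default diffuse attenuation K_d (m^-1) per band: clear-water shape with
#: its minimum in the green and a large NIR value so deep water is
#: near-black in the NIR.
DEFAULT_KD = np.array([0.12, 0.09, 0.07, 0.065, 0.10, 0.25, 0.45, 2.5])

_PRESETS: dict[str, dict[str, list[float]]] = {
    # Calibrated so bleached coral sits at ~0.02-0.03 sr^-1 and sand at
    # ~0.03-0.06 sr^-1 in the blue/green bands, with bleached > live there.
    "florida_default": {
        "live_coral": [0.012, 0.015, 0.018, 0.020, 0.016, 0.010, 0.008, 0.004],
        "bleached_coral": [0.022, 0.026, 0.028, 0.026, 0.020, 0.013, 0.010, 0.005],
        "sand": [0.035, 0.042, 0.048, 0.050, 0.042, 0.030, 0.022, 0.010],
        "algae": [0.008, 0.010, 0.016, 0.018, 0.012, 0.007, 0.009, 0.004],
        # Asymptotic clear-water column reflectance (what an optically deep
        # pixel shows); kept below every bottom endmember per band so that
        # reflectance decreases monotonically with depth.
        "deep_water": [0.006, 0.007, 0.006, 0.005, 0.003, 0.0015, 0.0008, 0.0003],
    }
}


@dataclasses.dataclass
class EndmemberLibrary:
    """Pure-class bottom reflectance spectra on the SuperDove band grid."""

    class_names: tuple[str, ...]
    spectra: np.ndarray  # (classes, bands), sr^-1

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (len(self.class_names), N_BANDS):
            raise ValueError("spectra must be (n_classes, n_bands)")
        if np.any(self.spectra < 0):
            raise ValueError("endmember reflectances must be >= 0")

    def spectrum(self, name: str) -> np.ndarray:
        return self.spectra[self.class_names.index(name)]


@dataclasses.dataclass
class SceneDistortion:
    """Per-date residual radiometric distortion applied to a true scene."""

    gain_true: np.ndarray  # per-band multiplicative factor
    offset_true: np.ndarray  # per-band additive term, sr^-1
    glint_amplitude: float  # peak of the smooth glint field, sr^-1
    noise_sd: np.ndarray  # per-band Gaussian noise sd, sr^-1

    def __post_init__(self) -> None:
        self.gain_true = np.broadcast_to(
            np.asarray(self.gain_true, dtype=float), (N_BANDS,)
        ).copy()
        self.offset_true = np.broadcast_to(
            np.asarray(self.offset_true, dtype=float), (N_BANDS,)
        ).copy()
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (N_BANDS,)
        ).copy()
        if np.any(self.gain_true <= 0):
            raise ValueError("gain_true must be > 0")
        if np.any(self.noise_sd < 0) or self.glint_amplitude < 0:
            raise ValueError("noise_sd and glint_amplitude must be >= 0")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth the generator records for validation."""

    class_map: np.ndarray  # (rows, cols) int labels into CLASS_NAMES
    depth_map: np.ndarray  # (rows, cols) meters, >= 0
    attenuation: np.ndarray  # per-band K_d, m^-1
    distortions: dict[_dt.date, SceneDistortion]
    bleaching_window: tuple[_dt.date, _dt.date]
    severity: float
    cloud_masks: dict[_dt.date, np.ndarray] = dataclasses.field(default_factory=dict)
    glint_fields: dict[_dt.date, np.ndarray] = dataclasses.field(default_factory=dict)
    library: EndmemberLibrary | None = None
    cloud_fraction: float = 0.05

    def __post_init__(self) -> None:
        if np.any(self.depth_map < 0):
            raise ValueError("depths must be >= 0")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must be in [0, 1]")
        if self.bleaching_window[0] > self.bleaching_window[1]:
            raise ValueError("bleaching_window must be ordered")

    def in_window(self, date: _dt.date) -> bool:
        lo, hi = self.bleaching_window
        return lo <= date <= hi

    def stable_mask(self) -> np.ndarray:
        """Pixels whose spectrum never changes across dates (non-coral)."""
        return self.class_map != LIVE


def make_endmember_library(preset_name: str = "florida_default") -> EndmemberLibrary:
    """Return a named endmember preset.

    The default preset encodes the orderings that make bleaching optically
    detectable: bleached coral brighter than live coral in the blue/green
    bands, and sand brighter still.
    """
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; valid presets: {sorted(_PRESETS)}"
        )
    spec = _PRESETS[preset_name]
    return EndmemberLibrary(
        class_names=CLASS_NAMES,
        spectra=np.array([spec[name] for name in CLASS_NAMES]),
    )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to [0, 1]."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)


def generate_reef_map(
    seed: int,
    n_rows: int,
    n_cols: int,
    coral_fraction: float,
    deep_fraction: float = 0.3,
    patch_sigma: float = 10.0,
    reef_concentration: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a benthic class map and a depth map.

    The shallow platform (< 6 m) carries contiguous live-coral patches at
    ``coral_fraction`` of its area (within +-0.05), with the remainder split
    between sand and algal flats; the rest of the grid is deep water
    (> 15 m). ``patch_sigma`` sets the coral patch scale in pixels: larger
    values give fewer, more compact patches. ``reef_concentration`` in
    [0, 1] biases coral toward the grid center, leaving surrounding sand
    and algal flats coral-free (patch reefs sit inside larger sediment
    plains, which is where stable normalization targets are found).
    Identical seeds give identical rasters.
    """
    if n_rows < 32 or n_cols < 32:
        raise ValueError("grid must be at least 32x32")
    if not 0 <= coral_fraction <= 1:
        raise ValueError("coral_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)

    # Depth: a smooth shelf field; deepest deep_fraction becomes deep water.
    shelf = _smooth_field(rng, shape, sigma=min(shape) / 6)
    deep = shelf >= np.quantile(shelf, 1 - deep_fraction)
    depth = np.empty(shape)
    local = _smooth_field(rng, shape, sigma=8.0)
    depth[~deep] = 1.0 + 4.5 * local[~deep]  # 1.0-5.5 m shallow platform
    depth[deep] = 16.0 + 9.0 * local[deep]  # 16-25 m
    class_map = np.full(shape, SAND, dtype=np.int8)
    class_map[deep] = DEEP

    shallow = ~deep
    n_shallow = int(shallow.sum())
    if coral_fraction > 0 and n_shallow > 0:
        blob = _smooth_field(rng, shape, sigma=patch_sigma)
        if reef_concentration > 0:
            rr = (np.arange(n_rows) - n_rows / 2)[:, None]
            cc = (np.arange(n_cols) - n_cols / 2)[None, :]
            s = min(n_rows, n_cols) / 3.5
            taper = np.exp(-(rr**2 + cc**2) / (2 * s**2))
            blob = (1 - reef_concentration) * blob + reef_concentration * taper
        vals = blob[shallow]
        thr = np.quantile(vals, 1 - coral_fraction)
        class_map[shallow & (blob > thr)] = LIVE
    # Algal flats on part of the remaining shallow area.
    algf = _smooth_field(rng, shape, sigma=10.0)
    remaining = shallow & (class_map == SAND)
    if remaining.any():
        thr = np.quantile(algf[remaining], 0.6)
        class_map[remaining & (algf > thr)] = ALGAE
    return class_map, depth


def _cloud_mask(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> np.ndarray:
    """Random smooth blobs covering ~fraction of the grid."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    f = _smooth_field(rng, shape, sigma=5.0)
    return f >= np.quantile(f, 1 - fraction)


def bottom_reflectance(
    truth: SyntheticTruth, date: _dt.date, library: EndmemberLibrary | None = None
) -> np.ndarray:
    """Per-pixel bottom spectra for a date, applying the bleaching mix."""
    lib = library or truth.library or make_endmember_library()
    spectra = lib.spectra.copy()
    if truth.in_window(date) and truth.severity > 0:
        s = truth.severity
        spectra[LIVE] = (1 - s) * lib.spectra[LIVE] + s * lib.spectra[BLEACHED]
    return spectra[truth.class_map]  # (rows, cols, bands)


def simulate_scene(
    truth: SyntheticTruth,
    date: _dt.date,
    seed: int,
    cloud_fraction: float | None = None,
) -> Scene:
    """Render one date's distorted scene from the recorded truth.

    Applies the water-column attenuation, then the date's gain/offset
    distortion, a smooth non-negative glint field added equally to every
    band, Gaussian sensor noise, and bright cloud blobs that are flagged
    invalid in the scene mask (and recorded in the truth).
    """
    if date not in truth.distortions:
        raise ValueError(
            f"date {date} outside the simulated series "
            f"({sorted(truth.distortions)[0]}..{sorted(truth.distortions)[-1]})"
        )
    dist = truth.distortions[date]
    rng = np.random.default_rng(seed)
    lib = truth.library or make_endmember_library()
    bottom = bottom_reflectance(truth, date, lib)  # (r, c, b)
    atten = np.exp(
        -2.0 * truth.attenuation[None, None, :] * truth.depth_map[:, :, None]
    )
    r_water = lib.spectra[DEEP][None, None, :]
    r_true = r_water * (1.0 - atten) + bottom * atten
    r = dist.gain_true[None, None, :] * r_true + dist.offset_true[None, None, :]

    shape = truth.class_map.shape
    # The glint field and noise are always drawn so that scenes rendered
    # from the same seed differ only through the distortion parameters.
    glint = _smooth_field(rng, shape, sigma=max(4.0, min(shape) / 10))
    glint = glint * dist.glint_amplitude
    truth.glint_fields[date] = glint
    r = r + glint[:, :, None]
    noise = rng.standard_normal(r.shape) * dist.noise_sd[None, None, :]
    r = r + noise

    frac = truth.cloud_fraction if cloud_fraction is None else cloud_fraction
    clouds = _cloud_mask(rng, shape, frac)
    truth.cloud_masks[date] = clouds
    r[clouds, :] = CLOUD_REFLECTANCE

    return Scene(
        reflectance=np.moveaxis(r, 2, 0),
        band_wavelengths=wavelengths(),
        valid_mask=~clouds,
        acquisition_date=date,
    )


@dataclasses.dataclass
class GeneratorConfig:
    """Study-condition defaults for a simulated acquisition series."""

    n_rows: int = 128
    n_cols: int = 128
    n_dates: int = 16
    coral_fraction: float = 0.15
    start_date: _dt.date = _dt.date(2023, 1, 15)
    cadence_days: int = 30
    bleaching_window: tuple[int, int] = (8, 10)  # inclusive date indices
    severity: float = 0.8
    gain_range: tuple[float, float] = (0.8, 1.2)
    offset_range: tuple[float, float] = (-0.005, 0.005)
    noise_sd_range: tuple[float, float] = (5e-5, 5e-4)
    glint_amplitude_range: tuple[float, float] = (0.0, 0.005)
    cloud_fraction: float = 0.05
    deep_fraction: float = 0.3
    patch_sigma: float = 10.0
    reef_concentration: float = 0.35
    preset: str = "florida_default"

    def dates(self) -> list[_dt.date]:
        return [
            self.start_date + _dt.timedelta(days=i * self.cadence_days)
            for i in range(self.n_dates)
        ]


def simulate_timeseries(
    config: GeneratorConfig, seed: int
) -> tuple[list[Scene], SyntheticTruth]:
    """Simulate a multi-date series sharing one reef map.

    Each date draws an independent :class:`SceneDistortion` from the
    configured ranges; all draws are recorded in the returned truth.
    """
    if config.n_dates < 3:
        raise ValueError("need at least 3 dates")
    w0, w1 = config.bleaching_window
    if not (0 <= w0 <= w1 < config.n_dates):
        raise ValueError("bleaching_window must lie within the date span")
    rng = np.random.default_rng(seed)
    class_map, depth = generate_reef_map(
        seed=int(rng.integers(2**31)),
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        coral_fraction=config.coral_fraction,
        deep_fraction=config.deep_fraction,
        patch_sigma=config.patch_sigma,
        reef_concentration=config.reef_concentration,
    )
    dates = config.dates()
    distortions = {}
    for d in dates:
        distortions[d] = SceneDistortion(
            gain_true=rng.uniform(*config.gain_range, size=N_BANDS),
            offset_true=rng.uniform(*config.offset_range, size=N_BANDS),
            glint_amplitude=float(rng.uniform(*config.glint_amplitude_range)),
            noise_sd=np.full(N_BANDS, rng.uniform(*config.noise_sd_range)),
        )
    truth = SyntheticTruth(
        class_map=class_map,
        depth_map=depth,
        attenuation=DEFAULT_KD.copy(),
        distortions=distortions,
        bleaching_window=(dates[w0], dates[w1]),
        severity=config.severity,
        library=make_endmember_library(config.preset),
        cloud_fraction=config.cloud_fraction,
    )
    scenes = [
        simulate_scene(truth, d, seed=int(rng.integers(2**31))) for d in dates
    ]
    return scenes, truth
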