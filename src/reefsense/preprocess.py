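"""Masking and clear-water NIR sun-glint correction.

Land, boats and clouds are removed by thresholding: land/boat pixels have
high NIR reflectance (water-leaving NIR is near zero), clouds are bright
across the visible bands. Sun glint is specular surface reflection,
approximately spectrally flat; over clear (low-turbidity) water the
water-leaving NIR is an approximately constant ambient level, so any
excess NIR above that ambient is glint and is subtracted from every band.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .bands import BRIGHTNESS_IDX, NIR_IDX
from .scene import Scene

log = logging.getLogger(__name__)


@dataclasses.dataclass
class MaskThresholds:
    """Reflectance thresholds for the land/boat and cloud masks (sr^-1)."""

    nir_land_min: float = 0.05
    brightness_cloud_min: float = 0.10

    def __post_init__(self) -> None:
        if self.nir_land_min <= 0 or self.brightness_cloud_min <= 0:
            raise ValueError("mask thresholds must be > 0")


def _nir_index(scene: Scene) -> int:
    """Index of the NIR band (wavelength >= 800 nm)."""
    idx = np.nonzero(scene.band_wavelengths >= 800)[0]
    if idx.size == 0:
        raise ValueError("scene has no NIR band (>= 800 nm)")
    return int(idx[0])


def build_mask(scene: Scene, thresholds: MaskThresholds | None = None) -> Scene:
    """Invalidate land/boat and cloud pixels.

    The returned scene's mask is the input mask minus pixels whose NIR
    reflectance reaches ``nir_land_min`` or whose mean visible (band 1-4)
    reflectance reaches ``brightness_cloud_min``. Reflectance values are
    untouched, and a previously invalid pixel is never re-validated.
    """
    thresholds = thresholds or MaskThresholds()
    nir = scene.reflectance[_nir_index(scene)]
    vis = scene.reflectance[list(BRIGHTNESS_IDX[: min(4, scene.n_bands)])].mean(axis=0)
    bad = (nir >= thresholds.nir_land_min) | (vis >= thresholds.brightness_cloud_min)
    new_mask = scene.valid_mask & ~bad
    out = scene.replace(valid_mask=new_mask)
    log.info(
        "build_mask %s: masked %.2f%% of pixels",
        scene.acquisition_date,
        100 * (1 - new_mask.mean()),
    )
    return out


def correct_glint(scene: Scene, ambient_percentile: float = 1.0) -> Scene:
    """Subtract the excess-NIR glint estimate from every band.

    Per valid pixel the glint estimate is g = max(0, NIR - NIR_ambient)
    where NIR_ambient is the ``ambient_percentile`` percentile of NIR over
    valid pixels (a percentile rather than the minimum, for robustness to
    dropped pixels). g is subtracted from every band and results are
    floored at zero; masked pixels are untouched.
    """
    if not scene.valid_mask.any():
        raise ValueError("no valid pixels to estimate ambient NIR from")
    nir_idx = _nir_index(scene)
    nir = scene.reflectance[nir_idx]
    ambient = float(np.percentile(nir[scene.valid_mask], ambient_percentile))
    g = np.maximum(0.0, nir - ambient)
    g[~scene.valid_mask] = 0.0
    corrected = scene.reflectance - g[None, :, :]
    clipped = corrected < 0
    clipped[:, ~scene.valid_mask] = False
    corrected = np.maximum(corrected, 0.0)
    out = scene.reflectance.copy()
    out[:, scene.valid_mask] = corrected[:, scene.valid_mask]
    frac_clipped = clipped[:, scene.valid_mask].mean()
    if frac_clipped > 0.01:
        log.warning(
            "correct_glint %s: clipped %.2f%% of valid pixels to 0",
            scene.acquisition_date,
            100 * frac_clipped,
        )
    return scene.replace(reflectance=out)


def preprocess_scene(
    scene: Scene,
    thresholds: MaskThresholds | None = None,
    ambient_percentile: float = 1.0,
) -> Scene:
    """Mask then glint-correct one scene."""
    return correct_glint(build_mask(scene, thresholds), ambient_percentile)
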