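"""Scene data model and raster / region I/O.

A :class:`Scene` is one acquisition date's co-registered multiband
remote-sensing-reflectance raster (R_rs, sr^-1) plus a validity mask and
grid metadata. Scenes are written as multiband float32 TIFFs with the
acquisition date, wavelengths, pixel size and nodata sentinel stored as a
JSON document in the TIFF description tag; the date is also embedded as an
ISO-8601 token in the file name so either source can recover it (the
metadata tag wins when both are present).

Regions of interest are GeoJSON polygons in the scene's projected frame
(x = column * pixel_size, y = row * pixel_size, row 0 at the raster top,
y increasing downward). A pixel belongs to an ROI iff its center lies
inside the polygon (center-inclusion rule).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import re
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as _shapely_shape

from .bands import wavelengths as _default_wavelengths

DEFAULT_NODATA = -9999.0

_DATE_RE = re.compile(r"(\d{4}-\d{2}-\d{2})")


class SceneReadError(RuntimeError):
    """Raised when a scene file is missing, unreadable or lacks a date."""


@dataclasses.dataclass
class Scene:
    """One date's multiband reflectance raster.

    Attributes
    ----------
    reflectance : (bands, rows, cols) float array of R_rs in sr^-1.
    band_wavelengths : strictly increasing band centers in nm.
    valid_mask : (rows, cols) bool array; True where the pixel is usable.
    acquisition_date : calendar date of the acquisition.
    pixel_size : ground sample distance in meters.
    nodata_value : sentinel written into invalid pixels on disk.
    """

    reflectance: np.ndarray
    band_wavelengths: np.ndarray
    valid_mask: np.ndarray
    acquisition_date: _dt.date
    pixel_size: float = 3.0
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.band_wavelengths = np.asarray(self.band_wavelengths, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (bands, rows, cols)")
        if self.band_wavelengths.shape[0] != self.reflectance.shape[0]:
            raise ValueError("one wavelength per band required")
        if np.any(np.diff(self.band_wavelengths) <= 0):
            raise ValueError("band wavelengths must be strictly increasing")
        if self.valid_mask.shape != self.reflectance.shape[1:]:
            raise ValueError("valid_mask shape must match the raster grid")
        if not np.all(np.isfinite(self.reflectance[:, self.valid_mask])):
            raise ValueError("reflectance must be finite on valid pixels")

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.reflectance.shape[1:]

    def replace(self, **kwargs) -> "Scene":
        """Copy with selected fields replaced (arrays are copied)."""
        fields = dict(
            reflectance=self.reflectance.copy(),
            band_wavelengths=self.band_wavelengths.copy(),
            valid_mask=self.valid_mask.copy(),
            acquisition_date=self.acquisition_date,
            pixel_size=self.pixel_size,
            nodata_value=self.nodata_value,
        )
        fields.update(kwargs)
        return Scene(**fields)


@dataclasses.dataclass
class RegionOfInterest:
    """Labeled set of (row, col) pixel indices on the shared grid."""

    label: str
    pixel_set: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        self.pixel_set = frozenset((int(r), int(c)) for r, c in self.pixel_set)
        if not self.pixel_set:
            raise ValueError(f"ROI {self.label!r} is empty")

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row and column index arrays, in row-major order."""
        pix = sorted(self.pixel_set)
        rows = np.fromiter((p[0] for p in pix), dtype=int, count=len(pix))
        cols = np.fromiter((p[1] for p in pix), dtype=int, count=len(pix))
        return rows, cols

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        rows, cols = self.indices()
        m[rows, cols] = True
        return m


def check_grid_compatible(scenes: "list[Scene]") -> None:
    """Reject mixing scenes of different grids in one analysis."""
    if not scenes:
        return
    ref = scenes[0]
    for s in scenes[1:]:
        if s.grid_shape != ref.grid_shape or s.pixel_size != ref.pixel_size:
            raise ValueError(
                f"grid mismatch: {s.grid_shape}@{s.pixel_size}m vs "
                f"{ref.grid_shape}@{ref.pixel_size}m"
            )


def write_scene(scene: Scene, path: str | Path, overwrite: bool = True) -> Path:
    """Write a scene as a multiband float32 TIFF.

    Invalid pixels are stored as the nodata sentinel in every band;
    metadata goes in the TIFF description tag as JSON. Round-trips
    losslessly at float32 precision on valid pixels.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists and overwrite=False")
    data = scene.reflectance.astype(np.float32).copy()
    data[:, ~scene.valid_mask] = np.float32(scene.nodata_value)
    meta = {
        "acquisition_date": scene.acquisition_date.isoformat(),
        "band_wavelengths_nm": [float(w) for w in scene.band_wavelengths],
        "pixel_size_m": float(scene.pixel_size),
        "nodata_value": float(scene.nodata_value),
    }
    tifffile.imwrite(
        path, data, description=json.dumps(meta), photometric="minisblack"
    )
    return path


def read_scene(path: str | Path) -> Scene:
    """Read a scene written by :func:`write_scene`.

    The acquisition date comes from the JSON metadata tag when present,
    else from an ISO-8601 token in the file name. Nodata pixels are
    excluded from the validity mask.
    """
    path = Path(path)
    if not path.exists():
        raise SceneReadError(f"scene file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description or ""
    except (tifffile.TiffFileError, ValueError, OSError) as exc:
        raise SceneReadError(f"unreadable raster {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    date = None
    if "acquisition_date" in meta:
        date = _dt.date.fromisoformat(meta["acquisition_date"])
    else:
        m = _DATE_RE.search(path.name)
        if m:
            date = _dt.date.fromisoformat(m.group(1))
    if date is None:
        raise SceneReadError(
            f"no acquisition date in metadata or filename of {path}"
        )
    nodata = float(meta.get("nodata_value", DEFAULT_NODATA))
    wl = meta.get("band_wavelengths_nm")
    if wl is None:
        wl = _default_wavelengths()[: data.shape[0]]
    data = data.astype(float)
    valid = np.all(data != nodata, axis=0) & np.all(np.isfinite(data), axis=0)
    return Scene(
        reflectance=data,
        band_wavelengths=np.asarray(wl, dtype=float),
        valid_mask=valid,
        acquisition_date=date,
        pixel_size=float(meta.get("pixel_size_m", 3.0)),
        nodata_value=nodata,
    )


def _rasterize_polygon(geom, scene: Scene) -> set[tuple[int, int]]:
    """Pixels of the scene grid whose centers fall inside the geometry."""
    ps = scene.pixel_size
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(0, int(np.floor(minx / ps - 0.5)))
    r0 = max(0, int(np.floor(miny / ps - 0.5)))
    nrows, ncols = scene.grid_shape
    c1 = min(ncols - 1, int(np.ceil(maxx / ps - 0.5)))
    r1 = min(nrows - 1, int(np.ceil(maxy / ps - 0.5)))
    if c1 < c0 or r1 < r0:
        return set()
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    xs = (cc.ravel() + 0.5) * ps
    ys = (rr.ravel() + 0.5) * ps
    inside = shapely.contains_xy(geom, xs, ys)
    return set(zip(rr.ravel()[inside].tolist(), cc.ravel()[inside].tolist()))


def load_rois(path: str | Path, scene: Scene) -> list[RegionOfInterest]:
    """Rasterize GeoJSON polygon features onto the scene grid.

    Features sharing a ``label`` property are merged into one ROI (union of
    pixel sets), so a patchy reef can be one logical region. A feature whose
    polygon covers no pixel center raises an error naming the ROI.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    merged: dict[str, set[tuple[int, int]]] = {}
    for i, feat in enumerate(features):
        label = str(feat.get("properties", {}).get("label", f"roi_{i}"))
        geom = _shapely_shape(feat["geometry"])
        pix = _rasterize_polygon(geom, scene)
        if not pix and label not in merged:
            raise ValueError(
                f"ROI {label!r} does not intersect the scene grid"
            )
        merged.setdefault(label, set()).update(pix)
    out = []
    for label, pix in merged.items():
        if not pix:
            raise ValueError(f"ROI {label!r} does not intersect the scene grid")
        out.append(RegionOfInterest(label=label, pixel_set=frozenset(pix)))
    return out
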