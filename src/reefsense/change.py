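"""ROI reflectance time series, change maps, anomaly detection, clustering.

Bleached coral is brighter than live coral in the blue band (492 nm), so a
bleaching event appears as (a) a positive normalized difference between a
during-event and a before-event scene over coral, and (b) an upward
excursion of the ROI-mean blue reflectance relative to a baseline period.
The detector standardizes each date against the baseline mean and standard
deviation and flags one-sided (elevation-only) z-score exceedances; the
z-score operationalization, with a configurable baseline window, is this
package's formalization of reading the elevation off a normalized
time-series plot.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .bands import BLUE_IDX
from .scene import RegionOfInterest, Scene, check_grid_compatible

log = logging.getLogger(__name__)

#: Label for masked pixels in classification rasters.
BACKGROUND = -1


def extract_roi_mean(
    scene: Scene, roi: RegionOfInterest
) -> tuple[np.ndarray | None, int]:
    """Per-band mean reflectance over valid ROI pixels, with pixel count.

    Returns (None, 0) when no ROI pixel is valid — an explicit missing
    record rather than zeros.
    """
    rows, cols = roi.indices()
    ok = scene.valid_mask[rows, cols]
    count = int(ok.sum())
    if count == 0:
        log.info("ROI %s has no valid pixels on %s", roi.label, scene.acquisition_date)
        return None, 0
    vals = scene.reflectance[:, rows[ok], cols[ok]]
    return vals.mean(axis=1), count


@dataclasses.dataclass
class ReflectanceTimeSeries:
    """Dates x bands matrix of ROI-mean normalized reflectance."""

    roi_label: str
    dates: list[_dt.date]
    values: np.ndarray  # (dates, bands), sr^-1
    counts: np.ndarray  # valid pixels per date

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValueError("dates must be strictly increasing")
        if np.any(self.counts <= 0):
            raise ValueError("every retained date needs a positive pixel count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time-series values must be finite")

    def band(self, band: int) -> np.ndarray:
        return self.values[:, band]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.dates, name="date"),
            columns=[f"band_{i + 1}" for i in range(self.values.shape[1])],
        )
        df["n_pixels"] = self.counts
        return df


def build_timeseries(
    scenes: list[Scene], roi: RegionOfInterest
) -> ReflectanceTimeSeries:
    """ROI-mean series over a normalized scene stack, sorted by date.

    Dates with no valid ROI pixels are dropped (with a log entry), not
    interpolated; duplicate acquisition dates are an error.
    """
    check_grid_compatible(scenes)
    dates = [s.acquisition_date for s in scenes]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate acquisition dates in scene stack")
    rows = []
    for s in sorted(scenes, key=lambda s: s.acquisition_date):
        mean, count = extract_roi_mean(s, roi)
        if mean is None:
            log.info("dropping %s for ROI %s (all masked)", s.acquisition_date, roi.label)
            continue
        rows.append((s.acquisition_date, mean, count))
    if not rows:
        raise ValueError(f"ROI {roi.label!r} has no valid pixels on any date")
    return ReflectanceTimeSeries(
        roi_label=roi.label,
        dates=[r[0] for r in rows],
        values=np.stack([r[1] for r in rows]),
        counts=np.array([r[2] for r in rows]),
    )


@dataclasses.dataclass
class ChangeMap:
    """Per-band normalized difference between two dates."""

    nd: np.ndarray  # (bands, rows, cols) in [-1, 1] on valid samples
    valid_mask: np.ndarray  # (rows, cols): valid in both scenes
    band_valid: np.ndarray  # (bands, rows, cols): band sum usable too
    before_date: _dt.date
    during_date: _dt.date


def normalized_difference(before: Scene, during: Scene) -> ChangeMap:
    """Per-band (during - before) / (during + before) change index.

    Positive where the scene brightened (the bleaching signature). Band
    samples whose sum is within 1e-9 of zero, or with a negative input,
    are set to 0 and dropped from ``band_valid`` (the heavily attenuated
    red/NIR bands are near-zero over water, so this is tracked per band
    rather than collapsing the whole pixel). Inputs are expected
    non-negative (preprocessed/normalized scenes), so nd is in [-1, 1].
    """
    check_grid_compatible([before, during])
    num = during.reflectance - before.reflectance
    den = during.reflectance + before.reflectance
    degenerate = (np.abs(den) < 1e-9) | (before.reflectance < 0) | (during.reflectance < 0)
    nd = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    nd = np.clip(nd, -1.0, 1.0)
    valid = before.valid_mask & during.valid_mask
    nd[:, ~valid] = 0.0
    band_valid = ~degenerate & valid[None, :, :]
    return ChangeMap(
        nd=nd, valid_mask=valid, band_valid=band_valid,
        before_date=before.acquisition_date, during_date=during.acquisition_date,
    )


@dataclasses.dataclass
class AnomalyReport:
    """One-sided z-score bleaching flags for one ROI and band."""

    roi_label: str
    band: int
    baseline_dates: list[_dt.date]
    flagged_dates: list[_dt.date]
    z_scores: dict[_dt.date, float]


def detect_bleaching(
    ts: ReflectanceTimeSeries,
    band: int = BLUE_IDX,
    baseline_dates: "list[_dt.date] | None" = None,
    candidate_dates: "list[_dt.date] | None" = None,
    z_threshold: float = 2.0,
) -> AnomalyReport:
    """Flag dates whose band reflectance is anomalously elevated.

    z per date = (value - baseline mean) / baseline sd for the chosen band
    (default the 492 nm blue band); candidate dates with z >= z_threshold
    are flagged, one-sided. The baseline must have at least 3 dates and
    excludes the candidates. By default the candidates are all
    non-baseline dates.
    """
    if baseline_dates is None:
        raise ValueError("baseline_dates is required")
    baseline_dates = sorted(baseline_dates)
    if len(baseline_dates) < 3:
        raise ValueError("need at least 3 baseline dates")
    if candidate_dates is None:
        candidate_dates = [d for d in ts.dates if d not in set(baseline_dates)]
    if set(baseline_dates) & set(candidate_dates):
        raise ValueError("baseline must exclude candidate dates")
    idx = {d: i for i, d in enumerate(ts.dates)}
    missing = [d for d in baseline_dates if d not in idx]
    if missing:
        raise ValueError(f"baseline dates not in series: {missing}")
    series = ts.band(band)
    base = series[[idx[d] for d in baseline_dates]]
    mu = base.mean()
    sd = base.std(ddof=1)
    if sd <= 0:
        raise ValueError(
            "baseline standard deviation is zero; add more baseline dates"
        )
    z_scores = {d: float((series[idx[d]] - mu) / sd) for d in ts.dates if d in idx}
    flagged = [
        d for d in candidate_dates if d in idx and z_scores[d] >= z_threshold
    ]
    return AnomalyReport(
        roi_label=ts.roi_label, band=band,
        baseline_dates=baseline_dates, flagged_dates=flagged, z_scores=z_scores,
    )


def isodata_classify(
    scene: Scene, n_classes: int, max_iter: int = 100, seed: int = 0
) -> np.ndarray:
    """Unsupervised spectral clustering of valid pixels (Iso-Cluster style).

    Plain seeded k-means (k-means++ initialization) on per-pixel spectra;
    split/merge heuristics of classic ISODATA are omitted as coral-cover
    delineation does not need them. Labels are arbitrary but deterministic
    given the seed; masked pixels are labeled ``BACKGROUND``.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    vm = scene.valid_mask
    n_valid = int(vm.sum())
    if n_classes >= 2 and n_valid < 10 * n_classes:
        raise ValueError(
            f"too few valid pixels ({n_valid}) for {n_classes} classes"
        )
    out = np.full(scene.grid_shape, BACKGROUND, dtype=int)
    X = scene.reflectance[:, vm].T
    if n_classes == 1:
        out[vm] = 0
        return out
    km = KMeans(
        n_clusters=n_classes, init="k-means++", n_init=10,
        max_iter=max_iter, random_state=seed,
    )
    out[vm] = km.fit_predict(X)
    return out
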