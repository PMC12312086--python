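"""Pseudo-invariant feature (PIF) radiometric normalization.

Residual radiometric distortions between acquisition dates (atmosphere,
view and solar geometry) are removed by regressing each band of the
reference scene on the same band of the adjusted scene over pixels inside
pseudo-invariant features: square windows whose spectra are stable through
time (deep water, sand, algal flats). Candidate windows are ranked by the
spectral information divergence (SID) between their mean spectra in the
two scenes; the lowest-divergence non-overlapping windows become PIFs.
The fitted per-band gain/offset maps the adjusted scene onto the
reference's radiometric frame.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging

import numpy as np

from .bands import BLUE_IDX
from .scene import RegionOfInterest, Scene, check_grid_compatible

log = logging.getLogger(__name__)

_SID_EPS = 1e-12


def spectral_information_divergence(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetric information divergence of two non-negative spectra.

    Each spectrum is floored at 1e-12 and normalized to unit sum, giving
    probability vectors p and q; the result is the symmetrized
    Kullback-Leibler divergence KL(p||q) + KL(q||p). It is non-negative,
    symmetric, zero iff the spectra are proportional, and invariant to
    positive rescaling of either spectrum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("spectra must be 1-D, equal length >= 2")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("spectra must be non-negative")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("spectra must have positive sum")
    p = np.maximum(x, _SID_EPS)
    q = np.maximum(y, _SID_EPS)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


@dataclasses.dataclass
class PIFPolygon:
    """A candidate/selected square PIF window."""

    anchor: tuple[int, int]  # (row, col) of the top-left pixel
    size: int  # side length in pixels
    mean_ref: np.ndarray  # per-band mean in the reference scene
    mean_adj: np.ndarray  # per-band mean in the adjusted scene
    sid: float

    def overlaps(self, other: "PIFPolygon") -> bool:
        r0, c0 = self.anchor
        r1, c1 = other.anchor
        return (
            r0 < r1 + other.size
            and r1 < r0 + self.size
            and c0 < c1 + other.size
            and c1 < c0 + self.size
        )

    def window(self) -> tuple[slice, slice]:
        r, c = self.anchor
        return slice(r, r + self.size), slice(c, c + self.size)


@dataclasses.dataclass
class NormalizationModel:
    """Per-band linear map from an adjusted scene onto the reference."""

    gain: np.ndarray
    offset: np.ndarray
    r2: np.ndarray
    n_points: int
    reference_date: _dt.date


def score_pif_candidates(
    reference: Scene,
    adjusted: Scene,
    size: int = 30,
    stride: int | None = None,
    min_valid_fraction: float = 0.9,
    sid_bands: "tuple[int, ...] | None" = (0, 1, 2, 3),
) -> list[PIFPolygon]:
    """Score every stride-spaced square window by spectral stability.

    A window is eligible when at least ``min_valid_fraction`` of its pixels
    are valid in both scenes. Its SID is computed between the per-band
    means of the window in the two scenes, restricted to ``sid_bands``
    (default the blue/green bands 1-4, where the water column is
    transparent; the red, red-edge and NIR bands attenuate within a meter
    or two and are flattened by the glint correction, so over water they
    contribute clipping artifacts rather than stability information).
    Candidates are returned sorted ascending by SID, ties broken by
    row-major anchor order.
    """
    check_grid_compatible([reference, adjusted])
    if size < 2:
        raise ValueError("window size must be >= 2")
    stride = stride or size
    nrows, ncols = reference.grid_shape
    joint = reference.valid_mask & adjusted.valid_mask
    if sid_bands is None:
        sid_bands = tuple(range(reference.n_bands))
    sel = list(sid_bands)
    out: list[PIFPolygon] = []
    for r in range(0, nrows - size + 1, stride):
        for c in range(0, ncols - size + 1, stride):
            win = (slice(r, r + size), slice(c, c + size))
            m = joint[win]
            if m.mean() < min_valid_fraction:
                continue
            mean_ref = reference.reflectance[(slice(None),) + win][:, m].mean(axis=1)
            mean_adj = adjusted.reflectance[(slice(None),) + win][:, m].mean(axis=1)
            sid = spectral_information_divergence(
                np.maximum(mean_ref[sel], 0), np.maximum(mean_adj[sel], 0)
            )
            out.append(
                PIFPolygon(
                    anchor=(r, c), size=size, mean_ref=mean_ref,
                    mean_adj=mean_adj, sid=sid,
                )
            )
    if not out:
        raise ValueError("no eligible PIF candidate windows")
    out.sort(key=lambda p: (p.sid, p.anchor))
    return out


def select_pifs(candidates: list[PIFPolygon], n_pifs: int = 10) -> list[PIFPolygon]:
    """Greedily keep the n_pifs lowest-SID pairwise non-overlapping windows."""
    if n_pifs < 2:
        raise ValueError("n_pifs must be >= 2")
    chosen: list[PIFPolygon] = []
    for cand in candidates:
        if all(not cand.overlaps(s) for s in chosen):
            chosen.append(cand)
        if len(chosen) == n_pifs:
            return chosen
    raise ValueError(
        f"only {len(chosen)} non-overlapping PIF candidates found, "
        f"needed {n_pifs}"
    )


def fit_normalization(
    reference: Scene,
    adjusted: Scene,
    pifs: list[PIFPolygon],
    means_only: bool = False,
    on_degenerate: str = "error",
) -> NormalizationModel:
    """OLS of reference on adjusted over PIF pixels, per band.

    By default the regression pools every jointly valid pixel inside every
    PIF window (n_pifs * size^2 points), which stabilizes the offset; with
    ``means_only`` it uses only the per-window mean spectra, mirroring a
    coarser PIF-means regression.

    A band whose adjusted values have zero variance over the PIF pixels has
    an unidentifiable gain (this happens to the NIR band, which the glint
    correction flattens to the ambient level). ``on_degenerate="error"``
    raises naming the band; ``"mean_shift"`` falls back to gain 1 with an
    offset matching the band means, the best linear map available when the
    predictor is constant.
    """
    if on_degenerate not in ("error", "mean_shift"):
        raise ValueError("on_degenerate must be 'error' or 'mean_shift'")
    if len(pifs) < 2:
        raise ValueError("need at least 2 PIFs")
    check_grid_compatible([reference, adjusted])
    if means_only:
        x = np.stack([p.mean_adj for p in pifs], axis=1)  # (bands, n_pifs)
        y = np.stack([p.mean_ref for p in pifs], axis=1)
    else:
        joint = reference.valid_mask & adjusted.valid_mask
        cols_x, cols_y = [], []
        for p in pifs:
            win = p.window()
            m = joint[win]
            cols_x.append(adjusted.reflectance[(slice(None),) + win][:, m])
            cols_y.append(reference.reflectance[(slice(None),) + win][:, m])
        x = np.concatenate(cols_x, axis=1)
        y = np.concatenate(cols_y, axis=1)
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 regression points")
    gain = np.empty(x.shape[0])
    offset = np.empty(x.shape[0])
    r2 = np.empty(x.shape[0])
    for b in range(x.shape[0]):
        xb, yb = x[b], y[b]
        vx = xb.var()
        if vx <= 0:
            if on_degenerate == "mean_shift":
                gain[b] = 1.0
                offset[b] = yb.mean() - xb.mean()
                r2[b] = 0.0
                continue
            raise ValueError(f"degenerate predictor: band {b + 1} has zero "
                             "variance over PIF pixels")
        cov = np.cov(xb, yb, ddof=0)
        gain[b] = cov[0, 1] / cov[0, 0]
        offset[b] = yb.mean() - gain[b] * xb.mean()
        resid = yb - (gain[b] * xb + offset[b])
        vy = yb.var()
        r2[b] = 1.0 - resid.var() / vy if vy > 0 else 1.0
    return NormalizationModel(
        gain=gain, offset=offset, r2=r2, n_points=n,
        reference_date=reference.acquisition_date,
    )


def apply_normalization(scene: Scene, model: NormalizationModel) -> Scene:
    """Map a scene onto the reference frame: out = gain * in + offset.

    Applies per band on valid pixels; the mask is unchanged and negative
    results are floored at zero (with a log entry when that is frequent).
    """
    if model.gain.shape[0] != scene.n_bands:
        raise ValueError("band count mismatch between scene and model")
    out = scene.reflectance.copy()
    vm = scene.valid_mask
    out[:, vm] = model.gain[:, None] * scene.reflectance[:, vm] + model.offset[:, None]
    neg = out[:, vm] < 0
    if neg.mean() > 0.01:
        log.warning(
            "apply_normalization %s: floored %.2f%% of valid samples at 0",
            scene.acquisition_date, 100 * neg.mean(),
        )
    out[:, vm] = np.maximum(out[:, vm], 0.0)
    return scene.replace(reflectance=out)


def select_pifs_iterative(
    reference: Scene,
    adjusted: Scene,
    size: int = 30,
    n_pifs: int = 10,
    stride: int | None = None,
    max_iterations: int = 5,
    on_degenerate: str = "mean_shift",
) -> list[PIFPolygon]:
    """Iteratively refine the PIF selection by provisional normalization.

    The initial SID ranking is confounded by exactly the scene-wide
    radiometric differences normalization is meant to remove: a common
    additive offset changes dark windows' spectral shape far more than
    bright ones', so the ranking mixes that brightness effect with genuine
    surface change. Each pass fits a provisional model on the current
    PIFs, applies it to the adjusted scene, and re-scores SID against the
    provisionally normalized scene, in which the common distortion cancels
    and real change dominates the ranking. Iteration stops when the
    selected window anchors repeat (a fixed point) or after
    ``max_iterations`` passes. The returned polygons carry the SID and
    means of the raw (reference, adjusted) pair.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    pifs = select_pifs(
        score_pif_candidates(reference, adjusted, size=size, stride=stride),
        n_pifs=n_pifs,
    )
    for _ in range(max_iterations - 1):
        model = fit_normalization(
            reference, adjusted, pifs, on_degenerate=on_degenerate
        )
        provisional = apply_normalization(adjusted, model)
        new = select_pifs(
            score_pif_candidates(reference, provisional, size=size, stride=stride),
            n_pifs=n_pifs,
        )
        if {p.anchor for p in new} == {p.anchor for p in pifs}:
            break
        pifs = new
    # Re-express the final windows against the raw pair so the polygons'
    # mean_adj/sid describe the actual adjusted scene.
    raw = {
        p.anchor: p
        for p in score_pif_candidates(reference, adjusted, size=size, stride=stride)
    }
    return [raw[p.anchor] for p in pifs]


def normalize_to_reference(
    reference: Scene,
    adjusted: Scene,
    size: int = 30,
    n_pifs: int = 10,
    stride: int | None = None,
    means_only: bool = False,
    on_degenerate: str = "mean_shift",
    max_iterations: int = 5,
) -> tuple[Scene, NormalizationModel, list[PIFPolygon]]:
    """Full PIF workflow for one adjusted scene: select (iteratively), fit, apply."""
    pifs = select_pifs_iterative(
        reference, adjusted, size=size, n_pifs=n_pifs, stride=stride,
        max_iterations=max_iterations, on_degenerate=on_degenerate,
    )
    model = fit_normalization(
        reference, adjusted, pifs, means_only=means_only, on_degenerate=on_degenerate
    )
    return apply_normalization(adjusted, model), model, pifs


def polygon_size_variance_profile(
    scene: Scene,
    anchor_region: RegionOfInterest,
    sizes: list[int],
    band: int = BLUE_IDX,
) -> dict[int, float]:
    """Variance of window-mean reflectance as a function of window size.

    For each size, the region is tiled with non-overlapping square windows
    fully contained in the region's pixel set; the variance of the windows'
    band means is returned. Larger windows average more pixels, so the
    profile decreases (sigma^2 / n for iid noise) — the rationale for
    preferring 30x30 PIF polygons over 5x5.
    """
    region_mask = anchor_region.mask(scene.grid_shape)
    rows, cols = anchor_region.indices()
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    band_img = scene.reflectance[band]
    out: dict[int, float] = {}
    for size in sizes:
        means = []
        for r in range(r0, r1 - size + 2, size):
            for c in range(c0, c1 - size + 2, size):
                win = (slice(r, r + size), slice(c, c + size))
                if region_mask[win].all():
                    means.append(band_img[win].mean())
        if len(means) < 2:
            feasible = [s for s in sizes if s <= min(r1 - r0 + 1, c1 - c0 + 1) // 2]
            raise ValueError(
                f"region too small for size {size}; feasible sizes: {feasible}"
            )
        out[size] = float(np.var(means, ddof=1))
    return out
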