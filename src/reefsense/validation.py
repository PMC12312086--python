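"""Seeded validation studies for every pipeline property.

Each function runs one property study end to end on synthetic data and
returns a plain dict of measured quantities. They are consumed by the test
suite and by the acceptance script, and the heavier ones are what the
numbered analysis drivers narrate.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

from .bands import BLUE_IDX, N_BANDS
from .experiments import (cheeca_config, horseshoe_config, run_cheeca_like,
                          run_horseshoe_like)
from .pif import (fit_normalization, score_pif_candidates, select_pifs,
                  select_pifs_iterative, spectral_information_divergence,
                  polygon_size_variance_profile)
from .preprocess import correct_glint
from .scene import RegionOfInterest, Scene
from .synth import (GeneratorConfig, SceneDistortion, simulate_scene,
                    simulate_timeseries, wavelengths)


def sid_brute_force(x, y, eps: float = 1e-12) -> float:
    """Independent two-sum KL oracle for the SID (pure-Python loops)."""
    p = [max(float(v), eps) for v in x]
    q = [max(float(v), eps) for v in y]
    sp, sq = sum(p), sum(q)
    p = [v / sp for v in p]
    q = [v / sq for v in q]
    kl_pq = sum(pi * math.log(pi / qi) for pi, qi in zip(p, q))
    kl_qp = sum(qi * math.log(qi / pi) for pi, qi in zip(p, q))
    return kl_pq + kl_qp


def sid_oracle_study(seed: int, n_pairs: int = 1000) -> dict:
    """Compare the SID implementation to the brute-force oracle."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    max_sym_err = 0.0
    max_self = 0.0
    max_scale = 0.0
    for _ in range(n_pairs):
        x = rng.uniform(1e-4, 0.1, size=8)
        y = rng.uniform(1e-4, 0.1, size=8)
        s = spectral_information_divergence(x, y)
        max_err = max(max_err, abs(s - sid_brute_force(x, y)))
        max_sym_err = max(
            max_sym_err, abs(s - spectral_information_divergence(y, x))
        )
        max_self = max(max_self, spectral_information_divergence(x, x))
        c = float(rng.uniform(0.1, 10))
        max_scale = max(max_scale, spectral_information_divergence(x, c * x))
    return {
        "n_pairs": n_pairs,
        "max_abs_error_vs_oracle": max_err,
        "max_symmetry_error": max_sym_err,
        "max_self_divergence": max_self,
        "max_scale_divergence": max_scale,
    }


def textured_scene(seed: int, n_rows: int = 128, n_cols: int = 128) -> Scene:
    """A multi-band raster with genuine spatial variance in every band.

    Each band is a base level in [0.02, 0.05] sr^-1 plus a smooth
    large-scale field and fine per-pixel texture, mimicking benthic albedo
    and depth structure. Parameter-recovery studies need the regressor to
    carry signal in every band; rendered over-water reef scenes have
    near-zero NIR spatial variance, which makes full-band gain recovery
    ill-posed for any estimator (errors-in-variables attenuation), so the
    recovery property is assessed on textured rasters while reef-scene
    behavior is covered by the scenario studies.
    """
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    out = np.empty((N_BANDS, n_rows, n_cols))
    for b in range(N_BANDS):
        level = rng.uniform(0.02, 0.05)
        smooth = ndimage.gaussian_filter(
            rng.standard_normal((n_rows, n_cols)), sigma=6.0, mode="reflect"
        )
        smooth = smooth / max(smooth.std(), 1e-12) * 0.15 * level
        texture = rng.standard_normal((n_rows, n_cols)) * 0.08 * level
        out[b] = np.maximum(level + smooth + texture, 1e-4)
    return Scene(
        reflectance=out,
        band_wavelengths=wavelengths(),
        valid_mask=np.ones((n_rows, n_cols), dtype=bool),
        acquisition_date=_dt.date(2023, 1, 1),
    )


def simulate_normalization_pair(
    seed: int,
    gain_range=(0.8, 1.2),
    offset_range=(-0.005, 0.005),
    noise_sd: float = 1e-4,
) -> tuple[Scene, Scene, float, float]:
    """Textured reference scene plus an algebraically distorted copy.

    The adjusted scene is gain * reference + offset + Gaussian noise with
    scalar gain/offset drawn from the given ranges. Returns (reference,
    adjusted, gain, offset) where gain/offset map reference -> adjusted.
    """
    rng = np.random.default_rng(seed)
    reference = textured_scene(int(rng.integers(2**31)))
    g = float(rng.uniform(*gain_range))
    o = float(rng.uniform(*offset_range))
    adj = g * reference.reflectance + o
    adj = adj + rng.standard_normal(adj.shape) * noise_sd
    adjusted = reference.replace(
        reflectance=adj,
        acquisition_date=reference.acquisition_date + _dt.timedelta(days=30),
    )
    return reference, adjusted, g, o


def normalization_recovery_study(seed: int, n_runs: int = 100) -> dict:
    """Gain/offset recovery on algebraically constructed scene pairs.

    With adjusted = g * reference + o, the fitted model (reference on
    adjusted) should recover gain 1/g and offset -o/g per band.
    """
    rng = np.random.default_rng(seed)
    ok = 0
    worst_gain, worst_offset = 0.0, 0.0
    for _ in range(n_runs):
        s = int(rng.integers(2**31))
        reference, adjusted, g, o = simulate_normalization_pair(s)
        cands = score_pif_candidates(reference, adjusted, size=30)
        pifs = select_pifs(cands, n_pifs=10)
        model = fit_normalization(reference, adjusted, pifs)
        rel_gain = np.abs(model.gain * g - 1).max()
        abs_off = np.abs(model.offset - (-o / g)).max()
        worst_gain = max(worst_gain, float(rel_gain))
        worst_offset = max(worst_offset, float(abs_off))
        if rel_gain <= 0.02 and abs_off <= 5e-4:
            ok += 1
    return {
        "n_runs": n_runs,
        "recovery_rate": ok / n_runs,
        "worst_rel_gain_error": worst_gain,
        "worst_abs_offset_error": worst_offset,
    }


def exact_linear_recovery() -> dict:
    """Noise-free algebraic case: adjusted = 0.5 * reference - 0.001."""
    gen = GeneratorConfig(
        n_rows=128, n_cols=128, n_dates=3, coral_fraction=0.1,
        bleaching_window=(1, 1), severity=0.0, cloud_fraction=0.0,
        noise_sd_range=(0.0, 0.0), glint_amplitude_range=(0.003, 0.003),
    )
    scenes, _ = simulate_timeseries(gen, seed=7)
    reference = scenes[0]
    adjusted = reference.replace(
        reflectance=0.5 * reference.reflectance - 0.001,
        acquisition_date=reference.acquisition_date + _dt.timedelta(days=1),
    )
    pifs = select_pifs(score_pif_candidates(reference, adjusted, size=30), 10)
    model = fit_normalization(reference, adjusted, pifs)
    return {
        "max_gain_error": float(np.abs(model.gain - 2.0).max()),
        "max_offset_error": float(np.abs(model.offset - 0.002).max()),
    }


def pif_placement_study(seed: int, n_pairs: int = 20) -> dict:
    """PIF selection across a bleaching change, scored against truth.

    Each pair is a reference date outside the bleaching window and an
    adjusted date inside it; a PIF is correctly placed when its window
    contains no live-coral pixel (the only class whose spectrum changed).
    """
    rng = np.random.default_rng(seed)
    base = horseshoe_config().generator
    stable_flags = []
    from .preprocess import preprocess_scene

    for _ in range(n_pairs):
        gen = GeneratorConfig(**{**base.__dict__, "n_dates": 6,
                                 "bleaching_window": (4, 5)})
        scenes, truth = simulate_timeseries(gen, seed=int(rng.integers(2**31)))
        reference = preprocess_scene(scenes[2])  # pre-window
        adjusted = preprocess_scene(scenes[4])  # in-window
        pifs = select_pifs_iterative(reference, adjusted, size=30, n_pifs=10)
        stable = truth.stable_mask()
        stable_flags.extend(bool(stable[p.window()].all()) for p in pifs)
    return {
        "n_pairs": n_pairs,
        "n_pifs": len(stable_flags),
        "stable_fraction": float(np.mean(stable_flags)),
    }


def variance_profile_study(seed: int, n_seeds: int = 50,
                           sizes=(5, 10, 20, 30, 50, 100)) -> dict:
    """Window-mean variance vs window size on iid-noise rasters.

    For iid noise the variance of a size-s window mean is sigma^2 / s^2,
    so the size-5 to size-100 ratio is (100/5)^2 = 400.
    """
    rng = np.random.default_rng(seed)
    n = 400
    roi = RegionOfInterest(
        label="noise",
        pixel_set=frozenset(
            (r, c) for r in range(n) for c in range(n)
        ),
    )
    profiles = []
    for _ in range(n_seeds):
        data = rng.standard_normal((N_BANDS, n, n)) * 1e-3 + 0.02
        scene = Scene(
            reflectance=data, band_wavelengths=wavelengths(),
            valid_mask=np.ones((n, n), dtype=bool),
            acquisition_date=_dt.date(2023, 1, 1),
        )
        prof = polygon_size_variance_profile(scene, roi, sizes=list(sizes))
        profiles.append([prof[s] for s in sizes])
    mean_prof = np.mean(profiles, axis=0)
    by_size = dict(zip(sizes, mean_prof))
    return {
        "n_seeds": n_seeds,
        "variance_ratio_5_vs_100": float(by_size[5] / by_size[100]),
        "mean_profile": {int(s): float(v) for s, v in by_size.items()},
        "profile_non_increasing": bool(np.all(np.diff(mean_prof) <= 0)),
    }


def glint_correction_study(seed: int, amplitude: float = 0.005,
                           noise_sd: float = 1e-4) -> dict:
    """RMS glint-removal performance against the glint-free twin scene.

    Renders the same reef/date/seed twice — once with a glint field of the
    given amplitude, once without — so the two scenes differ only by the
    glint. Reports the RMS error in the blue/green bands (1-3) before and
    after correction, and the idempotence of a second pass.
    """
    gen = GeneratorConfig(
        n_rows=128, n_cols=128, n_dates=3, coral_fraction=0.1,
        bleaching_window=(1, 1), severity=0.0, cloud_fraction=0.0,
        noise_sd_range=(noise_sd, noise_sd),
        glint_amplitude_range=(amplitude, amplitude),
        offset_range=(0.001, 0.001), gain_range=(1.0, 1.0),
    )
    scenes, truth = simulate_timeseries(gen, seed=seed)
    date = scenes[0].acquisition_date
    render_seed = seed + 1
    glinted = simulate_scene(truth, date, seed=render_seed)
    truth.distortions[date] = SceneDistortion(
        gain_true=truth.distortions[date].gain_true,
        offset_true=truth.distortions[date].offset_true,
        glint_amplitude=0.0,
        noise_sd=truth.distortions[date].noise_sd,
    )
    clean = simulate_scene(truth, date, seed=render_seed)
    corrected = correct_glint(glinted)
    twice = correct_glint(corrected)
    vm = glinted.valid_mask
    b13 = slice(0, 3)

    def rms(a: Scene, b: Scene) -> float:
        d = a.reflectance[b13][:, vm] - b.reflectance[b13][:, vm]
        return float(np.sqrt(np.mean(d**2)))

    rms_before = rms(glinted, clean)
    rms_after = rms(corrected, clean)
    idem = float(
        np.abs(twice.reflectance[:, vm] - corrected.reflectance[:, vm]).max()
    )
    return {
        "rms_before": rms_before,
        "rms_after": rms_after,
        "rms_reduction": 1.0 - rms_after / rms_before,
        "idempotence_max_change": idem,
        "noise_sd": noise_sd,
    }


def detection_power_study(seed: int, n_seeds: int = 50,
                          severity: float = 0.5) -> dict:
    """Full-pipeline detection of the bleaching window at a given severity."""
    cfg = horseshoe_config(severity=severity)
    ok = 0
    for i in range(n_seeds):
        rep = run_horseshoe_like(cfg, seed=seed + i)
        if rep["detected_all_window_dates"] and rep["n_false_flags"] <= 1:
            ok += 1
    return {"n_seeds": n_seeds, "severity": severity, "success_rate": ok / n_seeds}


def detection_specificity_study(seed: int, n_seeds: int = 200) -> dict:
    """Per-date false-flag rate of the full pipeline with no bleaching."""
    cfg = horseshoe_config(severity=0.0)
    flags = 0
    dates = 0
    for i in range(n_seeds):
        rep = run_horseshoe_like(cfg, seed=seed + i)
        flags += len(rep["flagged_dates"])
        dates += len(rep["z_scores"]) - len(
            [d for d in rep["z_scores"] if d < rep["window_dates"][0]]
        )
    normal_tail = 0.022750131948179195  # one-sided P(Z >= 2)
    return {
        "n_seeds": n_seeds,
        "n_candidate_dates": dates,
        "false_flag_rate_per_date": flags / dates,
        "normal_tail_at_z2": normal_tail,
    }


def change_contrast_study(seed: int, n_seeds: int = 50) -> dict:
    """Coral-vs-sand blue-band change-map contrast and core-vs-patch z.

    One dense-cover run per seed provides both the normalized-difference
    contrast (criterion behind the bright-gold change regions) and the
    pure-core vs mixed-patch z-score comparison.
    """
    cfg = cheeca_config()
    nd_ok = 0
    core_gt_patch = 0
    n_pairs = 0
    for i in range(n_seeds):
        rep = run_cheeca_like(cfg, seed=seed + i)
        nd_ok += rep["coral_nd_exceeds_sand"]
        for p in rep["patches"]:
            n_pairs += 1
            core_gt_patch += p["core_exceeds_patch"]
    return {
        "n_seeds": n_seeds,
        "coral_exceeds_sand_rate": nd_ok / n_seeds,
        "core_exceeds_patch_rate": core_gt_patch / n_pairs,
        "n_core_patch_pairs": n_pairs,
    }
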