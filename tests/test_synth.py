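import datetime as dt

import numpy as np
import pytest

from reefsense.synth import (ALGAE, BLEACHED, CLOUD_REFLECTANCE, DEEP,
                             DEFAULT_KD, LIVE, SAND, EndmemberLibrary,
                             GeneratorConfig, SceneDistortion, SyntheticTruth,
                             bottom_reflectance, generate_reef_map,
                             make_endmember_library, simulate_scene,
                             simulate_timeseries)


class TestReefMap:
    def test_deterministic(self):
        a = generate_reef_map(seed=7, n_rows=64, n_cols=64, coral_fraction=0.1)
        b = generate_reef_map(seed=7, n_rows=64, n_cols=64, coral_fraction=0.1)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_coral_fraction_of_shallow_area(self):
        cm, depth = generate_reef_map(seed=3, n_rows=128, n_cols=128,
                                      coral_fraction=0.2)
        shallow = cm != DEEP
        frac = (cm == LIVE).sum() / shallow.sum()
        assert abs(frac - 0.2) <= 0.05

    def test_depth_ranges(self):
        cm, depth = generate_reef_map(seed=3, n_rows=64, n_cols=64,
                                      coral_fraction=0.1)
        assert depth[cm == DEEP].min() >= 15.0
        assert depth[cm != DEEP].max() < 6.0
        assert (depth >= 0).all()

    def test_all_classes_present(self):
        cm, _ = generate_reef_map(seed=1, n_rows=96, n_cols=96,
                                  coral_fraction=0.15)
        for cls in (LIVE, SAND, ALGAE, DEEP):
            assert (cm == cls).any()

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="32"):
            generate_reef_map(seed=0, n_rows=16, n_cols=64, coral_fraction=0.1)


def _identity_truth(class_map, depth, severity=0.0, window=None, lib=None):
    date = dt.date(2023, 6, 1)
    window = window or (date, date)
    return date, SyntheticTruth(
        class_map=class_map,
        depth_map=depth,
        attenuation=DEFAULT_KD.copy(),
        distortions={
            date: SceneDistortion(
                gain_true=1.0, offset_true=0.0,
                glint_amplitude=0.0, noise_sd=0.0,
            )
        },
        bleaching_window=window,
        severity=severity,
        library=lib or make_endmember_library(),
        cloud_fraction=0.0,
    )


class TestObservationModel:
    def test_two_flow_closed_form(self):
        """Undistorted scene matches R_w(1-e^{-2Kz}) + R_b e^{-2Kz} exactly."""
        cm, depth = generate_reef_map(seed=5, n_rows=64, n_cols=64,
                                      coral_fraction=0.1)
        date, truth = _identity_truth(cm, depth)
        scene = simulate_scene(truth, date, seed=0)
        lib = truth.library
        bottom = lib.spectra[cm]  # (r, c, b)
        att = np.exp(-2.0 * DEFAULT_KD[None, None, :] * depth[:, :, None])
        expected = lib.spectra[DEEP][None, None, :] * (1 - att) + bottom * att
        np.testing.assert_allclose(
            scene.reflectance, np.moveaxis(expected, 2, 0), atol=1e-12
        )

    def test_reflectance_decreases_with_depth(self):
        """Same bottom, deeper water -> dimmer in every band."""
        cm = np.full((32, 32), SAND, dtype=np.int8)
        lib = make_endmember_library()
        for band in range(8):
            shallow_r = None
            for z in (1.0, 5.0, 20.0):
                date, truth = _identity_truth(cm, np.full((32, 32), z), lib=lib)
                s = simulate_scene(truth, date, seed=0)
                v = s.reflectance[band, 0, 0]
                if shallow_r is not None:
                    assert v < shallow_r
                shallow_r = v

    def test_bleaching_mix_in_window_only(self):
        lib = make_endmember_library()
        cm = np.full((32, 32), LIVE, dtype=np.int8)
        depth = np.ones((32, 32))
        date, truth = _identity_truth(
            cm, depth, severity=0.5,
            window=(dt.date(2023, 6, 1), dt.date(2023, 6, 1)),
        )
        mixed = bottom_reflectance(truth, date)
        expect = 0.5 * lib.spectra[LIVE] + 0.5 * lib.spectra[BLEACHED]
        np.testing.assert_allclose(mixed[0, 0], expect)
        outside = bottom_reflectance(truth, dt.date(2023, 1, 1))
        np.testing.assert_allclose(outside[0, 0], lib.spectra[LIVE])

    def test_distortion_is_exactly_linear(self):
        """Rendering with (g, o) equals g*(identity render) + o, same seed."""
        cm, depth = generate_reef_map(seed=5, n_rows=64, n_cols=64,
                                      coral_fraction=0.1)
        date, truth = _identity_truth(cm, depth)
        base = simulate_scene(truth, date, seed=9)
        truth.distortions[date] = SceneDistortion(
            gain_true=1.1, offset_true=0.002, glint_amplitude=0.0, noise_sd=0.0,
        )
        distorted = simulate_scene(truth, date, seed=9)
        np.testing.assert_allclose(
            distorted.reflectance, 1.1 * base.reflectance + 0.002, atol=1e-12
        )

    def test_same_seed_scenes_differ_only_by_distortion_params(self):
        """Glint/noise draws are seed-determined, so an amplitude change
        moves the scene by exactly amplitude_ratio * glint_field."""
        cm, depth = generate_reef_map(seed=5, n_rows=64, n_cols=64,
                                      coral_fraction=0.1)
        date, truth = _identity_truth(cm, depth)
        truth.distortions[date].glint_amplitude = 0.004
        a = simulate_scene(truth, date, seed=4)
        field_a = truth.glint_fields[date].copy()
        truth.distortions[date].glint_amplitude = 0.0
        b = simulate_scene(truth, date, seed=4)
        np.testing.assert_allclose(
            a.reflectance - b.reflectance,
            np.broadcast_to(field_a, (8,) + field_a.shape), atol=1e-12,
        )


class TestTimeseries:
    def test_series_shape_truth_and_clouds(self, small_series):
        scenes, truth, gen = small_series
        assert len(scenes) == gen.n_dates
        dates = [s.acquisition_date for s in scenes]
        assert dates == sorted(dates)
        w0, w1 = gen.bleaching_window
        assert truth.bleaching_window == (dates[w0], dates[w1])
        for s in scenes:
            clouds = truth.cloud_masks[s.acquisition_date]
            assert np.array_equal(s.valid_mask, ~clouds)
            # Cloud pixels painted bright in every band.
            if clouds.any():
                assert np.all(s.reflectance[:, clouds] == CLOUD_REFLECTANCE)
            frac = clouds.mean()
            assert abs(frac - gen.cloud_fraction) <= 0.01

    def test_deterministic(self):
        gen = GeneratorConfig(n_rows=64, n_cols=64, n_dates=3,
                              bleaching_window=(1, 1))
        s1, _ = simulate_timeseries(gen, seed=42)
        s2, _ = simulate_timeseries(gen, seed=42)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.reflectance, b.reflectance)

    def test_window_outside_span_rejected(self):
        gen = GeneratorConfig(n_dates=5, bleaching_window=(4, 6))
        with pytest.raises(ValueError, match="window"):
            simulate_timeseries(gen, seed=0)

    def test_stable_mask_excludes_live_coral_only(self, small_series):
        _, truth, _ = small_series
        assert np.array_equal(truth.stable_mask(), truth.class_map != LIVE)


class TestLibrary:
    def test_preset_orderings(self):
        lib = make_endmember_library()
        blue_green = slice(0, 4)
        assert np.all(lib.spectrum("bleached_coral")[blue_green]
                      > lib.spectrum("live_coral")[blue_green])
        assert np.all(lib.spectrum("sand")[blue_green]
                      > lib.spectrum("bleached_coral")[blue_green])
        # Water-column asymptote below every bottom endmember.
        deep = lib.spectrum("deep_water")
        for name in ("live_coral", "bleached_coral", "sand", "algae"):
            assert np.all(lib.spectrum(name) >= deep)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="florida_default"):
            make_endmember_library("atlantis")

    def test_negative_spectra_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            EndmemberLibrary(("a",), -np.ones((1, 8)))
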