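import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import flat_scene, make_scene
from reefsense.pif import (NormalizationModel, PIFPolygon,
                           apply_normalization, fit_normalization,
                           normalize_to_reference,
                           polygon_size_variance_profile,
                           score_pif_candidates, select_pifs,
                           select_pifs_iterative,
                           spectral_information_divergence)
from reefsense.scene import RegionOfInterest

spectra = st.lists(
    st.floats(min_value=1e-6, max_value=1.0, allow_nan=False), min_size=2,
    max_size=12,
)


class TestSID:
    def test_identity_is_zero(self):
        x = np.array([0.01, 0.02, 0.03])
        assert spectral_information_divergence(x, x) == 0.0

    def test_scale_invariance(self):
        x = np.array([0.01, 0.02, 0.03])
        assert spectral_information_divergence(x, 2 * x) <= 1e-14

    def test_frozen_oracle_example(self):
        # Independently computed two-sum KL value for this pair.
        got = spectral_information_divergence(
            np.array([0.02, 0.03, 0.04]), np.array([0.04, 0.03, 0.02])
        )
        assert abs(got - 0.3080654135821981) <= 1e-12

    def test_input_validation(self):
        x = np.array([0.01, 0.02])
        with pytest.raises(ValueError):
            spectral_information_divergence(x, np.array([0.01, 0.02, 0.03]))
        with pytest.raises(ValueError):
            spectral_information_divergence(x, np.array([-0.01, 0.02]))
        with pytest.raises(ValueError):
            spectral_information_divergence(x, np.zeros(2))

    @settings(max_examples=50, deadline=None)
    @given(spectra, spectra)
    def test_non_negative_and_symmetric(self, xs, ys):
        if len(xs) != len(ys):
            ys = (ys * len(xs))[: len(xs)]
        x, y = np.array(xs), np.array(ys)
        s = spectral_information_divergence(x, y)
        assert s >= -1e-12
        assert s == spectral_information_divergence(y, x)

    @settings(max_examples=50, deadline=None)
    @given(spectra, st.floats(min_value=0.1, max_value=10.0))
    def test_scale_invariance_property(self, xs, c):
        x = np.array(xs)
        assert spectral_information_divergence(x, c * x) <= 1e-10


def _pair(seed=0, shape=(90, 90)):
    """Reference with spatial texture and an identical copy."""
    rng = np.random.default_rng(seed)
    data = rng.uniform(0.01, 0.05, size=(8,) + shape)
    ref = make_scene(data, date=dt.date(2023, 4, 18))
    adj = ref.replace(acquisition_date=dt.date(2023, 5, 18))
    return ref, adj


class TestScoring:
    def test_identical_scenes_all_zero_sid(self):
        ref, adj = _pair()
        cands = score_pif_candidates(ref, adj, size=30)
        assert len(cands) == 9
        assert all(c.sid == 0.0 for c in cands)

    def test_gain_only_distortion_sid_near_zero(self):
        ref, adj = _pair()
        adj = adj.replace(reflectance=1.3 * adj.reflectance)
        cands = score_pif_candidates(ref, adj, size=30)
        assert max(c.sid for c in cands) <= 1e-12

    def test_sorted_ascending_with_row_major_ties(self):
        ref, adj = _pair()
        cands = score_pif_candidates(ref, adj, size=30)
        assert [c.anchor for c in cands] == sorted(c.anchor for c in cands)

    def test_mostly_invalid_window_excluded(self):
        ref, adj = _pair()
        mask = ref.valid_mask.copy()
        mask[0:30, 0:30] = False  # 100% invalid, far below the 90% rule
        ref = ref.replace(valid_mask=mask)
        cands = score_pif_candidates(ref, adj, size=30)
        assert all(c.anchor != (0, 0) for c in cands)

    def test_no_eligible_window_errors(self):
        ref, adj = _pair()
        ref = ref.replace(valid_mask=np.zeros(ref.grid_shape, bool))
        with pytest.raises(ValueError, match="eligible"):
            score_pif_candidates(ref, adj, size=30)


def _poly(anchor, sid, size=30):
    m = np.full(8, 0.02)
    return PIFPolygon(anchor=anchor, size=size, mean_ref=m, mean_adj=m, sid=sid)


class TestSelection:
    def test_ties_resolve_row_major(self):
        cands = [_poly(a, 0.0) for a in [(0, 0), (0, 30), (30, 0), (30, 30)]]
        chosen = select_pifs(cands, n_pifs=2)
        assert [c.anchor for c in chosen] == [(0, 0), (0, 30)]

    def test_overlapping_window_skipped(self):
        cands = [_poly((0, 0), 0.1), _poly((10, 10), 0.2), _poly((40, 40), 0.3)]
        chosen = select_pifs(cands, n_pifs=2)
        assert [c.anchor for c in chosen] == [(0, 0), (40, 40)]

    def test_too_few_nonoverlapping_errors(self):
        cands = [_poly((0, 0), 0.1), _poly((10, 10), 0.2)]
        with pytest.raises(ValueError, match="only 1"):
            select_pifs(cands, n_pifs=2)


class TestFitting:
    def test_identity_pair(self):
        ref, adj = _pair()
        pifs = select_pifs(score_pif_candidates(ref, adj, size=30), 4)
        m = fit_normalization(ref, adj, pifs)
        np.testing.assert_allclose(m.gain, 1.0, atol=1e-10)
        np.testing.assert_allclose(m.offset, 0.0, atol=1e-10)
        np.testing.assert_allclose(m.r2, 1.0, atol=1e-10)

    def test_exact_algebraic_pair(self):
        ref, _ = _pair(seed=1)
        adj = ref.replace(
            reflectance=0.5 * ref.reflectance - 0.001,
            acquisition_date=dt.date(2023, 5, 18),
        )
        pifs = select_pifs(score_pif_candidates(ref, adj, size=30), 4)
        m = fit_normalization(ref, adj, pifs)
        np.testing.assert_allclose(m.gain, 2.0, atol=1e-8)
        np.testing.assert_allclose(m.offset, 0.002, atol=1e-8)

    def test_degenerate_band_errors_by_default(self):
        ref, adj = _pair(seed=2)
        const = adj.reflectance.copy()
        const[7] = 0.02  # NIR flattened, as after glint correction
        adj = adj.replace(reflectance=const)
        pifs = select_pifs(score_pif_candidates(ref, adj, size=30), 4)
        with pytest.raises(ValueError, match="band 8"):
            fit_normalization(ref, adj, pifs)
        m = fit_normalization(ref, adj, pifs, on_degenerate="mean_shift")
        assert m.gain[7] == 1.0 and m.r2[7] == 0.0
        assert abs(m.offset[7] - (ref.reflectance[7].mean() - 0.02)) < 1e-3

    def test_means_only_mode(self):
        ref, _ = _pair(seed=3)
        adj = ref.replace(
            reflectance=0.8 * ref.reflectance + 0.002,
            acquisition_date=dt.date(2023, 5, 18),
        )
        pifs = select_pifs(score_pif_candidates(ref, adj, size=30), 4)
        m = fit_normalization(ref, adj, pifs, means_only=True)
        assert m.n_points == 4
        np.testing.assert_allclose(m.gain, 1.25, atol=1e-8)


class TestApply:
    def test_identity_model(self):
        s = flat_scene(0.02)
        m = NormalizationModel(
            gain=np.ones(8), offset=np.zeros(8), r2=np.ones(8),
            n_points=10, reference_date=dt.date(2023, 4, 18),
        )
        out = apply_normalization(s, m)
        np.testing.assert_array_equal(out.reflectance, s.reflectance)

    def test_normalized_matches_reference_on_pifs(self):
        ref, _ = _pair(seed=4)
        adj = ref.replace(
            reflectance=0.5 * ref.reflectance - 0.001,
            acquisition_date=dt.date(2023, 5, 18),
        )
        norm, model, pifs = normalize_to_reference(ref, adj, size=30, n_pifs=4)
        for p in pifs:
            win = (slice(None),) + p.window()
            np.testing.assert_allclose(
                norm.reflectance[win], ref.reflectance[win], atol=1e-10
            )

    def test_negative_results_floored(self):
        s = flat_scene(0.02)
        m = NormalizationModel(
            gain=np.ones(8), offset=np.full(8, -0.05), r2=np.ones(8),
            n_points=10, reference_date=dt.date(2023, 4, 18),
        )
        out = apply_normalization(s, m)
        assert (out.reflectance == 0).all()

    def test_band_count_mismatch(self):
        s = flat_scene(0.02)
        m = NormalizationModel(
            gain=np.ones(3), offset=np.zeros(3), r2=np.ones(3),
            n_points=10, reference_date=dt.date(2023, 4, 18),
        )
        with pytest.raises(ValueError, match="band count"):
            apply_normalization(s, m)


def test_iterative_selection_is_fixed_point_stable():
    ref, _ = _pair(seed=5)
    adj = ref.replace(
        reflectance=1.1 * ref.reflectance + 0.001,
        acquisition_date=dt.date(2023, 5, 18),
    )
    once = select_pifs_iterative(ref, adj, size=30, n_pifs=4, max_iterations=1)
    many = select_pifs_iterative(ref, adj, size=30, n_pifs=4, max_iterations=5)
    assert len(many) == 4
    # Polygons describe the raw adjusted scene regardless of iterations.
    for p in many:
        win = (slice(None),) + p.window()
        np.testing.assert_allclose(
            p.mean_adj, adj.reflectance[win].mean(axis=(1, 2)), atol=1e-12
        )
    assert {p.anchor for p in once} <= {c.anchor for c in
                                        score_pif_candidates(ref, adj, 30)}


class TestVarianceProfile:
    def test_constant_raster_zero_everywhere(self):
        s = flat_scene(0.02, shape=(100, 100))
        roi = RegionOfInterest(
            "all", frozenset((r, c) for r in range(100) for c in range(100))
        )
        prof = polygon_size_variance_profile(s, roi, sizes=[5, 10, 25])
        # Window means of a constant raster differ only in the last ulp.
        assert all(v <= 1e-30 for v in prof.values())

    def test_region_too_small_lists_feasible(self):
        s = flat_scene(0.02, shape=(100, 100))
        roi = RegionOfInterest(
            "small", frozenset((r, c) for r in range(20) for c in range(20))
        )
        with pytest.raises(ValueError, match="feasible"):
            polygon_size_variance_profile(s, roi, sizes=[5, 50])
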