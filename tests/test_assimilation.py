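"""Heterogeneity maps: normalization algebra, variants, masks, cuts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardialt import assimilation as asm
from cardialt import synthdata
from cardialt.parameters import ModelParameters


def _three_pixel(values, delta, recip=False):
    s = np.array([values], dtype=float)
    mask = np.ones_like(s, dtype=bool)
    if recip:
        return asm.make_reciprocal_map(s, delta, mask)
    return asm.make_heterogeneity_map(s, delta, mask, smooth=False)


class TestNormalization:
    def test_three_pixel_hand_example(self):
        h = _three_pixel([1.0, 2.0, 3.0], 0.5)
        assert np.allclose(h.H, [[0.5, 1.0, 1.5]])

    def test_reciprocal_hand_example(self):
        # 1/{0.5, 1, 1.5} = {2, 1, 2/3}; mean 11/9 -> H = {1.5, 6/7, 9/14}
        h = _three_pixel([0.5, 1.0, 1.5], 0.5, recip=True)
        assert np.allclose(h.H, [[1.5, 6.0 / 7.0, 9.0 / 14.0]])
        assert h.source == "reciprocal"

    def test_delta_zero_is_identity(self):
        h = _three_pixel([1.0, 5.0, 9.0], 0.0)
        assert np.all(h.H == 1.0)

    def test_constant_input_flagged_degenerate(self):
        h = _three_pixel([2.0, 2.0, 2.0], 0.5)
        assert h.degenerate
        assert np.all(h.H == 1.0)

    def test_constant_reciprocal_is_identity(self):
        h = _three_pixel([3.0, 3.0, 3.0], 0.5, recip=True)
        assert np.all(h.H == 1.0)

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _three_pixel([1.0, 2.0], 1.5)

    def test_nonpositive_reciprocal_rejected(self):
        with pytest.raises(ValueError):
            _three_pixel([0.0, 1.0], 0.5, recip=True)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            asm.make_heterogeneity_map(np.ones((3, 3)), 0.5,
                                       np.zeros((3, 3), bool))

    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_mean_one_and_max_deviation_delta(self, seed, delta):
        rng = np.random.default_rng(seed)
        s = rng.random((12, 12)) + 0.5
        mask = rng.random((12, 12)) > 0.3
        if not mask.any() or np.ptp(s[mask]) == 0:
            return
        for h in (asm.make_heterogeneity_map(s, delta, mask, smooth=False),
                  asm.make_reciprocal_map(s, delta, mask)):
            assert h.mask_mean == pytest.approx(1.0, abs=1e-9)
            assert h.max_deviation == pytest.approx(delta, abs=1e-9)
            assert np.all(h.H[~mask] == 1.0)

    def test_smoothing_metadata_recorded(self):
        s = np.random.default_rng(0).random((20, 20))
        h = asm.make_heterogeneity_map(s, 0.5, np.ones((20, 20), bool))
        assert h.smoothing["smoothed"]
        assert h.smoothing["radius_px"] == 6
        assert h.smoothing["sigma_px"] == pytest.approx(np.sqrt(5.0))


class TestVariants:
    def test_homogeneous_fields_are_uniform(self):
        p = ModelParameters()
        flds = asm.apply_heterogeneity(p, asm.ModelVariant.homogeneous(),
                                       shape=(4, 4))
        for name, grid in flds.items():
            assert np.all(grid == getattr(p, name))

    def test_h1_leaves_apd_parameters_uniform(self):
        p = ModelParameters()
        h = _three_pixel([1.0, 2.0, 3.0], 0.5)
        flds = asm.apply_heterogeneity(p, asm.ModelVariant.h1(h))
        assert np.allclose(flds["D_par"], p.D_par * h.H)
        assert np.all(flds["tau_si"] == p.tau_si)

    def test_h2_leaves_diffusivity_uniform(self):
        p = ModelParameters()
        h = _three_pixel([1.0, 2.0, 3.0], 0.5)
        flds = asm.apply_heterogeneity(p, asm.ModelVariant.h2(h))
        assert np.all(flds["D_par"] == p.D_par)
        assert np.allclose(flds["tau_so1"], p.tau_so1 * h.H)

    def test_h3_bounds_interval_arithmetic(self):
        # delta = 0.5 -> every scaled parameter lies in [0.5, 1.5] * mean
        rng = np.random.default_rng(4)
        s = rng.random((16, 16))
        mask = np.ones((16, 16), bool)
        H1 = asm.make_heterogeneity_map(s, 0.5, mask, smooth=False)
        H2 = asm.make_reciprocal_map(H1.H, 0.5, mask)
        p = ModelParameters()
        flds = asm.apply_heterogeneity(p, asm.ModelVariant.h3(H1, H2))
        assert flds["D_par"].min() >= 0.005 - 1e-12
        assert flds["D_par"].max() <= 0.015 + 1e-12
        assert flds["tau_si"].min() >= 1.45065 - 1e-9
        assert flds["tau_si"].max() <= 4.35195 + 1e-9

    def test_nonpositive_h_rejected(self):
        p = ModelParameters()
        h = _three_pixel([1.0, 2.0, 3.0], 1.0)  # min H = 0
        with pytest.raises(ValueError):
            asm.apply_heterogeneity(p, asm.ModelVariant.h1(h))

    def test_h3_with_unit_map_reproduces_h1_run(self):
        from cardialt import tissue_sim as ts

        rng = np.random.default_rng(5)
        mask = np.ones((12, 12), bool)
        H1 = asm.make_heterogeneity_map(rng.random((12, 12)), 0.5, mask,
                                        smooth=False)
        unit = asm.HeterogeneityMap(H=np.ones((12, 12)), delta=0.0,
                                    mask=mask)
        dom_a = asm.build_variant_domain(asm.ModelVariant.h1(H1), dx=0.05)
        dom_b = asm.build_variant_domain(
            asm.ModelVariant.h3(H1, unit), dx=0.05)
        proto = ts.StimulusProtocol(schedule=[(5.0, 1)], site="base")
        rec_a = ts.run_protocol(dom_a, proto, dt=0.02)
        rec_b = ts.run_protocol(dom_b, proto, dt=0.02)
        assert np.array_equal(rec_a.u_stack, rec_b.u_stack)


class TestTissueMask:
    def test_known_polygon_recovered(self):
        scene = synthdata.two_region_scene(ny=48, nx=48, duration_s=3.0,
                                           noise_sigma=0.05, seed=21)
        movie = synthdata.generate_movie(scene)
        truth = scene.tissue_mask()
        mask = asm.compute_tissue_mask(movie, snr_threshold=3.0)
        jacc = (mask & truth).sum() / (mask | truth).sum()
        assert jacc > 0.95

    def test_all_noise_movie_rejected(self):
        rng = np.random.default_rng(6)
        from cardialt.ffi import OpticalMovie

        movie = OpticalMovie(stack=rng.normal(0, 1.0, (600, 16, 16)))
        with pytest.raises(ValueError):
            asm.compute_tissue_mask(movie, snr_threshold=3.0)

    def test_noiseless_full_frame_signal(self):
        scene = synthdata.two_region_scene(ny=24, nx=24, duration_s=3.0,
                                           noise_sigma=0.0, border_px=0,
                                           seed=22)
        movie = synthdata.generate_movie(scene)
        mask = asm.compute_tissue_mask(movie, snr_threshold=3.0)
        assert mask.all()


class TestCutsAndResampling:
    def _map(self, seed=0, shape=(32, 32), delta=0.5):
        rng = np.random.default_rng(seed)
        return asm.make_heterogeneity_map(rng.random(shape), delta,
                                          np.ones(shape, bool))

    def test_constant_map_constant_profile(self):
        mask = np.ones((16, 16), bool)
        h = asm.HeterogeneityMap(H=np.full((16, 16), 1.0), delta=0.0,
                                 mask=mask)
        _, vals = asm.extract_1d_cut(h, [(2, 2), (13, 13)])
        assert np.allclose(vals, 1.0)

    def test_axis_aligned_cut_matches_row(self):
        h = self._map(7)
        s, vals = asm.extract_1d_cut(h, [(10, 2), (10, 29)], n_samples=28)
        expected = np.interp(np.linspace(2, 29, 28), np.arange(32),
                             h.H[10, :])
        assert np.allclose(vals, expected, atol=1e-9)

    def test_path_outside_mask_rejected(self):
        h = self._map(8)
        mask = h.mask.copy()
        mask[:, 16:] = False
        h2 = asm.HeterogeneityMap(H=h.H, delta=h.delta, mask=mask)
        with pytest.raises(ValueError):
            asm.extract_1d_cut(h2, [(5, 5), (5, 30)])

    def test_resample_preserves_mean_one(self):
        h = self._map(9)
        out = asm.resample_map(h, (48, 48))
        assert out.mask_mean == pytest.approx(1.0, abs=1e-9)
        assert out.H.shape == (48, 48)
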