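"""dAPD maps: preprocessing, extraction, classification, transitions."""

import numpy as np
import pytest

from cardialt import alternans as alt
from cardialt import ffi


def _pulse_movie(widths_ms, shape=(8, 8), cl_ms=250.0, dt_ms=2.0,
                 n_cycles=8, start_ms=20.0):
    """Rectangular-pulse movie with per-beat widths cycling over the list."""
    n = int(n_cycles * cl_ms / dt_ms)
    t = np.arange(n) * dt_ms
    y = np.zeros(n)
    for k in range(n_cycles):
        w = widths_ms[k % len(widths_ms)]
        y[(t >= start_ms + k * cl_ms) & (t < start_ms + k * cl_ms + w)] = 1.0
    stack = np.broadcast_to(y[:, None, None], (n,) + shape).copy()
    return ffi.OpticalMovie(stack=stack, frame_interval_ms=dt_ms,
                            provenance="synthetic")


class TestPreprocess:
    def test_constant_movie_unchanged_up_to_offset(self):
        movie = ffi.OpticalMovie(stack=np.full((50, 6, 6), 3.0))
        out = alt.preprocess_movie(movie)
        assert np.allclose(out.stack - out.stack.mean(), 0.0, atol=1e-12)

    def test_linear_ramp_removed(self):
        t = np.arange(200.0)
        stack = np.broadcast_to((0.05 * t)[:, None, None],
                                (200, 5, 5)).copy()
        out = alt.preprocess_movie(ffi.OpticalMovie(stack=stack))
        resid = out.stack[:, 2, 2]
        slope = np.polyfit(t, resid, 1)[0]
        assert abs(slope) < 1e-6

    def test_impulse_response_widths(self):
        stack = np.zeros((51, 21, 21))
        stack[25, 10, 10] = 1.0
        out = alt.preprocess_movie(ffi.OpticalMovie(stack=stack))
        trace = out.stack[:, 10, 10]
        # temporal rectangular window: 7 frames share the impulse equally
        # (the detrend leaves a small offset everywhere else)
        big = np.flatnonzero(np.abs(trace) > 0.3 * np.abs(trace).max())
        assert big.min() == 22 and big.max() == 28
        # spatial Gaussian truncated at 4 px radius; difference of frames
        # cancels the detrend offset
        d = out.stack[25] - out.stack[10]
        assert d[10, 14] - d[10, 16] > 0
        assert d[10, 15] == pytest.approx(d[10, 16], abs=1e-12)

    def test_short_movie_rejected(self):
        with pytest.raises(ValueError):
            alt.preprocess_movie(ffi.OpticalMovie(stack=np.ones((5, 4, 4))))


class TestAPDExtraction:
    def test_square_pulse_width(self):
        # the 20% threshold interpolates asymmetrically on a square edge:
        # up to (1 - 2*0.2) * frame_interval of systematic widening
        movie = _pulse_movie([100.0])
        seq = alt.extract_apd_sequence(movie.pixel_trace(3, 3), 2.0)
        assert len(seq.apds) == 8
        assert np.allclose(seq.apds, 100.0, atol=1.5)

    def test_alternating_widths(self):
        movie = _pulse_movie([120.0, 80.0])
        seq = alt.extract_apd_sequence(movie.pixel_trace(3, 3), 2.0)
        assert np.allclose(seq.apds[::2], 120.0, atol=1.5)
        assert np.allclose(seq.apds[1::2], 80.0, atol=1.5)

    def test_flat_trace_yields_empty_sequence(self):
        seq = alt.extract_apd_sequence(np.zeros(100), 2.0)
        assert seq.n_beats == 0

    def test_agrees_with_model_detector(self):
        from cardialt import ap_model as am
        from cardialt.parameters import ModelParameters

        p = ModelParameters()
        t, trace, _ = am.simulate_cell(p, 2000.0, dt=0.01,
                                       cycle_length_ms=500.0,
                                       record_interval_ms=2.0)
        seq_model = am.apd_sequence_from_trace(trace, 2.0)
        seq_optical = alt.extract_apd_sequence(trace, 2.0)
        n = min(seq_model.n_beats, seq_optical.n_beats)
        assert n >= 3
        assert np.allclose(seq_model.apds[:n], seq_optical.apds[:n],
                           atol=2.0)


class TestDeltaAPDMap:
    def test_uniform_alternation_sign(self):
        movie = _pulse_movie([120.0, 80.0])
        m = alt.delta_apd_map(movie, beat_pair=(0, 1))
        assert np.allclose(m.delta, -40.0, atol=1.5)
        m2 = alt.delta_apd_map(movie, beat_pair=(1, 2))
        assert np.allclose(m2.delta, 40.0, atol=1.5)

    def test_antisymmetry_in_beat_order(self):
        movie = _pulse_movie([120.0, 80.0])
        a = alt.delta_apd_map(movie, beat_pair=(2, 3)).delta
        b = alt.delta_apd_map(movie, beat_pair=(3, 2)).delta
        assert np.allclose(a, -b)

    def test_non_alternating_movie_is_all_nodal(self):
        movie = _pulse_movie([100.0])
        m = alt.delta_apd_map(movie)
        assert m.nodal_mask.all()

    def test_synthetic_da_sign_partition(self, da_movie_pre, da_scene):
        m = alt.classify_pattern(alt.delta_apd_map(da_movie_pre))
        assert m.label == "DA"
        labels = da_scene.region_labels
        cols = np.arange(da_scene.nx)[None, :] * np.ones((da_scene.ny, 1))
        interior = np.abs(cols - da_scene.nx / 2 + 0.5) > 8
        s_left = np.sign(np.nanmedian(m.delta[(labels == 0) & interior]))
        s_right = np.sign(np.nanmedian(m.delta[(labels == 1) & interior]))
        assert s_left == -s_right != 0
        # a nodal line separates the regions: every interior row crosses
        # at least one nodal pixel inside the transition band
        band = (np.abs(cols - da_scene.nx / 2 + 0.5) <= 3.0) & (labels >= 0)
        rows_with_node = (m.nodal_mask & band).any(axis=1)
        tissue_rows = band.any(axis=1)
        assert rows_with_node[tissue_rows].mean() > 0.9

    def test_nodal_band_follows_temporal_resolution(self, da_movie):
        # the +-2 ms band is set by the 2 ms frame interval; at coarser
        # sampling the band scales with the resolution and the nodal region
        # can only widen
        fine = alt.preprocess_movie(da_movie)
        coarse_stack = da_movie.stack[::4]
        coarse = alt.preprocess_movie(
            ffi.OpticalMovie(stack=coarse_stack, frame_interval_ms=8.0,
                             mask=da_movie.mask))
        m_fine = alt.delta_apd_map(fine, nodal_band_ms=2.0)
        m_coarse = alt.delta_apd_map(coarse, nodal_band_ms=8.0)
        tissue = da_movie.mask
        frac_fine = (m_fine.nodal_mask & tissue).sum() / tissue.sum()
        frac_coarse = (m_coarse.nodal_mask & tissue).sum() / tissue.sum()
        assert frac_coarse >= frac_fine


class TestPatternClassification:
    def _map(self, delta, mask=None):
        m = alt.DeltaAPDMap(delta=delta, beat_pair=(0, 1),
                            tissue_mask=mask)
        return alt.classify_pattern(m)

    def test_whole_tissue_one_sign_is_ca(self):
        assert self._map(np.full((20, 20), 10.0)).label == "CA"

    def test_two_opposite_regions_is_da(self):
        d = np.full((20, 20), 10.0)
        d[:, 10:] = -10.0
        m = self._map(d)
        assert m.label == "DA"
        assert (m.summary["n_components_positive"]
                + m.summary["n_components_negative"]) == 2

    def test_below_band_is_none(self):
        m = self._map(np.full((20, 20), 0.5))
        assert m.label == "none"
        assert m.summary["nodal_fraction"] == 1.0


class TestTransitions:
    @pytest.mark.parametrize("labels,expected", [
        (["none", "CA", "CA", "DA"], 1),
        (["CA", "DA", "CA", "DA"], 3),
        (["none", "none", "none"], 0),
        (["CA", "none", "DA"], 1),
    ])
    def test_counting(self, labels, expected):
        assert alt.count_transitions(labels) == expected
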