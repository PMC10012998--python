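"""Fourier transformation imaging: spectra, maps, classification."""

import numpy as np
import pytest

from cardialt import ffi, synthdata


def _tone_movie(f_hz=1.0, duration_s=10.0, dt_ms=2.0, shape=(6, 6),
                gain=1.0, provenance="simulated"):
    t = np.arange(int(duration_s * 1000 / dt_ms)) * dt_ms / 1000.0
    trace = gain * np.sin(2 * np.pi * f_hz * t)
    stack = np.broadcast_to(trace[:, None, None],
                            (len(t),) + shape).copy()
    return ffi.OpticalMovie(stack=stack, frame_interval_ms=dt_ms,
                            provenance=provenance)


class TestTransform:
    def test_pure_tone_single_peak_everywhere(self):
        movie = _tone_movie(1.0)
        stack = ffi.ffi_transform(movie)
        k = stack.nearest_bin(1.0)
        amp = stack.amplitude
        peak = amp[k]
        others = np.delete(amp, k, axis=0)
        assert np.all(peak > 0)
        assert others.max() < 1e-9 * peak.min()

    def test_constant_movie_is_dc_only(self):
        movie = ffi.OpticalMovie(stack=np.ones((100, 4, 4)),
                                 provenance="simulated")
        stack = ffi.ffi_transform(movie)
        assert np.abs(stack.amplitude[1:]).max() < 1e-9

    def test_window_beyond_movie_rejected(self):
        movie = _tone_movie(1.0, duration_s=1.0)
        with pytest.raises(ValueError):
            ffi.ffi_transform(movie, window=(0, 10_000))

    def test_parseval_consistency(self):
        rng = np.random.default_rng(3)
        stack_data = rng.random((256, 3, 3))
        movie = ffi.OpticalMovie(stack=stack_data, provenance="simulated")
        fs = ffi.ffi_transform(movie)
        energy_f = fs.energy_map()
        energy_t = (stack_data**2).sum(axis=0)
        assert np.allclose(energy_f, energy_t, rtol=1e-9)

    def test_gain_invariance_of_phase_linearity_of_amplitude(self):
        a = ffi.ffi_transform(_tone_movie(2.0, gain=1.0))
        b = ffi.ffi_transform(_tone_movie(2.0, gain=7.5))
        k = a.nearest_bin(2.0)
        assert np.allclose(b.amplitude[k], 7.5 * a.amplitude[k], rtol=1e-9)
        assert np.allclose(ffi.phase_difference(b.phase[k], a.phase[k]), 0.0,
                           atol=1e-9)

    def test_nearest_bin_error_bound(self):
        movie = _tone_movie(1.0, duration_s=3.7)
        fs = ffi.ffi_transform(movie)
        for f in (0.5, 1.33, 4.01):
            k = fs.nearest_bin(f)
            assert abs(fs.frequencies[k] - f) <= 0.5 * fs.df + 1e-12

    def test_above_nyquist_rejected(self):
        fs = ffi.ffi_transform(_tone_movie(1.0))
        with pytest.raises(ValueError):
            ffi.extract_frequency_map(fs, 10 * fs.nyquist)


class TestSubharmonicContent:
    def test_two_two_movie_has_f12_peak(self, da_movie, da_fourier):
        # paced at 8 Hz: secondary amplitude peak at the bin nearest 4 Hz
        k4 = da_fourier.nearest_bin(4.0)
        kp = da_fourier.nearest_bin(8.0)
        mask = da_movie.mask
        amp_4 = da_fourier.amplitude[k4][mask].mean()
        amp_p = da_fourier.amplitude[kp][mask].mean()
        neighborhood = da_fourier.amplitude[k4 - 3:k4 + 4][:, mask].mean(axis=1)
        assert amp_4 >= 0.05 * amp_p
        assert int(np.argmax(neighborhood)) == 3  # local max at the 4 Hz bin

    def test_phase_jump_of_pi_across_nodal_line(self, da_fourier,
                                                da_region_masks):
        k4 = da_fourier.nearest_bin(4.0)
        ph = da_fourier.phase[k4]
        left, right = da_region_masks
        jump = ffi.phase_difference(ffi.circular_mean(ph[left]),
                                    ffi.circular_mean(ph[right]))
        assert abs(abs(jump) - np.pi) < 0.05

    def test_no_phase_jump_at_pacing_frequency(self, da_fourier,
                                               da_region_masks):
        kp = da_fourier.nearest_bin(8.0)
        ph = da_fourier.phase[kp]
        left, right = da_region_masks
        jump = ffi.phase_difference(ffi.circular_mean(ph[left]),
                                    ffi.circular_mean(ph[right]))
        assert abs(jump) < np.pi / 2

    def test_amplitude_valley_on_nodal_line(self, da_scene, da_fourier):
        k4 = da_fourier.nearest_bin(4.0)
        amp = da_fourier.amplitude[k4]
        rows = slice(12, 52)
        centre = amp[rows, 31:33].mean()
        interior = amp[rows, 12:24].mean()
        assert centre < 0.5 * interior


class TestRhythmClassification:
    def _trace_spectrum(self, pattern, f_p, deltas, duration_s=4.0):
        # Hann taper keeps spectral leakage of the pacing line well below
        # the peak-detection thresholds
        r = synthdata.RhythmSpec(pacing_hz=f_p, pattern=pattern,
                                 apd_base=60.0, apd_deltas=deltas)
        y = synthdata.generate_ap_train(r, duration_s)
        n = len(y)
        freqs = np.fft.rfftfreq(n, d=2e-3)
        amp = np.abs(np.fft.rfft((y - y.mean()) * np.hanning(n)))
        return freqs, amp

    def test_two_two_at_8p5_hz(self):
        freqs, amp = self._trace_spectrum("two_two", 8.5, (15.0,))
        res = ffi.classify_rhythm(freqs, amp, 8.5)
        assert res["label"] == "two_two"
        assert res["peaks"]["f_1_2"]["hz"] == pytest.approx(4.25, abs=0.3)

    def test_four_four_has_two_extra_lines(self):
        freqs, amp = self._trace_spectrum("four_four", 8.0, (25.0, 15.0))
        res = ffi.classify_rhythm(freqs, amp, 8.0)
        assert res["label"] == "four_four"
        freqs2, amp2 = self._trace_spectrum("two_two", 8.0, (25.0,))

        def n_sub_fp_lines(freqs, amp, f_p):
            kp = int(np.argmin(np.abs(freqs - f_p)))
            a_p = amp[kp]
            count = 0
            for k in range(2, kp - 2):
                if amp[k] >= 0.05 * a_p and amp[k] == amp[k - 2:k + 3].max():
                    count += 1
            return count

        extra = (n_sub_fp_lines(freqs, amp, 8.0)
                 - n_sub_fp_lines(freqs2, amp2, 8.0))
        assert extra == 2

    def test_one_to_one_stays_clean(self):
        freqs, amp = self._trace_spectrum("one_to_one", 3.2, ())
        res = ffi.classify_rhythm(freqs, amp, 3.2)
        assert res["label"] == "one_to_one"
        k_half = int(np.argmin(np.abs(freqs - 1.6)))
        kp = int(np.argmin(np.abs(freqs - 3.2)))
        assert amp[k_half] < 0.01 * amp[kp]

    def test_white_noise_is_fibrillation(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(2000)
        freqs = np.fft.rfftfreq(len(y), d=2e-3)
        amp = np.abs(np.fft.rfft(y))
        res = ffi.classify_rhythm(freqs, amp, 8.0)
        assert res["label"] == "fibrillation"


@pytest.fixture(scope="module")
def frequency_series():
    movies = []
    for f_p, pattern in [(3.0, "one_to_one"), (4.0, "one_to_one"),
                         (6.0, "two_two"), (7.0, "two_two")]:
        deltas = (12.0,) if pattern == "two_two" else ()
        r = synthdata.RhythmSpec(pacing_hz=f_p, pattern=pattern,
                                 apd_base=60.0, apd_deltas=deltas)
        y = synthdata.generate_ap_train(r, 4.0)
        stack = np.broadcast_to(y[:, None, None],
                                (len(y), 4, 4)).copy()
        movies.append((f_p, ffi.OpticalMovie(stack=stack,
                                             provenance="simulated")))
    roi = np.ones((4, 4), dtype=bool)
    return ffi.build_frequency_series(movies, roi)


class TestFrequencySeries:
    def test_fundamental_ridge(self, frequency_series):
        series = frequency_series
        for i, f_p in enumerate(series.pacing_hz):
            k = int(np.argmin(np.abs(series.frequencies - f_p)))
            assert series.power[i, k] == pytest.approx(1.0, abs=1e-9)

    def test_subharmonic_ridge_only_above_cut_in(self, frequency_series):
        series = frequency_series
        for i, f_p in enumerate(series.pacing_hz):
            k = int(np.argmin(np.abs(series.frequencies - f_p / 2)))
            band = series.power[i, max(0, k - 1):k + 2].max()
            if f_p >= 6.0:
                assert band > 0.05
            else:
                assert band < 0.02

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            ffi.build_frequency_series([(1.0, None), (2.0, None)],
                                       np.zeros((2, 2), bool))


class TestUltrastructure:
    def test_generator_field_recovered(self):
        g = synthdata.generate_ultrastructure_field((48, 48), 8.0, 0.1,
                                                    seed=11)
        scene = synthdata.two_region_scene(ny=48, nx=48, duration_s=4.0,
                                           noise_sigma=0.02, seed=11, g=g)
        movie = synthdata.generate_movie(scene)
        a05 = ffi.extract_ultrastructure(movie, 0.5)
        m = movie.mask
        r = np.corrcoef(a05[m], g[m])[0, 1]
        assert r > 0.9

    def test_pacing_site_invariance(self):
        g = synthdata.generate_ultrastructure_field((48, 48), 8.0, 0.1,
                                                    seed=12)
        maps = []
        for edge in ("top", "left"):
            scene = synthdata.two_region_scene(ny=48, nx=48, duration_s=4.0,
                                               noise_sigma=0.02, seed=12,
                                               g=g, pacing_edge=edge)
            movie = synthdata.generate_movie(scene)
            maps.append(ffi.extract_ultrastructure(movie, 0.5))
        m = scene.tissue_mask()
        r = np.corrcoef(maps[0][m], maps[1][m])[0, 1]
        assert r > 0.9

    def test_uniform_baseline_movie_is_flat(self):
        scene = synthdata.two_region_scene(ny=32, nx=32, duration_s=4.0,
                                           noise_sigma=0.0, seed=13)
        movie = synthdata.generate_movie(scene)
        a05 = ffi.extract_ultrastructure(movie, 0.5)
        m = movie.mask
        cov = a05[m].std() / a05[m].mean()
        # residual window leakage only: far below the cov ~ 0.1 contrast of
        # a genuine ultrastructure field
        assert cov < 0.05

    def test_short_window_rejected(self):
        movie = _tone_movie(1.0, duration_s=2.0)
        with pytest.raises(ValueError):
            ffi.extract_ultrastructure(movie, 0.5)
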