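"""Fourier transformation imaging (FFI) of voltage-sensitive movies.

Each pixel's intensity time series is transformed to the complex Fourier
domain and the amplitude |F_xy(f)| and phase arg F_xy(f) are recomposed into
spatial maps at chosen frequencies -- no spatial filtering is involved.  At a
pacing frequency f_p, a secondary spectral line at f_p/2 signals a 2:2
(period-doubled) action-potential rhythm; discordant alternans appears as a
phase jump of ~pi across the nodal line together with an amplitude valley on
it.  A further line near 3 f_p/4 signals a 4:4 rhythm, and a broadband
elevated baseline signals fibrillation.  The amplitude at a low frequency
(0.5 Hz by default) is pacing-independent and reflects the optical
ultrastructure of the tissue; it is the input to heterogeneity assimilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "OpticalMovie", "FourierStack", "FrequencySeriesMap", "ffi_transform",
    "extract_frequency_map", "build_frequency_series", "extract_ultrastructure",
    "classify_rhythm", "pixel_spectrum", "circular_mean",
]


@dataclass
class OpticalMovie:
    """Intensity stack I(x, y, t) with acquisition metadata.

    ``stack`` is indexed (frame, row, col).  ``provenance`` distinguishes
    experimental recordings, simulator output ("simulated") and generator
    output ("synthetic"); it selects the default detrending behaviour of
    :func:`ffi_transform` (photobleaching drift removal is pointless on
    simulated membrane potential).
    """

    stack: np.ndarray
    frame_interval_ms: float = 2.0
    pixel_size_um: float = 600.0
    mask: np.ndarray | None = None
    provenance: str = "synthetic"

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 3 or self.stack.shape[0] < 2:
            raise ValueError("stack must be (nt>=2, ny, nx)")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame interval must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.stack.shape[1:]:
                raise ValueError("mask shape does not match frames")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_shape(self):
        return self.stack.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_ms / 1000.0

    @property
    def sampling_rate_hz(self) -> float:
        return 1000.0 / self.frame_interval_ms

    def pixel_trace(self, row, col) -> np.ndarray:
        return np.asarray(self.stack[:, row, col], dtype=float)

    @classmethod
    def from_recording(cls, recording, pixel_size_um=None) -> "OpticalMovie":
        """Wrap a tissue-simulation recording; identical analysis path."""
        px = (pixel_size_um if pixel_size_um is not None
              else recording.dx_cm * 1e4)
        return cls(stack=np.asarray(recording.u_stack),
                   frame_interval_ms=recording.frame_interval_ms,
                   pixel_size_um=px, mask=recording.tissue_mask,
                   provenance="simulated")


@dataclass
class FourierStack:
    """Per-pixel amplitude and phase over the (one-sided) frequency axis."""

    frequencies: np.ndarray
    amplitude: np.ndarray      # (nf, ny, nx), >= 0
    phase: np.ndarray          # (nf, ny, nx), in (-pi, pi]
    window: dict = field(default_factory=dict)

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])

    def nearest_bin(self, f_target: float) -> int:
        if f_target > self.nyquist + 1e-12:
            raise ValueError(f"{f_target} Hz is above Nyquist "
                             f"({self.nyquist:.3f} Hz)")
        return int(np.argmin(np.abs(self.frequencies - f_target)))

    def energy_map(self) -> np.ndarray:
        """Windowed time-domain signal energy per pixel (Parseval).

        Equals sum_t x(t)^2 of the (detrended, tapered) window that was
        transformed, reconstructed from the one-sided spectrum.
        """
        n = self.window["n_frames"]
        w = np.full(len(self.frequencies), 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0
        return np.tensordot(w, self.amplitude**2, axes=(0, 0)) / n


@dataclass
class FrequencySeriesMap:
    """Normalized ROI spectra stacked over pacing frequencies.

    ``power[i, j]`` is the ROI-averaged spectral amplitude at spectral
    frequency ``frequencies[j]`` for pacing frequency ``pacing_hz[i]``,
    normalized so each row peaks at 1.
    """

    pacing_hz: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.power, index=self.pacing_hz,
                            columns=self.frequencies)


def _resolve_window(movie, window, f_p):
    if window is not None:
        a, b = window
        if a < 0 or b > movie.n_frames or b - a < 2:
            raise ValueError("window exceeds the movie or is too short")
        return int(a), int(b)
    if f_p is not None and f_p > 0:
        skip = int(np.ceil(1000.0 / f_p / movie.frame_interval_ms))
        if movie.n_frames - skip >= 2:
            return skip, movie.n_frames
    return 0, movie.n_frames


def ffi_transform(movie: OpticalMovie, window=None, f_p=None,
                  detrend=None, taper="rectangular") -> FourierStack:
    """Pixel-wise discrete Fourier transform of a movie window.

    Parameters
    ----------
    window : (start_frame, stop_frame), optional
        Defaults to the whole recording; when ``f_p`` is given instead, the
        first beat (one pacing cycle) is dropped to remove the onset
        transient.
    detrend : bool, optional
        Per-pixel linear detrend before the transform.  Default: on for
        experimental/synthetic movies, off for simulated membrane potential.
    taper : "rectangular" or "hann"
    """
    a, b = _resolve_window(movie, window, f_p)
    x = np.asarray(movie.stack[a:b], dtype=np.float64)
    n = x.shape[0]
    if detrend is None:
        detrend = movie.provenance != "simulated"
    if detrend:
        x = sp_signal.detrend(x, axis=0, type="linear")
    if taper == "hann":
        x = x * np.hanning(n)[:, None, None]
    elif taper != "rectangular":
        raise ValueError("taper must be 'rectangular' or 'hann'")
    F = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=movie.frame_interval_ms / 1000.0)
    return FourierStack(
        frequencies=freqs, amplitude=np.abs(F), phase=np.angle(F),
        window={"start_frame": a, "stop_frame": b, "n_frames": n,
                "detrend": bool(detrend), "taper": taper,
                "frame_interval_ms": movie.frame_interval_ms})


def extract_frequency_map(stack: FourierStack, f_target: float):
    """Amplitude and phase maps at the bin nearest ``f_target`` (Hz).

    Returns (amplitude grid, phase grid, info) with the selected bin and its
    actual frequency recorded in ``info``.
    """
    k = stack.nearest_bin(f_target)
    info = {"bin": k, "bin_frequency_hz": float(stack.frequencies[k]),
            "target_hz": float(f_target),
            "bin_error_hz": float(abs(stack.frequencies[k] - f_target))}
    return stack.amplitude[k], stack.phase[k], info


def pixel_spectrum(movie: OpticalMovie, row, col, half=3, **kw):
    """ROI-averaged amplitude spectrum around one pixel (like a local probe).

    Averages the amplitude over a (2*half)x(2*half) neighbourhood, mirroring
    the small fields of view used when inspecting local AP rhythms.
    """
    stack = ffi_transform(movie, **kw)
    r0, r1 = max(0, row - half), min(movie.frame_shape[0], row + half)
    c0, c1 = max(0, col - half), min(movie.frame_shape[1], col + half)
    amp = stack.amplitude[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return stack.frequencies, amp


def extract_ultrastructure(movie: OpticalMovie, f_low: float = 0.5,
                           window=None, detrend=None) -> np.ndarray:
    """Low-frequency Fourier amplitude map |F_xy(f_low)| (the ultrastructure).

    Requires a window of at least 2/f_low seconds so the target frequency is
    spectrally resolved.  The map is zeroed outside the movie's tissue mask
    when one is present.
    """
    stack = ffi_transform(movie, window=window, detrend=detrend)
    n_s = stack.window["n_frames"] * movie.frame_interval_ms / 1000.0
    if n_s < 2.0 / f_low:
        raise ValueError(f"window of {n_s:.2f} s is too short to resolve "
                         f"{f_low} Hz (need >= {2.0 / f_low:.2f} s)")
    amp, _, _ = extract_frequency_map(stack, f_low)
    if movie.mask is not None:
        amp = np.where(movie.mask, amp, 0.0)
    return amp


def _is_local_max(amp, k, halfwidth=2):
    lo = max(0, k - halfwidth)
    hi = min(len(amp), k + halfwidth + 1)
    return amp[k] >= amp[lo:hi].max() - 1e-15


def _subharmonic_peak(freqs, amp, f_target, tol_fraction, exclude=()):
    """Strongest local maximum within +-tol_fraction of f_target."""
    sel = np.flatnonzero(np.abs(freqs - f_target) <= tol_fraction * f_target)
    sel = [k for k in sel if k not in exclude]
    best = None
    for k in sel:
        if _is_local_max(amp, k) and (best is None or amp[k] > amp[best]):
            best = k
    return best


def classify_rhythm(freqs, amp, f_p, peak_fraction=0.05,
                    fibrillation_fraction=0.20, f12_tolerance=0.15) -> dict:
    """Classify a pixel/ROI spectrum as 1:1, 2:2, 4:4 or fibrillation.

    A subharmonic line "exists" when it is a local maximum over +-2 bins and
    its amplitude is at least ``peak_fraction`` of the pacing peak.  The
    split f_1/2 line of experimental 4:4 rhythms is handled by accepting any
    peak within +-``f12_tolerance`` of f_p/2 and reporting multiplicity.
    Fibrillation: the median off-peak amplitude between 0.25 f_p and 2 f_p
    exceeds ``fibrillation_fraction`` of the pacing peak.

    Returns a dict with ``label``, the peak bins, the f_1/2 multiplicity and
    an ``entrained`` flag (pacing peak dominant above 0.25 f_p).
    """
    freqs = np.asarray(freqs, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if len(freqs) != len(amp):
        raise ValueError("frequency and amplitude axes disagree")
    kp = int(np.argmin(np.abs(freqs - f_p)))
    a_p = amp[kp]
    out = {"f_p_bin": kp, "f_p_hz": float(freqs[kp]), "entrained": True,
           "multiplicity_f12": 0, "peaks": {}}
    nontrivial = np.flatnonzero(freqs > 0.25 * f_p)
    if a_p <= 0:
        out["entrained"] = False
    elif len(nontrivial):
        k_max = nontrivial[int(np.argmax(amp[nontrivial]))]
        if amp[k_max] > a_p and abs(freqs[k_max] - f_p) > 0.1 * f_p:
            out["entrained"] = False

    # off-peak baseline between 0.25 f_p and 2 f_p, excluding peak vicinities
    band = (freqs > 0.25 * f_p) & (freqs < 2.0 * f_p)
    for f_line in (f_p, f_p / 2, 3 * f_p / 4, f_p / 4, 3 * f_p / 2, 2 * f_p):
        band &= np.abs(freqs - f_line) > 2.5 * (freqs[1] - freqs[0])
    baseline = np.median(amp[band]) if band.any() else 0.0
    out["baseline_fraction"] = float(baseline / a_p) if a_p > 0 else np.inf
    if out["baseline_fraction"] >= fibrillation_fraction:
        out["label"] = "fibrillation"
        return out

    k12 = _subharmonic_peak(freqs, amp, f_p / 2, f12_tolerance, exclude={kp})
    has_12 = k12 is not None and amp[k12] >= peak_fraction * a_p
    if has_12:
        out["peaks"]["f_1_2"] = {"bin": int(k12), "hz": float(freqs[k12]),
                                 "fraction": float(amp[k12] / a_p)}
        sel = np.flatnonzero(np.abs(freqs - f_p / 2) <= f12_tolerance * f_p / 2)
        out["multiplicity_f12"] = int(sum(
            1 for k in sel if k != kp and _is_local_max(amp, k)
            and amp[k] >= peak_fraction * a_p))
    k34 = _subharmonic_peak(freqs, amp, 3 * f_p / 4, 0.10,
                            exclude={kp} | ({k12} if k12 is not None else set()))
    has_34 = (k34 is not None and amp[k34] >= peak_fraction * a_p)
    if has_12 and has_34:
        out["peaks"]["f_3_4"] = {"bin": int(k34), "hz": float(freqs[k34]),
                                 "fraction": float(amp[k34] / a_p)}
        out["label"] = "four_four"
    elif has_12:
        out["label"] = "two_two"
    else:
        out["label"] = "one_to_one"
    return out


def build_frequency_series(movies, roi, **ffi_kw) -> FrequencySeriesMap:
    """Stack ROI-averaged normalized spectra over pacing frequencies.

    ``movies`` is a sequence of (f_p, OpticalMovie); ``roi`` a boolean grid.
    Spectra are interpolated onto the frequency axis of the first movie when
    window lengths differ; each row is normalized to its maximum.
    """
    movies = list(movies)
    if len(movies) < 2:
        raise ValueError("need at least two pacing frequencies")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    ref_freqs = None
    rows, f_ps = [], []
    for f_p, movie in sorted(movies, key=lambda t: t[0]):
        stack = ffi_transform(movie, f_p=f_p, **ffi_kw)
        # drop the DC bin: columns are normalized to the dominant
        # oscillatory peak, not the mean intensity
        spec = stack.amplitude[1:, roi].mean(axis=1)
        if ref_freqs is None:
            ref_freqs = stack.frequencies[1:]
        elif (len(stack.frequencies) - 1 != len(ref_freqs)
              or not np.allclose(stack.frequencies[1:], ref_freqs)):
            spec = np.interp(ref_freqs, stack.frequencies[1:], spec)
        m = spec.max()
        rows.append(spec / m if m > 0 else spec)
        f_ps.append(f_p)
    return FrequencySeriesMap(pacing_hz=np.asarray(f_ps),
                              frequencies=ref_freqs,
                              power=np.vstack(rows))


def circular_mean(phases, axis=None):
    """Mean of angles in radians, result in (-pi, pi]."""
    return np.angle(np.mean(np.exp(1j * np.asarray(phases)), axis=axis))


def phase_difference(a, b):
    """Wrapped difference a - b in (-pi, pi]."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))
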