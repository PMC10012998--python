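"""Synthetic optical-mapping movies with controlled alternans content.

Emulates voltage-sensitive fluorescence recordings of paced ventricular
tissue: 600x600 um^2 pixels, 2 ms frames, action-potential trains with 1:1,
2:2 or 4:4 rhythms, antiphase spatial domains separated by nodal transition
bands, a plane travelling wave from the pacing edge, a smooth multiplicative
baseline-amplitude field (the optical "ultrastructure"), slow linear drift
and additive Gaussian noise.  Everything is deterministic given the seed.

The AP waveform is a parametric template (exponential upstroke, plateau,
sigmoidal repolarization) calibrated so that the 20%-threshold APD equals
the requested value; a 4:4 rhythm is realized as an amplitude-modulated 2:2
cycle (APDs a+d1, a-d1, a+d2, a-d2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .ffi import OpticalMovie

__all__ = [
    "RhythmSpec", "SceneSpec", "generate_ap_train", "generate_movie",
    "generate_ultrastructure_field", "two_region_scene", "ap_template",
]

RISE_TAU_MS = 2.0
FALL_WIDTH_MS = 12.0


@dataclass
class RhythmSpec:
    """Pacing frequency and the repeating per-beat APD cycle.

    ``pattern``: one_to_one | two_two | four_four | broadband.
    ``apd_deltas`` defines the cycle around ``apd_base``: () for 1:1,
    (d,) for 2:2 (APDs a+d, a-d), (d1, d2) for 4:4
    (a+d1, a-d1, a+d2, a-d2).  ``antiphase`` shifts the cycle by half a
    period (the pi phase offset of a discordant region).
    """

    pacing_hz: float = 8.0
    pattern: str = "two_two"
    apd_base: float = 80.0
    apd_deltas: tuple = (20.0,)
    antiphase: bool = False

    def __post_init__(self):
        if self.pacing_hz <= 0:
            raise ValueError("pacing frequency must be positive")
        cl = 1000.0 / self.pacing_hz
        if self.pattern != "broadband" and self.max_apd >= cl:
            raise ValueError("APD exceeds the cycle length (wave fusion)")
        n = {"one_to_one": 0, "two_two": 1, "four_four": 2,
             "broadband": None}.get(self.pattern, -1)
        if n == -1:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if n is not None and len(self.apd_deltas) != n:
            raise ValueError(f"{self.pattern} needs {n} apd_delta entries")

    @property
    def max_apd(self) -> float:
        return self.apd_base + max((abs(d) for d in self.apd_deltas),
                                   default=0.0)

    def apd_cycle(self, alternation_scale: float = 1.0) -> np.ndarray:
        """Repeating APD sequence; ``alternation_scale`` in [0, 1] ramps the
        alternation to zero inside a nodal transition band."""
        a = self.apd_base
        if self.pattern == "one_to_one":
            cyc = [a]
        elif self.pattern == "two_two":
            d = self.apd_deltas[0] * alternation_scale
            cyc = [a + d, a - d]
        elif self.pattern == "four_four":
            d1 = self.apd_deltas[0] * alternation_scale
            d2 = self.apd_deltas[1] * alternation_scale
            cyc = [a + d1, a - d1, a + d2, a - d2]
        else:
            raise ValueError("broadband rhythms have no APD cycle")
        cyc = np.asarray(cyc)
        if self.antiphase:
            cyc = np.roll(cyc, len(cyc) // 2)
        return cyc


def _template_shape(t, t_rep):
    with np.errstate(over="ignore"):
        rise = -np.expm1(-np.maximum(t, 0.0) / RISE_TAU_MS)
        fall = 1.0 / (1.0 + np.exp(
            np.clip((t - t_rep) / FALL_WIDTH_MS, -60, 60)))
    return np.where(t >= 0, rise * fall, 0.0)


@lru_cache(maxsize=512)
def _calibrated_t_rep(apd_ms, threshold_fraction):
    """Repolarization midpoint such that the 20%-of-peak duration is apd_ms.

    The closed-form start value ignores the rise/fall overlap (the peak sits
    below 1 for short APDs); two fixed-point corrections on a fine grid pin
    the crossing to within ~0.1 ms.
    """
    t_rep = apd_ms - FALL_WIDTH_MS * np.log(
        (1.0 - threshold_fraction) / threshold_fraction)
    t = np.arange(0.0, apd_ms + 120.0, 0.05)
    for _ in range(3):
        y = _template_shape(t, t_rep)
        above = t[y >= threshold_fraction * y.max()]
        t_rep += apd_ms - (above.max() - above.min())
    return float(t_rep)


def ap_template(t_ms, apd_ms, threshold_fraction=0.2):
    """Normalized AP waveform with a 20%-threshold duration of ``apd_ms``.

    Exponential upstroke (tau = 2 ms) times a sigmoidal repolarization of
    width 12 ms whose centre is calibrated so the waveform stays above
    ``threshold_fraction`` of its peak for exactly ``apd_ms``.
    """
    t = np.asarray(t_ms, dtype=float)
    t_rep = _calibrated_t_rep(round(float(apd_ms), 6),
                              float(threshold_fraction))
    return _template_shape(t, t_rep)


def generate_ap_train(rhythm: RhythmSpec, duration_s, frame_interval_ms=2.0,
                      delay_ms=0.0, alternation_scale=1.0, rng=None):
    """Sampled AP train following the rhythm's repeating APD cycle.

    ``delay_ms`` shifts the train (wave travel time).  Broadband rhythms
    draw irregular beat intervals and APDs from ``rng`` (seeded Generator).
    """
    n = int(round(duration_s * 1000.0 / frame_interval_ms))
    t = np.arange(n) * frame_interval_ms
    out = np.zeros(n)
    cl = 1000.0 / rhythm.pacing_hz
    if rhythm.pattern == "broadband":
        if rng is None:
            rng = np.random.default_rng(0)
        tt = 0.0
        while tt < duration_s * 1000.0:
            apd = rhythm.apd_base * rng.uniform(0.4, 1.3)
            out += ap_template(t - tt - delay_ms, apd)
            tt += cl * rng.uniform(0.5, 1.6)
        return np.clip(out, 0.0, 1.2)
    cyc = rhythm.apd_cycle(alternation_scale)
    n_beats = int(np.ceil(duration_s * 1000.0 / cl)) + 1
    for k in range(n_beats):
        out += ap_template(t - k * cl - delay_ms, cyc[k % len(cyc)])
    return out


@dataclass
class SceneSpec:
    """Full description of one synthetic optical-mapping scene.

    ``region_labels`` assigns each pixel a region index into ``rhythms``
    (label -1 = background); ``alternation_scale`` ramps alternans to zero
    across nodal transition bands; ``g`` is the multiplicative baseline
    amplitude (ultrastructure) field.  Wave travel is a plane wave from the
    pacing edge at conduction velocity ``cv_cm_ms``.
    """

    ny: int = 128
    nx: int = 128
    pixel_size_um: float = 600.0
    frame_interval_ms: float = 2.0
    duration_s: float = 4.0
    rhythms: list = field(default_factory=lambda: [RhythmSpec()])
    region_labels: np.ndarray | None = None
    alternation_scale: np.ndarray | None = None
    g: np.ndarray | None = None
    noise_sigma: float = 0.02
    drift_per_s: float = 0.01
    baseline_wander_amp: float = 0.10
    pacing_edge: str = "top"      # top | left | bottom | right
    cv_cm_ms: float = 0.05
    seed: int = 0

    def tissue_mask(self) -> np.ndarray:
        if self.region_labels is None:
            return np.ones((self.ny, self.nx), dtype=bool)
        return self.region_labels >= 0

    def travel_delay_ms(self) -> np.ndarray:
        rows = np.arange(self.ny)[:, None] * np.ones((1, self.nx))
        cols = np.ones((self.ny, 1)) * np.arange(self.nx)[None, :]
        dist_px = {"top": rows, "bottom": self.ny - 1 - rows,
                   "left": cols, "right": self.nx - 1 - cols}[self.pacing_edge]
        dist_cm = dist_px * self.pixel_size_um * 1e-4
        return dist_cm / self.cv_cm_ms


def generate_ultrastructure_field(shape, correlation_length_px=10.0,
                                  cov=0.10, seed=0) -> np.ndarray:
    """Smooth positive random field with mean exactly 1.

    Gaussian-filtered white noise rescaled to coefficient of variation
    ``cov``; ``correlation_length_px`` is the half-width at half-maximum of
    the spatial autocorrelation (sigma of the filter = L / 1.665).
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    sigma = correlation_length_px / (2.0 * np.sqrt(np.log(2.0)))
    z = ndimage.gaussian_filter(z, sigma, mode="wrap")
    z = (z - z.mean()) / z.std()
    return 1.0 + cov * z


def _quantize(values, n_levels):
    """Map values in [0, 1] to level indices and the level values."""
    levels = np.linspace(0.0, 1.0, n_levels)
    idx = np.clip(np.round(values * (n_levels - 1)).astype(int), 0,
                  n_levels - 1)
    return idx, levels


def generate_movie(scene: SceneSpec) -> OpticalMovie:
    """Render a scene into a movie: I = g * AP(t - delay) + drift*t + noise.

    Per-pixel trains are assembled from a precomputed bank indexed by
    (region, quantized alternation scale); travel delays are rounded to the
    frame interval.  A slow (sub-1 Hz) baseline wander, common to the whole
    frame but multiplied by the local baseline amplitude g, emulates the
    fluorescence baseline fluctuations whose low-frequency Fourier
    amplitude reveals the ultrastructure.  Background pixels contain noise
    (and drift) only.  Output is bitwise reproducible for a fixed seed.
    """
    ny, nx = scene.ny, scene.nx
    n = int(round(scene.duration_s * 1000.0 / scene.frame_interval_ms))
    rng = np.random.default_rng(scene.seed)
    labels = (scene.region_labels if scene.region_labels is not None
              else np.zeros((ny, nx), dtype=int))
    alt = (scene.alternation_scale if scene.alternation_scale is not None
           else np.ones((ny, nx)))
    g = scene.g if scene.g is not None else np.ones((ny, nx))
    delay_frames = np.round(scene.travel_delay_ms()
                            / scene.frame_interval_ms).astype(int)
    max_delay = int(delay_frames.max())

    n_levels = 17
    alt_idx, alt_levels = _quantize(alt, n_levels)
    # bank[(region, level)] -> train with a lead-in pad so that every pixel
    # is in the steady periodic regime from the first frame (recordings
    # start mid-pacing; there is no wave-onset transient in the movie)
    pad_frames = max_delay + 1
    pad_s = pad_frames * scene.frame_interval_ms / 1000.0
    bank = {}
    for r, rhythm in enumerate(scene.rhythms):
        if rhythm.pattern in ("one_to_one", "broadband"):
            lvls = [n_levels - 1]       # alternation scale irrelevant
        else:
            lvls = range(n_levels)
        for li in lvls:
            bank[(r, li)] = generate_ap_train(
                rhythm, scene.duration_s + pad_s, scene.frame_interval_ms,
                alternation_scale=alt_levels[li],
                rng=np.random.default_rng(scene.seed + 7 * r))
    wander = np.zeros(n)
    if scene.baseline_wander_amp > 0:
        w = rng.standard_normal(n)
        sigma_frames = 250.0 / scene.frame_interval_ms  # ~0.25 s lowpass
        w = ndimage.gaussian_filter1d(w, sigma_frames, mode="wrap")
        std = w.std()
        if std > 0:
            wander = scene.baseline_wander_amp * (w - w.mean()) / std
    stack = np.zeros((n, ny, nx), dtype=np.float64)
    for i in range(ny):
        for j in range(nx):
            r = labels[i, j]
            if r < 0:
                continue
            rhythm = scene.rhythms[r]
            li = (n_levels - 1 if rhythm.pattern in ("one_to_one", "broadband")
                  else alt_idx[i, j])
            d = delay_frames[i, j]
            train = bank[(r, li)]
            seg = train[pad_frames - d:pad_frames - d + n]
            stack[:, i, j] = g[i, j] * (seg + wander)
    t_s = np.arange(n) * scene.frame_interval_ms / 1000.0
    stack += scene.drift_per_s * t_s[:, None, None]
    if scene.noise_sigma > 0:
        stack += rng.normal(0.0, scene.noise_sigma, size=stack.shape)
    return OpticalMovie(stack=stack, frame_interval_ms=scene.frame_interval_ms,
                        pixel_size_um=scene.pixel_size_um,
                        mask=scene.tissue_mask(), provenance="synthetic")


def two_region_scene(ny=96, nx=96, pacing_hz=8.0, apd_base=70.0,
                     apd_delta=20.0, pattern="two_two", duration_s=4.0,
                     nodal_band_px=10, noise_sigma=0.02, border_px=6,
                     orientation="vertical", seed=0, **kw) -> SceneSpec:
    """Canonical discordant-alternans scene: two antiphase regions.

    The tissue is an inset rectangle split into two halves whose alternans
    cycles are shifted by pi; the alternation amplitude ramps linearly to
    zero over ``nodal_band_px`` pixels on each side of the split, creating
    a nodal line.  The default 10-pixel (6 mm) ramp keeps the |dAPD| <= 2 ms
    nodal line wider than one pixel, matching the mm-scale nodal bands of
    optically mapped ventricles.
    """
    labels = np.full((ny, nx), -1, dtype=int)
    labels[border_px:-border_px, border_px:-border_px] = 0
    rows = np.arange(ny)[:, None] * np.ones((1, nx))
    cols = np.ones((ny, 1)) * np.arange(nx)[None, :]
    coord = cols if orientation == "vertical" else rows
    half = (nx if orientation == "vertical" else ny) / 2.0
    signed = coord - half + 0.5
    labels[(signed >= 0) & (labels >= 0)] = 1
    alt_scale = np.clip(np.abs(signed) / max(nodal_band_px, 1e-9), 0.0, 1.0)
    deltas = {"one_to_one": (), "two_two": (apd_delta,),
              "four_four": (apd_delta, 0.6 * apd_delta)}[pattern]
    r0 = RhythmSpec(pacing_hz=pacing_hz, pattern=pattern, apd_base=apd_base,
                    apd_deltas=deltas, antiphase=False)
    r1 = RhythmSpec(pacing_hz=pacing_hz, pattern=pattern, apd_base=apd_base,
                    apd_deltas=deltas, antiphase=True)
    return SceneSpec(ny=ny, nx=nx, duration_s=duration_s,
                     rhythms=[r0, r1], region_labels=labels,
                     alternation_scale=alt_scale, noise_sigma=noise_sigma,
                     seed=seed, **kw)
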