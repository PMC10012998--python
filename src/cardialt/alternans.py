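"""APD-based alternans maps: preprocessing, dAPD, CA/DA classification.

The action-potential duration (APD) of each beat is measured per pixel by
threshold crossing at 20% of the signal amplitude, and the beat-to-beat
difference dAPD_n = APD_{n+1} - APD_n is recomposed into a map.  Pixels with
|dAPD| <= 2 ms (set by the 2 ms frame interval of the recordings) are
non-alternating -- on the boundary between antiphase regions these form the
nodal lines.  Concordant alternans (CA): essentially one sign everywhere;
discordant alternans (DA): at least two opposite-sign regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sp_signal

from .ap_model import APDSequence
from .ffi import OpticalMovie

__all__ = [
    "DeltaAPDMap", "preprocess_movie", "extract_apd_sequence",
    "delta_apd_map", "classify_pattern", "count_transitions",
    "NODAL_BAND_MS",
]

NODAL_BAND_MS = 2.0


@dataclass
class DeltaAPDMap:
    """Pixelwise dAPD (ms) for one beat pair, with the +-2 ms nodal band."""

    delta: np.ndarray                 # ms; NaN where beats were missing
    beat_pair: tuple
    nodal_band_ms: float = NODAL_BAND_MS
    tissue_mask: np.ndarray | None = None
    label: str | None = None          # filled in by classify_pattern
    summary: dict = field(default_factory=dict)

    @property
    def nodal_mask(self) -> np.ndarray:
        """Non-alternating pixels: |dAPD| within the nodal band."""
        return np.abs(self.delta) <= self.nodal_band_ms

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.delta)

    @property
    def alternating_mask(self) -> np.ndarray:
        return np.isfinite(self.delta) & (np.abs(self.delta) > self.nodal_band_ms)


def _masked_gaussian(frame_stack, mask, sigma, radius):
    """Gaussian smoothing that does not bleed across the tissue boundary."""
    m = mask.astype(float)
    norm = ndimage.gaussian_filter(m, sigma, radius=radius)
    out = np.empty_like(frame_stack)
    for k in range(frame_stack.shape[0]):
        num = ndimage.gaussian_filter(frame_stack[k] * m, sigma, radius=radius)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[k] = np.where(mask, num / np.where(norm > 0, norm, 1.0),
                              frame_stack[k])
    return out


def preprocess_movie(movie: OpticalMovie, time_window_frames: int = 7,
                     spatial_radius_px: int = 4,
                     spatial_sigma_px: float = 2.0,
                     baseline_window_ms: float = 500.0) -> OpticalMovie:
    """The standard pre-analysis chain before APD extraction.

    In order: per-pixel detrend, rectangular moving average in time
    (7 frames), spatial Gaussian smoothing (kernel truncated at a 4-pixel
    radius, sigma 2 px), the latter restricted to the tissue mask so no
    signal bleeds across the boundary.

    Detrending subtracts a per-pixel diastolic baseline estimated by
    morphological opening along time (rolling minimum then maximum over
    ``baseline_window_ms``, smoothed).  This removes photobleaching drift
    *and* sub-Hz baseline wander -- which would otherwise alias into the
    beat-to-beat APD difference -- while leaving the action potentials
    untouched (the window exceeds any APD).  Movies shorter than the
    baseline window fall back to a linear detrend.
    """
    if movie.n_frames <= time_window_frames:
        raise ValueError("movie shorter than the temporal filter window")
    x = np.asarray(movie.stack, dtype=np.float64)
    w = int(round(baseline_window_ms / movie.frame_interval_ms))
    if w >= 3 and movie.n_frames > 2 * w:
        base = ndimage.minimum_filter1d(x, w, axis=0, mode="nearest")
        base = ndimage.maximum_filter1d(base, w, axis=0, mode="nearest")
        base = ndimage.uniform_filter1d(base, max(3, w // 2), axis=0,
                                        mode="nearest")
        x = x - base
    else:
        x = sp_signal.detrend(x, axis=0, type="linear")
    x = ndimage.uniform_filter1d(x, size=time_window_frames, axis=0,
                                 mode="nearest")
    if spatial_sigma_px > 0:
        if movie.mask is not None:
            x = _masked_gaussian(x, movie.mask, spatial_sigma_px,
                                 spatial_radius_px)
        else:
            x = ndimage.gaussian_filter(
                x, (0, spatial_sigma_px, spatial_sigma_px),
                radius=(0, spatial_radius_px, spatial_radius_px))
    return OpticalMovie(stack=x, frame_interval_ms=movie.frame_interval_ms,
                        pixel_size_um=movie.pixel_size_um, mask=movie.mask,
                        provenance=movie.provenance)


def _crossings(y, thr):
    above = y >= thr
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    return rises, falls


def _interp_cross(y, idx, thr, dt, up):
    """Sub-frame crossing time of ``thr`` near segmentation index ``idx``.

    Walks outward from the global-threshold crossing to the first crossing
    of the per-beat threshold, then interpolates linearly.
    """
    n = len(y)
    i = idx
    if up:
        while i > 1 and y[i - 1] >= thr:
            i -= 1
    else:
        while i < n - 1 and y[i] >= thr:
            i += 1
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return i * dt
    frac = (thr - y0) / (y1 - y0)
    return (i - 1 + min(max(frac, 0.0), 1.0)) * dt


def extract_apd_sequence(trace, frame_interval_ms,
                         threshold_fraction: float = 0.2,
                         baseline_percentile: float = 10.0,
                         min_apd_ms: float = 20.0) -> APDSequence:
    """Per-beat APDs of one pixel trace by 20%-threshold crossing.

    Beats are segmented by crossings of a global threshold (20% of the
    trace amplitude above its ``baseline_percentile``).  Each APD is then
    re-measured against its own beat: local diastolic baseline (minimum of
    the preceding inter-beat segment) and local peak, so slow baseline
    wander does not alias into the beat-to-beat APD difference.  Crossing
    times get sub-frame resolution by linear interpolation.  A trace with
    no suprathreshold deflection yields an empty sequence (no exception).
    Deflections shorter than ``min_apd_ms`` are treated as noise blips and
    dropped.
    """
    y = np.asarray(trace, dtype=float)
    base = np.percentile(y, baseline_percentile)
    amp = y.max() - base
    if amp <= 0:
        return APDSequence(np.empty(0), float("nan"), threshold_fraction)
    thr = base + threshold_fraction * amp
    rises, falls = _crossings(y, thr)
    apds, ups, downs = [], [], []
    prev_fall = 0
    for bi, r in enumerate(rises):
        f = falls[falls > r]
        if len(f) == 0:
            break
        f = f[0]
        # per-beat thresholds: each crossing is referenced to its adjacent
        # diastole (preceding for the upstroke, following for the
        # repolarization) so residual baseline movement cancels
        nxt = rises[bi + 1] if bi + 1 < len(rises) else len(y)
        dia_prev = y[prev_fall:r]
        dia_next = y[f:nxt]
        base_up = dia_prev.min() if len(dia_prev) else base
        base_dn = dia_next.min() if len(dia_next) else base_up
        peak_b = y[r:f].max() if f > r else y[r]
        thr_up = base_up + threshold_fraction * (peak_b - base_up)
        thr_dn = base_dn + threshold_fraction * (peak_b - base_dn)
        t_up = _interp_cross(y, r, thr_up, frame_interval_ms, up=True)
        t_dn = _interp_cross(y, f, thr_dn, frame_interval_ms, up=False)
        prev_fall = f
        if t_dn - t_up < min_apd_ms:
            continue
        apds.append(t_dn - t_up)
        ups.append(t_up)
        downs.append(t_dn)
    apds = np.asarray(apds)
    ups = np.asarray(ups)
    di = np.full(len(apds), np.nan)
    if len(apds) > 1:
        di[:-1] = ups[1:] - np.asarray(downs)[:-1]
    return APDSequence(apds=apds, cycle_length=float("nan"),
                       threshold_fraction=threshold_fraction,
                       upstroke_times=ups, di_ms=di)


def delta_apd_map(movie: OpticalMovie, beat_pair="last2",
                  threshold_fraction: float = 0.2,
                  nodal_band_ms: float = NODAL_BAND_MS,
                  preprocess: bool = False) -> DeltaAPDMap:
    """Pixelwise dAPD = APD_{n+1} - APD_n for a beat pair.

    Beats are indexed ordinally from each pixel's first detected beat;
    because every pixel sees every paced wave, this keeps the beat parity
    consistent across the tissue even where wave travel delays shift a
    pixel's last beat past the end of the recording.  ``beat_pair`` is a
    pair of such indices, or ``"last2"`` (default): the last two beats
    complete at every pixel, i.e. (n_min - 2, n_min - 1) with n_min the
    minimum beat count over the tissue.  Pixels lacking either beat are
    NaN (reported, not fatal).
    """
    if preprocess:
        movie = preprocess_movie(movie)
    nt, ny, nx = movie.stack.shape
    delta = np.full((ny, nx), np.nan)
    mask = (movie.mask if movie.mask is not None
            else np.ones((ny, nx), dtype=bool))
    stack = np.asarray(movie.stack, dtype=float)
    apd_seqs = {}
    for i in range(ny):
        for j in range(nx):
            if mask[i, j]:
                apd_seqs[i, j] = extract_apd_sequence(
                    stack[:, i, j], movie.frame_interval_ms,
                    threshold_fraction).apds
    if beat_pair == "last2":
        counts = [len(a) for a in apd_seqs.values() if len(a) >= 2]
        if not counts:
            return DeltaAPDMap(delta=delta, beat_pair=(0, 1),
                               nodal_band_ms=nodal_band_ms, tissue_mask=mask)
        n_min = min(counts)
        beat_pair = (n_min - 2, n_min - 1)
    n0, n1 = beat_pair
    for (i, j), apds in apd_seqs.items():
        if 0 <= n0 < len(apds) and 0 <= n1 < len(apds):
            delta[i, j] = apds[n1] - apds[n0]
    return DeltaAPDMap(delta=delta, beat_pair=(n0, n1),
                       nodal_band_ms=nodal_band_ms, tissue_mask=mask)


def classify_pattern(m: DeltaAPDMap, min_alternating_fraction: float = 0.05,
                     concordance_fraction: float = 0.95) -> DeltaAPDMap:
    """Label a dAPD map as none / CA / DA and summarize its regions.

    Alternating pixels (beyond the nodal band) are split by sign into
    connected components.  ``none``: alternating area below 5% of the
    tissue; ``CA``: one sign holds at least 95% of the alternating area;
    ``DA`` otherwise.  The map is returned with ``label`` and ``summary``
    filled in.
    """
    tissue = (m.tissue_mask if m.tissue_mask is not None
              else np.isfinite(m.delta))
    alt = m.alternating_mask & tissue
    n_tissue = max(int(tissue.sum()), 1)
    pos = alt & (m.delta > 0)
    neg = alt & (m.delta < 0)
    lab_pos, n_pos = ndimage.label(pos)
    lab_neg, n_neg = ndimage.label(neg)
    areas = ([int(a) for a in np.bincount(lab_pos.ravel())[1:]]
             + [int(a) for a in np.bincount(lab_neg.ravel())[1:]])
    alt_fraction = alt.sum() / n_tissue
    if alt_fraction < min_alternating_fraction:
        label = "none"
    else:
        dominant = max(pos.sum(), neg.sum()) / max(int(alt.sum()), 1)
        label = "CA" if dominant >= concordance_fraction else "DA"
    m.label = label
    m.summary = {
        "alternating_fraction": float(alt_fraction),
        "nodal_fraction": float((m.nodal_mask & tissue).sum() / n_tissue),
        "n_components_positive": int(n_pos),
        "n_components_negative": int(n_neg),
        "component_areas_px": sorted(areas, reverse=True),
        "positive_fraction": float(pos.sum() / max(int(alt.sum()), 1)),
    }
    return m


def count_transitions(maps_or_labels) -> int:
    """CA<->DA transitions along an ordered pacing-down stage sequence.

    Stages labelled ``none`` do not interrupt or contribute transitions.
    """
    labels = [m.label if isinstance(m, DeltaAPDMap) else m
              for m in maps_or_labels]
    seq = [lab for lab in labels if lab in ("CA", "DA")]
    return int(sum(1 for a, b in zip(seq[:-1], seq[1:]) if a != b))
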