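"""Heterogeneity assimilation: from optical ultrastructure to parameter fields.

The low-frequency Fourier amplitude map s = |F_xy(0.5 Hz)| is smoothed and
normalized into a heterogeneity field

    H(x, y) = delta * r / max|r| + 1,      r = s - mean(s),

which has mean 1 over the tissue mask and maximal deviation delta in [0, 1].
This "direct" field is H1; the "reciprocal" field H2 applies the same
normalization to 1/H1, emphasizing low-amplitude areas.  Fields multiply
model parameters pointwise, p(x, y) = p_mean * H(x, y): H1 scales the
diffusivities (D_par, D_perp), H2 the APD-regulating time constants
(tau_w+, tau_so, tau_si -- both sub-constants of each).  Model variants:
homogeneous (no map), H1 (diffusivity only), H2 (APD only), H3 (both).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ffi import OpticalMovie
from .parameters import ModelParameters
from .tissue_sim import TissueDomain, build_diffusion_field

__all__ = [
    "HeterogeneityMap", "ModelVariant", "compute_tissue_mask",
    "make_heterogeneity_map", "make_reciprocal_map", "apply_heterogeneity",
    "build_variant_domain", "extract_1d_cut", "resample_map",
    "DIFFUSIVITY_PARAMS", "APD_PARAMS",
]

# Parameter sets P1 (diffusivity) and P2 (APD-regulating time constants).
DIFFUSIVITY_PARAMS = ("D_par", "D_perp")
APD_PARAMS = ("tau_w1_plus", "tau_w2_plus", "tau_so1", "tau_so2", "tau_si")

SMOOTH_RADIUS_PX = 6
SMOOTH_SIGMA_PX = float(np.sqrt(5.0))  # kernel variance 5 px^2


@dataclass
class HeterogeneityMap:
    """Mean-1 multiplicative heterogeneity field with max deviation delta."""

    H: np.ndarray
    delta: float
    mask: np.ndarray
    source: str = "direct"            # direct | reciprocal
    smoothing: dict = field(default_factory=dict)
    degenerate: bool = False          # constant input (H forced to 1)

    def __post_init__(self):
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1]")
        if np.any(self.H[self.mask] < 0):
            raise ValueError("heterogeneity field must be nonnegative")

    @property
    def mask_mean(self) -> float:
        return float(self.H[self.mask].mean())

    @property
    def max_deviation(self) -> float:
        return float(np.abs(self.H[self.mask] - 1.0).max())


@dataclass
class ModelVariant:
    """Which heterogeneity map drives which parameter set."""

    name: str
    diffusivity_map: HeterogeneityMap | None = None
    apd_map: HeterogeneityMap | None = None

    @classmethod
    def homogeneous(cls):
        return cls("homogeneous")

    @classmethod
    def h1(cls, H1):
        return cls("H1", diffusivity_map=H1)

    @classmethod
    def h2(cls, H2):
        return cls("H2", apd_map=H2)

    @classmethod
    def h3(cls, H1, H2):
        return cls("H3", diffusivity_map=H1, apd_map=H2)


def compute_tissue_mask(movie: OpticalMovie, snr_threshold: float = 3.0,
                        preprocess: bool = True) -> np.ndarray:
    """Tissue mask from the per-pixel signal-to-noise ratio.

    SNR = (peak-to-peak of the smoothed trace) / (robust noise level),
    where the noise level is 1.4826 * MAD of the residual between the raw
    detrended trace and its 7-frame moving average.  Pixels above threshold
    are reduced to the largest connected component and holes are filled.
    """
    if movie.duration_s < 1.0:
        raise ValueError("need at least 1 s of signal for a stable mask")
    from scipy import signal as sp_signal

    raw = sp_signal.detrend(np.asarray(movie.stack, float), axis=0)
    smooth = ndimage.uniform_filter1d(raw, size=7, axis=0, mode="nearest")
    resid = raw - smooth
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=0)),
                               axis=0)
    signal_ptp = smooth.max(axis=0) - smooth.min(axis=0)
    with np.errstate(divide="ignore"):
        snr = np.where(noise > 0, signal_ptp / noise, np.inf)
    mask = snr >= snr_threshold
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    # isolated above-threshold speckle is noise, not tissue
    min_px = max(9, int(0.005 * mask.size))
    if mask.sum() < min_px:
        raise ValueError("empty tissue mask: no coherent region reaches "
                         "the SNR threshold")
    return ndimage.binary_fill_holes(mask)


def _masked_smooth(s, mask, sigma, radius):
    m = mask.astype(float)
    norm = ndimage.gaussian_filter(m, sigma, radius=radius)
    num = ndimage.gaussian_filter(np.where(mask, s, 0.0), sigma,
                                  radius=radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mask, num / np.where(norm > 0, norm, 1.0), 0.0)


def _normalize(s, delta, mask, source, smoothing_meta):
    r = np.zeros_like(s, dtype=float)
    r[mask] = s[mask] - s[mask].mean()
    m = np.abs(r[mask]).max()
    H = np.ones_like(r)
    degenerate = m == 0.0
    if not degenerate and delta > 0:
        H[mask] = delta * r[mask] / m + 1.0
    return HeterogeneityMap(H=H, delta=delta, mask=mask, source=source,
                            smoothing=smoothing_meta, degenerate=degenerate)


def make_heterogeneity_map(a05, delta, mask, smooth: bool = True,
                           sigma: float = SMOOTH_SIGMA_PX,
                           radius: int = SMOOTH_RADIUS_PX) -> HeterogeneityMap:
    """The direct (H1-type) heterogeneity field from an ultrastructure map.

    Smooths the amplitude map with a Gaussian kernel (radius 6 px, variance
    5 px^2) restricted to the mask, then normalizes to mean 1 and maximal
    deviation ``delta``.  A constant input yields H = 1 with the
    ``degenerate`` flag set.
    """
    a05 = np.asarray(a05, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    s = _masked_smooth(a05, mask, sigma, radius) if smooth else a05
    meta = {"smoothed": bool(smooth),
            "sigma_px": sigma if smooth else None,
            "radius_px": radius if smooth else None}
    return _normalize(s, delta, mask, "direct", meta)


def make_reciprocal_map(H1_input, delta, mask) -> HeterogeneityMap:
    """The reciprocal (H2-type) field: normalize 1/H1 to mean 1, deviation
    delta.  Emphasizes low-amplitude areas of the ultrastructure."""
    H1_input = np.asarray(H1_input, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if np.any(H1_input[mask] <= 0):
        raise ValueError("reciprocal of a nonpositive field")
    recip = np.zeros_like(H1_input)
    recip[mask] = 1.0 / H1_input[mask]
    return _normalize(recip, delta, mask, "reciprocal", {"smoothed": False})


def apply_heterogeneity(params: ModelParameters, variant: ModelVariant,
                        shape=None) -> dict:
    """Per-pixel parameter fields p(x, y) = p_mean * H(x, y) for a variant.

    Returns a dict with grids for D_par, D_perp (from the diffusivity map)
    and the five APD time constants (from the APD map); entries are uniform
    when the corresponding map is absent.  Raises if any scaled field would
    be nonpositive.
    """
    maps = [m for m in (variant.diffusivity_map, variant.apd_map)
            if m is not None]
    if shape is None:
        if not maps:
            raise ValueError("shape required for the homogeneous variant")
        shape = maps[0].H.shape
    for m in maps:
        if m.H.shape != shape:
            raise ValueError("heterogeneity maps must share the domain grid")

    def fields(names, hmap):
        H = hmap.H if hmap is not None else np.ones(shape)
        if np.any(H <= 0):
            raise ValueError("H <= 0 yields a nonphysical parameter")
        return {n: getattr(params, n) * H for n in names}

    out = fields(DIFFUSIVITY_PARAMS, variant.diffusivity_map)
    out.update(fields(APD_PARAMS, variant.apd_map))
    return out


def build_variant_domain(variant: ModelVariant, dx: float,
                         params: ModelParameters | None = None,
                         alpha=0.0, phase_field=None, mask=None,
                         shape=None) -> TissueDomain:
    """Assemble a simulation domain for a model variant.

    The phase field comes from ``phase_field`` directly, from smoothing a
    binary ``mask``, from the heterogeneity maps' own mask, or defaults to
    the full rectangle.
    """
    p = params or ModelParameters()
    flds = apply_heterogeneity(p, variant, shape=shape)
    shape = flds["D_par"].shape
    ny, nx = shape
    if phase_field is None:
        if mask is None:
            for m in (variant.diffusivity_map, variant.apd_map):
                if m is not None:
                    mask = m.mask
                    break
        if mask is not None and not mask.all():
            phase_field = np.clip(
                ndimage.gaussian_filter(mask.astype(float), 2.5), 0.0, 1.0)
        else:
            phase_field = np.ones(shape)
    diff = build_diffusion_field(alpha, flds["D_par"], flds["D_perp"])
    pfields = {n: flds[n] for n in APD_PARAMS}
    return TissueDomain(nx=nx, ny=ny, dx=dx, phase_field=phase_field,
                        diffusion=diff, params=p, parameter_fields=pfields)


def resample_map(h: HeterogeneityMap, target_shape) -> HeterogeneityMap:
    """Bilinear resampling to the solver grid, then renormalize to mean 1."""
    zoom = (target_shape[0] / h.H.shape[0], target_shape[1] / h.H.shape[1])
    H = ndimage.zoom(h.H, zoom, order=1)
    mask = ndimage.zoom(h.mask.astype(float), zoom, order=1) >= 0.5
    return _normalize(H, h.delta, mask, h.source,
                      {**h.smoothing, "resampled_to": list(target_shape)})


def extract_1d_cut(h: HeterogeneityMap, path, n_samples: int = 200):
    """Sample H along a pixel polyline (bilinear), with arc length attached.

    ``path`` is a sequence of (row, col) vertices inside the mask.  Returns
    (arc_length_px, values).  Raises if the path leaves the mask.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise ValueError("path must be a polyline of (row, col) vertices")
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.linspace(0.0, arc[-1], n_samples)
    rows = np.interp(s, arc, path[:, 0])
    cols = np.interp(s, arc, path[:, 1])
    coords = np.vstack([rows, cols])
    inside = ndimage.map_coordinates(h.mask.astype(float), coords, order=1)
    if np.any(inside < 0.5):
        raise ValueError("path exits the tissue mask")
    vals = ndimage.map_coordinates(h.H, coords, order=1)
    return s, vals
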