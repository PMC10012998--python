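"""Containers, configuration and rendering for the analysis pipeline.

Movies travel as multi-page TIFF with a JSON sidecar (metadata: frame
interval, pixel size, provenance; the tissue mask as a companion TIFF), or
as a single NPZ container.  Simulation recordings use NPZ.  All writes are
atomic (temp file + rename) so interrupted runs never leave corrupt files.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np

from .ffi import OpticalMovie

__all__ = ["write_movie", "read_movie", "write_map", "read_map",
           "render_maps", "atomic_write_bytes"]

REQUIRED_META = ("frame_interval_ms", "pixel_size_um")


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".tmp")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_save(path, writer) -> None:
    """Run ``writer(tmp_path)`` then atomically rename to ``path``.

    The temp file keeps the target suffix (numpy/tifffile infer formats
    from it).
    """
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp_",
                               suffix=path.suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_movie(movie: OpticalMovie, path) -> None:
    """Write a movie as multi-page TIFF + JSON sidecar (or .npz container).

    ``path.npz`` selects the NPZ container; any other suffix writes TIFF
    pages (uint16 stacks stay uint16, float stacks become float32) plus
    ``<path>.json`` metadata and, when a mask is present, ``<path>.mask.tif``.
    """
    path = Path(path)
    if path.suffix == ".npz":
        _atomic_save(path, lambda tmp: np.savez_compressed(
            tmp, stack=movie.stack,
            frame_interval_ms=movie.frame_interval_ms,
            pixel_size_um=movie.pixel_size_um,
            provenance=np.frombuffer(movie.provenance.encode(), dtype=np.uint8),
            mask=(np.zeros(0, bool) if movie.mask is None else movie.mask)))
        return
    import tifffile

    stack = movie.stack
    if stack.dtype != np.uint16:
        stack = stack.astype(np.float32)
    _atomic_save(path, lambda tmp: tifffile.imwrite(tmp, stack))
    meta = {"frame_interval_ms": movie.frame_interval_ms,
            "pixel_size_um": movie.pixel_size_um,
            "provenance": movie.provenance}
    if movie.mask is not None:
        mask_path = path.with_suffix(path.suffix + ".mask.tif")
        _atomic_save(mask_path,
                     lambda tmp: tifffile.imwrite(
                         tmp, movie.mask.astype(np.uint8)))
        meta["mask_file"] = mask_path.name
    atomic_write_bytes(path.with_suffix(path.suffix + ".json"),
                       (json.dumps(meta, indent=2) + "\n").encode())


def read_movie(path) -> OpticalMovie:
    """Read a movie container written by :func:`write_movie`.

    Raises a ``ValueError`` naming any missing metadata field.
    """
    path = Path(path)
    if path.suffix == ".npz":
        z = np.load(path, allow_pickle=False)
        for key in REQUIRED_META:
            if key not in z:
                raise ValueError(f"missing metadata field {key!r}")
        mask = z["mask"] if "mask" in z else np.zeros(0, bool)
        prov = (z["provenance"].tobytes().decode()
                if "provenance" in z else "experimental")
        return OpticalMovie(stack=z["stack"],
                            frame_interval_ms=float(z["frame_interval_ms"]),
                            pixel_size_um=float(z["pixel_size_um"]),
                            mask=None if mask.size == 0 else mask,
                            provenance=prov)
    import tifffile

    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ValueError("missing sidecar metadata: frame_interval_ms, "
                         "pixel_size_um (no JSON file found)")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise ValueError(f"missing metadata field(s): {', '.join(missing)}")
    stack = tifffile.imread(path)
    mask = None
    if meta.get("mask_file"):
        mask = tifffile.imread(path.parent / meta["mask_file"]).astype(bool)
    return OpticalMovie(stack=stack,
                        frame_interval_ms=float(meta["frame_interval_ms"]),
                        pixel_size_um=float(meta["pixel_size_um"]),
                        mask=mask,
                        provenance=meta.get("provenance", "experimental"))


def write_map(grid, path, metadata=None) -> None:
    """Float map as TIFF + JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    _atomic_save(path, lambda tmp: tifffile.imwrite(
        tmp, np.asarray(grid, dtype=np.float32)))
    if metadata is not None:
        atomic_write_bytes(path.with_suffix(path.suffix + ".json"),
                           (json.dumps(metadata, indent=2) + "\n").encode())


def read_map(path):
    import tifffile

    path = Path(path)
    grid = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return grid, meta


def render_maps(maps: dict, out_dir, mask=None, nodal_band_ms: float = 2.0,
                dpi: int = 120) -> list:
    """Render analysis maps to PNG with kind-appropriate palettes.

    ``maps`` maps name -> (kind, grid) with kind in
    {"delta_apd", "phase", "amplitude", "heterogeneity"}:
    diverging palette with a neutral nodal band for dAPD, cyclic for phase
    (so -pi and +pi render identically), linear (min-max over the mask) for
    amplitude-like maps.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, (kind, grid) in maps.items():
        grid = np.asarray(grid, dtype=float)
        m = np.ones(grid.shape, bool) if mask is None else mask
        fig, ax = plt.subplots(figsize=(4, 4))
        shown = np.where(m, grid, np.nan)
        if kind == "delta_apd":
            lim = np.nanmax(np.abs(shown)) if np.isfinite(shown).any() else 1.0
            lim = max(lim, nodal_band_ms)
            data = shown.copy()
            data[np.abs(shown) <= nodal_band_ms] = 0.0
            im = ax.imshow(data, cmap="RdBu_r", vmin=-lim, vmax=lim)
        elif kind == "phase":
            im = ax.imshow(shown, cmap="twilight", vmin=-np.pi, vmax=np.pi)
        else:
            lo = np.nanmin(shown) if np.isfinite(shown).any() else 0.0
            hi = np.nanmax(shown) if np.isfinite(shown).any() else 1.0
            im = ax.imshow(shown, cmap="viridis", vmin=lo, vmax=hi)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(name)
        ax.axis("off")
        out = out_dir / f"{name}.png"
        fig.savefig(out, dpi=dpi, bbox_inches="tight")
        plt.close(fig)
        written.append(out)
    return written
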