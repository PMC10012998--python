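"""End-to-end orchestration: synth -> assimilate -> simulate -> FFI -> dAPD.

This is the closed loop the package exists for: generate (or load) an
optical movie, extract its low-frequency ultrastructure, assimilate it into
heterogeneous model parameter fields, run the pacing protocol on the
resulting tissue model, and analyze the simulated voltage with the same FFI
and dAPD code that analyzed the movie.  Every stage writes its artifacts
and a manifest records inputs, seeds and checksums so a run is reproducible
from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__, alternans, assimilation, ffi, io, synthdata
from . import tissue_sim as ts
from .parameters import ModelParameters

__all__ = ["validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {"ny": 64, "nx": 64, "pacing_hz": 8.0, "duration_s": 4.0,
              "apd_base": 70.0, "apd_delta": 20.0, "noise_sigma": 0.02},
    "assimilation": {"delta": 0.5, "variant": "H3", "snr_threshold": 3.0},
    "simulation": {"dx_cm": 0.05, "dt_ms": 0.02,
                   "frequencies_hz": [3.0, 5.0], "n_beats": 6,
                   "site": "base", "record_interval_ms": 2.0},
    "analysis": {"f_low_hz": 0.5},
}


def validate_config(config: dict) -> dict:
    """Schema-check a pipeline configuration, filling defaults.

    Raises ``ValueError`` on out-of-range settings (this happens before any
    compute).
    """
    cfg = {k: dict(v) if isinstance(v, dict) else v
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if k not in cfg:
            raise ValueError(f"unknown config section {k!r}")
        if isinstance(cfg[k], dict):
            unknown = set(v) - set(cfg[k])
            if unknown:
                raise ValueError(f"unknown keys in {k!r}: {sorted(unknown)}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    a = cfg["assimilation"]
    if not (0.0 <= a["delta"] <= 1.0):
        raise ValueError("delta must lie in [0, 1]")
    if a["variant"] not in ("homogeneous", "H1", "H2", "H3"):
        raise ValueError("variant must be homogeneous/H1/H2/H3")
    s = cfg["simulation"]
    if s["dx_cm"] <= 0 or s["dt_ms"] <= 0:
        raise ValueError("dx and dt must be positive")
    if any(f <= 0 for f in s["frequencies_hz"]) or s["n_beats"] < 1:
        raise ValueError("pacing frequencies must be positive, n_beats >= 1")
    if cfg["scene"]["duration_s"] * cfg["scene"]["pacing_hz"] < 2:
        raise ValueError("scene must contain at least two beats")
    if cfg["scene"]["duration_s"] < 2.0 / cfg["analysis"]["f_low_hz"]:
        raise ValueError("scene too short to resolve the ultrastructure "
                         f"frequency {cfg['analysis']['f_low_hz']} Hz")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, progress=False) -> dict:
    """Execute the full pipeline; returns the manifest (also written).

    Stage failure aborts with the stage name in the raised error; artifacts
    of completed stages are preserved.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": cfg, "stages": [],
                "started_unix": time.time()}
    state = {}

    def stage(name, fn):
        t0 = time.time()
        try:
            artifacts = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed",
                                       "error": str(exc)})
            _write_manifest(out, manifest)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        entry = {"name": name, "status": "complete",
                 "wall_s": round(time.time() - t0, 3),
                 "artifacts": {k: {"file": str(p.name), "sha256": _sha256(p)}
                               for k, p in artifacts.items()}}
        manifest["stages"].append(entry)
        if progress:
            print(f"[{name}] done in {entry['wall_s']} s")

    def synth_stage():
        sc = cfg["scene"]
        scene = synthdata.two_region_scene(
            ny=sc["ny"], nx=sc["nx"], pacing_hz=sc["pacing_hz"],
            apd_base=sc["apd_base"], apd_delta=sc["apd_delta"],
            duration_s=sc["duration_s"], noise_sigma=sc["noise_sigma"],
            seed=cfg["seed"],
            g=synthdata.generate_ultrastructure_field(
                (sc["ny"], sc["nx"]), seed=cfg["seed"] + 1))
        movie = synthdata.generate_movie(scene)
        p = out / "movie.npz"
        io.write_movie(movie, p)
        state["movie"] = movie
        state["scene"] = scene
        return {"movie": p}

    def assimilate_stage():
        a = cfg["assimilation"]
        movie = state["movie"]
        mask = assimilation.compute_tissue_mask(movie, a["snr_threshold"])
        a05 = ffi.extract_ultrastructure(movie,
                                         cfg["analysis"]["f_low_hz"])
        H1 = assimilation.make_heterogeneity_map(a05, a["delta"], mask)
        H2 = assimilation.make_reciprocal_map(H1.H, a["delta"], mask)
        state["mask"], state["H1"], state["H2"] = mask, H1, H2
        arts = {}
        for nm, h in (("H1", H1), ("H2", H2)):
            p = out / f"{nm}.tif"
            io.write_map(h.H, p, {"delta": h.delta, "source": h.source,
                                  "smoothing": h.smoothing})
            arts[nm] = p
        return arts

    def simulate_stage():
        s = cfg["simulation"]
        a = cfg["assimilation"]
        variant = {
            "homogeneous": assimilation.ModelVariant.homogeneous(),
            "H1": assimilation.ModelVariant.h1(state["H1"]),
            "H2": assimilation.ModelVariant.h2(state["H2"]),
            "H3": assimilation.ModelVariant.h3(state["H1"], state["H2"]),
        }[a["variant"]]
        domain = assimilation.build_variant_domain(
            variant, dx=s["dx_cm"], params=ModelParameters(),
            mask=state["mask"], shape=state["mask"].shape)
        proto = ts.StimulusProtocol.pacing_down(s["frequencies_hz"],
                                                n_beats=s["n_beats"],
                                                site=s["site"])
        rec = ts.run_protocol(domain, proto, dt=s["dt_ms"],
                              record_interval_ms=s["record_interval_ms"])
        p = out / "recording.npz"
        rec.save_npz(p)
        state["recording"] = rec
        return {"recording": p}

    def ffi_stage():
        rec = state["recording"]
        movie = ffi.OpticalMovie.from_recording(rec)
        last = rec.stages[-1]
        f_p = last["frequency_hz"]
        window = (last["frame_start"], last["frame_end"])
        stack = ffi.ffi_transform(movie, window=window)
        arts = {}
        for f, tag in ((f_p, "fp"), (f_p / 2, "fp_half")):
            amp, ph, info = ffi.extract_frequency_map(stack, f)
            pa = out / f"amplitude_{tag}.tif"
            pp = out / f"phase_{tag}.tif"
            io.write_map(amp, pa, info)
            io.write_map(ph, pp, info)
            arts[f"amplitude_{tag}"] = pa
            arts[f"phase_{tag}"] = pp
            state[f"phase_{tag}"] = ph
        return arts

    def apd_stage():
        rec = state["recording"]
        movie = ffi.OpticalMovie.from_recording(rec)
        last = rec.stages[-1]
        sub = ffi.OpticalMovie(
            stack=movie.stack[last["frame_start"]:last["frame_end"]],
            frame_interval_ms=movie.frame_interval_ms,
            pixel_size_um=movie.pixel_size_um, mask=movie.mask,
            provenance="simulated")
        m = alternans.classify_pattern(alternans.delta_apd_map(sub))
        p = out / "delta_apd.tif"
        io.write_map(m.delta, p, {"label": m.label, **m.summary,
                                  "beat_pair": list(m.beat_pair)})
        pngs = io.render_maps(
            {"delta_apd": ("delta_apd", m.delta),
             "phase_fp_half": ("phase", state["phase_fp_half"])},
            out, mask=movie.mask)
        arts = {"delta_apd": p}
        for png in pngs:
            arts[png.stem + "_png"] = png
        return arts

    for name, fn in (("synth", synth_stage), ("assimilate", assimilate_stage),
                     ("simulate", simulate_stage), ("ffi", ffi_stage),
                     ("apd", apd_stage)):
        stage(name, fn)
    manifest["finished_unix"] = time.time()
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    io.atomic_write_bytes(out / "manifest.json",
                          (json.dumps(manifest, indent=2, default=str)
                           + "\n").encode())
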