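"""Shared I/O, configuration, and pipeline orchestration.

TIFF is the single image interchange format (multi-page, float32), ground
truth travels as a JSON sidecar, run configuration is YAML, and all tabular
outputs are CSV.  ``run_pipeline`` executes the requested stages and writes a
manifest (config hash, seed, versions) so every output is traceable;
deterministic stages are byte-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .calcium import (
    CalibrationParams,
    RatiometricStack,
    classify_overload,
    measure_neurites,
    overload_threshold,
    preprocess_channels,
    ratio_image,
)
from .plaques import PlaqueStack, max_projection, plaque_metrics, segment_plaques
from .synth import (
    CalciumSimParams,
    PlaqueSimParams,
    StimulusTrain,
    VSDSimParams,
    generate_calcium_stack,
    generate_plaque_volume,
    generate_vsd_movie,
)
from .vsd import VSDMovie, analyze_trace, compute_dff, epoch_movie, grid_synchrony

__all__ = [
    "read_stack",
    "write_stack",
    "write_ground_truth",
    "load_config",
    "run_pipeline",
]

log = logging.getLogger("slowosc")


def write_stack(path: str | Path, data: np.ndarray) -> Path:
    """Write an array as a multi-page float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32), photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    kind: str,
    frame_interval_s: float = 0.05,
    pixel_size_mm: float = 0.1,
    pixel_size_um: float = 0.5,
    z_step_um: float = 2.0,
    voxel_size_um: tuple[float, float, float] = (5.0, 2.0, 2.0),
    channel_order: tuple[str, str] = ("cfp", "yfp"),
):
    """Read a TIFF stack as a typed object.

    ``kind`` is one of ``movie`` (VSD time series), ``two_channel``
    (CFP/YFP calcium volume, channels on the first or second axis), or
    ``volume`` (single-channel plaque stack).  Physical metadata comes from
    the arguments (configuration overrides file tags).
    """
    arr = np.asarray(tifffile.imread(str(path)))
    if kind == "movie":
        if arr.ndim != 3:
            raise ValueError(f"movie must be 3-D (t, row, col); got shape {arr.shape}")
        return VSDMovie(
            frames=arr,
            frame_interval_s=frame_interval_s,
            pixel_size_mm=pixel_size_mm,
            meta={"path": str(path)},
        )
    if kind == "two_channel":
        if arr.ndim != 4:
            raise ValueError(f"two-channel volume must be 4-D; got shape {arr.shape}")
        if arr.shape[0] == 2:
            channels = {channel_order[0]: arr[0], channel_order[1]: arr[1]}
        elif arr.shape[1] == 2:
            channels = {channel_order[0]: arr[:, 0], channel_order[1]: arr[:, 1]}
        else:
            raise ValueError(f"no axis of size 2 in shape {arr.shape}")
        return RatiometricStack(
            cfp=channels["cfp"],
            yfp=channels["yfp"],
            z_step_um=z_step_um,
            pixel_size_um=pixel_size_um,
            meta={"path": str(path)},
        )
    if kind == "volume":
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3-D (z, row, col); got shape {arr.shape}")
        return PlaqueStack(volume=arr, voxel_size_um=voxel_size_um)
    raise ValueError(f"unknown stack kind {kind!r}")


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(path: str | Path, truth: Any) -> Path:
    """Serialize a ground-truth record as a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(truth), indent=1, sort_keys=True))
    return path


def load_config(path: str | Path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "stages" not in cfg:
        raise ValueError("config must be a mapping with a 'stages' list")
    _validate_config(cfg)
    return cfg


def _build_stage_params(cfg: dict, seed: int):
    """Construct (and thereby validate) every stage's parameter objects."""
    built = {}
    for stage in cfg["stages"]:
        name = stage["name"]
        opts = dict(stage.get("params", {}))
        if name == "simulate_vsd":
            stim_opts = opts.pop("stimulus", None)
            params = VSDSimParams(**{**opts, "seed": opts.get("seed", seed)})
            stim = StimulusTrain(**stim_opts) if stim_opts else None
            if stim is not None and stim.rate_hz >= params.nyquist_hz:
                raise ValueError(
                    f"stimulus rate {stim.rate_hz} Hz at or above Nyquist {params.nyquist_hz} Hz"
                )
            built[name] = (params, stim)
        elif name == "simulate_calcium":
            calib = opts.pop("calibration", None)
            if calib is not None:
                opts["calibration"] = CalibrationParams(**calib)
            if "ca_levels_nM" in opts:
                opts["ca_levels_nM"] = tuple(opts["ca_levels_nM"])
            built[name] = CalciumSimParams(**{**opts, "seed": opts.get("seed", seed)})
        elif name == "simulate_plaque":
            for key in ("volume_shape", "voxel_size_um", "radius_range_um", "intensity_range"):
                if key in opts:
                    opts[key] = tuple(opts[key])
            built[name] = PlaqueSimParams(**{**opts, "seed": opts.get("seed", seed)})
        elif name in ("analyze_vsd", "analyze_calcium", "analyze_plaque"):
            built[name] = opts
        else:
            raise ValueError(f"unknown stage {name!r}")
    return built


def _validate_config(cfg: dict, seed: int = 0) -> None:
    _build_stage_params(cfg, seed)


def run_pipeline(cfg: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the configured stages in order and write outputs plus a manifest.

    All parameters are validated up front, before any computation, so an
    invalid stage (e.g. a stimulus above Nyquist) aborts cleanly.  Returns
    the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    built = _build_stage_params(cfg, seed)

    outputs: list[str] = []
    state: dict[str, Any] = {}
    for stage in cfg["stages"]:
        name = stage["name"]
        log.info("running stage %s", name)
        try:
            if name == "simulate_vsd":
                params, stim = built[name]
                movie, truth = generate_vsd_movie(params, stim)
                state["vsd_movie"] = movie
                outputs.append(str(write_stack(out / "vsd_movie.tif", movie.frames)))
                outputs.append(str(write_ground_truth(out / "vsd_truth.json", truth)))
            elif name == "analyze_vsd":
                opts = built[name]
                movie = state.get("vsd_movie")
                if movie is None:
                    movie = read_stack(
                        opts["path"],
                        "movie",
                        frame_interval_s=opts.get("frame_interval_s", 0.05),
                        pixel_size_mm=opts.get("pixel_size_mm", 0.1),
                    )
                band = tuple(opts.get("band_hz", (0.0, 1.0)))
                rows = []
                for k, ep in enumerate(epoch_movie(movie, opts.get("epoch_s", 50.0))):
                    m = analyze_trace(compute_dff(ep), band=band, epoch_id=k)
                    sync = grid_synchrony(ep, tile_mm=opts.get("tile_mm", 1.0))
                    rows.append(
                        {
                            "epoch": k,
                            "total_power": m.total_power_sub1hz,
                            "mean_freq_hz": m.mean_frequency_hz,
                            "peak_freq_hz": m.peak_frequency_hz,
                            "synchrony_index": sync.synchrony_index,
                        }
                    )
                df = pd.DataFrame(rows)
                df.to_csv(out / "vsd_metrics.csv", index=False)
                outputs.append(str(out / "vsd_metrics.csv"))
            elif name == "simulate_calcium":
                params = built[name]
                stack, truth = generate_calcium_stack(params)
                state["calcium_stack"] = stack
                state["calcium_truth"] = truth
                data = np.stack([stack.cfp, stack.yfp])
                outputs.append(str(write_stack(out / "calcium_stack.tif", data)))
                outputs.append(
                    str(
                        write_ground_truth(
                            out / "calcium_truth.json",
                            {
                                "ca_levels_nM": truth.ca_levels_nM,
                                "true_ratios": truth.true_ratios,
                                "background_level": truth.background_level,
                            },
                        )
                    )
                )
            elif name == "analyze_calcium":
                opts = built[name]
                stack = state.get("calcium_stack")
                truth = state.get("calcium_truth")
                if stack is None:
                    raise ValueError("analyze_calcium requires a simulate_calcium stage")
                pre = preprocess_channels(stack, opts.get("median_radius", 2))
                ratio = ratio_image(pre)
                calib = CalibrationParams(**opts["calibration"]) if "calibration" in opts else CalibrationParams()
                rule = overload_threshold(opts.get("reference_ratios"))
                meas = measure_neurites(ratio, truth.labels, calib, rule)
                df = pd.DataFrame([vars(m) for m in meas])
                df.to_csv(out / "neurites.csv", index=False)
                outputs.append(str(out / "neurites.csv"))
            elif name == "simulate_plaque":
                params = built[name]
                volume, truth = generate_plaque_volume(params)
                state["plaque_stack"] = PlaqueStack(volume=volume, voxel_size_um=params.voxel_size_um)
                outputs.append(str(write_stack(out / "plaque_volume.tif", volume)))
                outputs.append(
                    str(
                        write_ground_truth(
                            out / "plaque_truth.json",
                            {
                                "count": truth.count,
                                "centers_vox": truth.centers_vox,
                                "radii_um": truth.radii_um,
                            },
                        )
                    )
                )
            elif name == "analyze_plaque":
                opts = built[name]
                stack = state.get("plaque_stack")
                if stack is None:
                    stack = read_stack(
                        opts["path"], "volume", voxel_size_um=tuple(opts.get("voxel_size_um", (5.0, 2.0, 2.0)))
                    )
                proj = max_projection(stack)
                seg = segment_plaques(
                    proj,
                    pixel_area_um2=stack.pixel_area_um2,
                    method=opts.get("method", "otsu"),
                    fixed_threshold=opts.get("fixed_threshold"),
                    min_area_um2=opts.get("min_area_um2", 2.0),
                )
                m = plaque_metrics(seg, stack)
                pd.DataFrame([dataclasses.asdict(m)]).to_csv(out / "plaque_metrics.csv", index=False)
                outputs.append(str(out / "plaque_metrics.csv"))
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "slowosc_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(str(Path(o).relative_to(out)) for o in outputs),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
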