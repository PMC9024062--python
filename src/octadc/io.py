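"""File formats and run configuration.

B-scans travel as 32-bit float TIFF (or NPY) with a JSON sidecar carrying
scale, depth pitch and provenance; raw volumes as one NPY array stack plus a
JSON sidecar recording the wavelength grid, seeds and the per-layer ground
truth (the parameter-recovery test surface).  Run configuration is a
pydantic-validated YAML document that round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, Field

from .recon import BScan
from .sim import RawFrame, make_source_spectrum, resample_to_k

__all__ = [
    "write_bscan",
    "read_bscan",
    "write_raw_volume",
    "read_raw_volume",
    "RunConfig",
    "load_config",
    "save_config",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# B-scan containers


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_bscan(path: str | Path, bscan: BScan) -> None:
    """Write pixels (float32 TIFF or NPY by extension) + JSON sidecar."""
    path = Path(path)
    pixels = bscan.image.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    elif path.suffix.lower() == ".npy":
        np.save(path, pixels)
    else:
        raise ValueError(f"unsupported container {path.suffix!r} (use .tif/.tiff/.npy)")
    meta = {
        "scale": bscan.scale,
        "depth_pitch_um": None if np.isnan(bscan.depth_pitch_um) else bscan.depth_pitch_um,
        "provenance": bscan.provenance,
        "schema_version": SCHEMA_VERSION,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_bscan(path: str | Path) -> BScan:
    """Read a B-scan; a missing sidecar warns and assumes linear scale."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif path.suffix.lower() == ".npy":
        pixels = np.load(path)
    else:
        raise ValueError(f"unsupported container {path.suffix!r}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pitch = meta.get("depth_pitch_um")
        return BScan(
            np.asarray(pixels, dtype=float),
            scale=meta.get("scale", "linear"),
            depth_pitch_um=float("nan") if pitch is None else float(pitch),
            provenance=meta.get("provenance", {}),
        )
    warnings.warn(f"no sidecar for {path.name}; assuming linear scale", stacklevel=2)
    log.warning("no sidecar for %s; assuming linear scale", path)
    return BScan(np.asarray(pixels, dtype=float))


# --------------------------------------------------------------------------
# raw volumes


def write_raw_volume(
    directory: str | Path,
    frames: list[RawFrame],
    truth: dict[str, Any] | None = None,
) -> None:
    """One NPY stack (n_frames x P x A) + JSON sidecar per volume.

    ``truth`` may carry the simulation ground truth (per-layer depths and
    dispersion coefficients, seeds) for parameter-recovery checks.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([f.fringes for f in frames]).astype(np.float32)
    np.save(directory / "fringes.npy", stack)
    f0 = frames[0]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_pixels": f0.n_pixels,
        "n_alines": f0.n_alines,
        "n_frames": len(frames),
        "repeats": f0.repeats,
        "volume_index": f0.volume_index,
        "wavelength_nm_range": [
            float(f0.source.wavelengths_nm[0]),
            float(f0.source.wavelengths_nm[-1]),
        ],
        "center_wavelength_nm": f0.source.center_wavelength_nm,
        "k_range": [float(f0.grid.k_values[0]), float(f0.grid.k_values[-1])],
        "k0": f0.grid.k0,
        "frames": [
            {
                "frame_index": f.frame_index,
                "bscan_index": f.bscan_index,
                "repeat_index": f.repeat_index,
            }
            for f in frames
        ],
        "truth": truth or {},
    }
    (directory / "volume.json").write_text(json.dumps(meta, indent=2))


def read_raw_volume(directory: str | Path) -> tuple[list[RawFrame], dict[str, Any]]:
    directory = Path(directory)
    meta = json.loads((directory / "volume.json").read_text())
    stack = np.load(directory / "fringes.npy")
    lam_lo, lam_hi = meta["wavelength_nm_range"]
    center = meta["center_wavelength_nm"]
    # rebuild the source grid from its defining parameters
    n_pixels = meta["n_pixels"]
    fwhm = (lam_hi - lam_lo) / 4.0  # grid spans center +/- 2*FWHM
    source = make_source_spectrum(center, fwhm, n_pixels)
    grid = resample_to_k(source)
    frames = []
    for arr, finfo in zip(stack, meta["frames"]):
        frames.append(
            RawFrame(
                np.asarray(arr, dtype=float),
                source,
                grid,
                repeats=meta["repeats"],
                frame_index=finfo["frame_index"],
                volume_index=meta["volume_index"],
                bscan_index=finfo["bscan_index"],
                repeat_index=finfo["repeat_index"],
            )
        )
    return frames, meta


# --------------------------------------------------------------------------
# run configuration


class SimulatorBlock(BaseModel):
    schema_version: int = SCHEMA_VERSION
    n_pixels: int = 256
    a_lines: int = 128
    center_wavelength_nm: float = 840.0
    fwhm_bandwidth_nm: float = 50.0
    n_volumes: int = 2
    bscans_per_volume: int = 4
    repeats: int = 1
    additive_sigma: float = 0.02
    speckle_density: int = 8
    seed: int = 0


class ReconstructionBlock(BaseModel):
    schema_version: int = SCHEMA_VERSION
    c_min: float = -30.0
    c_max: float = 30.0
    n_channels: int = 5
    interpolation: str = "cubic"
    floor_db: float = -50.0


class GroundTruthBlock(BaseModel):
    schema_version: int = SCHEMA_VERSION
    n_bands: int = 5
    boundaries: str = "auto"
    sweep_min: float = -40.0
    sweep_max: float = 40.0
    sweep_step: float = 5.0
    feather: int = 0
    n_train_volumes: int = 1


class ModelBlock(BaseModel):
    schema_version: int = SCHEMA_VERSION
    n_channels: int = 5
    encoder_stages: int = 2
    base_filters: int = 8
    growth_per_block: int = 8
    layers_per_block: int = 2
    final_activation: str = "sigmoid"
    loss: str = "dice"
    learning_rate: float = 1e-3
    epochs: int = 5
    batch_size: int = 8
    rng_seed: int = 0


class EvaluationBlock(BaseModel):
    schema_version: int = SCHEMA_VERSION
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 1.0
    n_scales: int = 5
    repeat_group: int = 1
    seeds: list[int] = Field(default_factory=lambda: [0, 1, 2])
    channel_counts: list[int] = Field(default_factory=lambda: [1, 3, 5])


class RunConfig(BaseModel):
    """Validated, losslessly round-tripping run configuration."""

    simulator: SimulatorBlock = Field(default_factory=SimulatorBlock)
    reconstruction: ReconstructionBlock = Field(default_factory=ReconstructionBlock)
    gtruth: GroundTruthBlock = Field(default_factory=GroundTruthBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
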