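"""Shared file I/O: TIFF stacks, trajectory tables, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic_imaging import Timelapse

__all__ = [
    "write_timelapse",
    "read_timelapse",
    "write_trajectory",
    "load_config",
    "dump_config",
]


def write_timelapse(path, tl: Timelapse) -> None:
    """Multi-page TIFF with the axis order and calibration in the metadata."""
    axes = "TCZYX" if tl.channels else "TZYX"
    meta = {
        "axes": axes,
        "pixel_size_um": tl.pixel_size,
        "z_step_um": tl.z_step,
        "frame_interval_s": tl.frame_interval,
        "channels": list(tl.channels) if tl.channels else None,
        **tl.meta,
    }
    tifffile.imwrite(path, tl.data.astype(np.float32),
                     metadata={"mpresolve": json.dumps(meta)})


def read_timelapse(path) -> Timelapse:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        raw = tif.pages[0].tags.get("ImageDescription")
        meta = {}
        if raw is not None:
            try:
                meta = json.loads(json.loads(raw.value).get("mpresolve", "{}"))
            except (json.JSONDecodeError, AttributeError, TypeError):
                meta = {}
    channels = tuple(meta["channels"]) if meta.get("channels") else None
    return Timelapse(
        data=np.asarray(data, dtype=float),
        pixel_size=float(meta.get("pixel_size_um", 0.11)),
        z_step=float(meta.get("z_step_um", 0.6)),
        frame_interval=float(meta.get("frame_interval_s", 60.0)),
        channels=channels,
        meta={k: v for k, v in meta.items()
              if k not in {"axes", "pixel_size_um", "z_step_um",
                           "frame_interval_s", "channels"}})


def write_trajectory(path, trajectory) -> None:
    """Trajectory as CSV plus a JSON sidecar with scenario metadata."""
    path = Path(path)
    trajectory.to_frame().to_csv(path, index=False)
    meta = {
        "scenario": trajectory.scenario.name,
        "duration_s": trajectory.scenario.duration,
        "U0_mV": trajectory.scenario.U0,
        "r0_um": trajectory.scenario.r0_um,
        "initial_luminal": trajectory.scenario.initial_luminal,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
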