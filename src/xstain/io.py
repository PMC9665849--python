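"""Plain-format I/O: TIFF stacks with JSON sidecars, CSV profile matrices.

Depths are written in micrometers and times in minutes at the I/O boundary;
in memory everything is mm / min.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .projprep import IntensityProfile, ProjectionStack

__all__ = ["write_stack", "read_stack", "write_profile_csv", "read_profile_csv"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(stack: ProjectionStack, tif_path, json_path=None, ground_truth=None):
    """Write a multi-page grayscale TIFF plus a JSON sidecar with timestamps
    (minutes), pixel size (mm) and, optionally, the generating ground truth."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, stack.frames.astype(np.float32))
    meta = {
        "timestamps_min": stack.timestamps.tolist(),
        "pixel_size_mm": stack.pixel_size,
    }
    if ground_truth is not None:
        meta["ground_truth"] = _jsonable(ground_truth)
    json_path = Path(json_path) if json_path else tif_path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=1))
    return tif_path, json_path


def read_stack(tif_path, json_path=None) -> ProjectionStack:
    tif_path = Path(tif_path)
    frames = tifffile.imread(tif_path).astype(float)
    json_path = Path(json_path) if json_path else tif_path.with_suffix(".json")
    meta = json.loads(json_path.read_text())
    return ProjectionStack(frames, np.asarray(meta["timestamps_min"], float),
                           float(meta["pixel_size_mm"]))


def write_profile_csv(profile: IntensityProfile, path, float_format="%.6g"):
    """Depth rows (um) x time columns (min), with the stage recorded in the
    index name."""
    df = pd.DataFrame(profile.values,
                      index=np.round(profile.depth_grid * 1000.0, 6),
                      columns=profile.time_grid)
    df.index.name = f"depth_um[{profile.stage}]"
    df.columns.name = "time_min"
    df.to_csv(path, float_format=float_format)
    return Path(path)


def read_profile_csv(path) -> IntensityProfile:
    df = pd.read_csv(path, index_col=0)
    stage = "raw_w"
    name = df.index.name or ""
    if "[" in name:
        stage = name.split("[", 1)[1].rstrip("]")
    return IntensityProfile(df.index.to_numpy(float) / 1000.0,
                            df.columns.to_numpy(float),
                            df.to_numpy(float), stage)
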