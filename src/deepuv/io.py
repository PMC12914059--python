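"""File I/O: multi-page TIFF stacks and masks, CSV tables, JSON/YAML configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml


def save_stack(path, stack: np.ndarray) -> None:
    """Write a (T, H, W) float stack as a multi-page float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def load_stack(path) -> np.ndarray:
    data = tifffile.imread(str(path))
    return data[None] if data.ndim == 2 else data


def save_mask(path, mask: np.ndarray) -> None:
    """Write an integer label mask as 16-bit TIFF."""
    mask = np.asarray(mask)
    if mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("more labels than uint16 can hold")
    tifffile.imwrite(str(path), mask.astype(np.uint16))


def load_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def save_map(path, map_: np.ndarray) -> None:
    """Write a float map (possibly NaN outside mask) as float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(map_, dtype=np.float32))


def save_json(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_yaml(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def save_png(path, rgb: np.ndarray) -> None:
    """Write an RGB float image in [0, 1] as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(str(path), np.clip(rgb, 0, 1))
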