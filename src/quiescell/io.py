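"""Standard-format I/O: multi-page TIFF stacks, CSV tables, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .render import CHANNELS, ImageStack

__all__ = ["save_stack", "load_stack", "save_masks", "load_masks",
           "write_json", "read_json"]


def save_stack(stack: ImageStack, out_dir) -> None:
    """Write one multi-page TIFF per channel plus ground-truth labels and
    frame timestamps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(stack.channel_names):
        tifffile.imwrite(out / f"{name}.tif", stack.data[i], compression=None)
    tifffile.imwrite(out / "labels.tif", stack.labels, compression=None)
    pd.DataFrame({"frame": np.arange(stack.n_frames),
                  "time_h": stack.times}).to_csv(out / "times.csv", index=False)


def load_stack(in_dir) -> ImageStack:
    src = Path(in_dir)
    data = np.stack([tifffile.imread(src / f"{name}.tif") for name in CHANNELS])
    labels_path = src / "labels.tif"
    labels = (tifffile.imread(labels_path) if labels_path.exists()
              else np.zeros(data.shape[1:], dtype=np.uint16))
    times = pd.read_csv(src / "times.csv")["time_h"].to_numpy()
    return ImageStack(data=data, times=times, labels=labels)


def save_masks(masks, path) -> None:
    tifffile.imwrite(Path(path), np.stack(masks).astype(np.uint16),
                     compression=None)


def load_masks(path) -> list[np.ndarray]:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [arr[i].astype(np.int32) for i in range(arr.shape[0])]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
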