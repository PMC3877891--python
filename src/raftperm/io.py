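"""File-format helpers: multi-page TIFF stacks, single images, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from raftperm.nb_brightness import ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "write_truth",
    "read_truth",
]


def write_stack(path, stack: ImageStack) -> None:
    """Write an image stack as a 16-bit multi-page TIFF."""
    frames = np.asarray(stack.frames)
    if frames.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed the 16-bit range")
    tifffile.imwrite(path, frames.astype(np.uint16))


def read_stack(path, **kwargs) -> ImageStack:
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames.astype(np.int64), **kwargs)


def write_image(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def read_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_truth(artifact_path, truth: dict) -> Path:
    """Write a ground-truth sidecar next to an artifact (`.truth.json`)."""
    p = Path(artifact_path)
    sidecar = p.with_suffix(p.suffix + ".truth.json") if p.suffix == "" else \
        p.parent / (p.stem + ".truth.json")
    sidecar.write_text(json.dumps(truth, cls=_NumpyEncoder, indent=2))
    return sidecar


def read_truth(artifact_path) -> dict:
    p = Path(artifact_path)
    sidecar = p.parent / (p.stem + ".truth.json")
    return json.loads(sidecar.read_text())
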