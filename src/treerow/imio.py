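"""Raster and JSON I/O.

Conventions used across the package:

* images are ``uint8`` RGB arrays of shape ``(H, W, 3)``;
* label masks are single-channel integer arrays of shape ``(H, W)`` with
  0 = background, written as 16-bit grayscale PNG;
* ``x`` is the column index, ``y`` the row index, both 0-based, ``y``
  increasing downward.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an RGB image as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {arr.shape}")
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as an HxWx3 uint8 array."""
    with Image.open(Path(path)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a label mask as single-channel 16-bit PNG (0 = background)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected HxW mask, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask values outside the uint16 range")
    Image.fromarray(arr.astype(np.uint16)).save(Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel label raster as an int32 HxW array."""
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(p)
    with Image.open(p) as im:
        if im.mode in ("I;16", "I", "L", "P"):
            arr = np.asarray(im if im.mode != "P" else im.convert("L"))
        else:
            # collapse accidental RGB label exports to one channel
            rgb = np.asarray(im.convert("RGB"))
            if not (rgb[..., 0] == rgb[..., 1]).all() or not (rgb[..., 0] == rgb[..., 2]).all():
                raise ValueError(f"{p}: multi-channel raster is not a label mask")
            arr = rgb[..., 0]
    return arr.astype(np.int32)


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
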