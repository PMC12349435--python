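"""Prompt-conditioned segmentation backends and instance assembly.

A *backend* is anything that takes an RGB image plus a handful of
foreground point prompts and returns one binary mask: foundation models
behind an adapter, a subprocess wrapping an external model server, or the
two built-in offline backends:

* :class:`OracleBackend` — returns the ground-truth instance receiving the
  majority of the prompt points (synthetic scenes only; a test instrument
  that isolates prompt quality from segmentation quality);
* :class:`RegionGrowBackend` — seeded region growing by color similarity,
  a classical baseline that runs with no trained weights.

All backend outputs pass through a contract check (shape, binariness)
before anything downstream touches them.  Per-tree masks are merged into a
single instance raster by :func:`assemble_instances`; pixels claimed by
several trees go to the tree whose prompt center C is nearest.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage

from . import imio
from .prompts import PromptSet

__all__ = [
    "SegmenterBackend",
    "BackendError",
    "OracleBackend",
    "RegionGrowBackend",
    "ExternalBackend",
    "segment_one",
    "region_grow",
    "assemble_instances",
    "segment_scene",
    "keep_largest_component",
]

Point = tuple[float, float]


class BackendError(RuntimeError):
    """A backend violated the segmenter contract or failed outright."""


class SegmenterBackend(Protocol):
    name: str
    stochastic: bool

    def __call__(self, image: np.ndarray, points: Sequence[Point]) -> np.ndarray: ...


def segment_one(
    image: np.ndarray, points: Sequence[Point], backend: SegmenterBackend
) -> np.ndarray:
    """Run one backend call under the contract check.

    Points outside the image are clamped into bounds with a warning.  The
    returned mask is boolean, with the image's HxW shape.
    """
    img = np.asarray(image)
    H, W = img.shape[:2]
    clamped = []
    for x, y in points:
        cx, cy = min(max(float(x), 0.0), W - 1.0), min(max(float(y), 0.0), H - 1.0)
        if (cx, cy) != (float(x), float(y)):
            warnings.warn(f"prompt point ({x}, {y}) outside image, clamped", stacklevel=2)
        clamped.append((cx, cy))
    try:
        mask = backend(img, clamped)
    except BackendError:
        raise
    except Exception as exc:  # noqa: BLE001 - contract boundary
        raise BackendError(f"backend {getattr(backend, 'name', backend)!r} failed: {exc}") from exc
    mask = np.asarray(mask)
    if mask.shape != (H, W):
        raise BackendError(
            f"backend {getattr(backend, 'name', backend)!r} returned shape "
            f"{mask.shape}, expected {(H, W)}"
        )
    uniq = np.unique(mask)
    if not np.isin(uniq, [0, 1, False, True]).all():
        raise BackendError(
            f"backend {getattr(backend, 'name', backend)!r} returned non-binary values"
        )
    return mask.astype(bool)


def _round_point(p: Point, shape: tuple[int, int]) -> tuple[int, int]:
    H, W = shape
    x = int(np.clip(np.floor(p[0] + 0.5), 0, W - 1))  # round half away from zero
    y = int(np.clip(np.floor(p[1] + 0.5), 0, H - 1))
    return x, y


@dataclass
class OracleBackend:
    """Ground-truth lookup backend (synthetic scenes only).

    Returns the truth instance containing the majority of the prompt
    points; ties are broken by the instance containing C (the third point
    in canonical B, T, C, R, L order); if no point lands on any instance,
    the mask is empty.
    """

    truth_instances: np.ndarray
    name: str = "oracle"
    stochastic: bool = False

    def __call__(self, image: np.ndarray, points: Sequence[Point]) -> np.ndarray:
        truth = np.asarray(self.truth_instances)
        votes: dict[int, int] = {}
        hit_labels = []
        for p in points:
            x, y = _round_point(p, truth.shape)
            label = int(truth[y, x])
            hit_labels.append(label)
            if label > 0:
                votes[label] = votes.get(label, 0) + 1
        if not votes:
            return np.zeros(truth.shape, dtype=bool)
        best = max(votes.values())
        winners = sorted(lab for lab, v in votes.items() if v == best)
        if len(winners) > 1 and len(hit_labels) >= 3 and hit_labels[2] in winners:
            winner = hit_labels[2]  # C's instance breaks the tie
        else:
            winner = winners[0]
        return truth == winner


def region_grow(
    image: np.ndarray,
    points: Sequence[Point],
    color_tol: float = 40.0,
    connectivity: int = 8,
    corridor: tuple[float, float] | None = None,
) -> np.ndarray:
    """Union of color flood fills from each seed point.

    Growth from a seed repeatedly admits pixels adjacent to the region
    (4- or 8-connected) whose RGB Euclidean distance to the running region
    mean is within ``color_tol``; the mean is updated after every wave so
    the region tracks slow color drift.  ``corridor=(x_left, x_right)``
    confines growth to that column band (the strip between the tree's
    neighbor axes).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    H, W = img.shape[:2]
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)

    allowed = np.ones((H, W), dtype=bool)
    if corridor is not None:
        cols = np.arange(W)
        allowed &= (cols >= corridor[0]) & (cols <= corridor[1])

    out = np.zeros((H, W), dtype=bool)
    for p in points:
        x, y = _round_point(p, (H, W))
        if not allowed[y, x]:
            continue
        region = np.zeros((H, W), dtype=bool)
        region[y, x] = True
        mean = img[y, x].copy()
        while True:
            cand = ndimage.binary_dilation(region, structure=struct) & ~region & allowed
            if not cand.any():
                break
            dist = np.linalg.norm(img[cand] - mean, axis=1)
            newly = np.zeros((H, W), dtype=bool)
            newly[cand] = dist <= color_tol
            if not newly.any():
                break
            region |= newly
            mean = img[region].mean(axis=0)
        out |= region
    return out


@dataclass
class RegionGrowBackend:
    """Offline reference backend: seeded region growing by color.

    A classical baseline, not a stand-in claim about any foundation model's
    behavior; it exists so the pipeline end-to-end path runs and is testable
    with no trained weights.
    """

    color_tol: float = 40.0
    connectivity: int = 8
    corridor: tuple[float, float] | None = None
    name: str = "regiongrow"
    stochastic: bool = False

    def __call__(self, image: np.ndarray, points: Sequence[Point]) -> np.ndarray:
        return region_grow(
            image, points, self.color_tol, self.connectivity, self.corridor
        )


@dataclass
class ExternalBackend:
    """Subprocess adapter: the seam where a real promptable model plugs in.

    The command is invoked as ``<command> <image.png> <prompts.json> <out.png>``
    inside a temp directory; it must write a binary-mask PNG to the output
    path.  The prompt JSON holds ``{"points": [[x, y], ...], "point_labels":
    [1, ...]}`` with label 1 = foreground, matching promptable-segmenter
    conventions.  No model is bundled; any server honoring the protocol works.
    """

    command: Sequence[str]
    name: str = "external"
    stochastic: bool = True

    def __call__(self, image: np.ndarray, points: Sequence[Point]) -> np.ndarray:
        with tempfile.TemporaryDirectory() as tmp:
            tmp_path = Path(tmp)
            img_p, json_p, out_p = tmp_path / "image.png", tmp_path / "prompts.json", tmp_path / "mask.png"
            imio.write_image(img_p, image)
            imio.write_json(
                json_p,
                {"points": [[float(x), float(y)] for x, y in points],
                 "point_labels": [1] * len(points)},
            )
            proc = subprocess.run(
                [*self.command, str(img_p), str(json_p), str(out_p)],
                capture_output=True, text=True,
            )
            if proc.returncode != 0:
                raise BackendError(f"external backend failed: {proc.stderr.strip()}")
            if not out_p.is_file():
                raise BackendError("external backend wrote no mask")
            return imio.read_mask(out_p) > 0


def keep_largest_component(mask: np.ndarray) -> np.ndarray:
    """Optional post-processing: retain only the largest connected component."""
    m = np.asarray(mask).astype(bool)
    labeled, n = ndimage.label(m)
    if n <= 1:
        return m
    sizes = ndimage.sum_labels(m, labeled, index=np.arange(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def segment_scene(
    image: np.ndarray,
    prompts: PromptSet,
    backend: SegmenterBackend | Callable[[int], SegmenterBackend],
    largest_component: bool = False,
) -> dict[int, np.ndarray]:
    """Segment every prompted tree; returns label -> binary mask.

    ``backend`` may be a single backend or a factory ``label -> backend``
    (used e.g. to give each tree its own corridor-confined region grower).
    """
    masks: dict[int, np.ndarray] = {}
    for label in sorted(prompts.entries):
        be = backend(label) if _is_factory(backend) else backend
        mask = segment_one(image, prompts.points(label), be)
        if largest_component:
            mask = keep_largest_component(mask)
        masks[label] = mask
    return masks


def _is_factory(backend) -> bool:
    # a factory is a plain callable without the backend's `name` attribute
    return not hasattr(backend, "name")


def assemble_instances(
    mask_set: dict[int, np.ndarray], prompts: PromptSet
) -> np.ndarray:
    """Merge per-tree binary masks into one instance raster.

    Mask ids must match prompt ids.  A pixel claimed by several trees is
    assigned to the tree whose prompt center C is nearest (Euclidean);
    exact distance ties go to the lower label.  The result is invariant to
    the input ordering of trees.
    """
    if set(mask_set) != set(prompts.entries):
        raise ValueError(
            f"mask ids {sorted(mask_set)} do not match prompt ids {sorted(prompts.entries)}"
        )
    if not mask_set:
        raise ValueError("empty mask set")
    labels = sorted(mask_set)
    shape = np.asarray(mask_set[labels[0]]).shape
    out = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for label in labels:
        m = np.asarray(mask_set[label]).astype(bool)
        if m.shape != shape:
            raise ValueError(f"mask {label} has shape {m.shape}, expected {shape}")
        cx, cy = prompts.entries[label]["C"]
        d = (xx - cx) ** 2 + (yy - cy) ** 2
        take = m & (d < best)  # strict < keeps the lower (earlier) label on ties
        out[take] = label
        best[take] = d[take]
    return out
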