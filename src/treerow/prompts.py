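"""Five-point diamond prompts above detected trunks.

Each labeled trunk anchors a prompt layout for the tree above it:

* a regression axis is fitted through the trunk's pixels (column on row,
  so near-vertical trunks stay finite-sloped), per-trunk angles are
  averaged into a shared row tilt ``alpha``, and each trunk's axis is
  re-anchored through its centroid at that shared angle;
* ``B`` is the axis point at the trunk's lowest pixel row;
* the summit ``T`` is either ``B`` displaced by a user-supplied height
  ``h`` along the axis (supervised) or the top of the continuous
  foreground run along the axis starting at ``B`` (unsupervised, from a
  vegetation mask);
* ``C`` is the midpoint of ``B`` and ``T``; the lateral points sit at
  ``C``'s height, 20% of the way toward the neighboring border:
  ``R = (x_c + 0.2*(x_br - x_c), y_c)`` and ``L = (x_c - 0.2*(x_c - x_bl), y_c)``.

Angles are in degrees from the image vertical, range (-90, 90).
Coordinates are floats in (x=column, y=row) with y increasing downward;
consumers round at their own boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
from skimage.filters import threshold_otsu

from . import imio
from .trunks import centroids as _centroids, labels_of

__all__ = [
    "TrunkAxis",
    "NeighborSpan",
    "PromptConfig",
    "PromptSet",
    "fit_free_axis",
    "mean_axis_angle",
    "constrained_axis",
    "horizontal_neighbors",
    "summit_supervised",
    "estimate_foreground",
    "summit_unsupervised",
    "build_prompts",
    "write_prompts",
    "read_prompts",
]

PROMPT_SCHEMA = "rowprompt-v1"
POINT_NAMES = ("B", "T", "C", "R", "L")


@dataclass(frozen=True)
class TrunkAxis:
    """A trunk's fitted line: anchored at the centroid, tilted from vertical."""

    label: int
    anchor: tuple[float, float]
    angle_deg: float            # constrained (shared) angle actually used
    bottom: tuple[float, float]  # B: axis point at the trunk's lowest row
    free_angle_deg: float       # unconstrained per-trunk fit

    def x_at(self, y: float) -> float:
        return self.anchor[0] + math.tan(math.radians(self.angle_deg)) * (y - self.anchor[1])


@dataclass(frozen=True)
class NeighborSpan:
    """Horizontal borders of a tree: nearest trunk x on each side (or the edge)."""

    label: int
    x_left: float
    x_right: float


@dataclass(frozen=True)
class PromptConfig:
    mode: Literal["supervised", "unsupervised"] = "supervised"
    height_px: float | None = None       # h, supervised mode
    gap_tolerance_px: int = 10
    edge_policy: Literal["edge", "half"] = "edge"
    shared_angle: bool = True            # constrain all axes to the mean angle

    def __post_init__(self) -> None:
        if self.mode == "supervised":
            if self.height_px is None or self.height_px <= 0:
                raise ValueError("supervised mode requires height_px > 0")
        elif self.mode != "unsupervised":
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PromptSet:
    """Per-tree five-point prompts: id -> {B, T, C, R, L}."""

    entries: dict[int, dict[str, tuple[float, float]]] = field(default_factory=dict)
    failures: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def points(self, label: int) -> list[tuple[float, float]]:
        """The five points of one tree in canonical B, T, C, R, L order."""
        e = self.entries[label]
        return [e[name] for name in POINT_NAMES]


def fit_free_axis(trunk_xy: np.ndarray) -> float:
    """Least-squares axis angle of one trunk, degrees from vertical.

    ``trunk_xy`` is an (N, 2) array of (x, y) pixel coordinates.  The fit is
    column-on-row, ``x = a*y + b``, returning ``atan(a)``; a row-on-column fit
    would blow up for the near-vertical trunks this stage exists for.
    """
    xy = np.asarray(trunk_xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] < 2:
        raise ValueError("need an (N>=2, 2) array of (x, y) coordinates")
    x, y = xy[:, 0], xy[:, 1]
    if np.unique(y).size < 2:
        raise ValueError("degenerate trunk: all pixels in one row")
    a = np.polyfit(y, x, 1)[0]
    return math.degrees(math.atan(a))


def mean_axis_angle(free_angles_deg) -> float:
    """Arithmetic mean of per-trunk angles (degrees)."""
    angles = list(free_angles_deg)
    if not angles:
        raise ValueError("no angles to average")
    return float(np.mean(angles))


def constrained_axis(
    trunk_xy: np.ndarray,
    alpha_deg: float,
    label: int = 0,
    free_angle_deg: float | None = None,
) -> TrunkAxis:
    """Axis through the trunk centroid at the shared angle ``alpha_deg``.

    The bottom point B lies on this line at the trunk's maximal pixel row.
    """
    xy = np.asarray(trunk_xy, dtype=float)
    if xy.size == 0:
        raise ValueError("empty trunk pixel set")
    cx, cy = float(xy[:, 0].mean()), float(xy[:, 1].mean())
    y_b = float(xy[:, 1].max())
    x_b = cx + math.tan(math.radians(alpha_deg)) * (y_b - cy)
    if free_angle_deg is None:
        free_angle_deg = fit_free_axis(xy)
    return TrunkAxis(
        label=label,
        anchor=(cx, cy),
        angle_deg=float(alpha_deg),
        bottom=(x_b, y_b),
        free_angle_deg=float(free_angle_deg),
    )


def horizontal_neighbors(
    centroid_xs, image_width: int, edge_policy: str = "edge", labels=None
) -> list[NeighborSpan]:
    """Left/right borders for each trunk from its nearest neighbors.

    ``centroid_xs`` must be sorted ascending (the 1..k left-to-right label
    order).  Interior trees use the neighboring trunk centroids; boundary
    trees use the image edge (policy ``"edge"``: 0 and width-1) or the
    midpoint between centroid and edge (policy ``"half"``).
    """
    xs = [float(v) for v in centroid_xs]
    if not xs:
        return []
    if edge_policy not in ("edge", "half"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    if labels is None:
        labels = list(range(1, len(xs) + 1))
    spans = []
    for i, cx in enumerate(xs):
        if i > 0:
            left = xs[i - 1]
        else:
            left = 0.0 if edge_policy == "edge" else (0.0 + cx) / 2.0
        if i < len(xs) - 1:
            right = xs[i + 1]
        else:
            w_edge = float(image_width - 1)
            right = w_edge if edge_policy == "edge" else (cx + w_edge) / 2.0
        spans.append(NeighborSpan(label=labels[i], x_left=left, x_right=right))
    return spans


def summit_supervised(axis: TrunkAxis, height_px: float) -> tuple[float, float]:
    """T: the point ``height_px`` pixels up the axis from B (Euclidean)."""
    if height_px <= 0:
        raise ValueError("height_px must be positive")
    a = math.radians(axis.angle_deg)
    x_b, y_b = axis.bottom
    x_t = x_b - height_px * math.sin(a)
    y_t = y_b - height_px * math.cos(a)
    if y_t < 0:
        warnings.warn(
            f"trunk {axis.label}: supervised summit above image top, clamped to y=0",
            stacklevel=2,
        )
        y_t = 0.0
        x_t = axis.x_at(0.0)
    return (x_t, y_t)


def estimate_foreground(image: np.ndarray) -> np.ndarray:
    """Vegetation mask from the excess-green index, Otsu-thresholded.

    ExG = 2g - r - b on channels normalized to [0, 1]; vegetation is
    green-dominant so ExG separates it from soil/sky backgrounds.  This is a
    self-contained stand-in for a dedicated foreground-segmentation tool;
    any user-supplied mask can be passed downstream instead.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 image")
    rgb = img.astype(float) / 255.0
    exg = 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]
    if float(exg.max() - exg.min()) < 1e-9:
        # constant index: green-dominant everywhere or nowhere
        return (exg > 0.05).astype(np.uint8)
    thr = threshold_otsu(exg)
    return (exg > thr).astype(np.uint8)


def _rasterize_axis_up(axis: TrunkAxis, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel trace of the axis from B's row up to row 0 (one pixel per row)."""
    H, W = shape
    y0 = int(min(round(axis.bottom[1]), H - 1))
    ys = np.arange(y0, -1, -1)
    xs = np.clip(np.rint(axis.x_at(ys.astype(float))).astype(int), 0, W - 1)
    return ys, xs


def summit_unsupervised(
    axis: TrunkAxis, foreground: np.ndarray, gap_tolerance_px: int = 10
) -> tuple[float, float]:
    """T from the foreground run along the axis above B.

    The axis is traced upward one row at a time from B; the run starts at
    the first foreground hit at-or-above B (the trunk base itself is usually
    not vegetation) and extends upward while off-mask gaps stay within
    ``gap_tolerance_px`` rows.  T is the run's topmost on-line point.
    """
    F = np.asarray(foreground) != 0
    ys, xs = _rasterize_axis_up(axis, F.shape)
    on = F[ys, xs]
    hits = np.nonzero(on)[0]
    if hits.size == 0:
        raise ValueError(f"trunk {axis.label}: summit not found (no foreground on axis)")
    top_idx = int(hits[0])
    gap = 0
    for idx in range(hits[0] + 1, len(ys)):
        if on[idx]:
            top_idx = idx
            gap = 0
        else:
            gap += 1
            if gap > gap_tolerance_px:
                break
    y_t = float(ys[top_idx])
    return (axis.x_at(y_t), y_t)


def _heights_by_label(height_px, labels) -> dict[int, float]:
    if isinstance(height_px, Mapping):
        return {int(k): float(v) for k, v in height_px.items()}
    return {label: float(height_px) for label in labels}


def build_prompts(
    trunk_instances: np.ndarray,
    config: PromptConfig,
    image: np.ndarray | None = None,
    foreground: np.ndarray | None = None,
    height_px: float | Mapping[int, float] | None = None,
) -> PromptSet:
    """Run the full prompt layout over a labeled trunk mask.

    Supervised mode takes ``height_px`` (scalar, or mapping label -> h;
    falls back to ``config.height_px``).  Unsupervised mode takes a
    ``foreground`` vegetation mask or derives one from ``image`` via
    :func:`estimate_foreground`.  Per-tree summit failures are recorded in
    ``PromptSet.failures`` rather than aborting the whole scene.
    """
    inst = np.asarray(trunk_instances)
    labels = labels_of(inst)
    result = PromptSet()
    if not labels:
        warnings.warn("no trunk instances: empty prompt set", stacklevel=2)
        return result

    pixel_sets: dict[int, np.ndarray] = {}
    for label in labels:
        ys, xs = np.nonzero(inst == label)
        pixel_sets[label] = np.column_stack([xs, ys]).astype(float)

    free_angles: dict[int, float] = {}
    for label in labels:
        try:
            free_angles[label] = fit_free_axis(pixel_sets[label])
        except ValueError as exc:
            result.failures[label] = str(exc)
    fitted = [free_angles[lab] for lab in labels if lab in free_angles]
    if not fitted:
        warnings.warn("no trunk could be fitted: empty prompt set", stacklevel=2)
        return result
    alpha = mean_axis_angle(fitted)

    cents = _centroids(inst)
    spans = horizontal_neighbors(
        [c[0] for c in cents], inst.shape[1], config.edge_policy, labels=labels
    )
    span_by_label = {s.label: s for s in spans}

    if config.mode == "unsupervised":
        if foreground is None:
            if image is None:
                raise ValueError("unsupervised mode needs an image or a foreground mask")
            foreground = estimate_foreground(image)
        if np.asarray(foreground).shape != inst.shape:
            raise ValueError("foreground shape does not match the trunk raster")
    else:
        h_arg = height_px if height_px is not None else config.height_px
        heights = _heights_by_label(h_arg, labels)

    for label in labels:
        if label in result.failures:
            continue
        angle = alpha if config.shared_angle else free_angles[label]
        axis = constrained_axis(
            pixel_sets[label], angle, label=label, free_angle_deg=free_angles[label]
        )
        try:
            if config.mode == "supervised":
                T = summit_supervised(axis, heights[label])
            else:
                T = summit_unsupervised(axis, foreground, config.gap_tolerance_px)
        except (ValueError, KeyError) as exc:
            result.failures[label] = str(exc)
            continue
        B = axis.bottom
        C = ((B[0] + T[0]) / 2.0, (B[1] + T[1]) / 2.0)
        span = span_by_label[label]
        R = (C[0] + 0.2 * (span.x_right - C[0]), C[1])
        L = (C[0] - 0.2 * (C[0] - span.x_left), C[1])
        result.entries[label] = {"B": B, "T": T, "C": C, "R": R, "L": L}
    return result


def write_prompts(path: str | Path, prompts: PromptSet, image_name: str = "") -> None:
    """Serialize to the versioned rowprompt JSON schema."""
    doc = {
        "schema": PROMPT_SCHEMA,
        "image": image_name,
        "trees": [
            {
                "id": label,
                "points": {name: list(entry[name]) for name in POINT_NAMES},
                "point_labels": [1, 1, 1, 1, 1],
            }
            for label, entry in sorted(prompts.entries.items())
        ],
    }
    if prompts.failures:
        doc["failures"] = {str(k): v for k, v in sorted(prompts.failures.items())}
    imio.write_json(path, doc)


def read_prompts(path: str | Path) -> PromptSet:
    doc = imio.read_json(path)
    if doc.get("schema") != PROMPT_SCHEMA:
        raise ValueError(f"unsupported prompt schema {doc.get('schema')!r}")
    ps = PromptSet()
    for tree in doc["trees"]:
        pts = tree["points"]
        missing = [name for name in POINT_NAMES if name not in pts]
        if missing:
            raise ValueError(f"tree {tree['id']}: missing point(s) {missing}")
        ps.entries[int(tree["id"])] = {
            name: (float(pts[name][0]), float(pts[name][1])) for name in POINT_NAMES
        }
    for k, v in doc.get("failures", {}).items():
        ps.failures[int(k)] = v
    return ps
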