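"""Trunk instancing: split a semantic trunk mask into labeled trunks.

The semantic mask normally comes from an external detector (any model that
marks trunk pixels); here it can also come straight from the synthetic
scene truth.  Foreground pixel coordinates are clustered with DBSCAN
(Euclidean metric), noise pixels and small clusters are dropped, and the
surviving clusters are relabeled 1..k left-to-right by centroid column so
ids are deterministic and align with the neighbor search downstream.

DBSCAN parameters are not dictated by any reference and default to values
that trunk geometry makes insensitive (trunks are compact ribbons tens to
hundreds of pixels apart): ``eps_px=5``, ``min_pts=20``, ``min_area_px=200``.
``subsample_stride > 1`` clusters a pixel subgrid and propagates labels back
to full resolution by nearest labeled pixel, since pixel-set DBSCAN can be
quadratic in the worst case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from . import imio

__all__ = ["ClusterParams", "cluster_trunk_mask", "centroids", "labels_of", "ingest_detection"]


@dataclass(frozen=True)
class ClusterParams:
    eps_px: float = 5.0
    min_pts: int = 20
    min_area_px: int = 200
    subsample_stride: int = 1

    def __post_init__(self) -> None:
        if self.eps_px <= 0:
            raise ValueError("eps_px must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if self.subsample_stride < 1:
            raise ValueError("subsample_stride must be >= 1")


def labels_of(instances: np.ndarray) -> list[int]:
    """Sorted nonzero labels present in an instance mask."""
    vals = np.unique(instances)
    return [int(v) for v in vals if v != 0]


def cluster_trunk_mask(mask: np.ndarray, params: ClusterParams | None = None) -> np.ndarray:
    """Label trunk instances in a binary mask; returns an HxW int32 grid.

    Empty input (or input whose every cluster is dropped) yields an all-zero
    grid with k = 0.
    """
    params = params or ClusterParams()
    mask = np.asarray(mask) != 0
    out = np.zeros(mask.shape, dtype=np.int32)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return out

    s = params.subsample_stride
    if s > 1:
        keep = (ys % s == 0) & (xs % s == 0)
        if not keep.any():
            keep = np.zeros_like(ys, dtype=bool)
            keep[0] = True
        sub_ys, sub_xs = ys[keep], xs[keep]
    else:
        sub_ys, sub_xs = ys, xs

    pts = np.column_stack([sub_xs, sub_ys]).astype(float)
    raw = DBSCAN(eps=params.eps_px, min_samples=params.min_pts).fit_predict(pts)

    if s > 1:
        core = raw >= 0
        if not core.any():
            return out
        tree = cKDTree(pts[core])
        _, nearest = tree.query(np.column_stack([xs, ys]).astype(float))
        full = raw[core][nearest]
    else:
        full = raw

    # drop noise and small clusters, then relabel left-to-right by centroid x
    surviving = []
    for cid in np.unique(full[full >= 0]):
        member = full == cid
        if member.sum() < params.min_area_px:
            continue
        surviving.append((float(xs[member].mean()), member))
    surviving.sort(key=lambda item: item[0])
    for new_label, (_, member) in enumerate(surviving, start=1):
        out[ys[member], xs[member]] = new_label
    return out


def centroids(instances: np.ndarray) -> list[tuple[float, float]]:
    """Per-label arithmetic-mean pixel coordinate ``(x, y)``, in label order."""
    result = []
    for label in labels_of(instances):
        ys, xs = np.nonzero(instances == label)
        result.append((float(xs.mean()), float(ys.mean())))
    return result


def ingest_detection(path: str | Path, like: np.ndarray | None = None) -> np.ndarray:
    """Read an externally produced label raster (the detector adapter seam).

    Values are preserved: a {0, 1} raster is a semantic (binary) mask, any
    other multi-valued raster is already an instance mask.  ``like`` checks
    the shape against a paired image.
    """
    grid = imio.read_mask(path)
    if like is not None and grid.shape != np.asarray(like).shape[:2]:
        raise ValueError(
            f"raster shape {grid.shape} does not match paired image "
            f"shape {np.asarray(like).shape[:2]}"
        )
    return grid
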