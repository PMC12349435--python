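"""Synthetic orchard-row scenes with pixel-perfect ground truth.

The generator emulates the geometry of row plantations used in variety
testing: 1-10 near-vertical trunks per image, regular spacing with jitter,
per-tree tilt within about +/-10 degrees from vertical, and foliage
canopies that may overlap between neighbors.  Canopies are unions of
axis-aligned ellipses jittered along the trunk axis -- deliberately
non-photorealistic, since the hard part of the segmentation problem is
neighbor overlap, not texture.  Vegetation is rendered green-dominant so
that an excess-green foreground estimate works by construction, which lets
the unsupervised summit search be exercised entirely offline.

Ground truth consists of a semantic trunk mask, trunk instances, tree
instances (a tree includes its trunk), and per-tree geometry records
(tilt, bottom point, summit, height in pixels).  Where two canopies
overlap, the pixel belongs to the tree whose trunk axis is horizontally
nearer; ties go to the lower label.  Output is bit-reproducible for a
fixed (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import imio

__all__ = [
    "SceneConfig",
    "TreeRecord",
    "SceneTruth",
    "generate_scene",
    "generate_batch",
    "save_scene",
    "load_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic orchard-row scene.

    Ranges given as ``(lo, hi)`` are sampled uniformly per tree; a single
    number fixes the value for every tree.  All lengths are pixels.
    """

    width: int = 360
    height: int = 260
    n_trees: int = 3
    trunk_spacing_px: float = 90.0
    spacing_jitter_px: float = 6.0
    trunk_tilt_deg: float | tuple[float, float] = (-10.0, 10.0)
    #: per-tree deviation from the scene's row tilt (trellis rows lean together)
    tilt_jitter_deg: float = 2.0
    trunk_width_px: int = 6
    tree_height_px: float | tuple[float, float] = (150.0, 215.0)
    #: canopy half-width; ``None`` derives it from spacing and overlap_fraction
    canopy_halfwidth_px: float | None = None
    #: left/right half-width imbalance, sampled in [-a, a]
    canopy_asymmetry: float = 0.25
    #: horizontal canopy overlap between neighbors, in [0, 1)
    overlap_fraction: float = 0.0
    vegetation_color: tuple[int, int, int] = (58, 138, 52)
    trunk_color: tuple[int, int, int] = (102, 72, 44)
    background_sky: tuple[int, int, int] = (152, 152, 166)
    background_ground: tuple[int, int, int] = (118, 106, 92)
    noise_sigma: float = 8.0
    n_clutter: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_trees > 0 and self.trunk_width_px >= self.trunk_spacing_px:
            raise ValueError("trunk width must be smaller than trunk spacing")
        if self.n_trees > 0:
            span = (self.n_trees - 1) * self.trunk_spacing_px + 4 * self.trunk_width_px
            if span > self.width:
                raise ValueError(
                    f"{self.n_trees} trunks at spacing {self.trunk_spacing_px} "
                    f"do not fit in width {self.width}"
                )

    @property
    def halfwidth(self) -> float:
        """Effective canopy half-width (derived from overlap when unset)."""
        if self.canopy_halfwidth_px is not None:
            return float(self.canopy_halfwidth_px)
        return self.trunk_spacing_px * (0.38 + 0.5 * self.overlap_fraction)


@dataclass(frozen=True)
class TreeRecord:
    """Ground-truth geometry of one tree."""

    label: int
    tilt_deg: float
    bottom: tuple[float, float]  # trunk bottom point B = (x, y)
    summit: tuple[float, float]  # true summit point (x, y)
    height_px: float             # Euclidean distance from bottom to summit


@dataclass
class SceneTruth:
    """Pixel-perfect annotations for a generated scene."""

    trunk_semantic: np.ndarray   # HxW uint8 in {0, 1}
    trunk_instances: np.ndarray  # HxW int32, 0 background, 1..k
    tree_instances: np.ndarray   # HxW int32, includes trunks
    per_tree: list[TreeRecord] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.per_tree)

    def vegetation_mask(self) -> np.ndarray:
        """Foliage-only foreground: tree pixels that are not trunk."""
        return ((self.tree_instances > 0) & (self.trunk_semantic == 0)).astype(np.uint8)


def _sample(rng: np.random.Generator, value, n: int) -> np.ndarray:
    if isinstance(value, (tuple, list)):
        lo, hi = value
        return rng.uniform(lo, hi, size=n)
    return np.full(n, float(value))


def _axis_x(x_b: float, y_b: float, tilt_deg: float, y) -> np.ndarray:
    # trunk axis parameterized as x = x_b + tan(tilt) * (y - y_b);
    # tilt is measured from the image vertical
    return x_b + math.tan(math.radians(tilt_deg)) * (np.asarray(y, dtype=float) - y_b)


def _render_tree_masks(cfg: SceneConfig, rng: np.random.Generator):
    """Sample per-tree geometry and rasterize trunk + canopy masks."""
    n = cfg.n_trees
    base = (cfg.width - (n - 1) * cfg.trunk_spacing_px) / 2.0
    xs = base + np.arange(n) * cfg.trunk_spacing_px
    xs = xs + rng.uniform(-cfg.spacing_jitter_px, cfg.spacing_jitter_px, size=n)
    xs = np.sort(np.clip(xs, 2 * cfg.trunk_width_px, cfg.width - 1 - 2 * cfg.trunk_width_px))

    # tilt model: one row-level tilt per scene (camera roll + trellis lean),
    # small per-tree jitter around it; a scalar config fixes every tree exactly
    if isinstance(cfg.trunk_tilt_deg, (tuple, list)):
        lo, hi = cfg.trunk_tilt_deg
        row_tilt = rng.uniform(lo, hi)
        tilts = np.clip(
            row_tilt + rng.uniform(-cfg.tilt_jitter_deg, cfg.tilt_jitter_deg, size=n), lo, hi
        )
    else:
        tilts = np.full(n, float(cfg.trunk_tilt_deg))
    heights = _sample(rng, cfg.tree_height_px, n)
    heights = np.minimum(heights, 0.92 * cfg.height)
    y_bottom = cfg.height - 1 - rng.integers(0, 4, size=n).astype(float)
    asym = rng.uniform(-cfg.canopy_asymmetry, cfg.canopy_asymmetry, size=n)

    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width]
    trunk_masks, canopy_masks, records = [], [], []
    for i in range(n):
        x_b, y_b, tilt, h = xs[i], y_bottom[i], tilts[i], heights[i]
        summit = (
            x_b - h * math.sin(math.radians(tilt)),
            y_b - h * math.cos(math.radians(tilt)),
        )

        # trunk ribbon: lower ~45% of the tree height, constant pixel width
        trunk_top = y_b - 0.45 * h
        axis = _axis_x(x_b, y_b, tilt, yy)
        trunk = (
            (yy >= trunk_top)
            & (yy <= y_b)
            & (np.abs(xx - axis) <= cfg.trunk_width_px / 2.0)
        )

        # canopy: ellipses strung along the axis from ~38% height up to the
        # summit; ellipse centers stop one vertical radius short of the summit
        # so the foliage tops out AT the summit rather than above it
        hw_l = cfg.halfwidth * (1.0 + asym[i])
        hw_r = cfg.halfwidth * (1.0 - asym[i])
        y_base = y_b - 0.38 * h
        y_top = summit[1]
        ry = max(0.16 * (y_base - y_top), 4.0)
        canopy = np.zeros((cfg.height, cfg.width), dtype=bool)
        n_blobs = 9
        for t in np.linspace(0.0, 1.0, n_blobs):
            cy = y_base + t * (y_top + ry - y_base)
            cx = _axis_x(x_b, y_b, tilt, cy)
            taper = 1.0 - 0.62 * t  # narrower toward the summit
            rx_l = max(hw_l * taper, 3.0) * rng.uniform(0.9, 1.1)
            rx_r = max(hw_r * taper, 3.0) * rng.uniform(0.9, 1.1)
            dx = xx - cx
            rx = np.where(dx < 0, rx_l, rx_r)
            canopy |= (dx / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        # small cap disc guarantees the true summit lies inside the tree
        canopy |= (xx - summit[0]) ** 2 + (yy - summit[1]) ** 2 <= 4.0**2

        trunk_masks.append(trunk)
        canopy_masks.append(canopy)
        records.append(
            TreeRecord(
                label=i + 1,
                tilt_deg=float(tilt),
                bottom=(float(x_b), float(y_b)),
                summit=(float(summit[0]), float(summit[1])),
                height_px=float(h),
            )
        )
    return trunk_masks, canopy_masks, records


def generate_scene(config: SceneConfig) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene and its ground truth.

    Returns ``(image, truth)`` where ``image`` is HxWx3 uint8.  Identical
    ``config`` (including its ``seed``) gives bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.height, cfg.width

    if cfg.n_trees == 0:
        image = _render_background(cfg, rng)
        zeros = np.zeros((H, W), dtype=np.int32)
        return image, SceneTruth(zeros.astype(np.uint8), zeros, zeros.copy(), [])

    trunk_masks, canopy_masks, records = _render_tree_masks(cfg, rng)

    # ownership of overlapping canopy pixels: horizontally nearest trunk axis,
    # ties to the lower label (strict < keeps the earlier tree)
    yy, xx = np.mgrid[0:H, 0:W]
    tree_instances = np.zeros((H, W), dtype=np.int32)
    best = np.full((H, W), np.inf)
    for i, rec in enumerate(records):
        full = trunk_masks[i] | canopy_masks[i]
        d = np.abs(xx - _axis_x(rec.bottom[0], rec.bottom[1], rec.tilt_deg, yy))
        take = full & (d < best)
        tree_instances[take] = rec.label
        best[take] = d[take]

    trunk_instances = np.zeros((H, W), dtype=np.int32)
    for i, rec in enumerate(records):
        trunk_instances[trunk_masks[i]] = rec.label
    # trunk ownership is authoritative: a tree always contains its own trunk
    own = trunk_instances > 0
    tree_instances[own] = trunk_instances[own]
    trunk_semantic = (trunk_instances > 0).astype(np.uint8)

    image = _render_background(cfg, rng)
    for i in range(cfg.n_trees):
        _paint(image, trunk_masks[i], cfg.trunk_color, cfg.noise_sigma, rng)
    for i in range(cfg.n_trees):
        shade = rng.uniform(-12.0, 12.0)  # per-tree tint so neighbors differ slightly
        color = tuple(np.clip(np.asarray(cfg.vegetation_color, float) + shade, 0, 255))
        _paint(image, canopy_masks[i], color, cfg.noise_sigma, rng)

    truth = SceneTruth(trunk_semantic, trunk_instances, tree_instances, records)
    return image, truth


def _render_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    H, W = cfg.height, cfg.width
    t = (np.arange(H, dtype=float) / max(H - 1, 1))[:, None, None]
    sky = np.asarray(cfg.background_sky, dtype=float)
    ground = np.asarray(cfg.background_ground, dtype=float)
    img = sky * (1 - t) + ground * t
    img = np.broadcast_to(img, (H, W, 3)).copy()
    # non-vegetation clutter: desaturated blobs (green never dominant)
    yy, xx = np.mgrid[0:H, 0:W]
    for _ in range(cfg.n_clutter):
        cx, cy = rng.uniform(0, W), rng.uniform(0, H)
        rx, ry = rng.uniform(6, 0.12 * W), rng.uniform(4, 0.1 * H)
        blob = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        gray = rng.uniform(70, 190)
        shift = rng.uniform(-15, 15, size=3)
        shift[1] = min(shift[1], 0.0)  # keep the green channel non-dominant
        img[blob] = np.clip(gray + shift, 0, 255)
    img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _paint(image, mask, color, sigma, rng: np.random.Generator) -> None:
    n = int(mask.sum())
    if n == 0:
        return
    vals = np.asarray(color, dtype=float) + rng.normal(0.0, sigma, size=(n, 3))
    image[mask] = np.clip(vals, 0, 255).astype(np.uint8)


def generate_batch(
    n_scenes: int,
    seed: int = 0,
    base_config: SceneConfig | None = None,
    ranges: dict | None = None,
) -> list[tuple[SceneConfig, np.ndarray, SceneTruth]]:
    """Generate ``n_scenes`` scenes with per-scene seeds derived from ``seed``.

    ``ranges`` maps SceneConfig field names to ``(lo, hi)`` intervals sampled
    uniformly per scene (integer fields are sampled on integers).  Each scene's
    effective config is returned alongside the scene, so a batch is fully
    reproducible from ``(seed, base_config, ranges)``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    base = base_config or SceneConfig()
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_scenes)
    out = []
    for i in range(n_scenes):
        overrides = {"seed": int(seeds[i])}
        if ranges:
            for key, (lo, hi) in ranges.items():
                cur = getattr(base, key)
                if isinstance(cur, int) and not isinstance(cur, bool):
                    overrides[key] = int(master.integers(int(lo), int(hi) + 1))
                else:
                    overrides[key] = float(master.uniform(lo, hi))
        cfg = replace(base, **overrides)
        image, truth = generate_scene(cfg)
        out.append((cfg, image, truth))
    return out


def save_scene(
    out_dir: str | Path, stem: str, config: SceneConfig, image: np.ndarray, truth: SceneTruth
) -> dict[str, Path]:
    """Write image, masks (16-bit PNG) and a JSON truth sidecar; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{stem}.png",
        "trunk_semantic": out / f"{stem}_trunk_semantic.png",
        "trunk_instances": out / f"{stem}_trunk_instances.png",
        "tree_instances": out / f"{stem}_tree_instances.png",
        "truth": out / f"{stem}_truth.json",
    }
    imio.write_image(paths["image"], image)
    imio.write_mask(paths["trunk_semantic"], truth.trunk_semantic)
    imio.write_mask(paths["trunk_instances"], truth.trunk_instances)
    imio.write_mask(paths["tree_instances"], truth.tree_instances)
    sidecar = {
        "config": asdict(config),
        "per_tree": [asdict(r) for r in truth.per_tree],
    }
    imio.write_json(paths["truth"], sidecar)
    return paths


def load_scene(out_dir: str | Path, stem: str) -> tuple[SceneConfig, np.ndarray, SceneTruth]:
    """Round-trip counterpart of :func:`save_scene`."""
    out = Path(out_dir)
    image = imio.read_image(out / f"{stem}.png")
    sidecar = imio.read_json(out / f"{stem}_truth.json")
    raw_cfg = sidecar["config"]
    for key in ("trunk_tilt_deg", "tree_height_px", "vegetation_color", "trunk_color",
                "background_sky", "background_ground"):
        if isinstance(raw_cfg.get(key), list):
            raw_cfg[key] = tuple(raw_cfg[key])
    cfg = SceneConfig(**raw_cfg)
    truth = SceneTruth(
        trunk_semantic=imio.read_mask(out / f"{stem}_trunk_semantic.png").astype(np.uint8),
        trunk_instances=imio.read_mask(out / f"{stem}_trunk_instances.png"),
        tree_instances=imio.read_mask(out / f"{stem}_tree_instances.png"),
        per_tree=[
            TreeRecord(
                label=r["label"],
                tilt_deg=r["tilt_deg"],
                bottom=tuple(r["bottom"]),
                summit=tuple(r["summit"]),
                height_px=r["height_px"],
            )
            for r in sidecar["per_tree"]
        ],
    )
    return cfg, image, truth
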