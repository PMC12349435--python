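"""End-to-end orchestration: trunk instancing -> prompts -> segmentation -> evaluation.

Operates on a directory of scenes as written by ``treerow synth`` (or any
directory following the same naming: ``<stem>.png`` image plus
``<stem>_trunk_semantic.png`` / ``<stem>_tree_instances.png`` /
``<stem>_truth.json`` sidecars).  Every parameter and seed lands in a JSON
manifest so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import imio
from .metrics import EvalReport, evaluate_run
from .prompts import (
    PromptConfig,
    PromptSet,
    build_prompts,
    read_prompts,
    write_prompts,
    POINT_NAMES,
)
from .segment import OracleBackend, RegionGrowBackend, assemble_instances, segment_scene
from .trunks import ClusterParams, cluster_trunk_mask, labels_of

log = logging.getLogger("treerow")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on (dumped to the manifest)."""

    input_dir: str
    output_dir: str
    cluster: ClusterParams = field(default_factory=ClusterParams)
    prompt: PromptConfig = field(default_factory=lambda: PromptConfig(mode="unsupervised"))
    backend: str = "regiongrow"          # regiongrow | oracle
    color_tol: float = 40.0
    corridor_confine: bool = True
    largest_component: bool = False
    dice_threshold: float = 0.1
    use_truth_trunks: bool = False       # skip clustering, take truth trunk instances
    height_from_truth: bool = False      # supervised h per tree from the truth sidecar
    seed: int = 0

    def to_manifest(self) -> dict:
        doc = asdict(self)
        doc["cluster"] = asdict(self.cluster)
        doc["prompt"] = asdict(self.prompt)
        return doc


def _scene_stems(input_dir: Path) -> list[str]:
    stems = []
    for p in sorted(input_dir.glob("*.png")):
        if p.stem.endswith(("_trunk_semantic", "_trunk_instances", "_tree_instances")):
            continue
        stems.append(p.stem)
    return stems


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Run the enabled stages over every scene in ``input_dir``.

    Per scene, writes ``<stem>_pred_trunks.png``, ``<stem>_prompts.json``
    and ``<stem>_pred_trees.png`` into ``output_dir``; afterwards writes
    ``report_per_image.csv``, ``report_per_tree.csv`` and ``manifest.json``.
    Scenes that fail are logged and skipped; if every scene fails a
    RuntimeError is raised.
    """
    in_dir, out_dir = Path(config.input_dir), Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stems = _scene_stems(in_dir)
    if not stems:
        raise RuntimeError(f"no scene images found in {in_dir}")

    preds: dict[str, np.ndarray] = {}
    truths: dict[str, np.ndarray] = {}
    n_failed = 0
    for stem in stems:
        t0 = time.perf_counter()
        try:
            preds[stem] = _run_scene(config, in_dir, out_dir, stem, truths)
        except Exception as exc:  # noqa: BLE001 - per-image isolation
            n_failed += 1
            log.error("scene %s failed: %s", stem, exc)
            continue
        log.info("scene %s done in %.2fs", stem, time.perf_counter() - t0)
    if n_failed == len(stems):
        raise RuntimeError("all scenes failed")

    report = evaluate_run(preds, {k: truths[k] for k in preds if k in truths},
                          config.dice_threshold)
    report.per_image.to_csv(out_dir / "report_per_image.csv", index=False)
    report.per_tree.to_csv(out_dir / "report_per_tree.csv", index=False)
    imio.write_json(out_dir / "manifest.json", config.to_manifest())
    imio.write_json(out_dir / "summary.json", report.summary())
    return report


def _run_scene(config, in_dir: Path, out_dir: Path, stem: str,
               truths: dict[str, np.ndarray]) -> np.ndarray:
    image = imio.read_image(in_dir / f"{stem}.png")
    truth_trees = None
    sidecar = None
    truth_json = in_dir / f"{stem}_truth.json"
    tree_png = in_dir / f"{stem}_tree_instances.png"
    if tree_png.is_file():
        truth_trees = imio.read_mask(tree_png)
        truths[stem] = truth_trees
    if truth_json.is_file():
        sidecar = imio.read_json(truth_json)

    # stage 1: trunk instances
    if config.use_truth_trunks:
        trunk_inst = imio.read_mask(in_dir / f"{stem}_trunk_instances.png")
    else:
        semantic = imio.read_mask(in_dir / f"{stem}_trunk_semantic.png")
        trunk_inst = cluster_trunk_mask(semantic != 0, config.cluster)
    imio.write_mask(out_dir / f"{stem}_pred_trunks.png", trunk_inst)

    # stage 2: prompts
    heights = None
    if config.prompt.mode == "supervised" and config.height_from_truth:
        if sidecar is None:
            raise RuntimeError(f"{stem}: height_from_truth set but no truth sidecar")
        by_bottom_x = sorted(sidecar["per_tree"], key=lambda r: r["bottom"][0])
        labels = labels_of(trunk_inst)
        if len(by_bottom_x) != len(labels):
            raise RuntimeError(f"{stem}: trunk count != truth tree count")
        heights = {lab: rec["height_px"] for lab, rec in zip(labels, by_bottom_x)}
    prompts = build_prompts(trunk_inst, config.prompt, image=image, height_px=heights)
    write_prompts(out_dir / f"{stem}_prompts.json", prompts, image_name=f"{stem}.png")
    if not prompts.entries:
        raise RuntimeError(f"{stem}: no prompts produced")

    # stage 3: segmentation
    if config.backend == "oracle":
        if truth_trees is None:
            raise RuntimeError(f"{stem}: oracle backend needs tree-instance truth")
        backend = OracleBackend(truth_trees)
    elif config.backend == "regiongrow":
        if config.corridor_confine:
            from .prompts import horizontal_neighbors
            from .trunks import centroids
            cents = centroids(trunk_inst)
            spans = {s.label: s for s in horizontal_neighbors(
                [c[0] for c in cents], image.shape[1], config.prompt.edge_policy,
                labels=labels_of(trunk_inst))}

            def backend(label, _spans=spans):
                s = _spans[label]
                return RegionGrowBackend(color_tol=config.color_tol,
                                         corridor=(s.x_left, s.x_right))
        else:
            backend = RegionGrowBackend(color_tol=config.color_tol)
    else:
        raise RuntimeError(f"unknown backend {config.backend!r}")

    masks = segment_scene(image, prompts, backend,
                          largest_component=config.largest_component)
    pred = assemble_instances(masks, prompts)
    imio.write_mask(out_dir / f"{stem}_pred_trees.png", pred)
    return pred


def validate_inputs(input_dir: str | Path) -> list[dict]:
    """Sanity-check a scene directory; returns machine-readable findings."""
    in_dir = Path(input_dir)
    findings: list[dict] = []
    if not in_dir.is_dir():
        return [{"kind": "missing_dir", "path": str(in_dir)}]
    stems = _scene_stems(in_dir)
    if not stems:
        findings.append({"kind": "no_scenes", "path": str(in_dir)})
    for stem in stems:
        try:
            image = imio.read_image(in_dir / f"{stem}.png")
        except Exception as exc:  # noqa: BLE001
            findings.append({"kind": "unreadable_image", "path": f"{stem}.png", "detail": str(exc)})
            continue
        for suffix in ("_trunk_semantic", "_trunk_instances", "_tree_instances"):
            p = in_dir / f"{stem}{suffix}.png"
            if not p.is_file():
                continue
            try:
                mask = imio.read_mask(p)
            except Exception as exc:  # noqa: BLE001
                findings.append({"kind": "unreadable_mask", "path": p.name, "detail": str(exc)})
                continue
            if mask.shape != image.shape[:2]:
                findings.append({
                    "kind": "shape_mismatch", "path": p.name,
                    "detail": f"mask {mask.shape} vs image {image.shape[:2]} ({stem}.png)",
                })
            if mask.min() < 0:
                findings.append({"kind": "negative_labels", "path": p.name})
        pj = in_dir / f"{stem}_prompts.json"
        if pj.is_file():
            findings.extend(_validate_prompt_json(pj))
    return findings


def _validate_prompt_json(path: Path) -> list[dict]:
    findings = []
    try:
        doc = imio.read_json(path)
    except Exception as exc:  # noqa: BLE001
        return [{"kind": "unreadable_json", "path": path.name, "detail": str(exc)}]
    if doc.get("schema") != "rowprompt-v1":
        findings.append({"kind": "schema_version", "path": path.name,
                         "detail": str(doc.get("schema"))})
    for tree in doc.get("trees", []):
        pts = tree.get("points", {})
        missing = [n for n in POINT_NAMES if n not in pts]
        if missing:
            findings.append({"kind": "schema_violation", "path": path.name,
                             "detail": f"tree {tree.get('id')}: missing {missing}"})
    return findings
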