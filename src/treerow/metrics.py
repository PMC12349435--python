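"""Segmentation evaluation: Dice, signed mean error, precision/recall,
Dice-matched Average Precision, and the paired Student t comparison.

Definitions (A = truth pixel set, B = predicted pixel set):

* Dice-Sorensen coefficient  DSC = 2|A n B| / (|A| + |B|), in [0, 1];
  both-empty is defined here as 1.0 (the masks agree there is nothing)
  and flagged so aggregates can exclude it.
* mean error  ME = (1/N) * sum(b_i - a_i) over all N pixels: positive
  means over-segmentation, negative under-segmentation.
* instance matching: predicted and true objects pair up greedily by
  descending pairwise Dice, each object used at most once, keeping pairs
  with Dice strictly above the threshold (default 0.1 — detection of the
  object matters more than a tight mask).  Matched = TP; leftover
  predictions = FP; leftover truths = FN.
* AP: ranked detections swept by descending score; area under the
  precision-recall curve with the all-point interpolation (precision
  envelope monotonized from the right).  Score ties keep input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trunks import labels_of

__all__ = [
    "dice",
    "mean_error",
    "pixel_precision_recall",
    "MatchResult",
    "match_instances",
    "average_precision",
    "paired_t_test",
    "EvalReport",
    "evaluate_run",
]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice-Sorensen coefficient of two binary masks; both empty -> 1.0."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    _check_shapes(a, b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def mean_error(truth: np.ndarray, pred: np.ndarray) -> float:
    """Signed mean of (pred - truth) over all pixels; + = over-segmentation."""
    t = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    _check_shapes(t, p)
    return float((p.astype(np.int8) - t.astype(np.int8)).mean())


def pixel_precision_recall(truth: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """Pixel-level precision and recall of a binary prediction.

    Empty denominators (no predicted / no true foreground) are defined as
    1.0 — nothing was claimed, so nothing was wrong.
    """
    t = np.asarray(truth).astype(bool)
    p = np.asarray(pred).astype(bool)
    _check_shapes(t, p)
    tp = int((t & p).sum())
    n_pred, n_truth = int(p.sum()), int(t.sum())
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return precision, recall


def _pairwise_dice(preds: np.ndarray, truths: np.ndarray):
    """Dice between every (pred label, truth label) pair via a joint histogram."""
    p_labels = labels_of(preds)
    t_labels = labels_of(truths)
    if not p_labels or not t_labels:
        return p_labels, t_labels, np.zeros((len(p_labels), len(t_labels)))
    p_idx = {lab: i for i, lab in enumerate(p_labels)}
    t_idx = {lab: i for i, lab in enumerate(t_labels)}
    p_flat = np.asarray(preds).ravel()
    t_flat = np.asarray(truths).ravel()
    both = (p_flat > 0) & (t_flat > 0)
    joint = np.zeros((len(p_labels), len(t_labels)), dtype=np.int64)
    if both.any():
        pi = np.vectorize(p_idx.get)(p_flat[both])
        ti = np.vectorize(t_idx.get)(t_flat[both])
        np.add.at(joint, (pi, ti), 1)
    p_sizes = np.array([(p_flat == lab).sum() for lab in p_labels])
    t_sizes = np.array([(t_flat == lab).sum() for lab in t_labels])
    d = 2.0 * joint / (p_sizes[:, None] + t_sizes[None, :])
    return p_labels, t_labels, d


@dataclass
class MatchResult:
    """Bookkeeping of instance matching at a Dice threshold."""

    pairs: list[tuple[int, int, float]]  # (pred label, truth label, dice)
    tp: int
    fp: int
    fn: int
    threshold: float
    unmatched_preds: list[int] = field(default_factory=list)
    unmatched_truths: list[int] = field(default_factory=list)


def match_instances(
    preds: np.ndarray, truths: np.ndarray, dice_threshold: float = 0.1
) -> MatchResult:
    """Greedy one-to-one matching of predicted to true instances.

    Candidate pairs with pairwise Dice strictly above the threshold are
    taken in descending-Dice order (ties broken by pred then truth label),
    each label used at most once.
    """
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    _check_shapes(preds, truths)
    p_labels, t_labels, d = _pairwise_dice(preds, truths)
    candidates = [
        (d[i, j], p, t)
        for i, p in enumerate(p_labels)
        for j, t in enumerate(t_labels)
        if d[i, j] > dice_threshold
    ]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for score, p, t in candidates:
        if p in used_p or t in used_t:
            continue
        pairs.append((p, t, float(score)))
        used_p.add(p)
        used_t.add(t)
    return MatchResult(
        pairs=pairs,
        tp=len(pairs),
        fp=len(p_labels) - len(pairs),
        fn=len(t_labels) - len(pairs),
        threshold=dice_threshold,
        unmatched_preds=[p for p in p_labels if p not in used_p],
        unmatched_truths=[t for t in t_labels if t not in used_t],
    )


def average_precision(
    scored_preds: list[tuple[np.ndarray, float]],
    truths: np.ndarray,
    dice_threshold: float = 0.1,
) -> float:
    """AP over ranked detections with Dice-threshold matching.

    Each detection is a ``(binary mask, score)`` pair; detectors without
    confidences should pass score 1.0 for all (a degenerate single-point
    PR curve).  Detections are swept by descending score (ties keep input
    order); a detection is a TP if its best Dice against a still-unmatched
    truth exceeds the threshold.  AP is the area under the monotonized
    precision-recall staircase.  Empty truths with predictions -> 0.0;
    both empty -> NaN (flagged undefined).
    """
    truths = np.asarray(truths)
    t_labels = labels_of(truths)
    if not scored_preds:
        return 0.0 if t_labels else float("nan")
    if not t_labels:
        return 0.0
    order = sorted(range(len(scored_preds)), key=lambda i: (-scored_preds[i][1], i))
    truth_masks = {t: truths == t for t in t_labels}
    unmatched = set(t_labels)
    tp_flags = []
    for i in order:
        mask = np.asarray(scored_preds[i][0]).astype(bool)
        _check_shapes(mask, truths)
        best_t, best_d = None, dice_threshold
        for t in sorted(unmatched):
            d = dice(mask, truth_masks[t])
            if d > best_d:
                best_t, best_d = t, d
        if best_t is not None:
            unmatched.discard(best_t)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    tp_cum = np.cumsum(tp_flags)
    ranks = np.arange(1, len(tp_flags) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / len(t_labels)
    # all-point interpolation: envelope precision monotonized from the right
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired Student t-test of per-image scores of two methods.

    Returns ``(t, two-sided p)`` with t = mean(d) / (sd(d)/sqrt(n)),
    d = x - y, sample sd (n-1).  Degenerate cases: identical samples ->
    (0, 1); constant nonzero difference -> (signed inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = x - y
    sd = d.std(ddof=1)
    md = d.mean()
    if sd == 0.0:
        if md == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, md), 0.0
    t = md / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class EvalReport:
    """Aggregated metrics for a set of prediction/truth image pairs.

    Per-image Dice is the mean over matched trees with unmatched truths
    contributing 0; that convention is recorded here because reference
    protocols rarely state it.
    """

    per_tree: pd.DataFrame    # image_id, tree_id (truth), pred_id, dice, precision, recall
    per_image: pd.DataFrame   # image_id, dice, me, ap, tp, fp, fn
    dice_mean: float
    dice_sd: float
    me_mean: float
    ap_mean: float
    instance_precision: float
    instance_recall: float
    n_images: int
    n_trees: int
    dice_threshold: float
    unpaired: list[str] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        return {
            "dice_mean": self.dice_mean,
            "dice_sd": self.dice_sd,
            "me_mean": self.me_mean,
            "ap_mean": self.ap_mean,
            "instance_precision": self.instance_precision,
            "instance_recall": self.instance_recall,
            "n_images": self.n_images,
            "n_trees": self.n_trees,
        }


def evaluate_run(
    pred_by_image: dict[str, np.ndarray],
    truth_by_image: dict[str, np.ndarray],
    dice_threshold: float = 0.1,
) -> EvalReport:
    """Score a run of instance predictions against ground truth.

    Images are paired by id; ids present on only one side are reported in
    ``unpaired`` and skipped.  Per image: instances are Dice-matched, each
    matched pair contributes per-tree Dice / pixel precision / recall,
    unmatched truths contribute Dice 0, ME is computed over the union
    foreground grids, and AP uses the (unscored, score=1) detection list.
    """
    shared = sorted(set(pred_by_image) & set(truth_by_image))
    unpaired = sorted(set(pred_by_image) ^ set(truth_by_image))
    tree_rows, image_rows = [], []
    tp_total = fp_total = fn_total = 0
    for image_id in shared:
        pred = np.asarray(pred_by_image[image_id])
        truth = np.asarray(truth_by_image[image_id])
        match = match_instances(pred, truth, dice_threshold)
        tp_total += match.tp
        fp_total += match.fp
        fn_total += match.fn
        dices = []
        for p_lab, t_lab, d in match.pairs:
            pm, tm = pred == p_lab, truth == t_lab
            prec, rec = pixel_precision_recall(tm, pm)
            tree_rows.append(
                {"image_id": image_id, "tree_id": t_lab, "pred_id": p_lab,
                 "dice": d, "precision": prec, "recall": rec}
            )
            dices.append(d)
        for t_lab in match.unmatched_truths:
            tree_rows.append(
                {"image_id": image_id, "tree_id": t_lab, "pred_id": 0,
                 "dice": 0.0, "precision": float("nan"), "recall": 0.0}
            )
            dices.append(0.0)
        img_dice = float(np.mean(dices)) if dices else 1.0
        me = mean_error(truth > 0, pred > 0)
        scored = [(pred == lab, 1.0) for lab in labels_of(pred)]
        ap = average_precision(scored, truth, dice_threshold)
        image_rows.append(
            {"image_id": image_id, "dice": img_dice, "me": me, "ap": ap,
             "tp": match.tp, "fp": match.fp, "fn": match.fn}
        )

    per_tree = pd.DataFrame(
        tree_rows, columns=["image_id", "tree_id", "pred_id", "dice", "precision", "recall"]
    )
    per_image = pd.DataFrame(
        image_rows, columns=["image_id", "dice", "me", "ap", "tp", "fp", "fn"]
    )
    dice_vals = per_image["dice"].to_numpy(dtype=float)
    ap_vals = per_image["ap"].to_numpy(dtype=float)
    return EvalReport(
        per_tree=per_tree,
        per_image=per_image,
        dice_mean=float(dice_vals.mean()) if len(dice_vals) else float("nan"),
        dice_sd=float(dice_vals.std(ddof=1)) if len(dice_vals) > 1 else 0.0,
        me_mean=float(per_image["me"].mean()) if len(per_image) else float("nan"),
        ap_mean=float(np.nanmean(ap_vals)) if len(ap_vals) else float("nan"),
        instance_precision=tp_total / (tp_total + fp_total) if tp_total + fp_total else 1.0,
        instance_recall=tp_total / (tp_total + fn_total) if tp_total + fn_total else 1.0,
        n_images=len(shared),
        n_trees=int(per_tree.shape[0]),
        dice_threshold=dice_threshold,
        unpaired=unpaired,
    )
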