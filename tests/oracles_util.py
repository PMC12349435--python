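"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (explicit
loops, explicit sums, numerical integration) and shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad


# ---------------------------------------------------------------- pixel metrics

def counting_dice(a, b) -> float:
    """Per-pixel counting: Dice of two binary grids."""
    inter = both = 0
    a = np.asarray(a)
    b = np.asarray(b)
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            av, bv = int(bool(a[i, j])), int(bool(b[i, j]))
            inter += av * bv
            both += av + bv
    if both == 0:
        return 1.0
    return 2.0 * inter / both


def counting_mean_error(truth, pred) -> float:
    total = 0
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    n = truth.shape[0] * truth.shape[1]
    for i in range(truth.shape[0]):
        for j in range(truth.shape[1]):
            total += int(bool(pred[i, j])) - int(bool(truth[i, j]))
    return total / n


def counting_precision_recall(truth, pred) -> tuple[float, float]:
    tp = fp = fn = 0
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    for i in range(truth.shape[0]):
        for j in range(truth.shape[1]):
            t, p = bool(truth[i, j]), bool(pred[i, j])
            tp += t and p
            fp += p and not t
            fn += t and not p
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return precision, recall


# ------------------------------------------------------------------- clustering

def transitive_closure_clusters(mask, eps: float) -> list[set]:
    """Union of foreground points within Euclidean eps, by explicit BFS."""
    pts = [tuple(p) for p in np.argwhere(np.asarray(mask) != 0)]
    unvisited = set(pts)
    clusters = []
    while unvisited:
        seed = unvisited.pop()
        queue = [seed]
        comp = {seed}
        while queue:
            cy, cx = queue.pop()
            near = [
                p for p in unvisited
                if (p[0] - cy) ** 2 + (p[1] - cx) ** 2 <= eps * eps
            ]
            for p in near:
                unvisited.discard(p)
                comp.add(p)
                queue.append(p)
        clusters.append(comp)
    return clusters


def partition_signature(instances) -> set[frozenset]:
    """Label-permutation-invariant signature of an instance mask."""
    inst = np.asarray(instances)
    out = set()
    for label in np.unique(inst):
        if label == 0:
            continue
        out.add(frozenset(map(tuple, np.argwhere(inst == label))))
    return out


# ------------------------------------------------------------- instance matching

def pairwise_dice_table(preds, truths) -> dict[tuple[int, int], float]:
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    table = {}
    p_labels = [int(v) for v in np.unique(preds) if v != 0]
    t_labels = [int(v) for v in np.unique(truths) if v != 0]
    for p in p_labels:
        for t in t_labels:
            pm, tm = preds == p, truths == t
            denom = pm.sum() + tm.sum()
            table[(p, t)] = 2.0 * (pm & tm).sum() / denom if denom else 1.0
    return table


def exhaustive_match(preds, truths, threshold: float):
    """Best one-to-one assignment: max matched count, then max total Dice.

    Enumerates every injective mapping of a pred subset onto truths; only
    feasible for small label counts.  Returns (tp, fp, fn, total_dice).
    """
    preds = np.asarray(preds)
    truths = np.asarray(truths)
    p_labels = [int(v) for v in np.unique(preds) if v != 0]
    t_labels = [int(v) for v in np.unique(truths) if v != 0]
    table = pairwise_dice_table(preds, truths)
    best_count, best_total = 0, 0.0
    for r in range(min(len(p_labels), len(t_labels)), -1, -1):
        found = False
        for p_sub in itertools.combinations(p_labels, r):
            for t_perm in itertools.permutations(t_labels, r):
                if all(table[(p, t)] > threshold for p, t in zip(p_sub, t_perm)):
                    found = True
                    total = sum(table[(p, t)] for p, t in zip(p_sub, t_perm))
                    best_total = max(best_total, total)
        if found:
            best_count = r
            break
    return (
        best_count,
        len(p_labels) - best_count,
        len(t_labels) - best_count,
        best_total,
    )


# ------------------------------------------------------------------------- AP

def ap_from_rank_sweep(scored_masks, truths, threshold: float) -> float:
    """AP via the equivalent per-TP identity, with its own matching sweep.

    Ranks detections by descending score (stable), matches each to the
    best-Dice unmatched truth above the threshold, and evaluates
    AP = (1/T) * sum over TP ranks k of max_{j >= k} precision_j,
    the textbook identity for all-point interpolated AP.
    """
    truths = np.asarray(truths)
    t_labels = [int(v) for v in np.unique(truths) if v != 0]
    if not t_labels:
        return 0.0 if scored_masks else float("nan")
    order = sorted(range(len(scored_masks)), key=lambda i: (-scored_masks[i][1], i))
    available = set(t_labels)
    flags = []
    for i in order:
        mask = np.asarray(scored_masks[i][0]) != 0
        best, best_d = None, threshold
        for t in sorted(available):
            tm = truths == t
            denom = mask.sum() + tm.sum()
            d = 2.0 * (mask & tm).sum() / denom if denom else 1.0
            if d > best_d:
                best, best_d = t, d
        if best is not None:
            available.discard(best)
            flags.append(True)
        else:
            flags.append(False)
    precisions = []
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += f
        precisions.append(tp / k)
    total = 0.0
    for k, f in enumerate(flags):
        if f:
            total += max(precisions[k:])
    return total / len(t_labels)


# -------------------------------------------------------------------- t-test

def closed_form_t(x, y) -> float:
    """t statistic by explicit sums (no numpy statistics helpers)."""
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    return mean / math.sqrt(var / n)


def t_sf_numeric(t: float, df: int) -> float:
    """Upper-tail t probability by quadrature of the density."""
    log_c = (
        math.lgamma((df + 1) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * math.log(df * math.pi)
    )

    def pdf(u):
        return math.exp(log_c - ((df + 1) / 2.0) * math.log1p(u * u / df))

    val, _ = quad(pdf, t, math.inf, epsabs=1e-13, epsrel=1e-13)
    return val


# ------------------------------------------------------------------- geometry

def normal_equations_slope(ys, xs) -> float:
    """Slope a of x = a*y + b by the explicit normal equations."""
    n = len(ys)
    sy = sum(ys)
    sx = sum(xs)
    syy = sum(v * v for v in ys)
    syx = sum(v * w for v, w in zip(ys, xs))
    return (n * syx - sy * sx) / (n * syy - sy * sy)


# ------------------------------------------------------- random instance cases

def random_instance_case(rng: np.random.Generator, shape=(64, 64), max_objects=4):
    """A (preds, truths, scores) triple of small random instance rasters.

    Truth objects are discs at mutually separated centers (instances in a
    planted row never interpenetrate); predictions are jittered, rescaled
    copies of truth objects, with occasional misses and spurious extra
    detections.  Each prediction therefore overlaps essentially one truth
    object - the regime actual instance segmentation output occupies.
    """
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    n_true = int(rng.integers(1, max_objects + 1))
    centers = []
    attempts = 0
    while len(centers) < n_true and attempts < 200:
        attempts += 1
        cx = rng.uniform(8, W - 8)
        cy = rng.uniform(8, H - 8)
        if all((cx - ox) ** 2 + (cy - oy) ** 2 >= 24.0**2 for ox, oy, _ in centers):
            centers.append((cx, cy, rng.uniform(3, 6)))
    truths = np.zeros(shape, dtype=np.int32)
    for label, (cx, cy, r) in enumerate(centers, start=1):
        truths[(xx - cx) ** 2 + (yy - cy) ** 2 <= r * r] = label
    preds = np.zeros(shape, dtype=np.int32)
    next_label = 1
    for cx, cy, r in centers:
        if rng.random() < 0.15:  # missed object
            continue
        jx, jy = rng.uniform(-2, 2, size=2)
        rr = r * rng.uniform(0.7, 1.3)
        preds[(xx - cx - jx) ** 2 + (yy - cy - jy) ** 2 <= rr * rr] = next_label
        next_label += 1
    for _ in range(int(rng.integers(0, 3))):  # spurious detections near a truth
        cx, cy, r = centers[int(rng.integers(0, len(centers)))]
        sx = cx + rng.uniform(-6, 6)
        sy = cy + rng.uniform(-6, 6)
        sr = rng.uniform(2, 4)
        blob = (xx - sx) ** 2 + (yy - sy) ** 2 <= sr * sr
        if blob.any() and not preds[blob].any():
            preds[blob] = next_label
            next_label += 1
    n_pred = len([v for v in np.unique(preds) if v != 0])
    scores = rng.uniform(0.1, 1.0, size=n_pred)
    return preds, truths, scores
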