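"""Instance-segmentation and image-fidelity metrics.

Segmentation accuracy is reported as average precision at an IoU threshold
(AP@50, AP@75): a predicted instance counts as correct when its mask IoU with
an unmatched ground-truth instance reaches the threshold. Matching is greedy
in descending prediction score, each prediction taking the unmatched ground
truth of highest IoU. Two AP variants are provided:

* ``precision`` (default) — the percentage of correctly predicted instances,
  pooled over images: ``100 * matched / total predictions``.
* ``coco`` — the 101-point interpolated average precision over the pooled
  score-ranked prediction list, x100.

Image fidelity is measured by the foreground mean absolute error: the mean
absolute pixel difference between a generated and a reference image,
restricted to the ground-truth leaf foreground (the union of GT leaf masks —
foreground is taken from ground truth, never from predictions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchResult",
    "EvalReport",
    "mask_iou",
    "match_instances",
    "ap_at_iou",
    "evaluate_instances",
    "foreground_mae",
]


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 0 when both are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


@dataclass
class MatchResult:
    """Greedy prediction-to-ground-truth assignment at threshold tau."""

    pairs: list[tuple[int, int, float]]  # (pred idx, gt idx, IoU)
    unmatched_pred: list[int]
    unmatched_gt: list[int]
    threshold: float


def match_instances(
    preds: list[np.ndarray],
    scores: list[float] | None,
    gts: list[np.ndarray],
    tau: float,
) -> MatchResult:
    """Greedily match predictions to ground truths at IoU >= tau.

    Predictions are visited in descending score (ties broken by lower
    prediction index); each takes the unmatched ground truth of highest IoU,
    ties broken by lower gt index. Deterministic.
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    if scores is None:
        scores = [1.0] * len(preds)
    if len(scores) != len(preds):
        raise ValueError("one score per prediction required")
    order = sorted(range(len(preds)), key=lambda i: (-scores[i], i))
    taken: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    unmatched_pred: list[int] = []
    for pi in order:
        best_iou, best_gt = 0.0, -1
        for gi, gt in enumerate(gts):  # ascending gi: lower gt id wins IoU ties
            if gi in taken:
                continue
            iou = mask_iou(preds[pi], gt)
            if iou > best_iou:
                best_iou, best_gt = iou, gi
        if best_gt >= 0 and best_iou >= tau:
            taken.add(best_gt)
            pairs.append((pi, best_gt, best_iou))
        else:
            unmatched_pred.append(pi)
    unmatched_gt = [gi for gi in range(len(gts)) if gi not in taken]
    return MatchResult(pairs, unmatched_pred, unmatched_gt, tau)


def _coco_ap(matched_flags: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP over a score-ranked pooled prediction list."""
    if n_gt == 0:
        return 0.0
    tp = np.cumsum(matched_flags)
    fp = np.cumsum(~matched_flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope (monotone non-increasing from the right)
    for i in range(len(precision) - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    grid = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, grid, side="left")
    p = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(p.mean())


def ap_at_iou(
    preds: list[list[np.ndarray]] | list[np.ndarray],
    gts: list[list[np.ndarray]] | list[np.ndarray],
    tau: float,
    scores: list[list[float]] | list[float] | None = None,
    variant: str = "precision",
) -> float:
    """AP at IoU threshold *tau*, in percent [0, 100].

    ``preds``/``gts`` may be single-image mask lists or per-image lists of
    mask lists; instances are pooled across images. ``variant='precision'``
    returns the percentage of correctly predicted instances;
    ``variant='coco'`` the 101-point interpolated AP.
    """
    if variant not in ("precision", "coco"):
        raise ValueError(f"unknown AP variant {variant!r}")
    preds_pi, gts_pi, scores_pi = _normalize_per_image(preds, gts, scores)

    flags: list[tuple[float, int, bool]] = []  # (score, global idx, matched)
    n_pred = n_matched = n_gt = 0
    gidx = 0
    for img_preds, img_gts, img_scores in zip(preds_pi, gts_pi, scores_pi):
        result = match_instances(img_preds, img_scores, img_gts, tau)
        matched_set = {pi for pi, _, _ in result.pairs}
        for pi in range(len(img_preds)):
            flags.append((img_scores[pi], gidx, pi in matched_set))
            gidx += 1
        n_pred += len(img_preds)
        n_matched += len(result.pairs)
        n_gt += len(img_gts)

    if variant == "precision":
        if n_pred == 0:
            warnings.warn("AP (precision variant) undefined with zero predictions; reporting 0")
            return 0.0
        return 100.0 * n_matched / n_pred
    flags.sort(key=lambda t: (-t[0], t[1]))
    matched_flags = np.array([m for _, _, m in flags], dtype=bool)
    return 100.0 * _coco_ap(matched_flags, n_gt)


def _normalize_per_image(preds, gts, scores):
    """Accept single-image or per-image nested inputs; return nested form."""

    def is_nested(x):
        return len(x) > 0 and isinstance(x[0], (list, tuple))

    if is_nested(preds) or is_nested(gts):
        preds_pi = [list(p) for p in preds]
        gts_pi = [list(g) for g in gts]
        if len(preds_pi) != len(gts_pi):
            raise ValueError("per-image preds and gts must align")
        if scores is None:
            scores_pi = [[1.0] * len(p) for p in preds_pi]
        else:
            scores_pi = [list(s) for s in scores]
    else:
        preds_pi = [list(preds)]
        gts_pi = [list(gts)]
        scores_pi = [list(scores) if scores is not None else [1.0] * len(preds)]
    for p, s in zip(preds_pi, scores_pi):
        if len(p) != len(s):
            raise ValueError("one score per prediction required")
    return preds_pi, gts_pi, scores_pi


@dataclass
class EvalReport:
    """Pooled AP at several thresholds plus per-image match details."""

    variant: str
    ap: dict[float, float]
    recall: dict[float, float]
    per_image: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "AP": {f"AP@{int(round(t * 100))}": v for t, v in self.ap.items()},
            "recall": {f"R@{int(round(t * 100))}": v for t, v in self.recall.items()},
            "per_image": self.per_image,
        }


def evaluate_instances(
    preds_per_image: list[list[np.ndarray]],
    gts_per_image: list[list[np.ndarray]],
    thresholds: tuple[float, ...] = (0.5, 0.75),
    scores_per_image: list[list[float]] | None = None,
    variant: str = "precision",
) -> EvalReport:
    """Full evaluation report: AP and recall at each threshold, pooled across
    images, with per-image match counts."""
    ap: dict[float, float] = {}
    recall: dict[float, float] = {}
    per_image: list[dict] = []
    for tau in thresholds:
        ap[tau] = ap_at_iou(preds_per_image, gts_per_image, tau, scores_per_image, variant)
        n_gt = sum(len(g) for g in gts_per_image)
        n_matched = 0
        for i, (p, g) in enumerate(zip(preds_per_image, gts_per_image)):
            s = scores_per_image[i] if scores_per_image else None
            result = match_instances(p, s, g, tau)
            n_matched += len(result.pairs)
            if tau == thresholds[0]:
                per_image.append(
                    {
                        "image": i,
                        "n_pred": len(p),
                        "n_gt": len(g),
                        "matched": len(result.pairs),
                        "mean_iou": float(np.mean([x[2] for x in result.pairs])) if result.pairs else 0.0,
                    }
                )
        recall[tau] = 100.0 * n_matched / n_gt if n_gt else 0.0
    return EvalReport(variant=variant, ap=ap, recall=recall, per_image=per_image)


def foreground_mae(
    generated: np.ndarray, reference: np.ndarray, foreground: np.ndarray
) -> float:
    """Mean absolute pixel difference restricted to the foreground mask.

    The foreground is the union of ground-truth leaf masks; channels of a
    foreground pixel all contribute to the mean.
    """
    g = np.asarray(generated, float)
    r = np.asarray(reference, float)
    m = np.asarray(foreground, bool)
    if g.shape != r.shape:
        raise ValueError(f"image shapes differ: {g.shape} vs {r.shape}")
    if m.shape != g.shape[:2]:
        raise ValueError(f"foreground shape {m.shape} does not match image {g.shape[:2]}")
    if not m.any():
        raise ValueError("empty foreground mask")
    return float(np.mean(np.abs(g[m] - r[m])))
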