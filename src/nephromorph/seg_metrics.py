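"""Segmentation evaluation: Dice coefficients and instance-level metrics.

The instance Dice-similarity-coefficient (iDSC) quantifies the mean
predicted area coverage per instance: for each prediction instance the
Dice score with its maximally overlapping ground-truth instance is
computed, the same is done vice versa for each ground-truth instance, and
the iDSC is the mean over all these per-instance scores (both directions
pooled). It ranges from 0 (no single ground-truth overlap) to 1 (perfect
predictions). F1 and positive predictive value (PPV) count true positives
as instances whose matched Dice lies strictly above a 0.5 threshold,
with one-to-one pairing by greedy highest-Dice-first matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .postprocess import InstanceMap

__all__ = ["InstanceMatchReport", "dsc", "idsc", "instance_f1_ppv", "pool_reports"]


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice-similarity-coefficient of two binary rasters.

    Defined as 2|a n b| / (|a| + |b|); two empty masks are reported as 1.0
    (perfect agreement about absence) with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both masks empty; DSC defined as 1.0", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class InstanceMatchReport:
    """Per-instance overlap scores and threshold-based match counts."""

    class_name: str | None
    pred_scores: dict[int, float]  # best-overlap Dice per prediction instance
    gt_scores: dict[int, float]  # best-overlap Dice per ground-truth instance
    pair_dice: dict[tuple[int, int], float]  # (pred id, gt id) -> Dice
    threshold: float = 0.5
    tp: int = 0
    fp: int = 0
    fn: int = 0
    f1: float = field(default=float("nan"))
    ppv: float = field(default=float("nan"))

    @property
    def n_pred(self) -> int:
        return len(self.pred_scores)

    @property
    def n_gt(self) -> int:
        return len(self.gt_scores)

    @property
    def idsc(self) -> float:
        """Pooled mean of all per-instance best-overlap Dice scores."""
        scores = list(self.pred_scores.values()) + list(self.gt_scores.values())
        if not scores:
            return float("nan")
        return float(np.mean(scores))


def _pairwise_dice(
    pred: InstanceMap, gt: InstanceMap, class_name: str | None
) -> tuple[dict[int, int], dict[int, int], dict[tuple[int, int], float]]:
    """Pixel counts per instance and Dice for every overlapping pair."""
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("prediction and ground truth must share raster shape")
    if class_name is None:
        p_ids = list(pred.records)
        g_ids = list(gt.records)
    else:
        p_ids = pred.ids_of_class(class_name)
        g_ids = gt.ids_of_class(class_name)
    p_sizes = {i: pred.records[i].n_pixels for i in p_ids}
    g_sizes = {i: gt.records[i].n_pixels for i in g_ids}

    p_mask = np.isin(pred.labels, p_ids) if p_ids else np.zeros_like(pred.labels, bool)
    g_mask = np.isin(gt.labels, g_ids) if g_ids else np.zeros_like(gt.labels, bool)
    both = p_mask & g_mask
    pair_dice: dict[tuple[int, int], float] = {}
    if both.any():
        pv = pred.labels[both].astype(np.int64)
        gv = gt.labels[both].astype(np.int64)
        key = pv * (int(gt.labels.max()) + 1) + gv
        uniq, counts = np.unique(key, return_counts=True)
        base = int(gt.labels.max()) + 1
        for k, c in zip(uniq.tolist(), counts.tolist()):
            pid, gid = divmod(k, base)
            pair_dice[(pid, gid)] = 2.0 * c / (p_sizes[pid] + g_sizes[gid])
    return p_sizes, g_sizes, pair_dice


def idsc(
    pred: InstanceMap,
    gt: InstanceMap,
    class_name: str | None = None,
    threshold: float = 0.5,
) -> InstanceMatchReport:
    """Instance-level Dice evaluation of a prediction against ground truth.

    If both maps contain no instance of the class the metric is undefined
    (NaN scores, with a warning).
    """
    p_sizes, g_sizes, pair_dice = _pairwise_dice(pred, gt, class_name)
    if not p_sizes and not g_sizes:
        warnings.warn(
            f"no instances of class {class_name!r} in either map; "
            "iDSC undefined",
            stacklevel=2,
        )
    pred_scores = {
        pid: max((d for (p, _), d in pair_dice.items() if p == pid), default=0.0)
        for pid in p_sizes
    }
    gt_scores = {
        gid: max((d for (_, g), d in pair_dice.items() if g == gid), default=0.0)
        for gid in g_sizes
    }
    report = InstanceMatchReport(
        class_name=class_name,
        pred_scores=pred_scores,
        gt_scores=gt_scores,
        pair_dice=pair_dice,
        threshold=threshold,
    )
    instance_f1_ppv(report, threshold)
    return report


def instance_f1_ppv(
    report: InstanceMatchReport, threshold: float = 0.5
) -> tuple[float, float]:
    """F1 and PPV at a Dice threshold (strictly above counts as a match).

    True positives are found by greedy one-to-one matching, highest Dice
    first; unmatched predictions are false positives and unmatched
    ground-truth instances false negatives. Updates the report in place and
    returns (F1, PPV); both are NaN when no instances exist on either side.
    """
    pairs = sorted(report.pair_dice.items(), key=lambda kv: (-kv[1], kv[0]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    tp = 0
    for (pid, gid), d in pairs:
        if d <= threshold:
            break
        if pid in used_p or gid in used_g:
            continue
        used_p.add(pid)
        used_g.add(gid)
        tp += 1
    fp = report.n_pred - tp
    fn = report.n_gt - tp
    report.threshold = threshold
    report.tp, report.fp, report.fn = tp, fp, fn
    if report.n_pred == 0 and report.n_gt == 0:
        report.f1 = report.ppv = float("nan")
    else:
        report.f1 = 2.0 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
        report.ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return report.f1, report.ppv


def pool_reports(reports: list[InstanceMatchReport], threshold: float = 0.5
                 ) -> InstanceMatchReport:
    """Pool per-image reports into one class-wise report.

    Metrics are averaged by pooling the instances of all images, matching
    the convention of averaging every per-instance score across test
    images. Instance ids are namespaced per source image.
    """
    pred_scores: dict[int, float] = {}
    gt_scores: dict[int, float] = {}
    pair_dice: dict[tuple[int, int], float] = {}
    tp = fp = fn = 0
    offset = 0
    for rep in reports:
        for pid, s in rep.pred_scores.items():
            pred_scores[pid + offset] = s
        for gid, s in rep.gt_scores.items():
            gt_scores[gid + offset] = s
        for (pid, gid), d in rep.pair_dice.items():
            pair_dice[(pid + offset, gid + offset)] = d
        f1_local = instance_f1_ppv(rep, threshold)
        del f1_local
        tp += rep.tp
        fp += rep.fp
        fn += rep.fn
        local_max = max(
            [0] + list(rep.pred_scores) + list(rep.gt_scores)
        )
        offset += local_max + 1
    out = InstanceMatchReport(
        class_name=reports[0].class_name if reports else None,
        pred_scores=pred_scores,
        gt_scores=gt_scores,
        pair_dice=pair_dice,
        threshold=threshold,
        tp=tp, fp=fp, fn=fn,
    )
    denom = 2 * tp + fp + fn
    out.f1 = 2.0 * tp / denom if denom else float("nan")
    out.ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    return out
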