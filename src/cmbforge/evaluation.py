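"""Detection evaluation: ROC/AUC, FROC and fixed-sensitivity operating points.

Patch-level performance is summarized by the ROC curve and its area.  For
whole-scan detection the clinically meaningful summary is the FROC curve —
lesion sensitivity against false positives per scan — because a scan
yields thousands of candidate locations and only a handful of lesions.
Candidates are matched to truth lesions one-to-one by greedy nearest-first
matching within a hit radius; matched candidates are true positives,
unmatched candidates false positives, and unmatched lesions count against
sensitivity at every threshold.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_auc_score

from .types import Candidate, DetectionRecord, LocationSample, OperatingPoint

__all__ = [
    "roc_auc",
    "froc",
    "operating_point_at_sensitivity",
    "greedy_match",
    "match_candidates_to_truth",
    "saturation_sweep",
]


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank formulation, ties averaged)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def greedy_match(points_a: np.ndarray, points_b: np.ndarray, spacing,
                 radius_mm: float) -> list[tuple[int, int]]:
    """One-to-one greedy nearest-first matching between two point sets.

    Returns (index_a, index_b) pairs with physical distance <= radius_mm;
    each point participates in at most one pair, closest pairs first.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        return []
    sp = np.asarray(spacing, dtype=float)
    d = np.sqrt((((a[:, None, :] - b[None, :, :]) * sp) ** 2).sum(axis=2))
    pairs = np.argwhere(d <= radius_mm)
    order = np.argsort(d[tuple(pairs.T)]) if pairs.size else []
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for idx in order:
        ia, ib = int(pairs[idx, 0]), int(pairs[idx, 1])
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        out.append((ia, ib))
    return out


def match_candidates_to_truth(
    candidates: list[Candidate],
    scores,
    truth: list[LocationSample],
    spacing,
    hit_radius_mm: float = 3.0,
    scan_id: str = "scan",
) -> list[DetectionRecord]:
    """Label scored candidates of one scan against its truth lesions.

    Greedy nearest-first one-to-one matching within `hit_radius_mm`;
    unmatched candidates become non-lesion records.  Truth lesions with no
    candidate yield no record — pass the total lesion count to froc().
    """
    if hit_radius_mm <= 0:
        raise ValueError("hit_radius_mm must be > 0")
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(candidates):
        raise ValueError("one score per candidate required")
    cand_pts = np.array([c.center for c in candidates], dtype=float).reshape(-1, 3)
    truth_pts = np.array([t.center for t in truth], dtype=float).reshape(-1, 3)
    matched = {ia for ia, _ in greedy_match(cand_pts, truth_pts, spacing, hit_radius_mm)}
    return [
        DetectionRecord(scan_id, c.center, float(s), i in matched)
        for i, (c, s) in enumerate(zip(candidates, scores))
    ]


def froc(records: list[DetectionRecord], n_scans: int,
         n_lesions: int | None = None) -> list[tuple[float, float, float]]:
    """FROC curve: (threshold, fp_per_scan, sensitivity) per threshold.

    Thresholds sweep the distinct record scores from high to low;
    sensitivity is the fraction of the n_lesions truth lesions whose
    matched candidate scores at or above the threshold.  n_lesions
    defaults to the number of matched (lesion) records, which is exact
    when every lesion was found by the screening stage.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    scores = np.array([r.score for r in records], dtype=float)
    is_lesion = np.array([r.is_lesion for r in records], dtype=bool)
    if n_lesions is None:
        n_lesions = int(is_lesion.sum())
    if n_lesions == 0:
        raise ValueError("froc undefined with no truth lesions")
    curve = []
    for thr in np.unique(scores)[::-1]:
        keep = scores >= thr
        sens = float((keep & is_lesion).sum()) / n_lesions
        fp = float((keep & ~is_lesion).sum()) / n_scans
        curve.append((float(thr), fp, sens))
    return curve


def operating_point_at_sensitivity(
    records: list[DetectionRecord],
    n_scans: int,
    target: float = 0.95,
    n_lesions: int | None = None,
) -> OperatingPoint:
    """Detection statistics at the highest threshold reaching `target` sensitivity."""
    scores = np.array([r.score for r in records], dtype=float)
    is_lesion = np.array([r.is_lesion for r in records], dtype=bool)
    if n_lesions is None:
        n_lesions = int(is_lesion.sum())
    curve = froc(records, n_scans, n_lesions)
    n_neg = int((~is_lesion).sum())
    if target <= 0:
        thr = float(scores.max()) + 1.0
        return OperatingPoint(0.0, 1.0, 0.0, thr)
    for thr, fp, sens in curve:  # thresholds already descending
        if sens >= target:
            keep = scores >= thr
            fp_count = int((keep & ~is_lesion).sum())
            spec = 1.0 - fp_count / n_neg if n_neg else 1.0
            return OperatingPoint(sens, spec, fp, thr)
    max_sens = curve[-1][2] if curve else 0.0
    raise ValueError(
        f"target sensitivity {target} unreachable; maximum achievable is {max_sens:.4f}"
    )


def saturation_sweep(train_and_score, sizes: list[int]) -> list[tuple[int, float]]:
    """AUC as a function of training-set size.

    `train_and_score(size)` must train at the given size and return
    (scores, labels) on a fixed evaluation set; the sweep reports
    (size, AUC) pairs and is used to locate the performance plateau.
    """
    if list(sizes) != sorted(sizes):
        raise ValueError("sizes must be ascending")
    out = []
    for size in sizes:
        scores, labels = train_and_score(int(size))
        out.append((int(size), roc_auc(scores, labels)))
    return out
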