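"""Performance metrics, cross-validation splits and the threshold sweep.

Metrics are computed one-vs-rest per foot class from a confusion summary
(TP, FP, FN, TN), on the percent scale:

    precision = TP / (TP + FP) * 100        recall = TP / (TP + FN) * 100
    specificity = TN / (TN + FP) * 100      accuracy = (TP + TN) / n * 100
    F-score = 2 P R / (P + R)               error rate = (FN + FP) / n * 100

Zero-denominator cases yield an explicit ``UNDEFINED`` marker rather than
a silent zero; averages skip undefined entries and report how many were
skipped. The overall accuracy of a three-angle run is the mean of the
three per-angle accuracy percentages. The threshold sweep re-runs
template matching at a ladder of similarity thresholds (0.50-0.95) and
reports the mean localization score 1/(1+d) of the best match per PoI —
the experiment that selected the default 0.90 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .template_matching import (
    POI_IDS,
    ImageMatcher,
    find_candidates,
    localization_score,
)

__all__ = [
    "UNDEFINED",
    "ConfusionSummary",
    "confusion",
    "class_metrics",
    "overall_accuracy",
    "per_angle_error_rates",
    "threshold_sweep",
    "kfold_split",
    "macro_average",
]

#: Marker returned when a metric's denominator is zero.
UNDEFINED = None

METRIC_NAMES = ("precision", "recall", "specificity", "accuracy", "f_score", "error_rate")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionSummary:
    """One-vs-rest confusion counts per class."""

    counts: dict[str, dict[str, int]]  # class -> {TP, FP, FN, TN}
    n_total: int
    classes: tuple[str, ...]

    def __getitem__(self, cls: str) -> dict[str, int]:
        return self.counts[cls]


def confusion(pred, truth, classes=None) -> ConfusionSummary:
    """Tally one-vs-rest TP/FP/FN/TN per class."""
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise EvaluationError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    if not pred:
        raise EvaluationError("empty prediction list")
    if classes is None:
        classes = tuple(sorted(set(truth) | set(pred)))
    counts = {}
    for c in classes:
        tp = sum(1 for p, t in zip(pred, truth) if p == c and t == c)
        fp = sum(1 for p, t in zip(pred, truth) if p == c and t != c)
        fn = sum(1 for p, t in zip(pred, truth) if p != c and t == c)
        tn = len(pred) - tp - fp - fn
        counts[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    return ConfusionSummary(counts=counts, n_total=len(pred), classes=tuple(classes))


def _ratio(num: float, den: float) -> float | None:
    return UNDEFINED if den == 0 else 100.0 * num / den


def class_metrics(cs: ConfusionSummary, cls: str) -> dict[str, float | None]:
    """Per-class metrics on the percent scale (F-score on 0-100 too)."""
    c = cs[cls]
    tp, fp, fn, tn = c["TP"], c["FP"], c["FN"], c["TN"]
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    n = tp + fn + fp + tn
    accuracy = _ratio(tp + tn, n)
    error_rate = _ratio(fn + fp, n)
    if precision is UNDEFINED or recall is UNDEFINED:
        f_score = UNDEFINED
    elif precision + recall == 0:
        f_score = 0.0  # both defined and zero: the harmonic-mean limit
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    return {
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "accuracy": accuracy,
        "f_score": f_score,
        "error_rate": error_rate,
    }


def metrics_table(pred, truth, classes=None) -> pd.DataFrame:
    """Class-by-metric table (rows = classes) of one-vs-rest percentages."""
    cs = confusion(pred, truth, classes)
    return pd.DataFrame({c: class_metrics(cs, c) for c in cs.classes}).T


def macro_average(values) -> tuple[float | None, int]:
    """Mean over defined entries; returns (mean, number skipped as undefined)."""
    values = list(values)
    defined = [v for v in values if v is not UNDEFINED]
    skipped = len(values) - len(defined)
    if not defined:
        return UNDEFINED, skipped
    return float(np.mean(defined)), skipped


def overall_accuracy(per_angle_preds: dict[str, list], truth: list) -> float:
    """Mean of the three per-angle plain accuracy percentages."""
    missing = [a for a in ("CIA", "AA", "MA") if a not in per_angle_preds]
    if missing:
        raise EvaluationError(f"missing per-angle prediction lists: {missing}")
    accs = []
    for angle in ("CIA", "AA", "MA"):
        preds = list(per_angle_preds[angle])
        if len(preds) != len(truth):
            raise EvaluationError(f"{angle} prediction list length mismatch")
        if not truth:
            raise EvaluationError("empty truth list")
        accs.append(100.0 * sum(p == t for p, t in zip(preds, truth)) / len(truth))
    return float(np.mean(accs))


def per_angle_error_rates(
    per_angle_preds: dict[str, list], truth: list, foot_type: str
) -> dict[str, float | None]:
    """One-vs-rest error-rate percent of each angle for one foot type."""
    out = {}
    for angle in ("CIA", "AA", "MA"):
        if angle not in per_angle_preds:
            raise EvaluationError(f"missing prediction list for angle {angle}")
        cs = confusion(per_angle_preds[angle], truth, classes=(foot_type,))
        out[angle] = class_metrics(cs, foot_type)["error_rate"]
    return out


def kfold_split(n_items: int, k: int = 10, seed: int = 0):
    """Seeded shuffled k-fold partition of ``range(n_items)``.

    Returns ``(folds, pairs)``: the k disjoint test folds (sizes differ by
    at most one) and the corresponding (train_idx, test_idx) pairs.
    """
    if n_items < k:
        raise EvaluationError(f"cannot split {n_items} items into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pairs = [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n_items))]
    folds = [te for _, te in pairs]
    return folds, pairs


def threshold_sweep(
    dataset,
    library,
    thresholds=tuple(np.round(np.arange(0.50, 0.951, 0.05), 2)),
    top_k: int | None = 50,
    max_templates_per_poi: int | None = 1,
) -> pd.DataFrame:
    """Mean localization score of the rank-1 match at each threshold.

    ``dataset`` is an iterable of ``(Radiograph, GroundTruth)``. For each
    image and PoI the best-similarity candidate above the threshold is
    compared against the ground-truth landmark via 1/(1+d); rows report
    the mean score, the number of localized (PoI, image) pairs, and the
    total candidate count (monotonically non-increasing in threshold —
    asserted during the sweep).
    """
    thresholds = sorted(float(t) for t in thresholds)
    for t in thresholds:
        if not 0.0 < t < 1.0:
            raise EvaluationError(f"threshold {t} outside (0, 1)")
    # Score maps do not depend on the threshold: match once, filter per level.
    per_poi_maps = []  # list of (gt_point, ScoreMap)
    for img, gt in dataset:
        matcher = ImageMatcher(np.asarray(img.pixels, dtype=np.float64))
        for poi_id in POI_IDS:
            tmpls = library.templates_for(poi_id, limit=max_templates_per_poi)
            for tmpl in tmpls:
                per_poi_maps.append((gt.landmark_points[poi_id], matcher.score(tmpl)))
    rows = []
    prev_count = None
    for t in thresholds:
        scores = []
        n_candidates = 0
        for gt_point, smap in per_poi_maps:
            cands = find_candidates(smap, threshold=t, top_k=top_k)
            n_candidates += len(cands)
            if cands:
                best = max(cands, key=lambda c: (c.similarity, -c.scan_index))
                from .angle_geometry import poi_center

                scores.append(localization_score(gt_point, poi_center(best.start)))
        if prev_count is not None and n_candidates > prev_count:
            raise AssertionError(
                "candidate count increased with a stricter threshold — matcher invariant broken"
            )
        prev_count = n_candidates
        rows.append(
            {
                "threshold": t,
                "mean_localization_score": float(np.mean(scores)) if scores else np.nan,
                "n_localized": len(scores),
                "n_candidates": n_candidates,
            }
        )
    return pd.DataFrame(rows)
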