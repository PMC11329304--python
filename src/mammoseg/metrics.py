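"""Per-image segmentation evaluation and dataset-level summaries.

Metrics follow the standard pixel confusion-matrix definitions:
DSC = 2|GT∩PR| / (|GT| + |PR|), recall (TPR) = TP/(TP+FN),
precision = TP/(TP+FP), FPR = FP/(FP+TN).  An image is a
false-negative *outcome* when the ground truth contains a mass but the
prediction overlaps none of it — the whole lesion is missed; such images
are scored DSC = 0 regardless of what the prediction marks elsewhere.

Zero-denominator conventions (recorded in report metadata): GT and PR both
empty => DSC = precision = recall = 1; PR empty with GT nonempty =>
precision recorded as 0.  The FPR universe defaults to all non-mass pixels
of the full frame; ``fpr_breast_only`` restricts TN to a supplied breast
region.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "fn_outcome", "summarize",
           "write_reports_csv"]

ZERO_DENOM_CONVENTIONS = {
    "both_empty": {"dsc": 1.0, "precision": 1.0, "recall": 1.0},
    "pred_empty_gt_nonempty": {"precision": 0.0},
}


@dataclass
class MetricsReport:
    TP: int
    FP: int
    FN: int
    TN: int
    dsc: float
    precision: float
    recall: float
    fpr: float
    fn_outcome: bool
    image_id: str = ""
    mass_class: str = "unknown"


def fn_outcome(pred: np.ndarray, gt: np.ndarray) -> bool:
    """True iff the ground truth has a mass pixel and the prediction
    overlaps none of it anywhere in the image."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    return bool(gt.any() and not (pred & gt).any())


def compute_metrics(pred: np.ndarray, gt: np.ndarray, image_id: str = "",
                    mass_class: str = "unknown",
                    region: np.ndarray | None = None,
                    fpr_breast_only: bool = False) -> MetricsReport:
    """Pixel confusion counts and derived metrics for one image."""
    pred = np.asarray(pred) > 0
    gt = np.asarray(gt) > 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())

    n_gt, n_pr = tp + fn, tp + fp
    if n_gt == 0 and n_pr == 0:
        dsc, precision, recall = 1.0, 1.0, 1.0
    else:
        dsc = 2.0 * tp / (n_gt + n_pr)
        precision = tp / n_pr if n_pr else 0.0
        recall = tp / n_gt if n_gt else 1.0

    if fpr_breast_only:
        if region is None:
            raise ValueError("fpr_breast_only requires a region mask")
        reg = np.asarray(region) > 0
        fp_r = int((pred & ~gt & reg).sum())
        tn_r = int((~pred & ~gt & reg).sum())
        fpr = fp_r / (fp_r + tn_r) if (fp_r + tn_r) else 0.0
    else:
        fpr = fp / (fp + tn) if (fp + tn) else 0.0

    missed = fn_outcome(pred, gt)
    if missed:
        dsc = 0.0
    return MetricsReport(TP=tp, FP=fp, FN=fn, TN=tn, dsc=dsc,
                         precision=precision, recall=recall, fpr=fpr,
                         fn_outcome=missed, image_id=image_id,
                         mass_class=mass_class)


def summarize(reports: list[MetricsReport],
              stratify_by_class: bool = False) -> dict:
    """Mean per-image metrics plus the FN-outcome percentage.

    FN-outcome images contribute dsc = 0 to the mean (already enforced by
    :func:`compute_metrics`).
    """
    if not reports:
        raise ValueError("empty report list")

    def _mean(rs, attr):
        return float(np.mean([getattr(r, attr) for r in rs]))

    out = {
        "n_images": len(reports),
        "dsc": _mean(reports, "dsc"),
        "precision": _mean(reports, "precision"),
        "recall": _mean(reports, "recall"),
        "fpr": _mean(reports, "fpr"),
        "fn_outcomes": int(sum(r.fn_outcome for r in reports)),
        "fn_pct": 100.0 * sum(r.fn_outcome for r in reports) / len(reports),
        "conventions": ZERO_DENOM_CONVENTIONS,
    }
    if stratify_by_class:
        strata = {}
        for cls in sorted({r.mass_class for r in reports}):
            sub = [r for r in reports if r.mass_class == cls]
            strata[cls] = {"n_images": len(sub), "dsc": _mean(sub, "dsc"),
                           "precision": _mean(sub, "precision"),
                           "recall": _mean(sub, "recall"),
                           "fpr": _mean(sub, "fpr"),
                           "fn_pct": 100.0 * sum(r.fn_outcome for r in sub) / len(sub)}
        out["by_class"] = strata
    return out


def write_reports_csv(reports: list[MetricsReport], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(asdict(reports[0]).keys()))
        writer.writeheader()
        for r in reports:
            writer.writerow(asdict(r))


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))
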