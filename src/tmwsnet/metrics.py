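"""Segmentation metrics and forestry structural-parameter extraction.

Metrics are computed from one-vs-rest confusion counts per class: mIoU and
the macro precision/recall/F1 means, plus overall accuracy under the name
``macc`` (that is how the accuracy metric is printed in the point-cloud
segmentation literature this package follows; the macro per-class accuracy
is additionally reported as ``macc_macro``).  The coefficient of
determination R^2 = 1 - SS_res/SS_tot evaluates continuous predictions such
as recovered tree parameters.

Structural parameters from a labeled cloud:

* tree height — top percentile of tree-point z minus a ground proxy (the 1st
  percentile of all z, robust to isolated low outliers);
* DBH — diameter of a least-squares circle fitted to the trunk slice 1.2 to
  1.4 m above ground (algebraic Kasa fit + one Gauss-Newton refinement);
* crown diameter — mean of the x- and y-extents of the crown points (tree
  points above half the tree height).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .geometry_io import LabeledCloud

logger = logging.getLogger("tmwsnet")

__all__ = ["ConfusionCounts", "MetricReport", "TreeParams", "confusion",
           "compute_metrics", "r_squared", "tree_height", "dbh_estimate",
           "crown_diameter", "extract_params", "params_report"]


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; each class's four counts sum to N."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_classes: int

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.fp[0] + self.fn[0] + self.tn[0])


@dataclass
class MetricReport:
    """All metrics (percent scale except r2) plus the underlying counts."""

    miou: float
    macc: float
    macc_macro: float
    mprec: float
    mrec: float
    mf1: float
    r2: float | None
    per_class: dict
    counts: ConfusionCounts

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "counts"}
        return json.dumps(d, default=lambda o: o.tolist() if hasattr(o, "tolist") else o)


@dataclass
class TreeParams:
    height: float
    dbh: float
    crown_diameter: float

    def __post_init__(self):
        if min(self.height, self.dbh, self.crown_diameter) <= 0:
            raise ValueError("tree parameters must be positive")


def confusion(pred, truth, n_classes: int = 2) -> ConfusionCounts:
    pred = np.asarray(pred, dtype=np.int64)
    truth = np.asarray(truth, dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same length")
    if pred.max(initial=0) >= n_classes or truth.max(initial=0) >= n_classes:
        raise ValueError("class values must be < n_classes")
    n = len(pred)
    tp = np.empty(n_classes, dtype=np.int64)
    fp = np.empty(n_classes, dtype=np.int64)
    fn = np.empty(n_classes, dtype=np.int64)
    for i in range(n_classes):
        tp[i] = np.sum((pred == i) & (truth == i))
        fp[i] = np.sum((pred == i) & (truth != i))
        fn[i] = np.sum((pred != i) & (truth == i))
    tn = n - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn, n_classes)


def _macro(numer, denom, name: str):
    valid = denom > 0
    if not valid.any():
        raise ValueError(f"no class with a defined {name}")
    if not valid.all():
        logger.info("%s: excluding %d empty-denominator class(es)",
                    name, int((~valid).sum()))
    ratio = np.zeros(len(numer))
    ratio[valid] = numer[valid] / denom[valid]
    return ratio, valid


def r_squared(truth, pred) -> float:
    """R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2."""
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    ss_res = np.sum((truth - pred) ** 2)
    ss_tot = np.sum((truth - truth.mean()) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


def compute_metrics(counts: ConfusionCounts, truth_values=None,
                    pred_values=None, raw_f1_sum: bool = False) -> MetricReport:
    """All segmentation metrics (percent); optional R^2 on paired values."""
    tp, fp, fn, tn = (c.astype(np.float64) for c in
                      (counts.tp, counts.fp, counts.fn, counts.tn))
    total = counts.total
    if total == 0:
        raise ValueError("empty evaluation")
    iou, iou_ok = _macro(tp, tp + fp + fn, "IoU")
    prec, prec_ok = _macro(tp, tp + fp, "precision")
    rec, rec_ok = _macro(tp, tp + fn, "recall")
    # F1 defined wherever precision and recall are; 0 when both vanish
    f1_ok = prec_ok & rec_ok
    pr = prec + rec
    f1 = np.zeros(counts.n_classes)
    pos = f1_ok & (pr > 0)
    f1[pos] = 2 * prec[pos] * rec[pos] / pr[pos]
    acc_cls, acc_ok = _macro(tp, tp + fn, "class accuracy")
    miou = 100.0 * iou[iou_ok].mean()
    # overall accuracy: correctly predicted points over all points
    macc = 100.0 * tp.sum() / total
    macc_macro = 100.0 * acc_cls[acc_ok].mean()
    mprec = 100.0 * prec[prec_ok].mean()
    mrec = 100.0 * rec[rec_ok].mean()
    mf1 = 100.0 * (f1[f1_ok].sum() if raw_f1_sum else f1[f1_ok].mean())
    r2 = None
    if truth_values is not None and pred_values is not None:
        r2 = r_squared(truth_values, pred_values)
    per_class = {int(i): {"iou": 100 * iou[i], "prec": 100 * prec[i],
                          "rec": 100 * rec[i], "f1": 100 * f1[i]}
                 for i in range(counts.n_classes)}
    return MetricReport(miou=miou, macc=macc, macc_macro=macc_macro,
                        mprec=mprec, mrec=mrec, mf1=mf1, r2=r2,
                        per_class=per_class, counts=counts)


# ---------------------------------------------------------------------------
# structural parameters


def _ground_z(cloud: LabeledCloud) -> float:
    return float(np.percentile(cloud.coords[:, 2], 1.0))


def tree_height(cloud: LabeledCloud) -> float:
    """99.9th percentile of tree-point z minus the 1st percentile of all z."""
    if cloud.labels is None or not np.any(cloud.labels == 1):
        raise ValueError("no tree-labeled points")
    top = float(np.percentile(cloud.coords[cloud.labels == 1, 2], 99.9))
    return top - _ground_z(cloud)


def _fit_circle(xy: np.ndarray):
    """Least-squares circle: algebraic (Kasa) fit + one Gauss-Newton step."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x ** 2 + y ** 2
    (cx, cy, c0), *_ = np.linalg.lstsq(A, b, rcond=None)
    r = np.sqrt(c0 + cx ** 2 + cy ** 2)
    # one Gauss-Newton refinement of the geometric residuals
    d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)
    d = np.maximum(d, 1e-12)
    J = np.column_stack([-(x - cx) / d, -(y - cy) / d, -np.ones(len(x))])
    res = d - r
    step, *_ = np.linalg.lstsq(J, -res, rcond=None)
    cx, cy, r = cx + step[0], cy + step[1], r + step[2]
    return cx, cy, float(r)


def dbh_estimate(cloud: LabeledCloud) -> float:
    """Diameter of the circle fitted to tree points 1.2-1.4 m above ground."""
    if cloud.labels is None or not np.any(cloud.labels == 1):
        raise ValueError("no tree-labeled points")
    g = _ground_z(cloud)
    z = cloud.coords[:, 2]
    sl = (cloud.labels == 1) & (z >= g + 1.2) & (z <= g + 1.4)
    if sl.sum() < 5:
        raise ValueError("insufficient breast-height points")
    _, _, r = _fit_circle(cloud.coords[sl, :2])
    return 2.0 * r


def crown_diameter(cloud: LabeledCloud) -> float:
    """Mean of x- and y-extent of tree points above half the tree height."""
    if cloud.labels is None or not np.any(cloud.labels == 1):
        raise ValueError("no tree-labeled points")
    g = _ground_z(cloud)
    h = tree_height(cloud)
    tree = cloud.coords[cloud.labels == 1]
    crown = tree[tree[:, 2] > g + 0.5 * h]
    if len(crown) == 0:
        raise ValueError("no crown points above half height")
    ext = crown[:, :2].max(axis=0) - crown[:, :2].min(axis=0)
    return float(ext.mean())


def extract_params(cloud: LabeledCloud) -> TreeParams:
    return TreeParams(height=tree_height(cloud), dbh=dbh_estimate(cloud),
                      crown_diameter=crown_diameter(cloud))


def params_report(predicted, truth, csv_path=None, json_path=None):
    """Residuals and per-parameter R^2 for (height, dbh, crown_diameter) pairs.

    ``predicted`` and ``truth`` are sequences of 3-tuples or TreeParams.
    Returns (DataFrame of residuals, dict of R^2 per parameter).
    """
    def as_rows(seq):
        return np.array([
            (p.height, p.dbh, p.crown_diameter) if isinstance(p, TreeParams) else tuple(p)
            for p in seq
        ])

    P, T = as_rows(predicted), as_rows(truth)
    if P.shape != T.shape:
        raise ValueError("predicted and truth must have the same length")
    if len(P) < 2:
        raise ValueError("need at least 2 samples")
    names = ["height", "dbh", "crown_diameter"]
    df = pd.DataFrame({
        **{f"true_{n}": T[:, i] for i, n in enumerate(names)},
        **{f"pred_{n}": P[:, i] for i, n in enumerate(names)},
        **{f"resid_{n}": P[:, i] - T[:, i] for i, n in enumerate(names)},
    })
    r2 = {n: r_squared(T[:, i], P[:, i]) for i, n in enumerate(names)}
    if csv_path:
        df.to_csv(csv_path, index=False)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(r2, fh, indent=2)
    return df, r2
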