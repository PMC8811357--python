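"""Subject-level and cluster-wise evaluation metrics, ROC and FROC curves.

Subject level (per cohort):

    TPR         = S_TP / (S_TP + S_FN)
    specificity = S_TN / (S_TN + S_FP)
    accuracy    = (S_TP + S_TN) / S_N

Cluster level, with 26-connectivity: a truth cluster is a true positive if
any detected cluster overlaps it by at least one voxel, a false negative
otherwise; a detected cluster overlapping no truth cluster is a false
positive.  One detection covering two truth clusters yields two TPs and no
FP (truth clusters are what Eq.-style TPR counts; FP is defined by "no
overlap with any truth cluster").

    cluster-wise TPR = TP_clus / (TP_clus + FN_clus)
    FPavg            = total FP clusters / number of subjects

Undefined ratios (zero denominators) are reported as ``None``, never
coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "EvalCounts",
    "SubjectMetrics",
    "subject_metrics",
    "cluster_metrics",
    "roc_curve",
    "froc_curve",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class EvalCounts:
    s_tp: int = 0
    s_fp: int = 0
    s_tn: int = 0
    s_fn: int = 0
    tp_clus: int = 0
    fn_clus: int = 0
    fp_clus_total: int = 0
    n_subjects: int = 0


@dataclass
class SubjectMetrics:
    tpr: float | None
    specificity: float | None
    accuracy: float | None
    counts: EvalCounts
    undefined: tuple = ()


def subject_metrics(decisions, labels) -> SubjectMetrics:
    """Subject-level TPR, specificity and accuracy from aligned booleans."""
    d = np.asarray(list(decisions), dtype=bool)
    t = np.asarray(list(labels), dtype=bool)
    if d.shape != t.shape:
        raise ValueError("decisions and labels must align")
    c = EvalCounts(
        s_tp=int((d & t).sum()),
        s_fp=int((d & ~t).sum()),
        s_tn=int((~d & ~t).sum()),
        s_fn=int((~d & t).sum()),
        n_subjects=int(len(d)),
    )
    undefined = []
    tpr = spec = acc = None
    if c.s_tp + c.s_fn > 0:
        tpr = c.s_tp / (c.s_tp + c.s_fn)
    else:
        undefined.append("tpr")
    if c.s_tn + c.s_fp > 0:
        spec = c.s_tn / (c.s_tn + c.s_fp)
    else:
        undefined.append("specificity")
    if c.n_subjects > 0:
        acc = (c.s_tp + c.s_tn) / c.n_subjects
    else:
        undefined.append("accuracy")
    return SubjectMetrics(tpr, spec, acc, c, tuple(undefined))


def _cluster_counts_one(detected: np.ndarray, truth: np.ndarray):
    """(tp, fn, fp) cluster counts for one subject.

    ``detected`` is a binary mask (labelled internally with
    26-connectivity); ``truth`` is an integer-labelled mask whose distinct
    nonzero values are the ground-truth clusters.
    """
    detected = np.asarray(detected) > 0
    truth = np.asarray(truth)
    truth_labels = np.unique(truth[truth > 0])
    tp = fn = 0
    for lab in truth_labels:
        if detected[truth == lab].any():
            tp += 1
        else:
            fn += 1
    det_labels, n_det = ndi.label(detected, structure=_STRUCT_26)
    fp = 0
    for lab in range(1, n_det + 1):
        if not (truth[det_labels == lab] > 0).any():
            fp += 1
    return tp, fn, fp


def cluster_metrics(detected_masks, truth_masks, n_subjects: int | None = None):
    """Cohort cluster-wise TPR and FPavg.

    ``detected_masks`` / ``truth_masks`` are aligned per-subject sequences.
    Returns ``(cluster_tpr, fpavg, EvalCounts)``; cluster TPR is ``None``
    when the cohort has no truth clusters.
    """
    detected_masks = list(detected_masks)
    truth_masks = list(truth_masks)
    if len(detected_masks) != len(truth_masks):
        raise ValueError("detected and truth cohorts must align")
    if n_subjects is None:
        n_subjects = len(detected_masks)
    c = EvalCounts(n_subjects=int(n_subjects))
    for det, tru in zip(detected_masks, truth_masks):
        if np.asarray(det).shape != np.asarray(tru).shape:
            raise ValueError("detected and truth masks must have the same shape")
        tp, fn, fp = _cluster_counts_one(det, tru)
        c.tp_clus += tp
        c.fn_clus += fn
        c.fp_clus_total += fp
    tpr = (
        c.tp_clus / (c.tp_clus + c.fn_clus) if (c.tp_clus + c.fn_clus) > 0 else None
    )
    fpavg = c.fp_clus_total / n_subjects if n_subjects > 0 else None
    return tpr, fpavg, c


def roc_curve(points):
    """Subject-level ROC from (threshold, fpr, tpr) triples.

    Points are sorted by FPR; the trapezoidal AUC is computed with (0,0)
    and (1,1) anchors.  Fewer than two distinct points leave the AUC
    undefined (``None``).
    """
    pts = [
        (th, float(fpr), float(tpr))
        for th, fpr, tpr in points
        if fpr is not None and tpr is not None
    ]
    pts.sort(key=lambda p: (p[1], p[2]))
    distinct = {(round(p[1], 12), round(p[2], 12)) for p in pts}
    if len(distinct) < 2:
        return pts, None
    xs = [0.0] + [p[1] for p in pts] + [1.0]
    ys = [0.0] + [p[2] for p in pts] + [1.0]
    auc = float(np.trapezoid(ys, xs))
    return pts, auc


def froc_curve(points):
    """FROC curve: (threshold, fpavg, cluster_tpr) sorted by FPavg (no AUC)."""
    pts = [
        (th, float(fpavg), float(tpr))
        for th, fpavg, tpr in points
        if fpavg is not None and tpr is not None
    ]
    pts.sort(key=lambda p: (p[1], p[2]))
    return pts
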