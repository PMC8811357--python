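"""Subject-level decision: candidate count vs threshold, plus a thresholding baseline.

A subject is called a CMB subject when the number of candidates surviving
the shape filter strictly exceeds Th_NCMB.  The default thresholds are
per-modality (35 for SWI, 30 for T2*-GRE): SWI enhances mimics as well as
microbleeds, so more residual false positives per subject are expected and
a higher count threshold performs better.

``baseline_candidate_mask`` implements the intensity-percentile baseline:
after identical preprocessing and vessel removal, every in-brain voxel
darker than the within-mask 5th-percentile intensity becomes an initial
candidate; the downstream shape filter and subject decision are shared with
the main pipeline so the two stage-2 variants are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import VolumeImage

__all__ = [
    "SubjectThreshold",
    "SubjectDecision",
    "decide_subject",
    "baseline_candidate_mask",
    "sweep_th_ncmb",
]

MODALITY_DEFAULTS = {"SWI": 35, "GRE": 30}


@dataclass(frozen=True)
class SubjectThreshold:
    """Count threshold on surviving candidates; strict 'greater than'."""

    th_ncmb: int = 35

    def __post_init__(self):
        if self.th_ncmb < 0:
            raise ValueError("th_ncmb must be nonnegative")

    @classmethod
    def for_modality(cls, modality: str) -> "SubjectThreshold":
        try:
            return cls(MODALITY_DEFAULTS[modality.upper()])
        except KeyError:
            raise ValueError(f"unknown modality {modality!r}; expected SWI or GRE") from None


@dataclass
class SubjectDecision:
    subject_id: str
    candidate_count: int
    th_ncmb: int
    is_cmb_subject: bool


def decide_subject(
    surviving_components, th: SubjectThreshold, subject_id: str = ""
) -> SubjectDecision:
    """CMB/non-CMB call: candidate count must strictly exceed th_ncmb."""
    count = (
        int(surviving_components)
        if np.isscalar(surviving_components)
        else len(surviving_components)
    )
    return SubjectDecision(
        subject_id=subject_id,
        candidate_count=count,
        th_ncmb=th.th_ncmb,
        is_cmb_subject=count > th.th_ncmb,
    )


def baseline_candidate_mask(
    vol: VolumeImage, mask: np.ndarray, percentile: float = 5.0
) -> np.ndarray:
    """Intensity-threshold baseline for stage 2.

    Candidates are in-brain voxels with intensity strictly below the
    within-mask ``percentile`` value (linear interpolation).  A constant
    image yields an empty mask.
    """
    mask = np.asarray(mask) > 0
    thr = np.percentile(vol.voxels[mask], percentile)
    return mask & (vol.voxels < thr)


def sweep_th_ncmb(candidate_counts, labels, grid=None):
    """Subject-level ROC sweep of the count threshold.

    ``candidate_counts`` and ``labels`` are aligned per-subject sequences.
    Returns ``(rows, knee)`` where rows carry threshold/TPR/FPR and the knee
    is the threshold maximizing the Youden index (TPR - FPR).
    """
    from .metrics import subject_metrics

    if grid is None:
        grid = range(10, 81, 5)
    counts = np.asarray(list(candidate_counts))
    labels = np.asarray(list(labels), dtype=bool)
    rows = []
    for th in grid:
        decisions = counts > th
        m = subject_metrics(decisions, labels)
        fpr = None if m.specificity is None else 1.0 - m.specificity
        rows.append(
            {"th_ncmb": int(th), "tpr": m.tpr, "fpr": fpr, "accuracy": m.accuracy}
        )
    defined = [r for r in rows if r["tpr"] is not None and r["fpr"] is not None]
    knee = (
        max(defined, key=lambda r: r["tpr"] - r["fpr"])["th_ncmb"] if defined else None
    )
    return rows, knee
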