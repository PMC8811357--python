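"""End-to-end orchestration: train, predict, evaluate, sweep.

The prediction path for one subject is

    reorient -> brain mask -> standardize -> vessel/sulci removal ->
    7-feature stack -> P(CMB) -> threshold at th_prob -> 26-connected
    components -> shape filter -> count vs Th_NCMB -> subject decision

and is deterministic given the configured seed.  Training runs the same
front end (so train and test voxels live in the same feature space),
samples labelled voxels against the truth masks and fits the probabilistic
voxel classifier.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd

from . import __version__
from .candidates import (
    CandidateModel,
    assemble_features,
    predict_probability,
    sample_training_voxels,
    threshold_candidates,
    train_voxel_classifier,
)
from .config import PipelineConfig
from .metrics import cluster_metrics, roc_curve, subject_metrics
from .phantom import PhantomSubject
from .preprocess import (
    VolumeImage,
    compute_brain_mask,
    read_volume,
    reorient_canonical,
    standardize_intensity,
)
from .shapes import compute_shape_attributes, filter_candidates, label_components
from .subjects import SubjectThreshold, baseline_candidate_mask, decide_subject, sweep_th_ncmb
from .vessels import remove_vessels

logger = logging.getLogger("cmbselect")

__all__ = [
    "SubjectResult",
    "prepare_subject",
    "run_predict",
    "run_train",
    "run_evaluate",
    "run_sweep",
    "save_model",
    "load_model",
    "make_kfold_splits",
    "make_loo_splits",
]


@dataclass
class SubjectResult:
    """Everything the pipeline produced for one subject."""

    decision: "SubjectDecision"
    report: pd.DataFrame
    candidate_mask: np.ndarray
    surviving_mask: np.ndarray
    probability_map: np.ndarray
    vessel_mask: np.ndarray
    n_initial_components: int


def prepare_subject(vol: VolumeImage, mask: np.ndarray | None, cfg: PipelineConfig, index: int = 0):
    """Shared front end: reorient, mask, standardize, remove vessels.

    Returns ``(vessel_removed standardized VolumeImage, brain mask,
    vessel mask)``.
    """
    vol = reorient_canonical(vol)
    brain = compute_brain_mask(vol, supplied=mask)
    std = standardize_intensity(vol, brain)
    vr = cfg.vessel_removal
    inpainted, vmask = remove_vessels(
        std,
        brain,
        vr.frangi,
        vr.sigma_grad,
        vr.sigma_window,
        seed=cfg.stage_seed("kmeans", index),
        feature_weights=vr.feature_weights,
    )
    logger.info("stage1: %d vessel voxels masked", int(vmask.sum()))
    return inpainted, brain, vmask


def _candidate_report(components) -> pd.DataFrame:
    rows = []
    for comp in components:
        rows.append(
            {
                "component_id": comp.label,
                "n_voxels": comp.n_voxels,
                "centroid_x_mm": round(float(comp.centroid_mm[0]), 6),
                "centroid_y_mm": round(float(comp.centroid_mm[1]), 6),
                "centroid_z_mm": round(float(comp.centroid_mm[2]), 6),
                "volume_mm3": round(comp.volume_mm3, 6),
                "ellipticity": round(comp.ellipticity, 6),
                "solidity": round(comp.solidity, 6),
                "diameter_mm": round(comp.diameter_mm, 6),
                "pass_volume": comp.criterion_flags["volume"],
                "pass_ellipticity": comp.criterion_flags["ellipticity"],
                "pass_solidity": comp.criterion_flags["solidity"],
                "pass_diameter": comp.criterion_flags["diameter"],
                "passes": comp.passes,
            }
        )
    cols = [
        "component_id", "n_voxels", "centroid_x_mm", "centroid_y_mm",
        "centroid_z_mm", "volume_mm3", "ellipticity", "solidity",
        "diameter_mm", "pass_volume", "pass_ellipticity", "pass_solidity",
        "pass_diameter", "passes",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_predict(
    vol: VolumeImage,
    mask: np.ndarray | None,
    model: CandidateModel | None,
    cfg: PipelineConfig,
    subject_id: str = "",
    index: int = 0,
    stage2: str = "classifier",
) -> SubjectResult:
    """Full prediction for one subject.

    ``stage2`` selects the candidate-detection variant: ``"classifier"``
    (the probabilistic voxel classifier; requires ``model``) or
    ``"percentile"`` (the intensity-5th-percentile baseline; ``model`` may
    be None).
    """
    inpainted, brain, vmask = prepare_subject(vol, mask, cfg, index)
    if stage2 == "classifier":
        if model is None:
            raise ValueError("stage2='classifier' requires a trained model")
        if model.config != cfg.features:
            raise ValueError("model feature configuration does not match pipeline config")
        stack = assemble_features(inpainted, brain, cfg.features)
        p_map = predict_probability(model, stack, brain)
        cmask = threshold_candidates(p_map, cfg.features.th_prob) & brain
    elif stage2 == "percentile":
        cmask = baseline_candidate_mask(inpainted, brain)
        p_map = cmask.astype(np.float64)
    else:
        raise ValueError(f"unknown stage2 variant {stage2!r}")
    comps = label_components(cmask)
    for comp in comps:
        compute_shape_attributes(comp, vol.voxel_size_mm)
    survivors = filter_candidates(comps, cfg.shape)
    logger.info(
        "stage3: %d initial components, %d survive shape filter",
        len(comps), len(survivors),
    )
    surviving_mask = np.zeros_like(cmask)
    for comp in survivors:
        surviving_mask[tuple(comp.indices.T)] = True
    decision = decide_subject(survivors, cfg.subject, subject_id=subject_id)
    return SubjectResult(
        decision=decision,
        report=_candidate_report(comps),
        candidate_mask=cmask,
        surviving_mask=surviving_mask,
        probability_map=p_map,
        vessel_mask=vmask,
        n_initial_components=len(comps),
    )


def run_train(subjects, cfg: PipelineConfig, metadata: dict | None = None) -> CandidateModel:
    """Train the voxel classifier on subjects with voxel-wise truth.

    ``subjects`` is an iterable of :class:`PhantomSubject` or of
    ``(VolumeImage, brain_mask_or_None, truth_labels)`` triples.  Subjects
    without positive truth voxels contribute nothing and are skipped.
    """
    training_sets = []
    n_used = 0
    for i, subj in enumerate(subjects):
        if isinstance(subj, PhantomSubject):
            vol, mask, truth = subj.image, subj.brain_mask, subj.cmb_truth
        else:
            vol, mask, truth = subj
        if not (np.asarray(truth) > 0).any():
            continue
        inpainted, brain, vmask = prepare_subject(vol, mask, cfg, index=i)
        stack = assemble_features(inpainted, brain, cfg.features)
        if not ((np.asarray(truth) > 0) & brain & ~vmask).any():
            continue  # every lesion voxel painted over: nothing to learn from
        training_sets.append(
            sample_training_voxels(
                stack,
                truth,
                brain,
                neg_pos_ratio=cfg.features.neg_pos_ratio,
                seed=cfg.stage_seed("sampling", i),
                exclude_positives=vmask,
            )
        )
        n_used += 1
    if not training_sets:
        raise ValueError("no training subject has positive truth voxels")
    meta = {"n_training_subjects": n_used, "config_hash": _config_hash(cfg)}
    if metadata:
        meta.update(metadata)
    return train_voxel_classifier(
        training_sets, cfg.features, seed=cfg.stage_seed("svm"), metadata=meta
    )


def _config_hash(cfg: PipelineConfig) -> str:
    import json

    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def save_model(model: CandidateModel, path) -> None:
    """Serialize a trained model (estimator + feature config + metadata)."""
    joblib.dump(
        {
            "format_version": 1,
            "package_version": __version__,
            "estimator": model.estimator,
            "config": model.config,
            "feature_names": model.feature_names,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path) -> CandidateModel:
    blob = joblib.load(path)
    if blob.get("format_version") != 1:
        raise ValueError("unsupported model file format")
    return CandidateModel(
        estimator=blob["estimator"],
        config=blob["config"],
        feature_names=tuple(blob["feature_names"]),
        metadata=blob.get("metadata", {}),
    )


def run_evaluate(decisions, labels):
    """Subject-level metrics for aligned decision/label sequences."""
    return subject_metrics(decisions, labels)


def run_sweep(candidate_counts, labels, grid=None):
    """ROC table over Th_NCMB plus trapezoidal AUC and the knee threshold."""
    rows, knee = sweep_th_ncmb(candidate_counts, labels, grid)
    pts = [(r["th_ncmb"], r["fpr"], r["tpr"]) for r in rows]
    _, auc = roc_curve(pts)
    return rows, knee, auc


def make_kfold_splits(ids, k: int, seed: int = 0):
    """Seeded k-fold partition: each id appears in exactly one test fold."""
    ids = list(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return [sorted(f) for f in folds]


def make_loo_splits(ids):
    """Leave-one-out: one fold per id."""
    return [[i] for i in ids]
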