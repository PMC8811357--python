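"""Stage 2: voxel-wise detection of initial microbleed candidates.

Seven per-voxel features are computed on the vessel-removed (and brain-mask
standardized) image, each normalized by its per-image maximum absolute
value:

1. ``intensity``      — the vessel-removed intensity itself;
2. ``exp_intensity``  — exp(p x standardized intensity), p = 1;
3. ``clahe``          — slice-wise contrast-limited adaptive histogram
                        equalization, clip limit 0.01;
4. ``frst_mean``      — fast radial symmetry transform (dark symmetry only),
                        averaged over radii {2, 3, 4, 6} voxels;
5. ``st_lambda1``     — principal eigenvalue of the 2-D structure tensor;
6. ``blobness``       — I - GaussianSmooth(I, sigma = 1.5 voxels), a
                        high-pass "blobness" residual;
7. ``log``            — Laplacian of Gaussian, sigma = 1.5 voxels.

A kernel SVM with Platt probability calibration maps each in-brain
7-vector to P(CMB); thresholding the probability map at th_prob (default
0.8, selected on FROC sweeps) gives the initial candidate mask that stage 3
filters by shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.exposure import equalize_adapthist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import VolumeImage
from .vessels import structure_tensor_features

__all__ = [
    "FeatureConfig",
    "VoxelFeatureStack",
    "CandidateModel",
    "FEATURE_NAMES",
    "clahe_map",
    "exp_intensity",
    "frst_map",
    "blobness_map",
    "log_map",
    "assemble_features",
    "sample_training_voxels",
    "train_voxel_classifier",
    "predict_probability",
    "threshold_candidates",
    "sweep_th_prob",
]

FEATURE_NAMES = (
    "intensity",
    "exp_intensity",
    "clahe",
    "frst_mean",
    "st_lambda1",
    "blobness",
    "log",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction and thresholding parameters for stage 2."""

    p: float = 1.0
    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    frst_radii_vox: tuple[int, ...] = (2, 3, 4, 6)
    frst_alpha: float = 2.0
    frst_grad_floor_pct: float = 5.0
    sigma_blob_vox: float = 1.5
    sigma_log_vox: float = 1.5
    sigma_st_grad: float = 1.0
    sigma_st_window: float = 1.5
    th_prob: float = 0.8
    neg_pos_ratio: int = 10

    def __post_init__(self):
        if not (0 <= self.th_prob <= 1):
            raise ValueError("th_prob must lie in [0, 1]")
        if any(r <= 0 for r in self.frst_radii_vox):
            raise ValueError("FRST radii must be positive")
        if self.sigma_blob_vox <= 0 or self.sigma_log_vox <= 0:
            raise ValueError("sigmas must be positive")
        if self.clahe_clip <= 0:
            raise ValueError("clahe clip limit must be positive")


@dataclass
class VoxelFeatureStack:
    """Seven aligned per-voxel maps, max-|value| normalized per image."""

    maps: dict
    feature_names: tuple = FEATURE_NAMES

    def matrix(self, mask: np.ndarray) -> np.ndarray:
        """(n_voxels, 7) feature matrix over ``mask`` voxels in scan order."""
        mask = np.asarray(mask) > 0
        return np.column_stack([self.maps[name][mask] for name in self.feature_names])


@dataclass
class CandidateModel:
    """Trained voxel classifier + the feature configuration it expects."""

    estimator: Pipeline
    config: FeatureConfig
    feature_names: tuple = FEATURE_NAMES
    metadata: dict = field(default_factory=dict)


def clahe_map(vol: VolumeImage, mask: np.ndarray, clip: float = 0.01, tiles: int = 8) -> np.ndarray:
    """Slice-wise CLAHE on intensities min-max rescaled to [0, 1] per volume.

    Constant slices (rescale undefined) are returned as zeros with a warning.
    Output is bounded in [0, 1].
    """
    if clip <= 0:
        raise ValueError("clip must be positive")
    data = vol.voxels.astype(np.float64)
    lo, hi = data.min(), data.max()
    out = np.zeros_like(data)
    if hi == lo:
        warnings.warn("constant volume: CLAHE undefined, returning zeros")
        return out
    scaled = (data - lo) / (hi - lo)
    nx, ny = data.shape[:2]
    kernel = (max(nx // tiles, 1), max(ny // tiles, 1))
    n_const = 0
    for z in range(data.shape[2]):
        sl = scaled[:, :, z]
        if np.ptp(sl) == 0:
            n_const += 1
            continue
        out[:, :, z] = equalize_adapthist(sl, kernel_size=kernel, clip_limit=clip)
    if n_const:
        warnings.warn(f"{n_const} constant slice(s): CLAHE skipped there")
    return np.clip(out, 0.0, 1.0)


def exp_intensity(std_vol: VolumeImage, p: float = 1.0) -> np.ndarray:
    """exp(p x intensity) on the standardized image; clipped at |p x I| = 50."""
    x = p * std_vol.voxels.astype(np.float64)
    if np.any(np.abs(x) > 50):
        warnings.warn("exp feature clipped to avoid overflow")
        x = np.clip(x, -50, 50)
    return np.exp(x)


def frst_map(
    vol: VolumeImage,
    mask: np.ndarray,
    radii=(2, 3, 4, 6),
    alpha: float = 2.0,
    grad_floor_pct: float = 5.0,
) -> np.ndarray:
    """Slice-wise fast radial symmetry transform, dark symmetry only.

    For each radius n, every pixel with gradient magnitude above the
    per-slice floor votes at its *negatively affected* position
    ``x - round(n * ghat)`` (dark centers lie opposite the gradient, which
    points from dark to bright).  Orientation and magnitude accumulators are
    combined as ``(|O~|/k_n)^alpha * |M|/k_n`` and smoothed with a Gaussian
    of sigma = n/2; outputs are averaged over radii.  Large positive values
    mean strong dark radial symmetry.  Radii that do not fit the slice are
    skipped with a warning.
    """
    if len(radii) == 0:
        raise ValueError("need at least one radius")
    mask = np.asarray(mask) > 0
    data = vol.voxels.astype(np.float64)
    nx, ny, nz = data.shape
    usable = [int(n) for n in radii if 2 * n + 1 < min(nx, ny)]
    if len(usable) < len(radii):
        warnings.warn("FRST radius >= slice extent skipped")
    out = np.zeros_like(data)
    if not usable:
        return out
    for z in range(nz):
        sl = data[:, :, z]
        gx, gy = np.gradient(sl)
        mag = np.hypot(gx, gy)
        if mag.max() == 0:
            continue
        floor = np.percentile(mag[mag > 0], grad_floor_pct)
        sel = mag > floor
        if not sel.any():
            continue
        px, py = np.nonzero(sel)
        ghx = gx[sel] / mag[sel]
        ghy = gy[sel] / mag[sel]
        gmag = mag[sel]
        acc = np.zeros((nx, ny))
        for n in usable:
            qx = px - np.round(n * ghx).astype(int)
            qy = py - np.round(n * ghy).astype(int)
            ok = (qx >= 0) & (qx < nx) & (qy >= 0) & (qy < ny)
            O = np.zeros((nx, ny))
            M = np.zeros((nx, ny))
            np.add.at(O, (qx[ok], qy[ok]), 1.0)
            np.add.at(M, (qx[ok], qy[ok]), gmag[ok])
            kn = 8.0 if n == 1 else 9.9
            F = (np.minimum(O, kn) / kn) ** alpha * (M / kn)
            acc += ndi.gaussian_filter(F, sigma=n / 2.0)
        out[:, :, z] = acc / len(usable)
    out[~mask] = 0.0
    return out


def blobness_map(vol: VolumeImage, sigma: float = 1.5) -> np.ndarray:
    """High-pass residual I - GaussianSmooth(I, sigma), slice-wise."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = vol.voxels.astype(np.float64)
    out = np.empty_like(data)
    for z in range(data.shape[2]):
        out[:, :, z] = data[:, :, z] - ndi.gaussian_filter(data[:, :, z], sigma)
    return out


def log_map(vol: VolumeImage, sigma: float = 1.5) -> np.ndarray:
    """Slice-wise Laplacian-of-Gaussian response."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data = vol.voxels.astype(np.float64)
    out = np.empty_like(data)
    for z in range(data.shape[2]):
        out[:, :, z] = ndi.gaussian_laplace(data[:, :, z], sigma)
    return out


def _normalize(m: np.ndarray) -> np.ndarray:
    peak = np.abs(m).max()
    return m if peak == 0 else m / peak


def assemble_features(
    vessel_removed: VolumeImage, mask: np.ndarray, cfg: FeatureConfig = FeatureConfig()
) -> VoxelFeatureStack:
    """Compute the 7 feature maps, each divided by its per-image max |value|.

    ``vessel_removed`` is expected in standardized units (mean 0 / sd 1
    within the brain mask), so the raw-intensity and exponential features
    operate on the same scale across subjects and scanners.  Any non-finite
    value within the brain mask raises an error naming the feature.
    """
    mask = np.asarray(mask) > 0
    builders = {
        "intensity": lambda: vessel_removed.voxels.astype(np.float64),
        "exp_intensity": lambda: exp_intensity(vessel_removed, cfg.p),
        "clahe": lambda: clahe_map(vessel_removed, mask, cfg.clahe_clip, cfg.clahe_tiles),
        "frst_mean": lambda: frst_map(
            vessel_removed, mask, cfg.frst_radii_vox, cfg.frst_alpha, cfg.frst_grad_floor_pct
        ),
        "st_lambda1": lambda: structure_tensor_features(
            vessel_removed, cfg.sigma_st_grad, cfg.sigma_st_window
        ).lambda1,
        "blobness": lambda: blobness_map(vessel_removed, cfg.sigma_blob_vox),
        "log": lambda: log_map(vessel_removed, cfg.sigma_log_vox),
    }
    maps = {}
    for name in FEATURE_NAMES:
        m = builders[name]()
        if not np.isfinite(m[mask]).all():
            raise ValueError(f"non-finite values in feature '{name}' within brain mask")
        maps[name] = _normalize(m)
    return VoxelFeatureStack(maps=maps)


def sample_training_voxels(
    stack: VoxelFeatureStack,
    truth: np.ndarray,
    brain_mask: np.ndarray,
    neg_pos_ratio: int = 10,
    seed: int = 0,
    exclude_positives: np.ndarray | None = None,
):
    """Training rows for one subject: all positives + sampled negatives.

    All truth voxels are kept as positives; negatives are drawn uniformly
    without replacement from in-brain background at ``neg_pos_ratio`` per
    positive.  ``exclude_positives`` (typically the stage-1 vessel mask)
    drops truth voxels that were painted over during vessel removal: an
    inpainted voxel no longer carries lesion signal, and labelling it
    positive would inject label noise.  Returns ``(X, y)``.
    """
    truth = np.asarray(truth)
    brain_mask = np.asarray(brain_mask) > 0
    pos_mask = (truth > 0) & brain_mask
    if exclude_positives is not None:
        pos_mask &= ~(np.asarray(exclude_positives) > 0)
    n_pos = int(pos_mask.sum())
    if n_pos == 0:
        raise ValueError("no positive voxels in truth mask")
    neg_mask = brain_mask & (truth == 0)
    neg_idx = np.flatnonzero(neg_mask.ravel())
    rng = np.random.default_rng(seed)
    n_neg = min(neg_pos_ratio * n_pos, len(neg_idx))
    chosen = rng.choice(neg_idx, size=n_neg, replace=False)
    sel_neg = np.zeros(truth.size, dtype=bool)
    sel_neg[chosen] = True
    sel_neg = sel_neg.reshape(truth.shape)
    X = np.vstack([stack.matrix(pos_mask), stack.matrix(sel_neg)])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    return X, y


def train_voxel_classifier(
    training_sets, cfg: FeatureConfig = FeatureConfig(), seed: int = 0, metadata: dict | None = None
) -> CandidateModel:
    """Fit the probabilistic voxel classifier on pooled training rows.

    ``training_sets`` is an iterable of ``(X, y)`` pairs (one per subject).
    The classifier is an RBF-kernel SVM with Platt-style probability
    calibration (internal cross-validated sigmoid fit); inputs are scaled to
    zero mean / unit variance first.  Both classes must be present.
    """
    Xs, ys = zip(*training_sets)
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(kernel="rbf", C=1.0, random_state=int(seed) % (2**31), cache_size=500)
    est = Pipeline(
        [
            ("scale", StandardScaler()),
            # Platt-style sigmoid calibration fitted on internal CV folds
            ("svm", CalibratedClassifierCV(svc, method="sigmoid", cv=5, ensemble=False)),
        ]
    )
    est.fit(X, y)
    meta = {"n_pos": int((y == 1).sum()), "n_neg": int((y == 0).sum()), "seed": int(seed)}
    if metadata:
        meta.update(metadata)
    return CandidateModel(estimator=est, config=cfg, metadata=meta)


def predict_probability(model: CandidateModel, stack: VoxelFeatureStack, mask: np.ndarray) -> np.ndarray:
    """Per-voxel P(CMB) map; voxels outside the brain mask are 0."""
    if tuple(stack.feature_names) != tuple(model.feature_names):
        raise ValueError("feature stack does not match the model's feature set")
    mask = np.asarray(mask) > 0
    X = stack.matrix(mask)
    p_map = np.zeros(mask.shape, dtype=np.float64)
    if len(X):
        probs = model.estimator.predict_proba(X)[:, 1]
        p_map[mask] = probs
    return p_map


def threshold_candidates(p_map: np.ndarray, th_prob: float = 0.8) -> np.ndarray:
    """Initial candidate mask: voxels with P(CMB) strictly above th_prob."""
    return np.asarray(p_map) > th_prob


def sweep_th_prob(model: CandidateModel, subjects, grid=None):
    """Cluster-wise FROC sweep of th_prob over a phantom/labelled cohort.

    ``subjects`` is an iterable of ``(p_map, truth_labels)`` pairs.  Returns
    a list of dicts with threshold, cluster-wise TPR and FPavg — the table
    used to pick the operating threshold (highest TPR at acceptable FPavg).
    """
    from .metrics import cluster_metrics

    if grid is None:
        grid = np.round(np.arange(0.0, 1.01, 0.1), 10)
    subjects = list(subjects)
    rows = []
    for th in grid:
        detected = [threshold_candidates(p, th) for p, _ in subjects]
        truths = [t for _, t in subjects]
        tpr, fpavg, _ = cluster_metrics(detected, truths)
        rows.append({"th_prob": float(th), "cluster_tpr": tpr, "fpavg": fpavg})
    return rows
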