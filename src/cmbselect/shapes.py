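"""Stage 3: shape-based filtering of initial candidate components.

Candidate voxels are grouped into 26-connected components and each component
is reduced to four physical shape attributes:

* volume V_c   (mm^3)  — voxel count x voxel volume; kept if 5 < V_c < 120;
* ellipticity e_c      — 1 - minor/major principal-axis ratio on the
  component's maximal-area axial slice (0 for a sphere); kept if e_c < 0.2;
* solidity S_c         — component volume / convex volume (1 for convex
  shapes); kept if S_c >= 0.6;
* diameter D_c (mm)    — longest line through the candidate, i.e. the max
  pairwise distance between voxel centers; kept if 2 < D_c < 10.

A candidate is retained only if *all* criteria hold.  Ellipticity is
evaluated in-plane because 3-5 mm slices make the through-plane extent of a
genuinely spherical 2-5 mm lesion an artefact of anisotropy, and solidity
falls back to the in-plane area ratio for single-slice components, where a
3-D hull is degenerate.  Elongated vessel fragments fail on ellipticity,
diameter or (for curved fragments) solidity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist

__all__ = [
    "ShapeCriteria",
    "CandidateComponent",
    "label_components",
    "compute_shape_attributes",
    "filter_candidates",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ShapeCriteria:
    """Pass bands for the four shape attributes.

    Volume and diameter bounds are open intervals (strict inequalities on
    both sides); ellipticity is a strict upper bound; solidity an inclusive
    lower bound.
    """

    vol_range_mm3: tuple[float, float] = (5.0, 120.0)
    ellipticity_max: float = 0.2
    solidity_min: float = 0.6
    diameter_range_mm: tuple[float, float] = (2.0, 10.0)

    def __post_init__(self):
        if self.vol_range_mm3[0] >= self.vol_range_mm3[1]:
            raise ValueError("volume range must be nonempty")
        if self.diameter_range_mm[0] >= self.diameter_range_mm[1]:
            raise ValueError("diameter range must be nonempty")
        if not (0 <= self.ellipticity_max <= 1) or not (0 <= self.solidity_min <= 1):
            raise ValueError("ellipticity/solidity thresholds must lie in [0, 1]")


@dataclass
class CandidateComponent:
    """A 26-connected candidate cluster and its physical shape attributes."""

    indices: np.ndarray  # (n, 3) voxel indices
    label: int = 0
    centroid_mm: np.ndarray | None = None
    volume_mm3: float | None = None
    ellipticity: float | None = None
    solidity: float | None = None
    diameter_mm: float | None = None
    passes: bool | None = None
    criterion_flags: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return len(self.indices)


def label_components(cmask: np.ndarray) -> list[CandidateComponent]:
    """Maximal 26-connected components of a candidate mask, in scan order."""
    cmask = np.asarray(cmask) > 0
    labels, n = ndi.label(cmask, structure=_STRUCT_26)
    comps = []
    for obj_slice, lab in zip(ndi.find_objects(labels), range(1, n + 1)):
        local = np.argwhere(labels[obj_slice] == lab)
        offset = np.array([s.start for s in obj_slice])
        comps.append(CandidateComponent(indices=local + offset, label=lab))
    return comps


def _convex_count(points: np.ndarray) -> int | None:
    """Number of integer lattice points inside the convex hull of ``points``.

    Returns None when the hull is degenerate (affinely dependent points).
    """
    if len(points) <= points.shape[1]:
        return None
    try:
        tri = Delaunay(points)
    except QhullError:
        return None
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, points.shape[1])
    inside = tri.find_simplex(grid) >= 0
    return int(inside.sum())


def compute_shape_attributes(
    comp: CandidateComponent, voxel_size_mm
) -> CandidateComponent:
    """Fill in volume, ellipticity, solidity and diameter for a component.

    All attributes are physical (mm), using voxel-center coordinates scaled
    by the voxel dimensions.  Components that are too degenerate for a 3-D
    convex hull (coplanar/collinear) use the in-plane 2-D hull on their
    maximal-area axial slice; a component with no measurable hull at all
    (single voxel, straight line of voxels) is convex by construction and
    gets solidity 1.
    """
    if comp.n_voxels == 0:
        raise ValueError("component is empty")
    spacing = np.asarray(voxel_size_mm, dtype=float)
    idx = np.asarray(comp.indices)
    coords = idx * spacing

    comp.centroid_mm = coords.mean(axis=0)
    comp.volume_mm3 = float(comp.n_voxels * spacing.prod())

    # diameter: longest line through the candidate.  Voxels are extended
    # patches, not points, so the line runs edge-to-edge: max pairwise
    # center distance plus one in-plane pitch for the two end-voxel halves.
    # A single voxel spans exactly one pitch.
    pitch = float(max(spacing[0], spacing[1]))
    if comp.n_voxels == 1:
        comp.diameter_mm = pitch
    else:
        comp.diameter_mm = float(pdist(coords).max() + pitch)

    # ellipticity from 2-D second moments on the maximal-area axial slice;
    # each voxel contributes its own patch moment s^2/12 so that tiny
    # components are measured as solid squares rather than point sets
    zs, counts = np.unique(idx[:, 2], return_counts=True)
    z_best = zs[counts.argmax()]
    in_slice = idx[idx[:, 2] == z_best]
    plane = in_slice[:, :2] * spacing[:2]
    if len(plane) < 1:
        comp.ellipticity = 0.0
    else:
        cov = np.zeros((2, 2)) if len(plane) == 1 else np.atleast_2d(np.cov(plane.T, bias=True))
        cov = cov + np.diag(spacing[:2] ** 2) / 12.0
        evals = np.linalg.eigvalsh(cov)
        major = float(np.sqrt(max(evals.max(), 0.0)))
        minor = float(np.sqrt(max(evals.min(), 0.0)))
        comp.ellipticity = 0.0 if major == 0 else 1.0 - minor / major

    # solidity: lattice-count ratio against the rasterized convex hull
    # (affine-invariant, so anisotropic spacing drops out)
    n_inside = _convex_count(idx.astype(float))
    if n_inside is not None:
        comp.solidity = float(comp.n_voxels / n_inside)
    else:
        n_inside_2d = _convex_count(in_slice[:, :2].astype(float))
        if n_inside_2d is not None:
            comp.solidity = float(len(in_slice) / n_inside_2d)
        else:
            comp.solidity = 1.0
    comp.solidity = float(min(comp.solidity, 1.0))
    return comp


def filter_candidates(
    components: list[CandidateComponent], criteria: ShapeCriteria = ShapeCriteria()
) -> list[CandidateComponent]:
    """Keep components satisfying all four shape criteria.

    Per-criterion pass flags are recorded on every component for QC; the
    returned list contains only the survivors.
    """
    vlo, vhi = criteria.vol_range_mm3
    dlo, dhi = criteria.diameter_range_mm
    survivors = []
    for comp in components:
        if comp.volume_mm3 is None:
            raise ValueError("component attributes not computed")
        flags = {
            "volume": vlo < comp.volume_mm3 < vhi,
            "ellipticity": comp.ellipticity < criteria.ellipticity_max,
            "solidity": comp.solidity >= criteria.solidity_min,
            "diameter": dlo < comp.diameter_mm < dhi,
        }
        comp.criterion_flags = flags
        comp.passes = all(flags.values())
        if comp.passes:
            survivors.append(comp)
    return survivors
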