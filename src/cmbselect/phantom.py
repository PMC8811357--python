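"""Seed-reproducible synthetic SWI/T2*-GRE-like phantom volumes.

Real susceptibility-weighted cohorts with voxel-wise microbleed labels are
access-restricted, so training and evaluation here run on phantoms that
emulate the structures the pipeline must tell apart:

* dark quasi-spherical microbleeds (CMBs), 2-10 mm by convention;
* dark curved tubes mimicking vessel flow voids;
* dark ribbons hugging the brain-mask surface, mimicking sulci;
* optionally one large dark blob mimicking a haemorrhage;
* a smooth background with additive Gaussian noise.

Objects darken a flat background multiplicatively (intensity =
background x (1 - contrast)), so contrast is scale-free.  Voxel membership
for every object is decided by the physical position of the voxel *center*,
and the default grid is anisotropic (0.8 x 0.8 x 3 mm) to mirror typical
3-D SWI acquisitions.  All randomness flows from the spec seed through one
:class:`numpy.random.Generator`, so identical specs give bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .preprocess import VolumeImage

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "PlacementError",
    "generate_phantom",
    "generate_cohort",
    "rasterize_ellipsoid",
    "rasterize_tube",
]


class PlacementError(RuntimeError):
    """An object class could not be placed after bounded retries."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic subject.

    ``cmb_diameter_range_mm`` must stay within the conventional 2-10 mm
    microbleed size band; the default restricts to 4.0-5.8 mm, the
    sub-range that a 0.8 x 0.8 x 3 mm grid can represent as measurable
    objects: smaller spheres rasterize to degenerate few-voxel components
    (partial-volume loss at 3 mm slices), larger ones exceed the 120 mm^3
    lesion-volume convention (see docs/methods.md).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 3.0)
    background_level: float = 100.0
    noise_sd: float = 5.0
    n_cmbs: int = 4
    cmb_diameter_range_mm: tuple[float, float] = (4.0, 5.8)
    cmb_contrast: float = 0.5
    n_vessels: int = 3
    vessel_radius_range_mm: tuple[float, float] = (0.6, 1.2)
    vessel_contrast: float = 0.5
    sulci_density: float = 2.0
    haemorrhage: bool = False
    haemorrhage_diameter_mm: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(
            g < m for g, m in zip(self.grid_shape, (32, 32, 8))
        ):
            raise ValueError("grid_shape must be a triple >= (32, 32, 8)")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        lo, hi = self.cmb_diameter_range_mm
        if not (2.0 <= lo <= hi <= 10.0):
            raise ValueError("cmb_diameter_range_mm must be a nonempty interval within [2, 10]")
        vlo, vhi = self.vessel_radius_range_mm
        if not (0 < vlo <= vhi):
            raise ValueError("vessel_radius_range_mm must be a nonempty positive interval")
        if not (0 < self.cmb_contrast <= 1) or not (0 < self.vessel_contrast <= 1):
            raise ValueError("contrasts must lie in (0, 1]")
        if self.noise_sd < 0 or self.sulci_density < 0:
            raise ValueError("noise_sd and sulci_density must be nonnegative")
        if self.n_cmbs < 0 or self.n_vessels < 0:
            raise ValueError("object counts must be nonnegative")


@dataclass
class PhantomSubject:
    """One synthetic subject: image, brain mask, labeled CMB truth.

    ``vessel_mask`` marks the tubular vessel mimics only; ``mimic_mask``
    additionally includes sulcal ribbons and any haemorrhage blob.  Both are
    generator truth for QC of the vessel-removal stage.
    """

    image: VolumeImage
    brain_mask: np.ndarray
    cmb_truth: np.ndarray
    has_cmb: bool
    placed_cmb_count: int
    spec: PhantomSpec
    vessel_mask: np.ndarray | None = None
    mimic_mask: np.ndarray | None = None
    subject_id: str | None = None


def _voxel_centers(grid_shape, voxel_size_mm):
    """Physical coordinates (mm) of voxel centers: index * spacing."""
    axes = [np.arange(n) * s for n, s in zip(grid_shape, voxel_size_mm)]
    return axes


def rasterize_ellipsoid(center_mm, semi_axes_mm, grid_shape, voxel_size_mm) -> np.ndarray:
    """Binary mask of voxels whose centers lie inside an ellipsoid.

    An ellipsoid entirely outside the grid yields an empty mask.
    """
    semi = np.asarray(semi_axes_mm, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    ax, ay, az = _voxel_centers(grid_shape, voxel_size_mm)
    cx, cy, cz = center_mm
    dx = ((ax - cx) / semi[0]) ** 2
    dy = ((ay - cy) / semi[1]) ** 2
    dz = ((az - cz) / semi[2]) ** 2
    return (
        dx[:, None, None] + dy[None, :, None] + dz[None, None, :]
    ) <= 1.0


def rasterize_tube(path_points_mm, radius_mm, grid_shape, voxel_size_mm) -> np.ndarray:
    """Binary mask of voxels whose centers lie within ``radius_mm`` of a polyline.

    A zero-length path degenerates to a sphere around the single point.
    Only the bounding box of the inflated path is scanned, so rasterizing
    short tubes in large grids stays cheap.
    """
    pts = np.atleast_2d(np.asarray(path_points_mm, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one path point")
    spacing = np.asarray(voxel_size_mm, dtype=float)
    grid_shape = tuple(grid_shape)
    lo = np.maximum(np.floor((pts.min(axis=0) - radius_mm) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((pts.max(axis=0) + radius_mm) / spacing).astype(int) + 1,
        np.asarray(grid_shape),
    )
    out = np.zeros(grid_shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    axes = [np.arange(l, h) * s for l, h, s in zip(lo, hi, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([X, Y, Z], axis=-1)  # (nx, ny, nz, 3)
    mind = np.full(coords.shape[:-1], np.inf)
    if pts.shape[0] == 1:
        mind = np.linalg.norm(coords - pts[0], axis=-1)
    else:
        for a, b in zip(pts[:-1], pts[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                d = np.linalg.norm(coords - a, axis=-1)
            else:
                t = np.clip(((coords - a) @ ab) / denom, 0.0, 1.0)
                proj = a + t[..., None] * ab
                d = np.linalg.norm(coords - proj, axis=-1)
            mind = np.minimum(mind, d)
    sub = mind <= radius_mm
    out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return out


def _brain_ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.voxel_size_mm)
    center = (np.asarray(spec.grid_shape) - 1) / 2 * np.asarray(spec.voxel_size_mm)
    semi = 0.44 * extent
    return rasterize_ellipsoid(center, semi, spec.grid_shape, spec.voxel_size_mm)


def _random_inmask_point(rng, mask, spacing):
    idx = np.argwhere(mask)
    i = rng.integers(len(idx))
    return idx[i] * spacing


def _vessel_path(rng, start_mm, spacing, length_mm):
    """Smooth low-order random walk, mostly in-plane (thick slices)."""
    step = 1.2
    n = max(int(length_mm / step), 3)
    theta = rng.uniform(0, 2 * np.pi)
    dz = rng.normal(0, 0.15)
    pts = [np.asarray(start_mm, dtype=float)]
    for _ in range(n):
        theta += rng.normal(0, 0.25)
        dz += rng.normal(0, 0.05)
        d = np.array([np.cos(theta), np.sin(theta), np.clip(dz, -0.3, 0.3)])
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + step * d)
    return np.asarray(pts)


def _sulcus_path(rng, shell, spacing, max_len=35):
    """Random walk over 26-neighbours constrained to the mask shell."""
    shell_idx = np.argwhere(shell)
    cur = tuple(shell_idx[rng.integers(len(shell_idx))])
    visited = {cur}
    path = [np.asarray(cur) * spacing]
    offsets = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
         if (i, j, k) != (0, 0, 0)]
    )
    for _ in range(max_len):
        nbrs = np.asarray(cur) + offsets
        ok = []
        for nb in nbrs:
            t = tuple(nb)
            if (
                all(0 <= c < s for c, s in zip(t, shell.shape))
                and shell[t]
                and t not in visited
            ):
                ok.append(t)
        if not ok:
            break
        cur = ok[rng.integers(len(ok))]
        visited.add(cur)
        path.append(np.asarray(cur) * spacing)
    return np.asarray(path)


def generate_phantom(spec: PhantomSpec) -> PhantomSubject:
    """Generate one phantom subject from ``spec``.

    Vessels and sulci are placed first; CMBs are then placed with bounded
    retries so that they overlap neither each other nor any mimic (a
    one-voxel dilated exclusion zone keeps truth components separable under
    26-connectivity).  Raises :class:`PlacementError` naming the object
    class if a requested object cannot fit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_size_mm, dtype=float)
    mask = _brain_ellipsoid_mask(spec)

    mimic = np.zeros(spec.grid_shape, dtype=bool)
    vessels = np.zeros(spec.grid_shape, dtype=bool)

    # vessels: dark curved tubes
    for _ in range(spec.n_vessels):
        placed = False
        for _attempt in range(200):
            start = _random_inmask_point(rng, mask, spacing)
            path = _vessel_path(rng, start, spacing, length_mm=rng.uniform(25, 50))
            radius = rng.uniform(*spec.vessel_radius_range_mm)
            tube = rasterize_tube(path, radius, spec.grid_shape, spec.voxel_size_mm) & mask
            if tube.sum() >= 10:
                vessels |= tube
                mimic |= tube
                placed = True
                break
        if not placed:
            raise PlacementError("could not place object class 'vessel'")

    # sulci: darkened ribbons within ~2 voxels of the mask surface
    n_sulci = int(rng.poisson(spec.sulci_density)) if spec.sulci_density > 0 else 0
    if n_sulci:
        shell = mask & ~ndi.binary_erosion(mask, iterations=2)
        for _ in range(n_sulci):
            path = _sulcus_path(rng, shell, spacing)
            if len(path) < 3:
                continue
            ribbon = rasterize_tube(path, 0.9, spec.grid_shape, spec.voxel_size_mm) & shell
            mimic |= ribbon

    # optional large haemorrhage blob
    if spec.haemorrhage:
        placed = False
        r = spec.haemorrhage_diameter_mm / 2
        inner = ndi.binary_erosion(mask, iterations=3)
        for _attempt in range(200):
            c = _random_inmask_point(rng, inner, spacing)
            blob = rasterize_ellipsoid(c, (r, r, r), spec.grid_shape, spec.voxel_size_mm) & mask
            if blob.sum() >= 8:
                mimic |= blob
                placed = True
                break
        if not placed:
            raise PlacementError("could not place object class 'haemorrhage'")

    # CMBs: dark spheres, non-overlapping with mimics and each other
    truth = np.zeros(spec.grid_shape, dtype=np.int32)
    occupied = ndi.binary_dilation(mimic, iterations=1)
    inner = ndi.binary_erosion(mask, iterations=2)
    if not inner.any():
        inner = mask
    placed_count = 0
    for k in range(1, spec.n_cmbs + 1):
        placed = False
        for _attempt in range(300):
            d = rng.uniform(*spec.cmb_diameter_range_mm)
            c = _random_inmask_point(rng, inner, spacing) + rng.uniform(-0.5, 0.5, 3) * spacing
            sph = rasterize_ellipsoid(c, (d / 2, d / 2, d / 2), spec.grid_shape, spec.voxel_size_mm)
            sph &= mask
            if not sph.any():
                continue
            if (sph & occupied).any():
                continue
            truth[sph] = k
            occupied |= ndi.binary_dilation(sph, iterations=1)
            placed = True
            break
        if not placed:
            raise PlacementError("could not place object class 'cmb'")
        placed_count += 1

    image = np.zeros(spec.grid_shape, dtype=np.float64)
    image[mask] = spec.background_level
    image[mimic] *= 1.0 - spec.vessel_contrast
    image[truth > 0] = spec.background_level * (1.0 - spec.cmb_contrast)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, spec.grid_shape)

    vol = VolumeImage.from_voxel_size(image, spec.voxel_size_mm)
    return PhantomSubject(
        image=vol,
        brain_mask=mask,
        cmb_truth=truth,
        has_cmb=placed_count > 0,
        placed_cmb_count=placed_count,
        spec=spec,
        vessel_mask=vessels,
        mimic_mask=mimic,
    )


def generate_cohort(
    n_subjects: int,
    prevalence: float,
    spec_template: PhantomSpec,
    seed: int,
    cmb_count_range: tuple[int, int] = (2, 6),
) -> list[PhantomSubject]:
    """Generate a cohort with a fixed CMB-subject prevalence.

    ``round(prevalence * n_subjects)`` subjects receive a CMB count drawn
    uniformly from ``cmb_count_range``; the rest receive none.  Per-subject
    seeds are derived deterministically from ``seed``, and positive/negative
    status is assigned by a seeded shuffle.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0 <= prevalence <= 1:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = int(round(prevalence * n_subjects))
    status = np.zeros(n_subjects, dtype=bool)
    status[:n_pos] = True
    rng.shuffle(status)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    subjects = []
    for i in range(n_subjects):
        if status[i]:
            n_cmbs = int(rng.integers(cmb_count_range[0], cmb_count_range[1] + 1))
        else:
            n_cmbs = 0
        spec = replace(spec_template, n_cmbs=n_cmbs, seed=int(sub_seeds[i]))
        subj = generate_phantom(spec)
        subj.subject_id = f"sub-{i:03d}"
        subjects.append(subj)
    return subjects


def write_cohort(subjects: list[PhantomSubject], out_dir) -> "pandas.DataFrame":
    """Write a cohort to NIfTI + manifest CSV (+ per-subject spec YAML)."""
    import pandas as pd
    import yaml
    from pathlib import Path

    from .preprocess import write_mask, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sid = s.subject_id or "sub"
        img_p = out / f"{sid}_image.nii"
        msk_p = out / f"{sid}_mask.nii"
        tru_p = out / f"{sid}_truth.nii"
        write_volume(s.image, img_p)
        write_mask(s.brain_mask, s.image, msk_p)
        write_mask(s.cmb_truth, s.image, tru_p)
        with open(out / f"{sid}_spec.yaml", "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in s.spec.__dict__.items()},
                fh,
            )
        rows.append(
            dict(
                subject_id=sid,
                image=str(img_p),
                mask=str(msk_p),
                truth=str(tru_p),
                has_cmb=bool(s.has_cmb),
                n_cmbs=int(s.placed_cmb_count),
                seed=int(s.spec.seed),
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
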