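"""Synthetic reference space, atlas assets, tumors, and rater noise.

Everything the pipeline consumes can be generated here without any
download: a mirror-symmetric ellipsoidal "brain" in a reference grid
whose midsagittal plane sits at world x = 0, a parcellation of that
brain into mirrored parcel pairs, tube-shaped white-matter "tracts", a
smooth resection probability map, multi-focus spherical tumors, and a
structured second-rater perturbation (boundary jitter, dropped satellite
components, added false components) that emulates how human and
automated segmentations actually disagree — at boundaries and whole
components, not as i.i.d. voxel flips.

All generators are deterministic for a fixed seed.  Geometry is
specified in world mm so fixtures are resolution-independent; the
default grid is 64 voxels at 2 mm per axis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DomainError, ValidationError
from .grids import (
    AtlasBundle,
    NATIVE,
    REFERENCE,
    TumorMask,
    VolumeGrid,
    save_mask,
    save_volume,
)

DEFAULT_SHAPE = (64, 64, 64)
DEFAULT_SPACING = (2.0, 2.0, 2.0)

_TRACT_BASENAMES = (
    "corticospinal_tract",
    "arcuate_fasciculus",
    "optic_radiation",
    "inferior_fronto_occipital_fasciculus",
    "uncinate_fasciculus",
    "superior_longitudinal_fasciculus",
    "frontal_aslant_tract",
    "inferior_longitudinal_fasciculus",
)


@dataclass(frozen=True)
class TumorSpec:
    """Planted tumor: a union of spheres given as (center_mm, radius_mm).

    The first focus is the main component; later foci are satellites.
    """

    foci: tuple[tuple[tuple[float, float, float], float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.foci:
            raise DomainError("need at least one focus")
        for _, r in self.foci:
            if r <= 0:
                raise DomainError("focus radii must be positive")


@dataclass(frozen=True)
class RaterNoiseSpec:
    """Structured second-rater disagreement.

    ``boundary_jitter_mm`` bounds a random uniform dilation/erosion of
    the whole mask; ``drop_satellite_prob`` removes each non-largest
    component independently (missed satellite lesions);
    ``add_false_component_prob`` adds one small spurious component
    (vessel / choroid plexus mistaken for tumor).
    """

    boundary_jitter_mm: float = 0.0
    drop_satellite_prob: float = 0.0
    add_false_component_prob: float = 0.0
    false_component_radius_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.drop_satellite_prob, self.add_false_component_prob):
            if not 0.0 <= p <= 1.0:
                raise DomainError("probabilities must lie in [0, 1]")
        if self.boundary_jitter_mm < 0:
            raise DomainError("boundary_jitter_mm must be >= 0")


def _reference_affine(shape, spacing) -> np.ndarray:
    """RAS+ affine whose world origin is the grid center, so for an even
    x-dimension the midplane x = 0 falls between two voxel columns."""
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = spacing[ax]
        affine[ax, 3] = -(shape[ax] - 1) / 2.0 * spacing[ax]
    return affine


def _world_axes(grid: VolumeGrid):
    sp = grid.spacing
    a = grid.affine
    coords = [
        a[ax, ax] * np.arange(grid.shape[ax]) + a[ax, 3] for ax in range(3)
    ]
    return np.meshgrid(*coords, indexing="ij", sparse=True)


def make_reference_space(
    shape=DEFAULT_SHAPE, spacing=DEFAULT_SPACING, fill: float = 0.82
) -> VolumeGrid:
    """Ellipsoidal brain mask, exactly mirror-symmetric across x = 0.

    ``fill`` scales the semi-axes relative to the half field of view.
    The x-dimension must be even so no voxel column sits on the
    midplane.
    """
    if shape[0] % 2 != 0:
        raise DomainError("x-dimension must be even (midplane between columns)")
    grid = VolumeGrid(
        data=np.zeros(shape, dtype=np.uint8),
        affine=_reference_affine(shape, spacing),
        space=REFERENCE,
    )
    x, y, z = _world_axes(grid)
    semi = [fill * shape[ax] * spacing[ax] / 2.0 for ax in range(3)]
    inside = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0
    grid.data = inside.astype(np.uint8)
    return grid


def make_parcellation(
    brain: VolumeGrid, n_parcels: int, seed: int = 0
) -> tuple[VolumeGrid, pd.DataFrame]:
    """Voronoi parcellation of the brain into mirrored parcel pairs.

    ``n_parcels`` must be even: n/2 seed points are sampled in the right
    hemisphere, right-hemisphere voxels take the label of their nearest
    seed (world mm), and the left hemisphere is the exact mirror image.
    Labels: parcel i has right label 2i-1 and left label 2i.  With
    ``n_parcels == 2`` the parcels are exactly the two hemispheres.
    """
    if n_parcels % 2 != 0 or n_parcels < 2:
        raise DomainError("n_parcels must be even and >= 2")
    brain_fg = brain.data > 0
    if n_parcels > int(brain_fg.sum()):
        raise DomainError("more parcels than brain voxels")
    x, _, _ = _world_axes(brain)
    right = brain_fg & (np.broadcast_to(x, brain.shape) > 0)
    right_idx = np.argwhere(right)
    k = n_parcels // 2
    rng = np.random.default_rng(seed)
    seeds = right_idx[rng.choice(right_idx.shape[0], size=k, replace=False)]
    seed_world = brain.world_coordinates(seeds)
    tree = cKDTree(seed_world)
    _, nearest = tree.query(brain.world_coordinates(right_idx), k=1)

    labels = np.zeros(brain.shape, dtype=np.int32)
    labels[tuple(right_idx.T)] = 2 * (nearest + 1) - 1  # right: odd labels
    # mirror: flipping the first axis maps world x -> -x on this grid
    flipped = labels[::-1, :, :]
    left = brain_fg & (np.broadcast_to(x, brain.shape) < 0)
    labels[left] = flipped[left] + 1  # left: even labels

    rows = []
    for i in range(1, k + 1):
        rows.append({"label": 2 * i - 1, "name": f"parcel_{i:02d}_right", "group": "right"})
        rows.append({"label": 2 * i, "name": f"parcel_{i:02d}_left", "group": "left"})
    grid = VolumeGrid(data=labels, affine=brain.affine.copy(), space=REFERENCE)
    return grid, pd.DataFrame(rows)


def make_tracts(
    brain: VolumeGrid, n_tracts: int = 3, seed: int = 0, radius_mm: float = 4.0
) -> dict[str, VolumeGrid]:
    """Tube-shaped binary tract masks in mirrored left/right pairs.

    ``n_tracts`` is the number of pairs.  Each right-hemisphere tube runs
    between two random interior points; the left tract is its mirror.
    """
    if n_tracts < 1:
        raise DomainError("need at least one tract pair")
    rng = np.random.default_rng(seed)
    brain_fg = brain.data > 0
    x, _, _ = _world_axes(brain)
    # points well inside the right hemisphere
    eroded = ndimage.binary_erosion(brain_fg, iterations=2)
    candidates = np.argwhere(eroded & (np.broadcast_to(x, brain.shape) > 0))
    coords_all = np.argwhere(np.ones(brain.shape, dtype=bool))
    world_all = brain.world_coordinates(coords_all)

    tracts: dict[str, VolumeGrid] = {}
    for t in range(n_tracts):
        a, b = candidates[rng.choice(candidates.shape[0], size=2, replace=False)]
        wa, wb = brain.world_coordinates(np.stack([a, b]))
        # distance from each voxel center to the segment [wa, wb]
        ab = wb - wa
        tt = np.clip(((world_all - wa) @ ab) / max(float(ab @ ab), 1e-9), 0, 1)
        closest = wa + tt[:, None] * ab
        dist = np.linalg.norm(world_all - closest, axis=1)
        tube = (dist <= radius_mm).reshape(brain.shape) & brain_fg
        right_tube = tube & (np.broadcast_to(x, brain.shape) > 0)
        left_tube = right_tube[::-1, :, :]
        name = _TRACT_BASENAMES[t % len(_TRACT_BASENAMES)]
        if t >= len(_TRACT_BASENAMES):
            name = f"{name}_{t // len(_TRACT_BASENAMES) + 1}"
        tracts[f"{name}_right"] = VolumeGrid(
            data=right_tube.astype(np.uint8), affine=brain.affine.copy(), space=REFERENCE
        )
        tracts[f"{name}_left"] = VolumeGrid(
            data=left_tube.astype(np.uint8), affine=brain.affine.copy(), space=REFERENCE
        )
    return tracts


def make_resection_map(
    brain: VolumeGrid,
    mode: str = "radial",
    constant: float = 0.85,
    p_surface: float = 0.95,
    p_deep: float = 0.30,
) -> VolumeGrid:
    """Resection probability map in [0, 1], zero outside the brain.

    ``mode="constant"`` sets every brain voxel to ``constant`` (so the
    resectability index of any tumor equals it exactly — useful as an
    oracle).  ``mode="radial"`` interpolates from ``p_deep`` at the brain
    center to ``p_surface`` at the surface: superficial tissue is more
    often resected than deep central tissue.
    """
    x, y, z = _world_axes(brain)
    brain_fg = brain.data > 0
    if mode == "constant":
        p = np.where(brain_fg, float(constant), 0.0)
    elif mode == "radial":
        # normalized ellipsoidal radius, ~1 at the brain surface
        shape, sp = brain.shape, brain.spacing
        semi = [0.82 * shape[ax] * sp[ax] / 2.0 for ax in range(3)]
        r = np.sqrt((x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2)
        r = np.clip(np.broadcast_to(r, brain.shape), 0.0, 1.0)
        p = np.where(brain_fg, p_deep + (p_surface - p_deep) * r, 0.0)
    else:
        raise ValidationError(f"unknown resection map mode {mode!r}")
    return VolumeGrid(data=p, affine=brain.affine.copy(), space=REFERENCE)


def make_tumor(
    brain: VolumeGrid,
    spec: TumorSpec,
    native_scale: float | None = None,
) -> tuple[TumorMask, TumorMask | None]:
    """Union of spherical foci as a reference-space mask, plus an
    optional native-space copy.

    Every focus center must lie inside the brain.  The native copy, when
    requested, shares the voxel data but carries an affine scaled by
    ``native_scale`` per axis — emulating a patient brain smaller
    (scale < 1) or larger than the reference brain, so native and
    normalized volumes differ by the factor scale cubed.
    """
    x, y, z = _world_axes(brain)
    inside = np.zeros(brain.shape, dtype=bool)
    brain_fg = brain.data > 0
    for center, radius in spec.foci:
        cx, cy, cz = center
        # nearest voxel of the center must be in the brain
        inv = np.linalg.inv(brain.affine)
        idx = np.rint(inv[:3, :3] @ np.asarray(center, float) + inv[:3, 3]).astype(int)
        if (
            np.any(idx < 0)
            or np.any(idx >= np.asarray(brain.shape))
            or not brain_fg[tuple(idx)]
        ):
            raise DomainError(f"focus center {center} lies outside the brain")
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        inside |= d2 <= radius**2
    inside &= brain_fg
    ref = TumorMask(
        grid=VolumeGrid(
            data=inside.astype(np.uint8), affine=brain.affine.copy(), space=REFERENCE
        )
    )
    native = None
    if native_scale is not None:
        if native_scale <= 0:
            raise DomainError("native_scale must be positive")
        aff = brain.affine.copy()
        aff[:3, :] *= native_scale
        native = TumorMask(
            grid=VolumeGrid(data=inside.astype(np.uint8), affine=aff, space=NATIVE)
        )
    return ref, native


def perturb_rater(
    mask: TumorMask, noise: RaterNoiseSpec, brain: VolumeGrid | None = None
) -> TumorMask:
    """Simulate a second rater's segmentation of the same tumor.

    Applies, in order: uniform boundary dilation/erosion by a random
    amount up to ``boundary_jitter_mm``; independent deletion of each
    non-largest connected component; addition of one small false
    component (inside ``brain`` when given, otherwise anywhere on the
    grid away from the tumor).  Deterministic for a fixed
    ``noise.seed``.
    """
    rng = np.random.default_rng(noise.seed)
    data = mask.data.astype(bool).copy()
    spacing = float(np.min(mask.grid.spacing))

    max_iters = int(noise.boundary_jitter_mm / spacing)
    if max_iters > 0 and data.any():
        shift = int(rng.integers(-max_iters, max_iters + 1))
        if shift > 0:
            data = ndimage.binary_dilation(data, iterations=shift)
        elif shift < 0:
            data = ndimage.binary_erosion(data, iterations=-shift)

    if noise.drop_satellite_prob > 0 and data.any():
        labels, n = ndimage.label(data, structure=ndimage.generate_binary_structure(3, 3))
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
            largest = int(np.argmax(sizes)) + 1
            for lab in range(1, n + 1):
                if lab != largest and rng.random() < noise.drop_satellite_prob:
                    data[labels == lab] = False

    if noise.add_false_component_prob > 0 and rng.random() < noise.add_false_component_prob:
        allowed = (brain.data > 0) if brain is not None else np.ones(mask.grid.shape, bool)
        allowed = allowed & ~ndimage.binary_dilation(data, iterations=2)
        candidates = np.argwhere(allowed)
        if candidates.shape[0] > 0:
            c_idx = candidates[int(rng.integers(candidates.shape[0]))]
            center = mask.grid.world_coordinates(c_idx[None, :])[0]
            x, y, z = _world_axes(mask.grid)
            d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
            blob = d2 <= noise.false_component_radius_mm**2
            if brain is not None:
                blob = blob & (brain.data > 0)
            data |= blob

    return TumorMask(
        grid=VolumeGrid(
            data=data.astype(np.uint8), affine=mask.grid.affine.copy(), space=mask.space
        )
    )


# ---------------------------------------------------------------------------
# Cohorts and on-disk fixtures


@dataclass
class SyntheticAtlas:
    """Bundle of generated atlas assets plus the brain mask."""

    bundle: AtlasBundle
    brain: VolumeGrid


def make_atlas(
    shape=DEFAULT_SHAPE,
    spacing=DEFAULT_SPACING,
    n_parcels: int = 8,
    n_tract_pairs: int = 3,
    resection_mode: str = "radial",
    seed: int = 0,
) -> SyntheticAtlas:
    """Generate a complete synthetic atlas bundle."""
    brain = make_reference_space(shape, spacing)
    parcellation, table = make_parcellation(brain, n_parcels, seed=seed)
    tracts = make_tracts(brain, n_tract_pairs, seed=seed + 1)
    resection = make_resection_map(brain, mode=resection_mode)
    bundle = AtlasBundle(
        parcellation=parcellation,
        parcel_table=table,
        tracts=tracts,
        resection_map=resection,
        brain=brain,
    )
    return SyntheticAtlas(bundle=bundle, brain=brain)


def random_tumor_spec(
    brain: VolumeGrid,
    rng: np.random.Generator,
    multifocal_prob: float = 0.23,
    main_radius_mm: tuple[float, float] = (14.0, 24.0),
    satellite_radius_mm: tuple[float, float] = (4.0, 8.0),
) -> TumorSpec:
    """Draw a random tumor: one main focus in a random hemisphere, plus
    with probability ``multifocal_prob`` a satellite at least 15 mm away.

    The defaults emulate a glioblastoma cohort: median main-tumor
    median volume around thirty mL and roughly one patient in five
    multifocal.
    """
    eroded = ndimage.binary_erosion(brain.data > 0, iterations=3)
    x, _, _ = _world_axes(brain)
    side = 1 if rng.random() < 0.5 else -1
    hemi = np.argwhere(eroded & (np.broadcast_to(x, brain.shape) * side > 0))
    c_idx = hemi[int(rng.integers(hemi.shape[0]))]
    center = tuple(brain.world_coordinates(c_idx[None, :])[0])
    r_main = float(rng.uniform(*main_radius_mm))
    foci = [(center, r_main)]
    if rng.random() < multifocal_prob:
        for _ in range(50):  # rejection-sample a satellite location
            s_idx = hemi[int(rng.integers(hemi.shape[0]))]
            s_center = tuple(brain.world_coordinates(s_idx[None, :])[0])
            gap = np.linalg.norm(np.subtract(s_center, center))
            r_sat = float(rng.uniform(*satellite_radius_mm))
            if gap >= r_main + r_sat + 15.0:
                foci.append((s_center, r_sat))
                break
    return TumorSpec(foci=tuple(foci), seed=int(rng.integers(2**31)))


@dataclass
class CohortPatient:
    patient_id: str
    spec: TumorSpec
    native_a: TumorMask
    reference_a: TumorMask
    reference_b: TumorMask
    native_b: TumorMask


def make_cohort(
    atlas: SyntheticAtlas,
    n_patients: int,
    seed: int = 0,
    noise: RaterNoiseSpec | None = None,
    multifocal_prob: float = 0.23,
) -> list[CohortPatient]:
    """Generate paired rater-A / rater-B masks for ``n_patients``.

    Rater A is the planted truth; rater B is a perturbed copy under
    ``noise`` (default: 2 mm boundary jitter, 15% satellite drop, 3%
    false components — the observed modes of human/machine
    disagreement).
    """
    rng = np.random.default_rng(seed)
    if noise is None:
        noise = RaterNoiseSpec(
            boundary_jitter_mm=2.0,
            drop_satellite_prob=0.15,
            add_false_component_prob=0.03,
        )
    patients = []
    for i in range(n_patients):
        spec = random_tumor_spec(atlas.brain, rng, multifocal_prob=multifocal_prob)
        scale = float(rng.normal(0.96, 0.02))
        ref_a, native_a = make_tumor(atlas.brain, spec, native_scale=scale)
        pnoise = RaterNoiseSpec(
            boundary_jitter_mm=noise.boundary_jitter_mm,
            drop_satellite_prob=noise.drop_satellite_prob,
            add_false_component_prob=noise.add_false_component_prob,
            false_component_radius_mm=noise.false_component_radius_mm,
            seed=int(rng.integers(2**31)),
        )
        ref_b = perturb_rater(ref_a, pnoise, brain=atlas.brain)
        native_b = TumorMask(
            grid=VolumeGrid(
                data=ref_b.data.copy(),
                affine=native_a.grid.affine.copy(),
                space=NATIVE,
            )
        )
        patients.append(
            CohortPatient(
                patient_id=f"patient_{i:04d}",
                spec=spec,
                native_a=native_a,
                reference_a=ref_a,
                reference_b=ref_b,
                native_b=native_b,
            )
        )
    return patients


def write_fixture_dir(path: str | Path, atlas: SyntheticAtlas, cohort) -> None:
    """Write a self-contained fixture directory:

    ::

        path/
          brain.nii.gz
          parcellation.nii.gz, labels.csv
          tracts/<name>.nii.gz
          resection_map.nii.gz
          patients/<id>_raterA_native.nii.gz
          patients/<id>_raterA_reference.nii.gz
          patients/<id>_raterB_native.nii.gz
          patients/<id>_raterB_reference.nii.gz
          manifest_raterA.csv, manifest_raterB.csv
    """
    path = Path(path)
    (path / "tracts").mkdir(parents=True, exist_ok=True)
    (path / "patients").mkdir(exist_ok=True)
    save_volume(atlas.brain, path / "brain.nii.gz", dtype=np.uint8)
    save_volume(atlas.bundle.parcellation, path / "parcellation.nii.gz", dtype=np.int32)
    atlas.bundle.parcel_table.to_csv(path / "labels.csv", index=False)
    save_volume(atlas.bundle.resection_map, path / "resection_map.nii.gz", dtype=np.float32)
    for name, tract in atlas.bundle.tracts.items():
        save_volume(tract, path / "tracts" / f"{name}.nii.gz", dtype=np.uint8)

    for rater in ("A", "B"):
        rows = []
        for p in cohort:
            native = p.native_a if rater == "A" else p.native_b
            ref = p.reference_a if rater == "A" else p.reference_b
            nat_name = f"patients/{p.patient_id}_rater{rater}_native.nii.gz"
            ref_name = f"patients/{p.patient_id}_rater{rater}_reference.nii.gz"
            save_mask(native, path / nat_name)
            save_mask(ref, path / ref_name)
            rows.append(
                {"patient_id": p.patient_id, "mask_native": nat_name, "mask_reference": ref_name}
            )
        with open(path / f"manifest_rater{rater}.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=["patient_id", "mask_native", "mask_reference"])
            writer.writeheader()
            writer.writerows(rows)
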