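"""Volumetric grids, binary tumor masks, and atlas bundles.

All volumes are carried as a :class:`VolumeGrid`: a 3D scalar array plus a
4x4 voxel-index -> world-mm affine in the RAS+ convention (world x grows
toward the patient's right).  Files in other on-disk orientations are
reoriented to RAS+ on load, so hemisphere logic downstream can rely on the
sign of world x alone.

The on-disk format is NIfTI-1 (``.nii`` / ``.nii.gz``), read and written
with nibabel.  DICOM ingestion is out of scope; series are expected to be
converted upstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DomainError, GeometryError, ValidationError

NATIVE = "native"
REFERENCE = "reference"

#: Default elementwise tolerance on affine entries for grid compatibility.
GRID_TOL = 1e-4

#: Default binarization threshold applied when loading masks that were
#: resampled or warped with interpolation.
BINARIZE_THRESHOLD = 0.5


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with world geometry.

    Parameters
    ----------
    data:
        3D array of voxel values.
    affine:
        4x4 voxel-index -> world-mm map, RAS+ convention.
    space:
        ``"native"`` (patient space) or ``"reference"`` (symmetric
        standard space with the midsagittal plane at world x = 0).
    """

    data: np.ndarray
    affine: np.ndarray
    space: str = NATIVE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0.0:
            raise GeometryError("affine direction matrix is singular")
        if self.space not in (NATIVE, REFERENCE):
            raise ValidationError(f"unknown space tag {self.space!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_ml(self) -> float:
        return voxel_volume_ml(self)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World-mm coordinates of voxel indices (N x 3 -> N x 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_x(self) -> np.ndarray:
        """World x coordinate of every voxel center, as an array of the
        grid's shape.  Cheap: built from the affine's first row only."""
        i, j, k = np.meshgrid(
            np.arange(self.shape[0]),
            np.arange(self.shape[1]),
            np.arange(self.shape[2]),
            indexing="ij",
            sparse=True,
        )
        a = self.affine
        return a[0, 0] * i + a[0, 1] * j + a[0, 2] * k + a[0, 3]


@dataclass
class TumorMask:
    """A strictly binary tumor segmentation on a :class:`VolumeGrid`.

    The mask may be empty (all zero); every downstream feature handles
    that case explicitly.
    """

    grid: VolumeGrid

    def __post_init__(self) -> None:
        values = np.unique(self.grid.data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValidationError("tumor mask must be strictly binary")
        self.grid.data = self.grid.data.astype(np.uint8)

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def space(self) -> str:
        return self.grid.space

    def voxel_count(self) -> int:
        return int(self.grid.data.sum())

    def is_empty(self) -> bool:
        return self.voxel_count() == 0

    def volume_ml(self) -> float:
        return self.voxel_count() * self.grid.voxel_volume_ml


def voxel_volume_ml(grid: VolumeGrid) -> float:
    """Volume of one voxel in mL: |det| of the affine's 3x3 block / 1000.

    Invariant under rotation of the grid; equals the product of spacings
    for axis-aligned grids.
    """
    det = abs(float(np.linalg.det(grid.affine[:3, :3])))
    if det <= 0.0:
        raise GeometryError("affine direction matrix is singular")
    return det / 1000.0


def check_same_grid(a: VolumeGrid, b: VolumeGrid, tol: float = GRID_TOL) -> bool:
    """True iff the two grids share shape and affine (elementwise, within
    ``tol``).  Pure predicate; never raises."""
    if a.shape != b.shape:
        return False
    return bool(np.all(np.abs(a.affine - b.affine) <= tol))


def require_same_grid(a: VolumeGrid, b: VolumeGrid, tol: float = GRID_TOL) -> None:
    if not check_same_grid(a, b, tol):
        raise GeometryError("grids differ in shape or affine beyond tolerance")


def _to_ras(img: nib.Nifti1Image) -> nib.Nifti1Image:
    return nib.as_closest_canonical(img)


def load_volume(path: str | Path, space: str = NATIVE) -> VolumeGrid:
    """Load a NIfTI scalar volume, reoriented to RAS+.

    4D files with a singleton trailing axis are squeezed to 3D; any other
    dimensionality is a geometry error.
    """
    img = _to_ras(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(
            f"{path}: expected a 3D volume (or 4D with singleton last axis), "
            f"got shape {data.shape}"
        )
    return VolumeGrid(data=np.asarray(data), affine=np.asarray(img.affine), space=space)


def load_mask(
    path: str | Path,
    binarize_threshold: float = BINARIZE_THRESHOLD,
    space: str = NATIVE,
) -> TumorMask:
    """Load a tumor mask and binarize it: values >= threshold become 1.

    Interpolated masks (after external resampling or nonlinear warping)
    carry fractional values; the 0.5 default is the natural majority rule
    for linearly interpolated binary labels.
    """
    grid = load_volume(path, space=space)
    grid.data = (np.asarray(grid.data, dtype=float) >= binarize_threshold).astype(np.uint8)
    return TumorMask(grid=grid)


def save_volume(grid: VolumeGrid, path: str | Path, dtype=None) -> None:
    """Write a grid as NIfTI-1.  ``.nii`` output is byte-stable across
    runs; gzipped output embeds no timestamp either (mtime forced to 0)."""
    data = grid.data if dtype is None else grid.data.astype(dtype)
    img = nib.Nifti1Image(data, grid.affine)
    path = Path(path)
    if path.suffix == ".gz":
        import gzip

        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as f:
                f.write(img.to_bytes())
    else:
        nib.save(img, str(path))


def save_mask(mask: TumorMask, path: str | Path) -> None:
    save_volume(mask.grid, path, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Atlas bundle


@dataclass
class AtlasBundle:
    """Reference-space atlas assets sharing one grid.

    ``parcellation`` is an integer-labeled volume (0 = outside any parcel)
    with a label table mapping label -> parcel name (and optional group,
    e.g. lobe or hemisphere).  ``tracts`` maps tract names to binary
    volumes.  ``resection_map`` holds per-voxel resection probabilities
    in [0, 1] from a historical surgical cohort.
    """

    parcellation: VolumeGrid
    parcel_table: pd.DataFrame  # columns: label, name[, group]
    tracts: Mapping[str, VolumeGrid]
    resection_map: VolumeGrid
    brain: VolumeGrid | None = None

    def __post_init__(self) -> None:
        ref = self.parcellation
        members: list[VolumeGrid] = [self.resection_map, *self.tracts.values()]
        if self.brain is not None:
            members.append(self.brain)
        for m in members:
            require_same_grid(ref, m)
        pmin = float(np.min(self.resection_map.data))
        pmax = float(np.max(self.resection_map.data))
        if pmin < 0.0 or pmax > 1.0:
            raise ValidationError(
                f"resection map values must lie in [0,1], got [{pmin}, {pmax}]"
            )
        if "label" not in self.parcel_table or "name" not in self.parcel_table:
            raise ValidationError("parcel table needs 'label' and 'name' columns")

    @property
    def grid(self) -> VolumeGrid:
        return self.parcellation

    def parcel_names(self) -> list[str]:
        return list(self.parcel_table["name"])

    def label_of(self, name: str) -> int:
        rows = self.parcel_table[self.parcel_table["name"] == name]
        if rows.empty:
            raise ValidationError(f"unknown parcel {name!r}")
        return int(rows["label"].iloc[0])


def load_parcel_table(path: str | Path) -> pd.DataFrame:
    """Read the two- or three-column parcel label CSV
    (label, name[, group])."""
    with open(path, newline="") as f:
        rows = list(csv.reader(f))
    if rows and rows[0][0].strip().lower() == "label":
        rows = rows[1:]
    records = []
    for r in rows:
        if not r:
            continue
        rec = {"label": int(r[0]), "name": r[1].strip()}
        if len(r) > 2:
            rec["group"] = r[2].strip()
        records.append(rec)
    if not records:
        raise ValidationError(f"{path}: empty parcel table")
    return pd.DataFrame(records)


def load_atlas(atlas_dir: str | Path) -> AtlasBundle:
    """Load an atlas directory:

    ::

        atlas_dir/
          parcellation.nii[.gz]     integer labels
          labels.csv                label,name[,group]
          tracts/<tract_name>.nii[.gz]
          resection_map.nii[.gz]
          brain.nii[.gz]            optional brain mask
    """
    atlas_dir = Path(atlas_dir)

    def _find(stem: str, required: bool = True) -> Path | None:
        for suffix in (".nii.gz", ".nii"):
            p = atlas_dir / f"{stem}{suffix}"
            if p.exists():
                return p
        if required:
            raise FileNotFoundError(f"{atlas_dir}: missing {stem}.nii[.gz]")
        return None

    parcellation = load_volume(_find("parcellation"), space=REFERENCE)
    parcellation.data = np.rint(np.asarray(parcellation.data)).astype(np.int32)
    table = load_parcel_table(atlas_dir / "labels.csv")
    resection = load_volume(_find("resection_map"), space=REFERENCE)
    resection.data = np.asarray(resection.data, dtype=float)

    tracts: dict[str, VolumeGrid] = {}
    tract_dir = atlas_dir / "tracts"
    if tract_dir.is_dir():
        for p in sorted(tract_dir.iterdir()):
            if p.name.endswith((".nii", ".nii.gz")):
                name = p.name.removesuffix(".nii.gz").removesuffix(".nii")
                g = load_volume(p, space=REFERENCE)
                g.data = (np.asarray(g.data, dtype=float) >= BINARIZE_THRESHOLD).astype(
                    np.uint8
                )
                tracts[name] = g

    brain_path = _find("brain", required=False)
    brain = None
    if brain_path is not None:
        brain = load_volume(brain_path, space=REFERENCE)
        brain.data = (np.asarray(brain.data, dtype=float) >= BINARIZE_THRESHOLD).astype(
            np.uint8
        )

    return AtlasBundle(
        parcellation=parcellation,
        parcel_table=table,
        tracts=tracts,
        resection_map=resection,
        brain=brain,
    )
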