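"""Per-patient tumor features from binary segmentation masks.

Given a tumor mask in the patient's native space and the same mask
resampled into a symmetric reference space (midsagittal plane at world
x = 0), this module computes the standard neurosurgical report features:

* laterality and the laterality index (V_L - V_R) / (V_L + V_R),
* contralateral infiltration (any tumor voxel opposite the dominant
  hemisphere),
* native and normalized (reference-space) tumor volumes in mL,
* multifocality and the number of tumor foci from 3D connected
  components,
* cortical-parcel and white-matter-tract overlap profiles,
* expected resectable volume (ERV), expected residual tumor volume
  (ERTV = V_norm - ERV) and the resectability index RI = ERV / V_norm
  against a per-voxel resection probability map.

Undefined scalar results (empty masks) are carried as NaN; undefined
categorical results as ``None``.  Laterality follows the convention that
world x > 0 is the patient's right hemisphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import DomainError, GeometryError, SpaceError, ValidationError
from .grids import AtlasBundle, REFERENCE, TumorMask, VolumeGrid, require_same_grid

LEFT = "left"
RIGHT = "right"
NONE = "none"


@dataclass(frozen=True)
class MultifocalityConfig:
    """Thresholds of the multifocality rule.

    A tumor is multifocal when a second component of at least
    ``min_second_volume`` mL lies at least ``min_distance`` mm (minimum
    voxel-center distance) from the largest component.  Components below
    ``min_focus_volume`` mL are not counted as foci; this floor removes
    resampling speckle.  Both thresholds are inclusive (>=).
    """

    min_second_volume: float = 0.1  # mL
    min_distance: float = 5.0  # mm
    connectivity: int = 26  # 6 | 18 | 26
    min_focus_volume: float = 0.1  # mL

    def __post_init__(self) -> None:
        if self.min_second_volume <= 0:
            raise DomainError("min_second_volume must be > 0")
        if self.min_distance < 0:
            raise DomainError("min_distance must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise DomainError("connectivity must be 6, 18, or 26")
        if self.min_focus_volume <= 0:
            raise DomainError("min_focus_volume must be > 0")


@dataclass
class Component:
    """One connected tumor component."""

    indices: np.ndarray  # (n, 3) voxel indices
    volume_ml: float
    centroid: np.ndarray  # world mm

    @property
    def n_voxels(self) -> int:
        return int(self.indices.shape[0])


@dataclass
class FeatureReport:
    """All per-patient tumor features.

    ``laterality_index`` is NaN when no tumor voxel falls in either
    hemisphere; the resectability triplet is NaN for an empty mask.
    Overlap maps hold the percentage of *tumor* volume inside each
    structure; involvement of a structure means overlap > 0.  They are
    ``None`` when the tumor is empty.
    """

    laterality: str  # left | right | none
    laterality_index: float
    contralateral_infiltration: bool | None
    native_volume_ml: float
    normalized_volume_ml: float
    left_volume_ml: float
    right_volume_ml: float
    multifocal: bool
    n_foci: int
    cortical_overlap: dict[str, float] | None
    subcortical_overlap: dict[str, float] | None
    expected_resectable_volume_ml: float
    expected_residual_volume_ml: float
    resectability_index: float

    def cortical_involvement(self) -> dict[str, bool] | None:
        if self.cortical_overlap is None:
            return None
        return {k: v > 0 for k, v in self.cortical_overlap.items()}

    def subcortical_involvement(self) -> dict[str, bool] | None:
        if self.subcortical_overlap is None:
            return None
        return {k: v > 0 for k, v in self.subcortical_overlap.items()}


# ---------------------------------------------------------------------------
# Hemisphere features


def _require_reference(mask: TumorMask) -> None:
    if mask.space != REFERENCE:
        raise SpaceError("operation requires a reference-space mask")


def hemisphere_volumes(mask: TumorMask) -> tuple[float, float]:
    """(V_L, V_R) in mL for a reference-space mask.

    Voxels with world x < 0 count to the left hemisphere, x > 0 to the
    right.  Voxel centers within half a voxel of the midplane (|x| <
    spacing_x / 2) belong to neither; the symmetric reference grid has a
    true midplane and such voxels are genuinely ambiguous.
    """
    _require_reference(mask)
    if mask.is_empty():
        return 0.0, 0.0
    x = mask.grid.world_x()[mask.data > 0]
    half = float(mask.grid.spacing[0]) / 2.0
    vml = mask.grid.voxel_volume_ml
    v_left = float(np.sum(x <= -half)) * vml
    v_right = float(np.sum(x >= half)) * vml
    return v_left, v_right


def laterality(v_left: float, v_right: float) -> str:
    """Dominant hemisphere: the one holding the larger tumor volume.

    ``none`` when no volume was detected.  An exact tie (a genuinely
    midline tumor) is assigned ``right`` deterministically.
    """
    if v_left < 0 or v_right < 0:
        raise DomainError("hemisphere volumes must be non-negative")
    if v_left + v_right == 0:
        return NONE
    if v_left > v_right:
        return LEFT
    return RIGHT


def laterality_index(v_left: float, v_right: float) -> float:
    """(V_L - V_R) / (V_L + V_R): +1 fully left, -1 fully right, 0 equal.

    NaN when both volumes are zero.
    """
    if v_left < 0 or v_right < 0:
        raise DomainError("hemisphere volumes must be non-negative")
    total = v_left + v_right
    if total == 0:
        return math.nan
    return (v_left - v_right) / total


def contralateral_infiltration(mask: TumorMask, side: str) -> bool | None:
    """True iff at least one tumor voxel lies opposite ``side``.

    ``None`` (undefined) when laterality is ``none``.
    """
    if side == NONE:
        return None
    if side not in (LEFT, RIGHT):
        raise ValidationError(f"unknown laterality {side!r}")
    v_left, v_right = hemisphere_volumes(mask)
    return (v_right > 0) if side == LEFT else (v_left > 0)


# ---------------------------------------------------------------------------
# Volumes


def native_volume(mask: TumorMask) -> float:
    """Tumor volume in the patient's own scan geometry: voxel count times
    native voxel volume, in mL."""
    if mask.space != "native":
        raise SpaceError("native_volume requires a native-space mask")
    return mask.volume_ml()


def normalized_volume(mask: TumorMask) -> float:
    """Tumor volume after spatial normalization: voxel count times
    reference voxel volume, in mL."""
    _require_reference(mask)
    return mask.volume_ml()


# ---------------------------------------------------------------------------
# Connected components and focality

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_components(mask: TumorMask, connectivity: int = 26) -> list[Component]:
    """Maximal connected components of the mask, sorted by volume
    descending (ties broken by first voxel in scan order, so the order is
    deterministic).  Component volumes sum exactly to the mask volume."""
    if connectivity not in _STRUCTURES:
        raise DomainError("connectivity must be 6, 18, or 26")
    if mask.is_empty():
        return []
    labels, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    vml = mask.grid.voxel_volume_ml
    comps = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        centroid = mask.grid.world_coordinates(idx).mean(axis=0)
        comps.append(Component(indices=idx, volume_ml=idx.shape[0] * vml, centroid=centroid))
    comps.sort(key=lambda c: -c.n_voxels)
    return comps


def min_component_distance(a: Component, b: Component, affine: np.ndarray) -> float:
    """Minimum Euclidean world-mm distance over all voxel-center pairs of
    the two components (set distance, not centroid distance)."""
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise DomainError("components must be non-empty")
    lin = np.asarray(affine, dtype=float)
    pa = a.indices @ lin[:3, :3].T + lin[:3, 3]
    pb = b.indices @ lin[:3, :3].T + lin[:3, 3]
    tree = cKDTree(pa)
    d, _ = tree.query(pb, k=1)
    return float(np.min(d))


def assess_focality(
    components: list[Component],
    config: MultifocalityConfig,
    affine: np.ndarray,
) -> tuple[bool, int]:
    """(multifocal, n_foci) from volume-sorted components.

    ``n_foci`` counts components of at least ``min_focus_volume`` mL.
    Multifocality additionally requires the second-largest component to
    reach ``min_second_volume`` mL and to lie at least ``min_distance``
    mm from the largest.
    """
    n_foci = sum(1 for c in components if c.volume_ml >= config.min_focus_volume)
    if len(components) < 2 or n_foci < 2:
        return False, n_foci
    first, second = components[0], components[1]
    if second.volume_ml < config.min_second_volume:
        return False, n_foci
    dist = min_component_distance(first, second, affine)
    return dist >= config.min_distance, n_foci


# ---------------------------------------------------------------------------
# Location profile


def location_profile(
    mask: TumorMask, atlas: AtlasBundle
) -> tuple[dict[str, float] | None, dict[str, float] | None]:
    """Percent of tumor volume inside each cortical parcel and each
    white-matter tract.

    Percentages are tumor-relative (share of the tumor, not of the
    structure); parcel percentages sum to at most 100 because tumor
    voxels outside every parcel are allowed.  Both maps are ``None`` for
    an empty tumor.
    """
    _require_reference(mask)
    require_same_grid(mask.grid, atlas.grid)
    n_tumor = mask.voxel_count()
    if n_tumor == 0:
        return None, None

    fg = mask.data > 0
    labels_under_tumor = atlas.parcellation.data[fg]
    counts = np.bincount(
        labels_under_tumor.astype(np.int64),
        minlength=int(atlas.parcel_table["label"].max()) + 1,
    )
    cortical = {
        str(row["name"]): 100.0 * counts[int(row["label"])] / n_tumor
        for _, row in atlas.parcel_table.iterrows()
    }
    subcortical = {
        name: 100.0 * float(np.sum(tract.data[fg] > 0)) / n_tumor
        for name, tract in atlas.tracts.items()
    }
    return cortical, subcortical


# ---------------------------------------------------------------------------
# Resectability


def expected_resectability(
    mask: TumorMask, resection_map: VolumeGrid
) -> tuple[float, float, float]:
    """(ERV, ERTV, RI) against a resection probability map.

    ERV is the sum of resection probabilities over tumor voxels, in mL;
    ERTV = V_norm - ERV; RI = ERV / V_norm in [0, 1].  All NaN for an
    empty mask.
    """
    _require_reference(mask)
    require_same_grid(mask.grid, resection_map)
    pmap = np.asarray(resection_map.data, dtype=float)
    if pmap.min() < 0.0 or pmap.max() > 1.0:
        raise ValidationError("resection map values must lie in [0,1]")
    if mask.is_empty():
        return math.nan, math.nan, math.nan
    vml = mask.grid.voxel_volume_ml
    v_norm = mask.volume_ml()
    erv = float(pmap[mask.data > 0].sum()) * vml
    ertv = v_norm - erv
    ri = erv / v_norm
    return erv, ertv, ri


# ---------------------------------------------------------------------------
# Full report


def extract_all_features(
    mask_native: TumorMask,
    mask_reference: TumorMask,
    atlas: AtlasBundle,
    config: MultifocalityConfig | None = None,
) -> FeatureReport:
    """Compose every feature into one :class:`FeatureReport`.

    Deterministic for fixed inputs.  An empty (or entirely sub-focus-
    threshold) mask yields laterality ``none``, zero foci, NaN laterality
    index and resectability, and ``None`` overlap profiles.
    """
    config = config or MultifocalityConfig()

    v_native = native_volume(mask_native)
    v_norm = normalized_volume(mask_reference)
    v_left, v_right = hemisphere_volumes(mask_reference)

    comps = connected_components(mask_reference, config.connectivity)
    multifocal, n_foci = assess_focality(comps, config, mask_reference.grid.affine)

    # no focus of countable size -> the patient is devoid of laterality
    side = laterality(v_left, v_right) if n_foci > 0 else NONE
    index = laterality_index(v_left, v_right)
    infiltration = contralateral_infiltration(mask_reference, side)

    cortical, subcortical = location_profile(mask_reference, atlas)
    erv, ertv, ri = expected_resectability(mask_reference, atlas.resection_map)

    return FeatureReport(
        laterality=side,
        laterality_index=index,
        contralateral_infiltration=infiltration,
        native_volume_ml=v_native,
        normalized_volume_ml=v_norm,
        left_volume_ml=v_left,
        right_volume_ml=v_right,
        multifocal=multifocal,
        n_foci=n_foci,
        cortical_overlap=cortical,
        subcortical_overlap=subcortical,
        expected_resectable_volume_ml=erv,
        expected_residual_volume_ml=ertv,
        resectability_index=ri,
    )
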