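"""Cohort-level maps: tumor probability maps, incidence profiles, and
voxel-wise permutation FDR for paired segmentation sources.

The tumor probability map assigns each reference-space voxel the fraction
of patients whose tumor covers it.  When two segmentation sources (e.g.
an automated and a manual rater) are available for the same patients, the
voxel-wise incidence difference is tested with a paired sign-flip
permutation scheme: each patient's (a, b) pair is swapped independently
with probability 1/2 per permutation, which realizes the null of
exchangeable raters.  The per-voxel false discovery rate is the empirical
exceedance ratio

    FDR(v) = E_perm[ #voxels with |D_perm| >= |D_obs(v)| ]
             / #voxels with |D_obs| >= |D_obs(v)|,

clipped to [0, 1] (a plug-in estimator without pi0 correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, GeometryError, ValidationError
from .features import FeatureReport
from .grids import TumorMask, VolumeGrid, require_same_grid


@dataclass
class ProbabilityMap:
    """Voxel-wise tumor incidence over a cohort; values are exactly
    k / n_patients."""

    grid: VolumeGrid
    n_patients: int


@dataclass
class FdrMap:
    """Observed incidence difference and its permutation FDR."""

    observed_difference: VolumeGrid
    fdr: VolumeGrid
    n_permutations: int
    seed: int


def build_probability_map(masks: list[TumorMask]) -> ProbabilityMap:
    """Voxel-wise mean of binary masks over the cohort."""
    if not masks:
        raise DomainError("need at least one mask")
    ref = masks[0].grid
    counts = np.zeros(ref.shape, dtype=np.int64)
    for m in masks:
        require_same_grid(ref, m.grid)
        counts += m.data
    prob = counts / len(masks)
    grid = VolumeGrid(data=prob, affine=ref.affine.copy(), space=ref.space)
    return ProbabilityMap(grid=grid, n_patients=len(masks))


def population_profile(reports: list[FeatureReport]) -> dict[str, dict[str, float]]:
    """Percent of patients with involvement, per cortical parcel and per
    tract.

    Patients with an empty tumor count toward the denominator with no
    involvement anywhere.  Returns ``{"cortical": {...}, "subcortical":
    {...}}`` with percentages in [0, 100].
    """
    if not reports:
        raise DomainError("need at least one report")
    defined = [r for r in reports if r.cortical_overlap is not None]
    if not defined:
        raise ValidationError("no report carries a location profile")
    cortical_names = list(defined[0].cortical_overlap)  # type: ignore[arg-type]
    subcortical_names = list(defined[0].subcortical_overlap or {})
    for r in defined:
        if list(r.cortical_overlap) != cortical_names or list(
            r.subcortical_overlap or {}
        ) != subcortical_names:
            raise ValidationError("reports carry inconsistent structure name sets")

    n = len(reports)
    out = {"cortical": {}, "subcortical": {}}
    for name in cortical_names:
        k = sum(
            1
            for r in defined
            if r.cortical_overlap[name] > 0  # type: ignore[index]
        )
        out["cortical"][name] = 100.0 * k / n
    for name in subcortical_names:
        k = sum(
            1
            for r in defined
            if (r.subcortical_overlap or {}).get(name, 0.0) > 0
        )
        out["subcortical"][name] = 100.0 * k / n
    return out


def voxelwise_difference_fdr(
    masks_a: list[TumorMask],
    masks_b: list[TumorMask],
    n_permutations: int = 1000,
    seed: int = 0,
    exclude_empty_voxels: bool = True,
) -> FdrMap:
    """Paired voxel-wise incidence difference with permutation FDR.

    ``masks_a[i]`` and ``masks_b[i]`` must segment the same patient.
    Voxels with zero incidence under both sources are excluded from the
    comparison by default (their difference is structurally zero and
    would dilute the FDR denominator); excluded voxels are reported with
    FDR 1.
    """
    if len(masks_a) != len(masks_b):
        raise ValidationError("paired mask lists must have equal length")
    if len(masks_a) < 1:
        raise ValidationError("need at least one pair")
    if n_permutations < 1:
        raise DomainError("n_permutations must be >= 1")
    ref = masks_a[0].grid
    for m in (*masks_a, *masks_b):
        require_same_grid(ref, m.grid)

    n = len(masks_a)
    # per-patient voxel-wise difference, in {-1, 0, +1}
    diffs = np.stack(
        [a.data.astype(np.int8) - b.data.astype(np.int8) for a, b in zip(masks_a, masks_b)]
    ).reshape(n, -1)
    any_tumor = np.zeros(diffs.shape[1], dtype=bool)
    for m in (*masks_a, *masks_b):
        any_tumor |= m.data.reshape(-1) > 0

    include = any_tumor if exclude_empty_voxels else np.ones_like(any_tumor)
    d = diffs[:, include].astype(np.float64)
    obs = d.mean(axis=0)
    abs_obs = np.abs(obs)

    order = np.sort(abs_obs)
    m_vox = abs_obs.size
    # denominator: #voxels with |obs| >= |obs(v)|
    denom = m_vox - np.searchsorted(order, abs_obs, side="left")
    denom = np.maximum(denom, 1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m_vox, dtype=np.float64)
    for _ in range(n_permutations):
        signs = rng.integers(0, 2, size=n) * 2 - 1
        perm = np.abs(signs @ d) / n
        perm.sort()
        exceed += m_vox - np.searchsorted(perm, abs_obs, side="left")
    numer = exceed / n_permutations

    fdr_vals = np.clip(numer / denom, 0.0, 1.0)

    obs_full = np.zeros(include.size)
    obs_full[include] = obs
    fdr_full = np.ones(include.size)
    fdr_full[include] = fdr_vals

    shape = ref.shape
    return FdrMap(
        observed_difference=VolumeGrid(
            data=obs_full.reshape(shape), affine=ref.affine.copy(), space=ref.space
        ),
        fdr=VolumeGrid(
            data=fdr_full.reshape(shape), affine=ref.affine.copy(), space=ref.space
        ),
        n_permutations=n_permutations,
        seed=seed,
    )
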