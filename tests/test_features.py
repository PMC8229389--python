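import math

import numpy as np
import pytest

from gsirads.errors import DomainError, GeometryError, SpaceError, ValidationError
from gsirads.features import (
    Component,
    MultifocalityConfig,
    assess_focality,
    connected_components,
    contralateral_infiltration,
    expected_resectability,
    extract_all_features,
    hemisphere_volumes,
    laterality,
    laterality_index,
    location_profile,
    min_component_distance,
    native_volume,
    normalized_volume,
)
from gsirads.grids import REFERENCE, TumorMask, VolumeGrid

from conftest import make_grid, make_mask, random_blob_mask


# ---------------------------------------------------------------------------
# Independent oracles


def flood_fill_components(data, connectivity):
    """Brute-force connected components by BFS flood fill."""
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                order = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((di, dj, dk))
    todo = {tuple(v) for v in np.argwhere(data)}
    comps = []
    while todo:
        start = todo.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in offsets:
                nb = (i + di, j + dj, k + dk)
                if nb in todo:
                    todo.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(comp)
    return comps


def pairwise_min_distance(points_a, points_b):
    """Exhaustive O(n^2) minimum pairwise Euclidean distance."""
    best = math.inf
    for p in points_a:
        for q in points_b:
            best = min(best, math.dist(p, q))
    return best


def brute_force_focality(data, grid, config):
    """Focality by exhaustive flood fill plus exhaustive distances."""
    comps = flood_fill_components(data, config.connectivity)
    vml = grid.voxel_volume_ml
    vols = sorted((len(c) * vml for c in comps), reverse=True)
    n_foci = sum(1 for v in vols if v >= config.min_focus_volume)
    # size ties broken by scan order of each component's first voxel
    comps.sort(key=lambda c: (-len(c), min(c)))
    if len(comps) < 2 or n_foci < 2 or vols[1] < config.min_second_volume:
        return False, n_foci
    pa = grid.world_coordinates(np.array(sorted(comps[0])))
    pb = grid.world_coordinates(np.array(sorted(comps[1])))
    return pairwise_min_distance(pa, pb) >= config.min_distance, n_foci


# ---------------------------------------------------------------------------
# Hemisphere features


class TestHemisphereVolumes:
    def test_all_right(self):
        data = np.zeros((8, 8, 8))
        data[5:8, :, :] = 1  # x > 0 in a center-origin grid
        mask = make_mask(data)
        v_l, v_r = hemisphere_volumes(mask)
        assert v_l == 0.0
        assert v_r == pytest.approx(mask.volume_ml())

    def test_empty(self):
        mask = make_mask(np.zeros((8, 8, 8)))
        assert hemisphere_volumes(mask) == (0.0, 0.0)

    def test_mirrored_blob_equal_volumes(self):
        rng = np.random.default_rng(3)
        half = rng.random((4, 8, 8)) < 0.3
        data = np.concatenate([half[::-1], half], axis=0).astype(np.uint8)
        mask = make_mask(data)
        v_l, v_r = hemisphere_volumes(mask)
        assert v_l == pytest.approx(v_r)

    def test_native_space_rejected(self):
        mask = make_mask(np.ones((4, 4, 4)), space="native")
        with pytest.raises(SpaceError):
            hemisphere_volumes(mask)


class TestLaterality:
    @pytest.mark.parametrize(
        "v_l,v_r,expected",
        [(0, 0, "none"), (10, 2, "left"), (2, 10, "right"), (5, 5, "right")],
    )
    def test_rule(self, v_l, v_r, expected):
        assert laterality(v_l, v_r) == expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            laterality(-1, 2)

    @pytest.mark.parametrize(
        "v_l,v_r,expected",
        [(0, 10, -1.0), (7, 7, 0.0), (30, 10, 0.5), (10, 0, 1.0)],
    )
    def test_index(self, v_l, v_r, expected):
        assert laterality_index(v_l, v_r) == pytest.approx(expected)

    def test_index_undefined_for_empty(self):
        assert math.isnan(laterality_index(0, 0))


class TestContralateralInfiltration:
    def test_strictly_ipsilateral(self):
        data = np.zeros((8, 8, 8))
        data[5:8, 2:5, 2:5] = 1
        assert contralateral_infiltration(make_mask(data), "right") is False

    def test_single_contralateral_voxel(self):
        data = np.zeros((8, 8, 8))
        data[5:8, 2:5, 2:5] = 1
        data[1, 4, 4] = 1
        assert contralateral_infiltration(make_mask(data), "right") is True

    def test_undefined_when_no_laterality(self):
        assert contralateral_infiltration(make_mask(np.zeros((4, 4, 4))), "none") is None


# ---------------------------------------------------------------------------
# Volumes


class TestVolumes:
    def test_native_voxel_arithmetic(self):
        data = np.zeros((10, 10, 10))
        data.flat[:1000] = 1
        mask = make_mask(data, space="native")
        assert native_volume(mask) == pytest.approx(1.0)

    def test_empty(self):
        assert native_volume(make_mask(np.zeros((4, 4, 4)), space="native")) == 0.0
        assert normalized_volume(make_mask(np.zeros((4, 4, 4)))) == 0.0

    def test_linear_scaling_cubes_the_volume(self):
        rng = np.random.default_rng(5)
        data = (rng.random((8, 8, 8)) < 0.5).astype(np.uint8)
        v1 = normalized_volume(make_mask(data))
        v2 = normalized_volume(make_mask(data, spacing=(1.1, 1.1, 1.1)))
        assert v2 == pytest.approx(v1 * 1.1**3)


# ---------------------------------------------------------------------------
# Components and focality


class TestConnectedComponents:
    def test_two_separated_cubes(self):
        data = np.zeros((12, 12, 12))
        data[1:4, 1:4, 1:4] = 1
        data[6:9, 1:4, 1:4] = 1
        comps = connected_components(make_mask(data))
        assert len(comps) == 2
        assert comps[0].n_voxels == comps[1].n_voxels == 27

    def test_corner_touch_connectivity(self):
        data = np.zeros((8, 8, 8))
        data[1:3, 1:3, 1:3] = 1
        data[3:5, 3:5, 3:5] = 1  # touches only at the corner voxel diagonal
        assert len(connected_components(make_mask(data), 26)) == 1
        assert len(connected_components(make_mask(data), 6)) == 2

    def test_empty(self):
        assert connected_components(make_mask(np.zeros((4, 4, 4)))) == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, shape=(10, 10, 10), density=0.2)
        comps = connected_components(mask, connectivity)
        oracle = flood_fill_components(mask.data, connectivity)
        assert sorted(c.n_voxels for c in comps) == sorted(len(c) for c in oracle)
        got = {frozenset(map(tuple, c.indices)) for c in comps}
        want = {frozenset(c) for c in oracle}
        assert got == want

    def test_volume_conservation(self):
        rng = np.random.default_rng(9)
        mask = random_blob_mask(rng, density=0.3)
        comps = connected_components(mask)
        assert sum(c.volume_ml for c in comps) == pytest.approx(mask.volume_ml())


class TestMinComponentDistance:
    def _component(self, indices, grid):
        idx = np.asarray(indices)
        return Component(
            indices=idx,
            volume_ml=idx.shape[0] * grid.voxel_volume_ml,
            centroid=grid.world_coordinates(idx).mean(axis=0),
        )

    def test_three_four_five(self):
        grid = make_grid(np.zeros((8, 8, 8)), origin=(0, 0, 0))
        a = self._component([[0, 0, 0]], grid)
        b = self._component([[3, 4, 0]], grid)
        assert min_component_distance(a, b, grid.affine) == pytest.approx(5.0)

    def test_face_adjacent(self):
        grid = make_grid(np.zeros((8, 8, 8)), origin=(0, 0, 0))
        a = self._component([[2, 2, 2]], grid)
        b = self._component([[3, 2, 2]], grid)
        assert min_component_distance(a, b, grid.affine) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid(np.zeros((16, 16, 16)), spacing=(1.0, 1.5, 2.0))
        ia = rng.integers(0, 7, size=(12, 3))
        ib = rng.integers(9, 16, size=(12, 3))
        a = self._component(ia, grid)
        b = self._component(ib, grid)
        oracle = pairwise_min_distance(
            grid.world_coordinates(ia), grid.world_coordinates(ib)
        )
        assert min_component_distance(a, b, grid.affine) == pytest.approx(oracle)

    def test_empty_component_rejected(self):
        grid = make_grid(np.zeros((4, 4, 4)))
        a = Component(indices=np.empty((0, 3), dtype=int), volume_ml=0, centroid=np.zeros(3))
        b = Component(indices=np.array([[1, 1, 1]]), volume_ml=0.001, centroid=np.ones(3))
        with pytest.raises(DomainError):
            min_component_distance(a, b, grid.affine)


class TestAssessFocality:
    def _fake(self, volume_ml, at):
        return Component(
            indices=np.array([at]), volume_ml=volume_ml, centroid=np.asarray(at, float)
        )

    def test_second_below_volume_floor(self):
        grid = make_grid(np.zeros((8, 8, 8)), origin=(0, 0, 0))
        comps = [self._fake(20.0, [0, 0, 0]), self._fake(0.05, [6, 0, 0])]
        assert assess_focality(comps, MultifocalityConfig(), grid.affine) == (False, 1)

    def test_second_too_close(self):
        grid = make_grid(np.zeros((8, 8, 8)), origin=(0, 0, 0))
        comps = [self._fake(20.0, [0, 0, 0]), self._fake(1.0, [3, 0, 0])]
        assert assess_focality(comps, MultifocalityConfig(), grid.affine) == (False, 2)

    def test_both_thresholds_met(self):
        grid = make_grid(np.zeros((16, 16, 16)), origin=(0, 0, 0))
        comps = [self._fake(20.0, [0, 0, 0]), self._fake(1.0, [10, 0, 0])]
        assert assess_focality(comps, MultifocalityConfig(), grid.affine) == (True, 2)

    def test_empty(self):
        grid = make_grid(np.zeros((4, 4, 4)))
        assert assess_focality([], MultifocalityConfig(), grid.affine) == (False, 0)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, connectivity, seed):
        rng = np.random.default_rng(100 + seed)
        # coarse spacing so random speckle crosses the 0.1 mL focus floor
        mask = random_blob_mask(rng, shape=(10, 10, 10), density=0.15, spacing=(3.0, 3.0, 3.0))
        config = MultifocalityConfig(connectivity=connectivity)
        comps = connected_components(mask, connectivity)
        got = assess_focality(comps, config, mask.grid.affine)
        want = brute_force_focality(mask.data, mask.grid, config)
        assert got == want


# ---------------------------------------------------------------------------
# Location profile and resectability


class TestLocationProfile:
    def test_containment(self, atlas_small):
        atlas = atlas_small.bundle
        name = atlas.parcel_names()[0]
        label = atlas.label_of(name)
        data = np.zeros(atlas.grid.shape, dtype=np.uint8)
        inside = np.argwhere(atlas.parcellation.data == label)[:30]
        data[tuple(inside.T)] = 1
        mask = TumorMask(grid=VolumeGrid(data=data, affine=atlas.grid.affine.copy(), space=REFERENCE))
        cortical, _ = location_profile(mask, atlas)
        assert cortical[name] == pytest.approx(100.0)
        assert all(v == 0.0 for k, v in cortical.items() if k != name)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_voxel_tally(self, atlas_small, seed):
        atlas = atlas_small.bundle
        rng = np.random.default_rng(seed)
        data = (rng.random(atlas.grid.shape) < 0.05).astype(np.uint8)
        mask = TumorMask(grid=VolumeGrid(data=data, affine=atlas.grid.affine.copy(), space=REFERENCE))
        cortical, subcortical = location_profile(mask, atlas)
        n = int(data.sum())
        for _, row in atlas.parcel_table.iterrows():
            count = sum(
                1
                for v in np.argwhere(data)
                if atlas.parcellation.data[tuple(v)] == row["label"]
            )
            assert cortical[row["name"]] == pytest.approx(100.0 * count / n)
        for name, tract in atlas.tracts.items():
            count = sum(1 for v in np.argwhere(data) if tract.data[tuple(v)] > 0)
            assert subcortical[name] == pytest.approx(100.0 * count / n)
        assert sum(cortical.values()) <= 100.0 + 1e-9

    def test_grid_mismatch_rejected(self, atlas_small):
        atlas = atlas_small.bundle
        mask = make_mask(np.ones((8, 8, 8)))
        with pytest.raises(GeometryError):
            location_profile(mask, atlas)

    def test_empty_tumor_undefined(self, atlas_small):
        atlas = atlas_small.bundle
        data = np.zeros(atlas.grid.shape, dtype=np.uint8)
        mask = TumorMask(grid=VolumeGrid(data=data, affine=atlas.grid.affine.copy(), space=REFERENCE))
        assert location_profile(mask, atlas) == (None, None)


class TestExpectedResectability:
    def _map(self, mask, value):
        return VolumeGrid(
            data=np.full(mask.grid.shape, value),
            affine=mask.grid.affine.copy(),
            space=REFERENCE,
        )

    def test_certainty_limit(self):
        data = np.zeros((8, 8, 8))
        data[2:5, 2:5, 2:5] = 1
        mask = make_mask(data)
        erv, ertv, ri = expected_resectability(mask, self._map(mask, 1.0))
        assert erv == pytest.approx(mask.volume_ml())
        assert ertv == pytest.approx(0.0)
        assert ri == pytest.approx(1.0)

    def test_zero_limit(self):
        data = np.zeros((8, 8, 8))
        data[2:5, 2:5, 2:5] = 1
        mask = make_mask(data)
        erv, ertv, ri = expected_resectability(mask, self._map(mask, 0.0))
        assert erv == 0.0
        assert ertv == pytest.approx(mask.volume_ml())
        assert ri == 0.0

    def test_hand_sum(self):
        data = np.zeros((8, 8, 8))
        data.flat[:10] = 1  # ten voxels at 1 mm isotropic
        mask = make_mask(data)
        erv, _, ri = expected_resectability(mask, self._map(mask, 0.5))
        assert erv == pytest.approx(0.005)
        assert ri == pytest.approx(0.5)

    def test_monotone_in_map(self):
        rng = np.random.default_rng(2)
        mask = random_blob_mask(rng, density=0.2)
        p1 = rng.random(mask.grid.shape) * 0.5
        p2 = p1 + 0.3
        g1 = VolumeGrid(data=p1, affine=mask.grid.affine.copy(), space=REFERENCE)
        g2 = VolumeGrid(data=p2, affine=mask.grid.affine.copy(), space=REFERENCE)
        assert expected_resectability(mask, g2)[0] > expected_resectability(mask, g1)[0]

    def test_out_of_range_map_rejected(self):
        mask = make_mask(np.ones((4, 4, 4)))
        with pytest.raises(ValidationError):
            expected_resectability(mask, self._map(mask, 1.5))

    def test_empty_mask_undefined(self):
        mask = make_mask(np.zeros((4, 4, 4)))
        erv, ertv, ri = expected_resectability(mask, self._map(mask, 0.5))
        assert math.isnan(erv) and math.isnan(ertv) and math.isnan(ri)


# ---------------------------------------------------------------------------
# Full report


class TestExtractAllFeatures:
    def test_right_hemisphere_blob(self, atlas_small):
        from gsirads.synthetic import make_tumor, TumorSpec

        atlas = atlas_small
        ref, nat = make_tumor(atlas.brain, TumorSpec(foci=(((30.0, 0.0, 0.0), 16.0),)), native_scale=0.95)
        report = extract_all_features(nat, ref, atlas.bundle)
        assert report.laterality == "right"
        assert report.laterality_index < 0
        assert report.multifocal is False
        assert report.n_foci == 1
        assert not math.isnan(report.resectability_index)
        assert 0.0 <= report.resectability_index <= 1.0
        assert report.expected_residual_volume_ml >= 0.0
        assert report.native_volume_ml == pytest.approx(
            report.normalized_volume_ml * 0.95**3
        )

    def test_empty_mask(self, atlas_small):
        atlas = atlas_small
        zero = np.zeros(atlas.brain.shape, dtype=np.uint8)
        nat = TumorMask(grid=VolumeGrid(data=zero.copy(), affine=atlas.brain.affine.copy(), space="native"))
        ref = TumorMask(grid=VolumeGrid(data=zero, affine=atlas.brain.affine.copy(), space=REFERENCE))
        report = extract_all_features(nat, ref, atlas.bundle)
        assert report.laterality == "none"
        assert math.isnan(report.laterality_index)
        assert report.contralateral_infiltration is None
        assert report.native_volume_ml == 0.0
        assert report.n_foci == 0
        assert report.multifocal is False
        assert math.isnan(report.resectability_index)
        assert report.cortical_overlap is None

    def test_subthreshold_speck_has_no_laterality(self, atlas_small):
        """A mask whose only component is below the focus floor counts
        zero foci and is devoid of laterality."""
        atlas = atlas_small
        data = np.zeros(atlas.brain.shape, dtype=np.uint8)
        inside = np.argwhere(atlas.brain.data > 0)
        data[tuple(inside[len(inside) // 4].T)] = 1  # one voxel = 0.064 mL < 0.1 mL
        nat = TumorMask(grid=VolumeGrid(data=data.copy(), affine=atlas.brain.affine.copy(), space="native"))
        ref = TumorMask(grid=VolumeGrid(data=data, affine=atlas.brain.affine.copy(), space=REFERENCE))
        report = extract_all_features(nat, ref, atlas.bundle)
        assert report.n_foci == 0
        assert report.laterality == "none"

    def test_mirror_symmetry(self, atlas_small):
        """Reflecting the mask across the midplane swaps hemispheres,
        negates the laterality index, and flips laterality."""
        from gsirads.synthetic import make_tumor, TumorSpec

        atlas = atlas_small
        ref, _ = make_tumor(
            atlas.brain,
            TumorSpec(foci=(((28.0, 6.0, -4.0), 15.0), ((-20.0, -10.0, 8.0), 7.0))),
        )
        mirrored = TumorMask(
            grid=VolumeGrid(
                data=ref.data[::-1, :, :].copy(),
                affine=ref.grid.affine.copy(),
                space=REFERENCE,
            )
        )
        v_l, v_r = hemisphere_volumes(ref)
        mv_l, mv_r = hemisphere_volumes(mirrored)
        assert (v_l, v_r) == pytest.approx((mv_r, mv_l))
        assert laterality_index(v_l, v_r) == pytest.approx(-laterality_index(mv_l, mv_r))
        sides = {laterality(v_l, v_r), laterality(mv_l, mv_r)}
        assert sides == {"left", "right"} or v_l == v_r
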