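import numpy as np
import pytest

from calciscore.shortening import (
    ShorteningConfig,
    define_stump,
    find_side_components,
    grow_stump,
    shorten,
    truncate_aorta,
)
from calciscore.volumes_io import ArteryLabelMap

from conftest import straight_tube
from oracles import (
    brute_dilate,
    flood_fill_components,
    geodesic_distance,
    min_pair_distance,
)

CFG = ShorteningConfig()


class TestFindSideComponents:
    def test_six_branches(self, small_tree):
        _, arteries, _ = small_tree
        comps = find_side_components(arteries)
        assert len(comps) == 6
        assert sorted(c.label for c in comps) == [2, 2, 3, 3, 4, 4]
        # oracle: per-label flood fill agrees on count and sizes
        for label in (2, 3, 4):
            oracle = flood_fill_components(arteries.grid == label)
            ours = [c for c in comps if c.label == label]
            assert len(oracle) == len(ours)
            assert sorted(o.sum() for o in oracle) == sorted(c.size for c in ours)

    def test_aorta_only(self):
        grid = np.zeros((10, 10, 10), dtype=np.uint8)
        grid[4:6, 4:6, :] = 1
        assert find_side_components(ArteryLabelMap(grid=grid, spacing=1.0)) == []

    def test_gap_splits_component(self):
        grid = np.zeros((30, 8, 8), dtype=np.uint8)
        grid[0:10, 3, 3] = 4
        grid[11:20, 3, 3] = 4  # 1-voxel gap at x=10
        comps = find_side_components(ArteryLabelMap(grid=grid, spacing=1.0))
        assert len(comps) == 2
        assert len(flood_fill_components(grid == 4)) == 2


class TestDefineStump:
    def test_collar_matches_brute_force(self):
        shape = (40, 16, 16)
        aorta = np.zeros(shape, dtype=bool)
        aorta[0:10, :, :] = True
        branch = straight_tube(shape, (10, 7, 7), axis=0, length=25, radius=2)
        stump = define_stump(branch, aorta, CFG)
        expected = branch & brute_dilate(aorta, iterations=2)
        assert np.array_equal(stump, expected)
        assert stump.any()
        assert stump[10:12].any() and not stump[12:].any()

    def test_detached_component(self):
        shape = (60, 16, 16)
        aorta = np.zeros(shape, dtype=bool)
        aorta[0:5, :, :] = True
        branch = straight_tube(shape, (37, 7, 7), axis=0, length=20, radius=2)
        assert min_pair_distance(aorta, branch) >= 30  # ~3 cm away everywhere
        stump = define_stump(branch, aorta, CFG)
        assert not stump.any()

    @pytest.mark.parametrize("gap_mm,kept", [(20, True), (30, False)])
    def test_islet_rule(self, gap_mm, kept):
        # component with two pieces inside the dilated-aorta collar: the
        # main collar and a satellite at a controlled surface gap
        shape = (16, 70, 16)
        aorta = np.zeros(shape, dtype=bool)
        aorta[0:6, :, :] = True  # slab: dilation reaches x=6,7
        comp = np.zeros(shape, dtype=bool)
        comp[6:8, 2:6, 6:10] = True  # main collar piece
        sat_y = 5 + gap_mm + 1  # surface gap of gap_mm voxels
        comp[6:8, sat_y:sat_y + 3, 6:10] = True
        stump = define_stump(comp, aorta, CFG)
        main = np.zeros(shape, dtype=bool)
        main[6:8, 2:6, 6:10] = True
        satellite = comp & ~main
        assert np.all(stump[main])
        assert stump[satellite].any() == kept

    def test_empty_aorta_rejected(self):
        a = np.zeros((8, 8, 8), dtype=bool)
        with pytest.raises(ValueError):
            define_stump(a.copy(), a, CFG)


class TestGrowStump:
    def test_straight_tube_exact_length(self):
        shape = (64, 8, 8)
        comp = straight_tube(shape, (0, 3, 3), axis=0, length=60)
        stump = np.zeros(shape, dtype=bool)
        stump[0:2, 3, 3] = True
        grown = grow_stump(stump, comp, CFG)
        xs = np.nonzero(grown.any(axis=(1, 2)))[0]
        assert xs.max() == 1 + 25  # exactly 25 voxels past the distal stump voxel
        assert np.all(grown[stump])

    def test_short_tube_saturates(self):
        shape = (16, 8, 8)
        comp = straight_tube(shape, (0, 3, 3), axis=0, length=10)
        stump = np.zeros(shape, dtype=bool)
        stump[0, 3, 3] = True
        grown = grow_stump(stump, comp, CFG)
        assert np.array_equal(grown, comp)

    def test_empty_stump(self):
        comp = np.ones((6, 6, 6), dtype=bool)
        stump = np.zeros((6, 6, 6), dtype=bool)
        assert not grow_stump(stump, comp, CFG).any()

    def test_hairpin_geodesic_not_euclidean(self):
        # hairpin: out 20 voxels, cross 3, back 20 -> geodesic length ~40+,
        # Euclidean end-to-end only ~3.  Growth must follow arc length.
        shape = (30, 10, 10)
        comp = np.zeros(shape, dtype=bool)
        comp[0:21, 2, 5] = True
        comp[20, 3:6, 5] = True
        comp[1:21, 5, 5] = True
        stump = np.zeros(shape, dtype=bool)
        stump[0, 2, 5] = True
        grown = grow_stump(stump, comp, CFG)
        dist = geodesic_distance(comp, stump)
        expected = (dist >= 0) & (dist <= CFG.n_dilations)
        assert np.array_equal(grown, expected)
        # return leg tip is ~44 steps away: not reached despite being
        # 3 voxels from the stump in Euclidean terms
        assert not grown[1, 5, 5]

    def test_monotone_in_dilations(self):
        shape = (40, 10, 10)
        comp = straight_tube(shape, (0, 4, 4), axis=0, length=38, radius=1)
        stump = np.zeros(shape, dtype=bool)
        stump[0:2, 4, 4] = True
        prev = None
        for n in (5, 10, 15, 25):
            g = grow_stump(stump, comp, ShorteningConfig(n_dilations=n))
            if prev is not None:
                assert np.all(g[prev])
            prev = g

    def test_stump_outside_component_rejected(self):
        comp = np.zeros((6, 6, 6), dtype=bool)
        comp[0, 0, 0] = True
        stump = np.zeros((6, 6, 6), dtype=bool)
        stump[5, 5, 5] = True
        with pytest.raises(ValueError):
            grow_stump(stump, comp, CFG)


class TestTruncateAorta:
    def _aorta(self, top=100, shape=(8, 8, 110)):
        a = np.zeros(shape, dtype=bool)
        a[2:6, 2:6, 0:top + 1] = True
        return a

    def test_cut_ten_above(self):
        aorta = self._aorta()
        sides = np.zeros_like(aorta)
        sides[0, 0, 60] = True
        out = truncate_aorta(aorta, sides, CFG)
        zs = np.nonzero(out.any(axis=(0, 1)))[0]
        assert zs.max() == 70
        assert np.array_equal(out[:, :, :71], aorta[:, :, :71])

    def test_side_at_top_no_cut(self):
        aorta = self._aorta(top=60)
        sides = np.zeros_like(aorta)
        sides[0, 0, 60] = True
        out = truncate_aorta(aorta, sides, CFG)
        assert np.array_equal(out, aorta)

    def test_global_max_governs(self):
        aorta = self._aorta()
        sides = np.zeros_like(aorta)
        sides[0, 0, 60] = True
        sides[7, 7, 80] = True
        out = truncate_aorta(aorta, sides, CFG)
        assert np.nonzero(out.any(axis=(0, 1)))[0].max() == 90

    def test_no_sides_errors(self):
        aorta = self._aorta()
        with pytest.raises(ValueError):
            truncate_aorta(aorta, np.zeros_like(aorta), CFG)

    def test_no_sides_passthrough(self):
        aorta = self._aorta()
        cfg = ShorteningConfig(on_no_side_arteries="passthrough")
        out = truncate_aorta(aorta, np.zeros_like(aorta), cfg)
        assert np.array_equal(out, aorta)


class TestShorten:
    def test_full_tree(self, small_tree):
        _, arteries, _ = small_tree
        result = shorten(arteries)
        assert result.spacing == (1.0, 1.0, 1.0)
        # shortening never adds side-artery tissue
        for label in (2, 3, 4):
            assert np.all(arteries.grid[result.grid == label] == label)
        # every component ran the full 25 dilations (branches are 40 mm)
        assert all(l.dilations_run == 25 for l in result.component_logs)
        # aorta ends exactly 10 slices above the highest side voxel
        sides = np.isin(result.grid, (2, 3, 4))
        z_side = np.nonzero(sides.any(axis=(0, 1)))[0].max()
        z_aorta = np.nonzero((result.grid == 1).any(axis=(0, 1)))[0].max()
        assert z_aorta == z_side + 10

    def test_branch_trimmed_to_25mm_past_stump(self, small_tree, small_tree_cfg):
        _, arteries, _ = small_tree
        result = shorten(arteries)
        # renal +x branch at z=50: reaches 25 voxels past its stump
        grid = result.grid
        cx = (small_tree_cfg.grid_shape[0] - 1) / 2.0
        surf = int(np.floor(cx + small_tree_cfg.aorta_radius_mm))  # last aorta x
        mask = (grid == 4) & (np.arange(grid.shape[0])[:, None, None] > cx)
        xs = np.nonzero(mask.any(axis=(1, 2)))[0]
        assert xs.max() == surf + 2 + 25  # stump collar (2) + 25 dilations

    def test_idempotent(self, small_tree):
        _, arteries, _ = small_tree
        once = shorten(arteries)
        twice = shorten(once.as_label_map())
        assert np.array_equal(once.grid, twice.grid)

    def test_no_op_when_already_short(self):
        grid = np.zeros((40, 40, 40), dtype=np.uint8)
        x, y = np.ogrid[:40, :40]
        disc = (x - 20) ** 2 + (y - 20) ** 2 <= 36
        grid[:, :, 0:23][disc[:, :, None] & np.ones((1, 1, 23), bool)] = 1
        grid[27:37, 19:22, 10:13] = 2  # 10 mm stub branch
        arteries = ArteryLabelMap(grid=grid, spacing=1.0)
        out = shorten(arteries)
        assert np.array_equal(out.grid, grid)

    def test_determinism(self, small_tree):
        _, arteries, _ = small_tree
        a = shorten(arteries)
        b = shorten(arteries)
        assert np.array_equal(a.grid, b.grid)

    def test_missing_aorta(self):
        grid = np.zeros((10, 10, 10), dtype=np.uint8)
        grid[2, 2, 2] = 2
        with pytest.raises(ValueError, match="aorta"):
            shorten(ArteryLabelMap(grid=grid, spacing=1.0))

    def test_labels_subset_of_input(self, small_tree):
        _, arteries, _ = small_tree
        out = shorten(arteries)
        assert set(np.unique(out.grid)) <= set(np.unique(arteries.grid))

    def test_detached_branch_removed(self):
        grid = np.zeros((60, 20, 40), dtype=np.uint8)
        grid[0:8, :, :] = 1
        grid[40:55, 8:12, 18:22] = 4  # floating fragment far from the aorta
        grid[9:20, 8:12, 10:14] = 2  # attached-ish iliac (1 voxel off surface?)
        grid[8, 9:11, 11:13] = 2  # make contact
        out = shorten(ArteryLabelMap(grid=grid, spacing=1.0))
        assert not (out.grid == 4).any()
        assert (out.grid == 2).any()
        detached = [l for l in out.component_logs if l.detached]
        assert len(detached) == 1 and detached[0].label == 4

    def test_equivalence_with_geodesic_oracle(self):
        # random small blobby components against the BFS oracle
        rng = np.random.default_rng(7)
        for trial in range(5):
            shape = (24, 24, 24)
            comp = rng.random(shape) < 0.35
            comp[0:4] = True  # keep some mass near the "aorta"
            aorta = np.zeros(shape, dtype=bool)
            aorta[0:2] = True
            cfg = ShorteningConfig(n_dilations=int(rng.integers(3, 12)))
            stump = define_stump(comp, aorta, cfg)
            if not stump.any():
                continue
            grown = grow_stump(stump, comp, cfg)
            dist = geodesic_distance(comp, stump)
            expected = (dist >= 0) & (dist <= cfg.n_dilations)
            assert np.array_equal(grown, expected)
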