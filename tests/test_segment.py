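"""Region growing, post-processing and overlap metrics against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.measure import label as sk_label

from conftest import small_phantom_spec, binary_label
from implmotion.phantom import generate_pair
from implmotion.segment import carve_margin, dice, hd95, largest_component, region_grow
from implmotion.volio import ImageVolume, LabelVolume, LABEL_IMPLANT


def make_volume(grid, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageVolume(grid=np.asarray(grid, dtype=float), spacing=spacing, origin=origin)


def make_mask(grid, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return LabelVolume(grid=np.asarray(grid, dtype=np.int16), spacing=spacing, origin=origin)


class TestRegionGrow:
    def test_uniform_sphere_equals_threshold_oracle(self):
        x, y, z = np.mgrid[:24, :24, :24]
        sphere = ((x - 12) ** 2 + (y - 12) ** 2 + (z - 12) ** 2 <= 64).astype(float) * 3000
        vol = make_volume(sphere)
        mask = region_grow(vol, (12, 12, 12), low=1000)
        np.testing.assert_array_equal(mask.grid > 0, sphere >= 1000)

    def test_two_blobs_seed_selects_one(self):
        grid = np.zeros((20, 10, 10))
        grid[2:5, 2:5, 2:5] = 2000
        grid[12:15, 2:5, 2:5] = 2000
        mask = region_grow(make_volume(grid), (3, 3, 3), low=1000)
        # Independent component oracle via skimage labelling.
        comp = sk_label(grid >= 1000, connectivity=3)
        np.testing.assert_array_equal(mask.grid > 0, comp == comp[3, 3, 3])
        assert mask.grid[13, 3, 3] == 0

    def test_seed_outside_range_raises(self):
        grid = np.zeros((8, 8, 8))
        grid[4, 4, 4] = 2000
        with pytest.raises(ValueError, match="seed intensity"):
            region_grow(make_volume(grid), (0, 0, 0), low=1000)
        with pytest.raises(IndexError):
            region_grow(make_volume(grid), (99, 0, 0), low=1000)

    def test_seed_invariance_within_component(self):
        grid = np.zeros((16, 16, 16))
        grid[4:12, 4:12, 4:12] = 2500
        vol = make_volume(grid)
        a = region_grow(vol, (4, 4, 4), low=1000)
        b = region_grow(vol, (11, 11, 11), low=1000)
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_connectivity_6_vs_26_diagonal_touch(self):
        grid = np.zeros((6, 6, 6))
        grid[1, 1, 1] = grid[2, 2, 2] = 2000
        vol = make_volume(grid)
        assert region_grow(vol, (1, 1, 1), low=1000, connectivity=26).grid.sum() == 2
        assert region_grow(vol, (1, 1, 1), low=1000, connectivity=6).grid.sum() == 1

    def test_reproduces_phantom_implant_label_exactly(self):
        # Hard-edge, noise-free phantom: thresholding at the metal value
        # recovers the ground-truth implant label.
        spec = small_phantom_spec(edge_sigma_mm=0.0, grid_shape=(48, 48, 48))
        v1, _, l1, _, _ = generate_pair(spec)
        seed = tuple(np.argwhere(l1.grid == LABEL_IMPLANT)[0])
        mask = region_grow(v1, seed, low=spec.intensity_metal)
        np.testing.assert_array_equal(mask.grid > 0, l1.grid == LABEL_IMPLANT)


class TestLargestComponent:
    def test_single_blob_unchanged(self):
        grid = np.zeros((10, 10, 10), dtype=np.int16)
        grid[2:5, 2:5, 2:5] = 1
        mask = make_mask(grid)
        np.testing.assert_array_equal(largest_component(mask).grid, grid)

    def test_small_blob_removed(self):
        grid = np.zeros((20, 10, 10), dtype=np.int16)
        grid[1:6, 1:6, 1:5] = 1  # 100 voxels
        grid[15:16, 1:6, 1:2] = 1  # 5 voxels
        out = largest_component(make_mask(grid))
        assert out.grid[2, 2, 2] == 1 and out.grid[15, 1, 1] == 0
        assert out.grid.sum() == 100

    def test_tie_broken_by_first_linear_index(self):
        grid = np.zeros((10, 10, 10), dtype=np.int16)
        grid[1, 1, 1] = 1
        grid[5, 5, 5] = 1
        out = largest_component(make_mask(grid))
        assert out.grid[1, 1, 1] == 1 and out.grid[5, 5, 5] == 0

    def test_other_labels_untouched(self):
        grid = np.zeros((10, 10, 10), dtype=np.int16)
        grid[1:3, 1:3, 1:3] = 1
        grid[7, 7, 7] = 1
        grid[5, 5, 5] = 2
        out = largest_component(make_mask(grid), label=1)
        assert out.grid[5, 5, 5] == 2

    def test_absent_label_raises(self):
        with pytest.raises(ValueError, match="absent"):
            largest_component(make_mask(np.zeros((4, 4, 4), dtype=np.int16)))


class TestCarveMargin:
    def test_far_apart_bone_unchanged(self):
        bone = np.zeros((30, 10, 10), dtype=np.int16)
        implant = np.zeros_like(bone)
        bone[0:3] = 1
        implant[20:23] = 1
        out = carve_margin(make_mask(bone), make_mask(implant), radius_mm=3.0)
        np.testing.assert_array_equal(out.grid, bone)

    def test_adjacent_voxel_removed(self):
        bone = np.zeros((10, 10, 10), dtype=np.int16)
        implant = np.zeros_like(bone)
        implant[4, 4, 4] = 1
        bone[5, 4, 4] = 1
        out = carve_margin(make_mask(bone), make_mask(implant), radius_mm=3.0)
        assert out.grid.sum() == 0

    def test_removal_count_matches_distance_oracle(self):
        # Plate implant abutting a bone slab at 0.45 mm spacing.
        spacing = (0.45, 0.45, 0.45)
        bone = np.zeros((24, 24, 24), dtype=np.int16)
        implant = np.zeros_like(bone)
        implant[4:20, 4:20, 10:13] = 1
        bone[4:20, 4:20, 13:22] = 1
        radius = 3.0
        carved = carve_margin(make_mask(bone, spacing), make_mask(implant, spacing), radius_mm=radius)
        # Brute-force oracle: a bone voxel is removed iff some implant voxel
        # lies within the ellipsoidal voxel ball of per-axis radius
        # ceil(radius / spacing).
        r_vox = np.ceil(radius / np.asarray(spacing))
        bv = np.argwhere(bone)
        iv = np.argwhere(implant)
        scaled = cdist(bv / r_vox, iv / r_vox)
        removed_oracle = (scaled.min(axis=1) <= 1.0 + 1e-12).sum()
        assert bone.sum() - carved.grid.sum() == removed_oracle

    def test_never_adds_and_implant_untouched(self, rng):
        bone = make_mask((rng.random((16, 16, 16)) > 0.6).astype(np.int16))
        implant_grid = (rng.random((16, 16, 16)) > 0.9).astype(np.int16)
        implant = make_mask(implant_grid.copy())
        out = carve_margin(bone, implant, radius_mm=2.0)
        assert np.all(out.grid <= bone.grid)
        np.testing.assert_array_equal(implant.grid, implant_grid)

    def test_geometry_mismatch_raises(self):
        a = make_mask(np.zeros((4, 4, 4), dtype=np.int16))
        b = make_mask(np.zeros((5, 4, 4), dtype=np.int16))
        with pytest.raises(ValueError):
            carve_margin(a, b)


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8, 8), dtype=np.int16)
        a[:2] = 1
        b = np.zeros_like(a)
        b[6:] = 1
        assert dice(make_mask(a), make_mask(a)) == 1.0
        assert dice(make_mask(a), make_mask(b)) == 0.0

    def test_half_cube(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        a[0:2, 0:2, 0:2] = 1  # 8 voxels
        b = np.zeros_like(a)
        b[0:2, 0:2, 0:1] = 1  # half of it
        assert dice(make_mask(a), make_mask(b)) == pytest.approx(2 * 4 / (8 + 4))

    def test_symmetric_and_empty_convention(self, rng):
        a = make_mask((rng.random((8, 8, 8)) > 0.5).astype(np.int16))
        b = make_mask((rng.random((8, 8, 8)) > 0.5).astype(np.int16))
        assert dice(a, b) == dice(b, a)
        empty = make_mask(np.zeros((8, 8, 8), dtype=np.int16))
        assert dice(empty, empty) == 1.0


class TestHD95:
    def test_identical_masks_zero(self):
        a = np.zeros((8, 8, 8), dtype=np.int16)
        a[2:6, 2:6, 2:6] = 1
        assert hd95(make_mask(a), make_mask(a)) == 0.0

    def test_one_voxel_shift_at_045(self):
        a = np.zeros((12, 12, 12), dtype=np.int16)
        a[3:8, 3:8, 3:8] = 1
        b = np.roll(a, 1, axis=0)
        value = hd95(make_mask(a, (0.45,) * 3), make_mask(b, (0.45,) * 3))
        assert value == pytest.approx(0.45, abs=1e-12)

    def _oracle(self, a, b, spacing):
        """All-pairs brute-force pooled surface-distance percentile."""
        def surface(m):
            pts = []
            idx = np.argwhere(m)
            for p in idx:
                for d in np.eye(3, dtype=int):
                    for s in (1, -1):
                        q = p + s * d
                        if np.any(q < 0) or np.any(q >= np.array(m.shape)) or not m[tuple(q)]:
                            pts.append(p)
                            break
                    else:
                        continue
                    break
            return np.asarray(pts) * spacing

        pa, pb = surface(a), surface(b)
        d_ab = cdist(pa, pb).min(axis=1)
        d_ba = cdist(pb, pa).min(axis=1)
        return np.percentile(np.concatenate([d_ab, d_ba]), 95)

    def test_matches_brute_force_oracle(self, rng):
        a = np.zeros((10, 10, 10), dtype=np.int16)
        a[2:7, 3:8, 2:6] = 1
        from scipy.ndimage import binary_dilation

        b = binary_dilation(a).astype(np.int16)
        spacing = np.array([0.45, 0.45, 0.45])
        got = hd95(make_mask(a, tuple(spacing)), make_mask(b, tuple(spacing)))
        assert got == pytest.approx(self._oracle(a > 0, b > 0, spacing), abs=1e-12)

    def test_translation_invariance_and_symmetry(self):
        a = np.zeros((10, 10, 10), dtype=np.int16)
        a[2:5, 2:5, 2:5] = 1
        b = np.roll(a, 2, axis=2)
        m1 = make_mask(a, (0.5,) * 3, origin=(0, 0, 0))
        m2 = make_mask(b, (0.5,) * 3, origin=(7.0, -3.0, 2.0))
        assert hd95(m1, m2) == hd95(m2, m1)
        m2b = make_mask(b, (0.5,) * 3, origin=(0, 0, 0))
        assert hd95(m1, m2) == hd95(m1, m2b)

    def test_empty_mask_rejected(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        b = a.copy()
        b[1, 1, 1] = 1
        with pytest.raises(ValueError):
            hd95(make_mask(a), make_mask(b))
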