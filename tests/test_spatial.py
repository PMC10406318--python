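"""Grid geometry: resampling, thresholding, overlap and mask algebra."""

import numpy as np
import pandas as pd
import pytest

import sysdecode as sd
from sysdecode.spatial import GridMismatchError


def _pmap(grid, values, name="m"):
    return sd.ProbabilityMap(grid, np.asarray(values, dtype=float), name=name)


def _mask(grid, members, name="m"):
    return sd.RegionMask(grid, members, name=name)


class TestVolumeGrid:
    def test_voxel_size_from_affine(self):
        g = sd.VolumeGrid.isotropic((4, 4, 4), 2.5)
        assert np.allclose(g.voxel_size, 2.5)

    def test_rejects_singular_affine(self):
        aff = np.zeros((4, 4))
        with pytest.raises(ValueError, match="invertible"):
            sd.VolumeGrid((4, 4, 4), aff)

    def test_world_voxel_round_trip(self, small_grid, rng):
        ijk = rng.integers(0, 12, size=(20, 3))
        back = small_grid.world_to_voxel(small_grid.voxel_centers(ijk))
        assert np.allclose(back, ijk, atol=1e-9)


class TestResample:
    def test_identity_resample_is_voxelwise_equal(self, small_grid, rng):
        vals = rng.random(small_grid.shape)
        out = sd.resample_to_grid(_pmap(small_grid, vals), small_grid)
        assert np.allclose(out.values, vals, atol=1e-7)

    def test_constant_map_stays_constant(self):
        src = sd.VolumeGrid.isotropic((10, 10, 10), 1.0)
        tgt = sd.VolumeGrid.isotropic((5, 5, 5), 2.0)
        out = sd.resample_to_grid(_pmap(src, np.full(src.shape, 0.7)), tgt)
        interior = out.values[1:-1, 1:-1, 1:-1]
        assert np.allclose(interior, 0.7, atol=1e-7)

    def test_trilinear_matches_hand_rolled_oracle(self):
        # single unit-probability voxel on a 1 mm grid, resampled to 2 mm:
        # compare every output voxel against direct trilinear interpolation
        # of the source at the target voxel centers
        src = sd.VolumeGrid.isotropic((12, 12, 12), 1.0)
        vals = np.zeros(src.shape)
        vals[5, 6, 7] = 1.0
        tgt = sd.VolumeGrid.isotropic((6, 6, 6), 2.0)
        out = sd.resample_to_grid(_pmap(src, vals), tgt, method="trilinear")

        def oracle(xyz):
            ijk = src.world_to_voxel(xyz)[0]
            base = np.floor(ijk).astype(int)
            frac = ijk - base
            acc = 0.0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        idx = base + [di, dj, dk]
                        if np.any(idx < 0) or np.any(idx >= src.shape):
                            continue
                        w = ((frac[0] if di else 1 - frac[0])
                             * (frac[1] if dj else 1 - frac[1])
                             * (frac[2] if dk else 1 - frac[2]))
                        acc += w * vals[tuple(idx)]
            return acc

        for t_idx in np.ndindex(tgt.shape):
            expect = oracle(tgt.voxel_centers(np.array([t_idx])))
            assert out.values[t_idx] == pytest.approx(expect, abs=1e-6)

    def test_trilinear_rejected_for_labels(self, small_grid):
        labels = np.zeros(small_grid.shape, dtype=np.int32)
        labels[0, 0, 0] = 1
        table = pd.DataFrame({"name": ["a"], "hemisphere": ["L"],
                              "group": ["g"]}, index=[1])
        parc = sd.Parcellation(small_grid, labels, table)
        with pytest.raises(ValueError, match="label"):
            sd.resample_to_grid(parc, small_grid, method="trilinear")

    def test_label_resample_preserves_label_set(self, rng):
        src = sd.VolumeGrid.isotropic((8, 8, 8), 2.0)
        labels = rng.integers(0, 4, size=src.shape).astype(np.int32)
        table = pd.DataFrame({"name": list("abc"), "hemisphere": ["L"] * 3,
                              "group": ["g"] * 3}, index=[1, 2, 3])
        parc = sd.Parcellation(src, labels, table)
        tgt = sd.VolumeGrid.isotropic((4, 4, 4), 4.0)
        out = sd.resample_to_grid(parc, tgt, method="nearest")
        assert set(np.unique(out.labels)) <= set(np.unique(labels))
        assert out.table.equals(parc.table)

    def test_nearest_round_trip_on_integer_multiple_grids(self, rng):
        fine = sd.VolumeGrid.isotropic((8, 8, 8), 2.0)
        # coarse voxel centers coincide with every other fine voxel center
        coarse = sd.VolumeGrid.isotropic((4, 4, 4), 4.0,
                                         origin=tuple(fine.affine[:3, 3]))
        labels = rng.integers(0, 3, size=coarse.shape).astype(np.int32)
        table = pd.DataFrame({"name": ["a", "b"], "hemisphere": ["L", "R"],
                              "group": ["g", "g"]}, index=[1, 2])
        parc = sd.Parcellation(coarse, labels, table)
        there = sd.resample_to_grid(parc, fine, method="nearest")
        back = sd.resample_to_grid(there, coarse, method="nearest")
        assert np.array_equal(back.labels, labels)


class TestThreshold:
    def test_strict_inequality_at_boundary(self):
        g = sd.VolumeGrid.isotropic((3, 1, 1), 2.0)
        pm = _pmap(g, np.array([0.2, 0.25, 0.3]).reshape(3, 1, 1))
        m = sd.threshold_probability(pm, 0.25)
        assert m.members.ravel().tolist() == [False, False, True]

    def test_all_zero_gives_empty_mask(self, small_grid):
        m = sd.threshold_probability(_pmap(small_grid, np.zeros(small_grid.shape)))
        assert m.is_empty

    def test_tau_zero_matches_exhaustive_scan(self, small_grid, rng):
        vals = rng.random(small_grid.shape) * (rng.random(small_grid.shape) > 0.5)
        m = sd.threshold_probability(_pmap(small_grid, vals), 0.0)
        assert m.n_voxels == int(sum(v > 0 for v in vals.ravel()))

    @pytest.mark.parametrize("tau1,tau2", [(0.1, 0.3), (0.0, 0.25), (0.4, 0.9)])
    def test_monotone_in_tau(self, small_grid, rng, tau1, tau2):
        pm = _pmap(small_grid, rng.random(small_grid.shape))
        lo = sd.threshold_probability(pm, tau1)
        hi = sd.threshold_probability(pm, tau2)
        assert not np.any(hi.members & ~lo.members)

    def test_rejects_tau_out_of_range(self, small_grid):
        pm = _pmap(small_grid, np.zeros(small_grid.shape))
        with pytest.raises(ValueError):
            sd.threshold_probability(pm, 1.0)


class TestOverlapFraction:
    def _parc(self, grid, labels):
        ids = sorted(set(np.unique(labels)) - {0})
        table = pd.DataFrame({"name": [f"p{i}" for i in ids],
                              "hemisphere": ["L"] * len(ids),
                              "group": ["g"] * len(ids)}, index=ids)
        return sd.Parcellation(grid, labels.astype(np.int32), table)

    def test_eight_of_ten_voxels(self, small_grid):
        labels = np.zeros(small_grid.shape, dtype=np.int32)
        labels.ravel()[:10] = 1
        cover = np.zeros(small_grid.shape, dtype=bool)
        cover.ravel()[:8] = True
        parc = self._parc(small_grid, labels)
        assert sd.overlap_fraction(_mask(small_grid, cover), parc, 1) == pytest.approx(0.8)

    def test_full_cover_gives_one_for_every_parcel(self, small_grid, rng):
        labels = rng.integers(0, 5, size=small_grid.shape)
        parc = self._parc(small_grid, labels)
        cover = _mask(small_grid, np.ones(small_grid.shape, dtype=bool))
        for lab in parc.label_ids:
            assert sd.overlap_fraction(cover, parc, lab) == 1.0

    def test_matches_brute_force_count(self, small_grid, rng):
        labels = rng.integers(0, 6, size=small_grid.shape)
        cover_arr = rng.random(small_grid.shape) > 0.6
        parc = self._parc(small_grid, labels)
        cover = _mask(small_grid, cover_arr)
        for lab in parc.label_ids:
            want = sum(1 for idx in np.ndindex(small_grid.shape)
                       if labels[idx] == lab and cover_arr[idx])
            total = int((labels == lab).sum())
            assert sd.overlap_fraction(cover, parc, lab) == pytest.approx(want / total)

    def test_monotone_in_cover(self, small_grid, rng):
        labels = rng.integers(0, 3, size=small_grid.shape)
        parc = self._parc(small_grid, labels)
        a = rng.random(small_grid.shape) > 0.7
        b = a | (rng.random(small_grid.shape) > 0.7)
        assert (sd.overlap_fraction(_mask(small_grid, b), parc, 1)
                >= sd.overlap_fraction(_mask(small_grid, a), parc, 1))

    def test_errors(self, small_grid):
        labels = np.ones(small_grid.shape, dtype=np.int32)
        parc = self._parc(small_grid, labels)
        other = sd.VolumeGrid.isotropic((12, 12, 12), 3.0)
        with pytest.raises(GridMismatchError):
            sd.overlap_fraction(_mask(other, np.ones(other.shape, bool)), parc, 1)
        with pytest.raises(ValueError, match="no voxels"):
            sd.overlap_fraction(_mask(small_grid, np.ones(small_grid.shape, bool)),
                                parc, 99)


class TestMaskAlgebra:
    def test_intersection_idempotent(self, small_grid, rng):
        a = _mask(small_grid, rng.random(small_grid.shape) > 0.5)
        assert np.array_equal(sd.mask_intersection(a, a).members, a.members)

    def test_disjoint_masks(self, small_grid):
        m1 = np.zeros(small_grid.shape, bool)
        m2 = np.zeros(small_grid.shape, bool)
        m1[0], m2[5] = True, True
        a, b = _mask(small_grid, m1), _mask(small_grid, m2)
        assert not sd.any_overlap(a, b)
        assert sd.mask_intersection(a, b).is_empty

    def test_inclusion_exclusion(self, small_grid, rng):
        a = _mask(small_grid, rng.random(small_grid.shape) > 0.4)
        b = _mask(small_grid, rng.random(small_grid.shape) > 0.6)
        union = sd.mask_union(a, b).n_voxels
        inter = sd.mask_intersection(a, b).n_voxels
        assert union == a.n_voxels + b.n_voxels - inter

    def test_grid_mismatch_rejected(self, small_grid):
        other = sd.VolumeGrid.isotropic((12, 12, 12), 3.0)
        with pytest.raises(GridMismatchError):
            sd.mask_union(_mask(small_grid, np.zeros(small_grid.shape, bool)),
                          _mask(other, np.zeros(other.shape, bool)))
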