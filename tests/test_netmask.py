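"""TFCE, sign-flip permutation inference, mask building and Dice."""

import numpy as np
import pytest

from mtlnet.netmask import (
    PermResult, build_network_masks, dice, one_sample_perm_test,
    paired_perm_test, participant_mask, split_by_parcellation, tfce,
)
from mtlnet.grids import SeedRoi, VolumeGrid


def brute_force_tfce(stat, E=0.5, H=2.0, dh=None, connectivity=26, n_steps=100):
    """Independent oracle: per-threshold BFS connected-component summation."""
    stat = np.asarray(stat, dtype=float)
    peak = stat.max()
    out = np.zeros_like(stat)
    if peak <= 0:
        return out
    if dh is None:
        dh = peak / n_steps
        steps = n_steps
    else:
        steps = int(np.floor(peak / dh + 1e-9))
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [(dx, dy, dz)
                 for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
                 if (dx, dy, dz) != (0, 0, 0)
                 and ((dx != 0) + (dy != 0) + (dz != 0)
                      <= {18: 2, 26: 3}[connectivity])]
    nx, ny, nz = stat.shape
    for k in range(1, steps + 1):
        h = dh * k
        supra = stat >= h
        visited = np.zeros_like(supra)
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not supra[x, y, z] or visited[x, y, z]:
                        continue
                    queue = [(x, y, z)]
                    visited[x, y, z] = True
                    comp = []
                    while queue:
                        cx, cy, cz = queue.pop()
                        comp.append((cx, cy, cz))
                        for dx, dy, dz in neigh:
                            px, py, pz = cx + dx, cy + dy, cz + dz
                            if (0 <= px < nx and 0 <= py < ny and 0 <= pz < nz
                                    and supra[px, py, pz]
                                    and not visited[px, py, pz]):
                                visited[px, py, pz] = True
                                queue.append((px, py, pz))
                    inc = (len(comp) ** E) * (h ** H) * dh
                    for c in comp:
                        out[c] += inc
    return out


class TestTfce:
    def test_all_zero_map(self):
        assert not tfce(np.zeros((4, 4, 4))).any()

    def test_negative_map_gives_zero(self):
        assert not tfce(-np.ones((3, 3, 3))).any()

    def test_single_voxel_hand_sum(self):
        # sum_{k=1..10} 1^0.5 * (0.1 k)^2 * 0.1 = 0.385
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 1.0
        out = tfce(m, E=0.5, H=2.0, dh=0.1)
        assert out[2, 2, 2] == pytest.approx(0.385, abs=1e-12)
        assert out.sum() == pytest.approx(0.385, abs=1e-12)

    def test_two_equal_blobs_symmetric(self):
        m = np.zeros((9, 4, 4))
        m[0:2, 0:2, 0:2] = 2.0
        m[7:9, 2:4, 2:4] = 2.0
        out = tfce(m)
        vals_a = out[0:2, 0:2, 0:2].ravel()
        vals_b = out[7:9, 2:4, 2:4].ravel()
        np.testing.assert_allclose(np.sort(vals_a), np.sort(vals_b), atol=1e-12)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_brute_force_oracle(self, connectivity):
        rng = np.random.default_rng(0)
        for _ in range(8):
            stat = rng.standard_normal((5, 5, 5))
            got = tfce(stat, connectivity=connectivity)
            want = brute_force_tfce(stat, connectivity=connectivity)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_scaling_monotonicity(self):
        rng = np.random.default_rng(1)
        stat = np.abs(rng.standard_normal((6, 6, 6)))
        lo = tfce(stat, dh=0.02)
        hi = tfce(2.5 * stat, dh=0.02)
        assert np.all(hi >= lo - 1e-12)


def _noise_maps(n, shape, seed):
    rng = np.random.default_rng(seed)
    return list(rng.standard_normal((n,) + shape))


class TestOneSamplePermTest:
    def test_requires_five_maps(self):
        with pytest.raises(ValueError, match="at least 5"):
            one_sample_perm_test(_noise_maps(4, (4, 4, 4), 0),
                                 np.ones((4, 4, 4), bool), n_perm=128)

    def test_exhaustive_enumeration_at_n8(self):
        maps = _noise_maps(8, (4, 4, 4), 1)
        res = one_sample_perm_test(maps, np.ones((4, 4, 4), bool),
                                   n_perm=1000, seed=0)
        assert res.n_perm_used == 256
        # p-values live on the (1 + k)/257 grid
        grid_pos = res.p_fwe_map * 257
        np.testing.assert_allclose(grid_pos, np.round(grid_pos), atol=1e-9)
        assert res.p_fwe_map.min() >= 1 / 257

    def test_planted_blob_detected(self):
        rng = np.random.default_rng(2)
        shape = (8, 8, 8)
        maps = []
        for _ in range(12):
            m = rng.standard_normal(shape) * 0.1
            m[2:5, 2:5, 2:5] += 5.0
            maps.append(m)
        res = one_sample_perm_test(maps, np.ones(shape, bool),
                                   n_perm=500, seed=3)
        assert res.sig_mask[2:5, 2:5, 2:5].all()
        assert res.sig_mask.sum() <= 27 + 40  # blob plus at most a thin rim

    def test_reproducible_and_order_invariant(self):
        maps = _noise_maps(10, (5, 5, 5), 4)
        mask = np.ones((5, 5, 5), bool)
        a = one_sample_perm_test(maps, mask, n_perm=200, seed=9)
        b = one_sample_perm_test(maps, mask, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.p_fwe_map, b.p_fwe_map)
        # subject order must not matter (exhaustive flips at n = 10... not
        # exhaustive at 200 perms, but the observed stat and exchangeable
        # null keep p-values identical for identical seeds after shuffling
        # because signs are drawn independently of map order)
        perm = list(reversed(maps))
        c = one_sample_perm_test(perm, mask, n_perm=1024, seed=9)
        d = one_sample_perm_test(maps, mask, n_perm=1024, seed=9)
        np.testing.assert_array_equal(c.sig_mask, d.sig_mask)

    def test_fwe_control_quick(self):
        """Smoke-scale FWE check at a 3-sigma Monte-Carlo bound (the
        spec-scale 2-sigma suite runs in test_acceptance)."""
        false_pos = 0
        n_datasets = 60
        for i in range(n_datasets):
            maps = _noise_maps(8, (6, 6, 6), 100 + i)
            res = one_sample_perm_test(maps, np.ones((6, 6, 6), bool),
                                       n_perm=256, seed=i)
            false_pos += bool(res.sig_mask.any())
        assert false_pos / n_datasets <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_datasets)


class TestPairedPermTest:
    def test_identical_lists_give_nothing(self):
        maps = _noise_maps(8, (4, 4, 4), 5)
        res = paired_perm_test(maps, maps, np.ones((4, 4, 4), bool),
                               n_perm=256, seed=0)
        assert not res.sig_mask.any()

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            paired_perm_test(_noise_maps(6, (4, 4, 4), 6),
                             _noise_maps(5, (4, 4, 4), 7),
                             np.ones((4, 4, 4), bool))

    def test_constant_blob_offset_detected_one_sided(self):
        rng = np.random.default_rng(8)
        shape = (6, 6, 6)
        blob = np.zeros(shape)
        blob[1:4, 1:4, 1:4] = 3.0
        maps_b = list(rng.standard_normal((10,) + shape) * 0.2)
        maps_a = [b + blob for b in maps_b]
        mask = np.ones(shape, bool)
        fwd = paired_perm_test(maps_a, maps_b, mask, n_perm=500, seed=1)
        rev = paired_perm_test(maps_b, maps_a, mask, n_perm=500, seed=1)
        assert fwd.sig_mask[1:4, 1:4, 1:4].all()
        assert not rev.sig_mask.any()

    def test_swapping_mirrors_the_one_sided_tests(self):
        rng = np.random.default_rng(9)
        shape = (5, 5, 5)
        maps_a = list(rng.standard_normal((8,) + shape))
        maps_b = list(rng.standard_normal((8,) + shape))
        mask = np.ones(shape, bool)
        ab = paired_perm_test(maps_a, maps_b, mask, n_perm=256, seed=2)
        ba = paired_perm_test(maps_b, maps_a, mask, n_perm=256, seed=2)
        # the two orderings test opposite one-sided hypotheses on the same
        # exhaustive sign-flip null, so the t-maps are exact mirrors
        np.testing.assert_allclose(ab.t_map, -ba.t_map, atol=1e-10)


def _fake_perm_result(sig, alpha=0.05):
    sig = np.asarray(sig, dtype=bool)
    return PermResult(t_map=sig.astype(float), tfce_map=sig.astype(float),
                      p_fwe_map=np.where(sig, 0.01, 1.0), sig_mask=sig,
                      null_max=np.zeros(100), n_perm_used=100, alpha=alpha)


class TestMaskBuilding:
    def test_intersection_rule(self):
        shape = (5, 5, 5)
        ones = np.ones(shape, bool)
        none = np.zeros(shape, bool)
        res = build_network_masks(_fake_perm_result(ones),
                                  _fake_perm_result(ones),
                                  _fake_perm_result(none),
                                  _fake_perm_result(none))
        assert not res.at_mask.any() and not res.pm_mask.any()

    def test_disjoint_paired_contrasts_give_disjoint_masks(self):
        shape = (6, 6, 6)
        ones = np.ones(shape, bool)
        prc_paired = np.zeros(shape, bool)
        prc_paired[:3] = True
        phc_paired = ~prc_paired
        res = build_network_masks(_fake_perm_result(ones),
                                  _fake_perm_result(ones),
                                  _fake_perm_result(prc_paired),
                                  _fake_perm_result(phc_paired))
        assert not (res.at_mask & res.pm_mask).any()
        assert res.provenance["n_voxels"]["AT"] == prc_paired.sum()

    def test_union_option(self):
        shape = (4, 4, 4)
        half = np.zeros(shape, bool)
        half[:2] = True
        res = build_network_masks(_fake_perm_result(half),
                                  _fake_perm_result(half),
                                  _fake_perm_result(~half),
                                  _fake_perm_result(half),
                                  at_combine="union")
        assert res.at_mask.all()


class TestParticipantMask:
    def _seed(self, shape, sl):
        vox = np.zeros(shape, bool)
        vox[sl] = True
        return SeedRoi("PRC", vox, VolumeGrid(shape))

    def test_full_gm_no_seed_overlap(self):
        shape = (5, 5, 5)
        group = np.ones(shape, bool)
        seed = self._seed(shape, np.s_[0, 0, 0])
        group[0, 0, 0] = False  # group mask avoids the seed entirely
        out = participant_mask(group, np.ones(shape), seeds=[seed])
        np.testing.assert_array_equal(out, group)

    def test_zero_gm_gives_empty(self):
        shape = (4, 4, 4)
        out = participant_mask(np.ones(shape, bool), np.zeros(shape))
        assert not out.any()

    def test_seed_removal_arithmetic(self):
        shape = (10, 10, 1)
        group = np.zeros(shape, bool)
        group.ravel()[:100] = True  # 100 voxels
        seed = self._seed(shape, np.s_[0, 0:10, 0])  # 10 of them are seed
        out = participant_mask(group, np.ones(shape), seeds=[seed])
        assert out.sum() == 90

    def test_gm_threshold_is_inclusive(self):
        shape = (3, 3, 3)
        out = participant_mask(np.ones(shape, bool), np.full(shape, 0.5))
        assert out.all()


class TestSplitByParcellation:
    def test_min_voxel_rule_inclusive_at_100(self):
        shape = (30, 10, 1)
        mask = np.ones(shape, bool)
        labels = np.zeros(shape, int)
        labels[0:10, 0:10, 0] = 1     # 100 voxels -> kept
        labels[10:20, 0:10, 0] = 2    # 100 voxels, 1 outside mask -> dropped
        mask[10, 0, 0] = False
        rois = split_by_parcellation(mask, labels, min_voxels=100)
        assert [r[0] for r in rois] == [1]
        assert rois[0][1].sum() == 100

    def test_empty_mask_gives_empty_list(self):
        assert split_by_parcellation(np.zeros((4, 4, 4), bool),
                                     np.ones((4, 4, 4), int)) == []

    def test_ordering_by_label_id(self):
        shape = (4, 4, 4)
        labels = np.zeros(shape, int)
        labels[0] = 5
        labels[1] = 2
        rois = split_by_parcellation(np.ones(shape, bool), labels, min_voxels=4)
        assert [r[0] for r in rois] == [2, 5]


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert dice(a, b) == 0.0

    def test_counting_example(self):
        # |a| = 4, |b| = 6, overlap 2 -> 2*2/10 = 0.4
        a = np.zeros((10, 1, 1), bool)
        b = np.zeros((10, 1, 1), bool)
        a[0:4] = True
        b[2:8] = True
        assert dice(a, b) == pytest.approx(0.4)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0
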