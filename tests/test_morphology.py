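import numpy as np
import pytest
from scipy import ndimage

import rootct as rc


def _mask(data, vs=0.05, label="m"):
    return rc.ROIMask(np.asarray(data, bool), vs, label=label)


def _bruteforce_fractional_dilation(mask, radius):
    """Direct evaluation of the boundary-offset dilation rule."""
    fg = np.argwhere(mask)
    out = mask.copy()
    for p in np.argwhere(~mask):
        d = np.sqrt(((fg - p) ** 2).sum(axis=1)).min()
        if d - 0.5 <= radius + 1e-9:
            out[tuple(p)] = True
    return out


def flood_fill_components(mask, connectivity=26):
    """Independent connected-component labeling by explicit BFS flood fill."""
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)]
    if connectivity == 6:
        offsets = [o for o in offsets if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    labels = np.zeros(mask.shape, np.int32)
    nxt = 0
    for start in map(tuple, np.argwhere(mask)):
        if labels[start]:
            continue
        nxt += 1
        stack = [start]
        labels[start] = nxt
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if (0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1]
                        and 0 <= p[2] < mask.shape[2]
                        and mask[p] and not labels[p]):
                    labels[p] = nxt
                    stack.append(p)
    return labels, nxt


class TestDilateROI:
    def test_radius_zero_is_identity(self, rng):
        m = rng.uniform(size=(12, 12, 12)) < 0.2
        out = rc.dilate_roi(_mask(m), 0.0)
        np.testing.assert_array_equal(out.data, m)

    @pytest.mark.parametrize("radius,expected", [(0.5, 7), (1.0, 19)])
    def test_single_voxel_counts(self, radius, expected):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        out = rc.dilate_roi(_mask(m), radius)
        assert out.voxel_count() == expected
        np.testing.assert_array_equal(out.data,
                                      _bruteforce_fractional_dilation(m, radius))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            rc.dilate_roi(_mask(np.ones((3, 3, 3))), -0.1)

    def test_extensive_and_monotone(self, rng):
        m = rng.uniform(size=(15, 15, 15)) < 0.1
        prev = m
        for r in (0.5, 1.0, 1.7, 2.5):
            out = rc.dilate_roi(_mask(m), r).data
            assert (out | m).sum() == out.sum()       # extensive
            assert (out | prev).sum() == out.sum()    # monotone in radius
            prev = out

    @pytest.mark.parametrize("radius", [1, 2])
    def test_integer_radius_matches_ball_structuring_element(self, rng, radius):
        # classical dilation with a Euclidean ball of radius r + 0.5 sampled
        # at voxel centres is the independent reference
        r = radius + 0.5
        n = int(np.ceil(r))
        z, y, x = np.mgrid[-n:n + 1, -n:n + 1, -n:n + 1]
        ball = z**2 + y**2 + x**2 <= r**2
        for _ in range(10):
            m = rng.uniform(size=(20, 20, 20)) < 0.05
            expected = ndimage.binary_dilation(m, structure=ball)
            out = rc.dilate_roi(_mask(m), float(radius))
            np.testing.assert_array_equal(out.data, expected)


class TestSubtractROI:
    def test_self_subtraction_empty(self, rng):
        m = _mask(rng.uniform(size=(8, 8, 8)) < 0.4)
        assert rc.subtract_roi(m, m).voxel_count() == 0

    def test_subtract_empty_is_identity(self, rng):
        m = rng.uniform(size=(8, 8, 8)) < 0.4
        out = rc.subtract_roi(_mask(m), _mask(np.zeros((8, 8, 8))))
        np.testing.assert_array_equal(out.data, m)

    def test_matches_andnot_oracle(self, rng):
        a = rng.uniform(size=(20, 20, 20)) < 0.5
        b = rng.uniform(size=(20, 20, 20)) < 0.5
        out = rc.subtract_roi(_mask(a), _mask(b))
        np.testing.assert_array_equal(out.data, a & ~b)
        assert not (out.data & b).any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rc.subtract_roi(_mask(np.ones((3, 3, 3))), _mask(np.ones((4, 4, 4))))


class TestLabelComponents:
    def test_corner_voxels_connectivity(self):
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        assert rc.label_components(_mask(m), 26).n_components == 1
        assert rc.label_components(_mask(m), 6).n_components == 2

    def test_empty_mask(self):
        lab = rc.label_components(_mask(np.zeros((4, 4, 4))))
        assert lab.n_components == 0 and lab.sizes == {}

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            rc.label_components(_mask(np.ones((3, 3, 3))), 8)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_partition_matches_flood_fill_oracle(self, rng, connectivity):
        m = rng.uniform(size=(30, 30, 30)) < 0.08
        lab = rc.label_components(_mask(m), connectivity)
        oracle, n = flood_fill_components(m, connectivity)
        assert lab.n_components == n
        # same partition up to label permutation
        pair = lab.labels.ravel() * (n + 1) + oracle.ravel()
        assert len(np.unique(pair[m.ravel()])) == n
        assert sum(lab.sizes.values()) == int(m.sum())


class TestSizeFilter:
    @staticmethod
    def _blocks_mask(sizes, shape=(40, 60, 90)):
        """Disjoint rectangular components with exactly the given voxel counts."""
        m = np.zeros(shape, bool)
        x0 = 0
        for s in sizes:
            width = int(np.ceil(s / (shape[0] - 2) / 10))
            # fill a (nz-2, 10, width) block then trim to exact size
            block = np.zeros(((shape[0] - 2), 10, width + 1), bool)
            block.ravel()[:s] = True
            m[1:-1, 1:11, x0:x0 + width + 1] = block
            x0 += width + 3
        return m

    def test_strict_inequality_deletion(self):
        m = self._blocks_mask([12000, 9999, 3])
        lab = rc.label_components(_mask(m))
        assert sorted(lab.sizes.values()) == [3, 9999, 12000]
        out, report = rc.size_filter(lab, 10000)
        assert report["retained_components"] == 1
        assert out.voxel_count() == 12000

    def test_equality_survives(self):
        m = self._blocks_mask([500])
        lab = rc.label_components(_mask(m))
        out, report = rc.size_filter(lab, 500)
        assert report["retained_components"] == 1
        assert out.voxel_count() == 500

    def test_min_voxels_validation(self):
        lab = rc.label_components(_mask(np.ones((3, 3, 3))))
        with pytest.raises(ValueError):
            rc.size_filter(lab, 0)

    def test_matches_count_and_compare_oracle(self, rng):
        m = rng.uniform(size=(64, 64, 64)) < 0.03
        lab = rc.label_components(_mask(m))
        out, _ = rc.size_filter(lab, 40)
        oracle_labels, n = flood_fill_components(m, 26)
        expected = np.zeros_like(m)
        for l in range(1, n + 1):
            comp = oracle_labels == l
            if comp.sum() >= 40:
                expected |= comp
        np.testing.assert_array_equal(out.data, expected)
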