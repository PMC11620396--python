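"""Skeletonization: simple-point tests vs brute-force homology, thinning
topology preservation, soft-skeleton behaviour, binarization contract."""

import numpy as np
import pytest

import oracles
from topotube.metrics import betti_numbers
from topotube.phantom import PhantomSpec, generate_tree, rasterize_tube
from topotube.skeletonize import (
    BinarizationParams,
    is_simple_boolean,
    is_simple_euler,
    lee_skeleton,
    skeletonize_toppreserving,
    soft_binarize,
    soft_skeleton,
)


def _patch(fill=False):
    p = np.full((3, 3, 3), fill, bool)
    p[1, 1, 1] = True
    return p


class TestSimplePoints:
    def test_isolated_voxel_not_simple(self):
        p = _patch()
        assert not is_simple_euler(p)
        assert not is_simple_boolean(p)

    def test_endpoint_is_simple(self):
        p = _patch(); p[1, 1, 2] = True
        assert is_simple_euler(p)
        assert is_simple_boolean(p)
        assert oracles.is_simple_bruteforce(p)

    def test_line_middle_not_simple(self):
        p = _patch(); p[1, 1, 0] = p[1, 1, 2] = True
        assert not is_simple_euler(p)
        assert not is_simple_boolean(p)
        assert not oracles.is_simple_bruteforce(p)

    def test_full_block_center_creates_cavity(self):
        # removing the center of a solid 3x3x3 block opens a cavity:
        # the brute-force oracle says non-simple, and both tests agree
        p = np.ones((3, 3, 3), bool)
        assert not oracles.is_simple_bruteforce(p)
        assert not is_simple_euler(p)
        assert not is_simple_boolean(p)

    def test_block_corner_is_simple(self):
        p = np.zeros((3, 3, 3), bool)
        p[1:, 1:, 1:] = True
        assert is_simple_euler(p)
        assert is_simple_boolean(p)
        assert oracles.is_simple_bruteforce(p)

    def test_background_center_rejected(self):
        p = np.zeros((3, 3, 3), bool)
        with pytest.raises(ValueError):
            is_simple_euler(p)
        with pytest.raises(ValueError):
            is_simple_boolean(p)

    @pytest.mark.parametrize("seed", range(4))
    def test_agreement_with_homology_oracle(self, seed):
        """Euler and Boolean characterizations both match the brute-force
        patch-homology definition of simplicity on random neighborhoods."""
        r = np.random.default_rng(seed)
        for _ in range(120):
            p = r.random((3, 3, 3)) < r.uniform(0.1, 0.9)
            p[1, 1, 1] = True
            e, b = is_simple_euler(p), is_simple_boolean(p)
            assert e == b
            assert e == oracles.is_simple_bruteforce(p)


class TestTopologyPreservingThinning:
    def test_thin_line_unchanged(self):
        m = np.zeros((8, 8, 8), bool)
        m[2, 2, 1:7] = True
        for method in ("euler", "boolean"):
            assert (skeletonize_toppreserving(m, method) == m).all()

    def test_solid_ball_collapses_to_point_like_core(self):
        m = np.zeros((12, 12, 12), bool)
        g = np.stack(np.meshgrid(*[np.arange(12)] * 3, indexing="ij"), -1)
        m[np.linalg.norm(g - 5.5, axis=-1) <= 4] = True
        for method in ("euler", "boolean"):
            out = skeletonize_toppreserving(m, method)
            assert betti_numbers(out).as_tuple() == (1, 0, 0)
            assert out.sum() <= 5
            assert not (out & ~m).any()

    def test_tube_loop_thins_to_closed_curve(self):
        t = np.linspace(0, 2 * np.pi, 60)
        poly = np.stack([10 + 6 * np.cos(t), 10 + 6 * np.sin(t), np.full_like(t, 10)], 1)
        m = rasterize_tube(poly, np.full(60, 1.5), (20, 20, 20))
        assert betti_numbers(m).as_tuple() == (1, 1, 0)
        for method in ("euler", "boolean"):
            out = skeletonize_toppreserving(m, method)
            assert betti_numbers(out).as_tuple() == (1, 1, 0)

    def test_empty_mask(self):
        m = np.zeros((6, 6, 6), bool)
        assert not skeletonize_toppreserving(m).any()

    def test_methods_agree_and_idempotent(self, phantom_bank):
        for ph in phantom_bank[:3]:
            a = skeletonize_toppreserving(ph.mask, "euler")
            b = skeletonize_toppreserving(ph.mask, "boolean")
            assert (a == b).all()
            assert (skeletonize_toppreserving(a, "euler") == a).all()

    def test_betti_preserved_on_phantoms(self, phantom_bank):
        for ph in phantom_bank:
            for method in ("euler", "boolean"):
                out = skeletonize_toppreserving(ph.mask, method)
                assert betti_numbers(out).as_tuple() == ph.betti.as_tuple()
                assert not (out & ~ph.mask).any()

    def test_no_deletable_simple_points_remain(self, phantom_bank):
        """The output is thin: every non-endpoint voxel is non-simple."""
        out = skeletonize_toppreserving(phantom_bank[0].mask, "euler")
        padded = np.pad(out, 1)
        for idx in np.argwhere(padded):
            x, y, z = idx
            nb = padded[x - 1:x + 2, y - 1:y + 2, z - 1:z + 2]
            n_fg = nb.sum() - 1
            if n_fg > 1:
                assert not is_simple_euler(nb)


class TestSoftSkeleton:
    def test_zero_input_stays_zero(self):
        assert not soft_skeleton(np.zeros((8, 8, 8), np.float32), 5).any()

    def test_one_voxel_line_is_its_own_skeleton(self):
        m = np.zeros((9, 9, 9), np.float32)
        m[4, 4, 1:8] = 1.0
        out = soft_skeleton(m, 3)
        assert np.allclose(out, m)

    def test_cylinder_recovers_most_of_reference_centerline(self):
        poly = np.stack([np.full(18, 13.0), np.full(18, 13.0), np.arange(4, 22.0)], 1)
        m = rasterize_tube(poly, np.full(18, 3.0), (26, 26, 26))
        ref = lee_skeleton(m)
        out = soft_skeleton(m.astype(np.float32), 6) >= 0.5
        covered = (out & ref).sum() / ref.sum()
        assert covered >= 0.9

    def test_output_in_unit_interval(self, phantom_bank):
        out = soft_skeleton(phantom_bank[0].mask.astype(np.float32), 8)
        assert out.min() >= 0 and out.max() <= 1

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            soft_skeleton(np.full((4, 4, 4), 1.5, np.float32), 3)
        with pytest.raises(ValueError):
            soft_skeleton(np.zeros((4, 4, 4), np.float32), 0)


class TestSoftBinarize:
    def test_confident_input_stays_confident(self, rng):
        out = soft_binarize(np.ones((5, 5, 5)) * 0.999, BinarizationParams(), rng)
        assert (out > 0.5).all()

    def test_hard_threshold_limit(self, rng):
        out = soft_binarize(
            np.full((4, 4, 4), 0.9), BinarizationParams(beta=0.0, tau=1e-3), rng
        )
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_deterministic_under_seed(self):
        p = np.random.default_rng(0).random((6, 6, 6))
        a = soft_binarize(p, BinarizationParams(), np.random.default_rng(7))
        b = soft_binarize(p, BinarizationParams(), np.random.default_rng(7))
        assert (a == b).all()

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            BinarizationParams(tau=0.0)


class TestLeeSkeleton:
    def test_line_unchanged(self):
        m = np.zeros((8, 8, 8), bool)
        m[3, 3, 1:7] = True
        assert (lee_skeleton(m) == m).all()

    def test_empty(self):
        assert not lee_skeleton(np.zeros((6, 6, 6), bool)).any()

    def test_cylinder_centerline_near_axis(self):
        poly = np.stack([np.full(18, 13.0), np.full(18, 13.0), np.arange(4, 22.0)], 1)
        m = rasterize_tube(poly, np.full(18, 3.0), (26, 26, 26))
        skel = lee_skeleton(m)
        pts = np.argwhere(skel).astype(float)
        d_axis = np.linalg.norm(pts[:, :2] - 13.0, axis=1)
        assert (d_axis <= 1.0).mean() >= 0.9
        assert not (skel & ~m).any()
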