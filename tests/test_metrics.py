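"""Metric suite: closed-form examples, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from topotube.metrics import (
    BettiProfile,
    SegPair,
    assd,
    betti_numbers,
    cl_dice,
    dice_coefficient,
    euler_characteristic,
    evaluate_pair,
    hd95,
    surface_voxels,
    topology_precision,
    topology_sensitivity,
)


def _vol(shape=(6, 6, 6)):
    return np.zeros(shape, bool)


class TestOverlapMetrics:
    def test_topology_precision_containment_and_ratio(self):
        S = _vol(); S[1:5, 1:5, 1:5] = True
        C = _vol(); C[2, 2, 2:6] = True  # 4 voxels, one outside S
        assert topology_precision(C, S) == pytest.approx(0.75)
        C_in = _vol(); C_in[2, 2, 2:5] = True
        assert topology_precision(C_in, S) == 1.0
        C_out = _vol(); C_out[5, 5, 5] = True
        S_small = _vol(); S_small[0, 0, 0] = True
        assert topology_precision(C_out, S_small) == 0.0

    def test_topology_sensitivity_coverage(self):
        C = _vol(); C[1, 1, 0:5] = True; C[1, 2, 0:5] = True  # 10 voxels
        S = _vol(); S[1, 1, 0:5] = True  # covers 5 of them
        assert topology_sensitivity(C, S) == pytest.approx(0.5)
        assert topology_sensitivity(C, _vol()) == 0.0

    def test_empty_set_conventions(self):
        assert topology_precision(_vol(), _vol()) == 1.0
        assert dice_coefficient(_vol(), _vol()) == 1.0

    def test_cl_dice_harmonic_mean(self):
        # Tprec = 1, Tsens = 0.5 -> 2/3
        S_G = _vol(); S_G[1:5, 1:5, 1:5] = True
        C_P = _vol(); C_P[2, 2, 1:5] = True
        S_P = _vol(); S_P[2, 2, 1:3] = True
        C_G = _vol(); C_G[2, 2, 1:5] = True
        pair = SegPair(S_P, S_G, C_P, C_G)
        assert topology_precision(C_P, S_G) == 1.0
        assert topology_sensitivity(C_G, S_P) == pytest.approx(0.5)
        assert cl_dice(pair) == pytest.approx(2 / 3)

    def test_cl_dice_identity_and_disjoint(self):
        S = _vol(); S[1:4, 1:4, 1:4] = True
        C = _vol(); C[2, 2, 1:4] = True
        assert cl_dice(SegPair(S, S, C, C)) == 1.0
        S2 = _vol(); S2[5, 5, 5] = True
        assert cl_dice(SegPair(S2, S, S2, C)) == 0.0

    def test_dice_from_confusion_counts(self):
        P = _vol(); P[0, 0, 0:3] = True  # tp=2, fp=1
        R = _vol(); R[0, 0, 0:2] = True; R[0, 1, 0] = True  # fn=1
        assert dice_coefficient(P, R) == pytest.approx(2 / 3)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_coefficient(_vol((4, 4, 4)), _vol((5, 5, 5)))


class TestSurfaceDistances:
    def test_identical_masks_zero(self):
        P = _vol(); P[2:4, 2:4, 2:4] = True
        assert assd(P, P) == 0.0
        assert hd95(P, P) == 0.0

    def test_singletons_three_apart(self):
        P = _vol((8, 8, 8)); P[1, 1, 1] = True
        R = _vol((8, 8, 8)); R[4, 1, 1] = True
        assert assd(P, R) == pytest.approx(3.0)
        assert hd95(P, R) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        P = _vol((8, 8, 8)); P[1, 1, 1] = True
        R = _vol((8, 8, 8)); R[1, 1, 4] = True
        assert assd(P, R, (1, 1, 0.5)) == pytest.approx(1.5)

    def test_empty_mask_raises(self):
        P = _vol(); P[1, 1, 1] = True
        with pytest.raises(ValueError):
            assd(P, _vol())
        with pytest.raises(ValueError):
            hd95(_vol(), P)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_masks(self, seed):
        r = np.random.default_rng(seed)
        spacing = tuple(r.uniform(0.5, 1.5, 3))
        P = r.random((8, 8, 8)) < 0.3
        R = r.random((8, 8, 8)) < 0.3
        if not (P.any() and R.any()):
            pytest.skip("degenerate draw")
        assert assd(P, R, spacing) == pytest.approx(
            oracles.assd_bruteforce(P, R, spacing), abs=1e-9
        )
        assert hd95(P, R, spacing) == pytest.approx(
            oracles.hd95_bruteforce(P, R, spacing), abs=1e-9
        )

    def test_symmetry(self, rng):
        P = rng.random((7, 7, 7)) < 0.4
        R = rng.random((7, 7, 7)) < 0.4
        assert assd(P, R) == assd(R, P)
        assert hd95(P, R) == hd95(R, P)
        assert dice_coefficient(P, R) == dice_coefficient(R, P)


class TestBettiNumbers:
    def test_single_voxel(self):
        m = _vol(); m[2, 2, 2] = True
        assert betti_numbers(m).as_tuple() == (1, 0, 0)

    def test_planar_ring_has_one_tunnel(self):
        m = np.zeros((5, 5, 3), bool)
        m[1:4, 1:4, 1] = True
        m[2, 2, 1] = False
        assert betti_numbers(m).as_tuple() == (1, 1, 0)
        assert betti_numbers(m).as_tuple() == oracles.betti_closed_cubes(m)

    def test_hollow_shell_has_one_cavity(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        m[2, 2, 2] = False
        assert betti_numbers(m).as_tuple() == (1, 0, 1)
        assert betti_numbers(m).as_tuple() == oracles.betti_closed_cubes(m)

    def test_empty_mask(self):
        assert betti_numbers(_vol()).as_tuple() == (0, 0, 0)

    def test_euler_characteristic_of_solid_block(self):
        m = _vol(); m[1:4, 1:4, 1:4] = True
        assert euler_characteristic(m) == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_gf2_homology_on_random_masks(self, seed):
        r = np.random.default_rng(100 + seed)
        m = r.random((6, 6, 6)) < r.uniform(0.2, 0.7)
        assert betti_numbers(m).as_tuple() == oracles.betti_closed_cubes(m)

    def test_bridge_deletion_increments_b0(self, phantom_bank):
        """Cutting a one-voxel bridge in a skeleton splits one component."""
        from topotube.skeletonize import lee_skeleton

        ph = phantom_bank[0]
        skel = lee_skeleton(ph.mask)
        base = betti_numbers(skel)
        # find a voxel whose removal disconnects the skeleton
        for idx in np.argwhere(skel):
            cut = skel.copy()
            cut[tuple(idx)] = False
            after = betti_numbers(cut)
            if after.b0 == base.b0 + 1 and after.b1 == base.b1:
                return
        pytest.fail("no bridge voxel found in skeleton")

    def test_negative_betti_rejected(self):
        with pytest.raises(ValueError):
            BettiProfile(1, -1, 0)


class TestReportsAndProperties:
    def test_evaluate_pair_identity(self):
        S = _vol(); S[1:4, 2:5, 1:5] = True
        C = _vol(); C[2, 3, 1:5] = True
        rep = evaluate_pair(SegPair(S, S, C, C), case_id="x")
        assert rep.dsc == 1.0 and rep.cldice == 1.0
        assert rep.assd_mm == 0.0 and rep.hd95_mm == 0.0
        assert rep.betti.as_tuple() == (1, 0, 0)
        assert rep.to_dict()["betti"] == (1, 0, 0)

    @given(
        hnp.arrays(bool, (5, 5, 5)),
        hnp.arrays(bool, (5, 5, 5)),
    )
    def test_dice_range_and_symmetry(self, P, R):
        d = dice_coefficient(P, R)
        assert 0.0 <= d <= 1.0
        assert d == dice_coefficient(R, P)
        assert d == pytest.approx(oracles.dice_bruteforce(P, R))

    @given(hnp.arrays(bool, (5, 5, 5)))
    def test_surface_is_subset_of_mask(self, m):
        s = surface_voxels(m)
        assert not (s & ~m).any()
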