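"""Three-regime pair loss, balancing coefficient, and the incremental /
partitioned evaluation contracts, all checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import schic3d as sc


def brute_force_total(structure, theta, params):
    """Independent O(l^2) double-loop evaluation of the objective."""
    n = structure.n_beads
    cid = structure.binning.chrom_id_array()
    tot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[j]))
            t = theta.theta_of(i, j)
            w = params.c_ratio if cid[i] == cid[j] else 1.0 - params.c_ratio
            tot += w * sc.pair_loss(t, d, params)
    for i in range(n - 1):
        if cid[i] == cid[i + 1]:
            d = float(np.linalg.norm(structure.coords[i] - structure.coords[i + 1]))
            tot += params.w_bb * max(0.0, d - params.d_target) ** 2
    return tot


class TestRatioCoefficient:
    @pytest.mark.parametrize(
        "intra,inter,expected",
        [(990, 10, 0.01), (100, 100, 0.5), (0, 50, 1.0), (7, 3, 1.0 / 3.0)],
    )
    def test_direct_evaluations(self, intra, inter, expected):
        assert sc.compute_ratio_coefficient(intra, inter) == pytest.approx(expected)

    def test_no_inter_contacts_degenerate(self):
        assert sc.compute_ratio_coefficient(123, 0) == 1.0

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            sc.compute_ratio_coefficient(0, 0)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 10_000), st.integers(1, 1000))
    def test_range_and_monotonicity(self, intra, inter):
        c = sc.compute_ratio_coefficient(intra, inter)
        assert 0.0 < c <= 1.0
        # monotone non-increasing in the intra count
        assert sc.compute_ratio_coefficient(intra + inter, inter) <= c


class TestPairLoss:
    def test_at_target_distance_zero(self):
        p = sc.LossParams()
        assert sc.pair_loss(1.0, p.d_target, p) == 0.0

    def test_regime1_quadratic_hinge(self):
        assert sc.pair_loss(1.0, 10.0, sc.LossParams()) == pytest.approx(4.0)

    def test_regime3_no_penalty_beyond_target(self):
        assert sc.pair_loss(0.3, 20.0, sc.LossParams()) == 0.0

    def test_regime3_repels_below_target(self):
        p = sc.LossParams()
        assert sc.pair_loss(0.3, 5.0, p) == pytest.approx(p.w3 * 9.0)

    def test_excluded_volume_shared_by_all_regimes(self):
        p = sc.LossParams()
        for t in (1.0, 0.85, 0.1):
            assert sc.pair_loss(t, 0.5, p) >= p.w1 * 0.25

    def test_stringency_ordering(self):
        """Regime 1 penalizes a stretched contact hardest, regime 3 least."""
        p = sc.LossParams()
        for d in (9.0, 12.0, 20.0):
            assert (
                sc.pair_loss(1.0, d, p)
                >= sc.pair_loss(0.85, d, p)
                >= sc.pair_loss(0.3, d, p)
            )

    def test_continuity_in_d(self):
        p = sc.LossParams()
        for t in (1.0, 0.8, 0.2):
            d = np.linspace(0.0, 20.0, 2001)
            v = np.array([sc.pair_loss(t, x, p) for x in d])
            assert np.all(np.abs(np.diff(v)) < 0.5)  # no jumps at regime edges


@pytest.fixture
def fifty_bead_setup():
    binning = sc.GenomeBinning(
        [("c1", None, 25_000_000), ("c2", None, 25_000_000)], 1_000_000
    )
    rng = np.random.default_rng(11)
    side = 5.0 * 50
    coords = rng.uniform(side / 2 - 15, side / 2 + 15, size=(50, 3))
    structure = sc.Structure(coords, binning, side)
    m = 40
    pairs = set()
    while len(pairs) < m:
        i, j = rng.integers(0, 50, size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    pairs = np.array(sorted(pairs))
    theta = rng.uniform(0.05, 1.0, size=m)
    theta[:10] = 1.0
    theta_m = sc.ThetaMatrix(50, pairs, theta, "gaussian", binning=binning)
    params = sc.LossParams(c_ratio=0.25)
    return structure, theta_m, params


class TestTotalLoss:
    def test_matches_brute_force(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        expected = brute_force_total(s, t, p)
        assert sc.total_loss(s, t, p) == pytest.approx(expected, rel=1e-9)

    def test_rigid_motion_invariance(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        base = sc.total_loss(s, t, p)
        shifted = s.copy()
        shifted.coords += np.array([3.0, -2.0, 5.0])
        assert sc.total_loss(shifted, t, p) == pytest.approx(base, rel=1e-9)
        # rotation about the centroid
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        c = s.coords.mean(axis=0)
        rot = s.copy()
        rot.coords = (s.coords - c) @ R.T + c
        assert sc.total_loss(rot, t, p) == pytest.approx(base, rel=1e-9)

    def test_outside_box_infinite(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        bad = s.copy()
        bad.coords[0] = [-1.0, 0.0, 0.0]
        assert sc.total_loss(bad, t, p) == np.inf

    def test_single_chromosome_inter_term_absent(self):
        """A haploid single-chromosome genome has no inter pairs; with
        c_ratio = 1 the loss equals the unweighted intra sum."""
        binning = sc.GenomeBinning([("c1", None, 20_000_000)], 1_000_000)
        rng = np.random.default_rng(5)
        side = 100.0
        s = sc.Structure(rng.uniform(40, 60, size=(20, 3)), binning, side)
        t = sc.ThetaMatrix(
            20, np.array([[0, 5]]), np.array([1.0]), "gaussian", binning=binning
        )
        p = sc.LossParams(c_ratio=1.0)
        assert sc.total_loss(s, t, p) == pytest.approx(
            brute_force_total(s, t, p), rel=1e-9
        )

    def test_zero_loss_configuration(self):
        """Contacts at the target distance, chain spacing below it, empty
        repulsion range -> exactly zero."""
        binning = sc.GenomeBinning([("c1", None, 2_000_000)], 1_000_000)
        coords = np.array([[10.0, 10.0, 10.0], [18.0, 10.0, 10.0]])
        s = sc.Structure(coords, binning, 10.0 * 5)
        t = sc.ThetaMatrix(
            2, np.array([[0, 1]]), np.array([1.0]), "gaussian", binning=binning
        )
        assert sc.total_loss(s, t, sc.LossParams()) == 0.0


class TestDeltaLoss:
    def test_null_move_zero(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        assert sc.delta_loss(s, 7, s.coords[7], t, p) == 0.0

    def test_oracle_equivalence_200_moves(self, fifty_bead_setup):
        """delta_loss equals the full brute-force recompute difference."""
        s, t, p = fifty_bead_setup
        rng = np.random.default_rng(99)
        base = brute_force_total(s, t, p)
        for _ in range(200):
            b = int(rng.integers(0, 50))
            new = s.coords[b] + rng.uniform(-2, 2, size=3)
            new = np.clip(new, 0.0, s.box_side)
            d = sc.delta_loss(s, b, new, t, p)
            moved = s.copy()
            moved.coords[b] = new
            full = brute_force_total(moved, t, p) - base
            assert d == pytest.approx(full, rel=1e-9, abs=1e-9)

    def test_isolated_bead_changes_only_backbone(self):
        """A bead with no theta entries, far from everything but its chain
        neighbours, only feels the backbone term."""
        binning = sc.GenomeBinning([("c1", None, 3_000_000)], 1_000_000)
        side = 15.0 * 5
        coords = np.array([[10.0, 10, 10], [40.0, 40, 40], [70.0, 70, 70]])
        s = sc.Structure(coords, binning, side)
        t = sc.ThetaMatrix(
            3, np.empty((0, 2), dtype=int), np.empty(0), "gaussian", binning=binning
        )
        p = sc.LossParams()
        d0 = float(np.linalg.norm(coords[1] - coords[0]))
        d2 = float(np.linalg.norm(coords[1] - coords[2]))
        new = coords[1] + np.array([1.0, 0.0, 0.0])
        nd0 = float(np.linalg.norm(new - coords[0]))
        nd2 = float(np.linalg.norm(new - coords[2]))
        expected = (
            max(0, nd0 - p.d_target) ** 2
            + max(0, nd2 - p.d_target) ** 2
            - max(0, d0 - p.d_target) ** 2
            - max(0, d2 - p.d_target) ** 2
        ) * p.w_bb
        assert sc.delta_loss(s, 1, new, t, p) == pytest.approx(expected, rel=1e-12)


class TestPartitionedLoss:
    def test_one_part_identical(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        assert sc.partitioned_loss(s, t, p, 1) == sc.total_loss(s, t, p)

    @pytest.mark.parametrize("n_parts", [2, 4, 7])
    def test_matches_serial(self, fifty_bead_setup, n_parts):
        s, t, p = fifty_bead_setup
        serial = sc.total_loss(s, t, p)
        assert sc.partitioned_loss(s, t, p, n_parts) == pytest.approx(
            serial, rel=1e-9
        )

    def test_more_parts_than_beads_clamped(self, fifty_bead_setup):
        s, t, p = fifty_bead_setup
        assert sc.partitioned_loss(s, t, p, 500) == pytest.approx(
            sc.total_loss(s, t, p), rel=1e-9
        )


class TestLossParamsValidation:
    def test_weight_ordering_enforced(self):
        with pytest.raises(ValueError):
            sc.LossParams(w1=0.1, w2=0.5)

    def test_threshold_range(self):
        with pytest.raises(ValueError):
            sc.LossParams(theta_threshold=1.0)

    def test_with_c_ratio_helper(self):
        p = sc.LossParams().with_c_ratio(990, 10)
        assert p.c_ratio == pytest.approx(0.01)
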