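"""Distance matrices, contact/non-contact statistics, P(s) scaling, radial
profiles and reproducibility metrics."""

import numpy as np
import pytest
from scipy.stats import maxwell

import schic3d as sc


class TestDistanceMatrix:
    def test_diagonal_zero_and_symmetry(self, two_chrom_binning, random_structure):
        dm = sc.distance_matrix(random_structure(two_chrom_binning))
        assert np.all(np.diag(dm.values) == 0)
        assert np.allclose(dm.values, dm.values.T)

    def test_three_four_five_triangle(self):
        b = sc.GenomeBinning([("c", None, 2_000_000)], 1_000_000)
        s = sc.Structure(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]), b, 10.0)
        assert sc.distance_matrix(s).values[0, 1] == 5.0

    def test_matches_brute_force(self, two_chrom_binning, random_structure):
        s = random_structure(two_chrom_binning, seed=8)
        dm = sc.distance_matrix(s).values
        for i in range(s.n_beads):
            for j in range(s.n_beads):
                assert dm[i, j] == pytest.approx(
                    np.linalg.norm(s.coords[i] - s.coords[j])
                )


class TestContactGroupStats:
    def _setup(self, contact_d, noncontact_d):
        b = sc.GenomeBinning([("c", None, 20_000_000)], 1_000_000)
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 50, size=(20, 3))
        s = sc.Structure(coords, b, 100.0)
        dm = sc.distance_matrix(s)
        # plant distances
        dm.values[:] = noncontact_d
        np.fill_diagonal(dm.values, 0.0)
        pairs = np.array([[0, 5], [2, 9], [4, 17]])
        for i, j in pairs:
            dm.values[i, j] = dm.values[j, i] = contact_d
        m = sc.BinaryContactMatrix(20, pairs, b)
        return dm, m

    def test_separated_groups_significant(self):
        dm, m = self._setup(1.0, 10.0)
        out = sc.contact_group_stats(dm, m)
        overall = out[out.band == "overall"].iloc[0]
        assert overall.contact_mean == pytest.approx(1.0)
        assert overall.noncontact_mean == pytest.approx(10.0)
        assert overall.p_value < 1e-4

    def test_identical_distributions_not_significant(self):
        dm, m = self._setup(7.0, 7.0)
        out = sc.contact_group_stats(dm, m)
        assert out[out.band == "overall"].iloc[0].p_value > 0.1

    def test_empty_band_reported_with_missing_stats(self):
        dm, m = self._setup(1.0, 10.0)
        out = sc.contact_group_stats(dm, m, genomic_bands=[(0, 2e6), (18e6, 20e6)])
        last = out[out.band == "18-20Mbp"].iloc[0]
        assert last.n_contact == 0 and np.isnan(last.p_value)

    def test_binning_mismatch_errors(self, two_chrom_binning, random_structure):
        dm = sc.distance_matrix(random_structure(two_chrom_binning))
        other = sc.GenomeBinning([("c", None, 20_000_000)], 1_000_000)
        m = sc.BinaryContactMatrix(20, np.array([[0, 5]]), other)
        with pytest.raises(ValueError):
            sc.contact_group_stats(dm, m)


class TestPsCurve:
    def test_all_pairs_within_threshold(self):
        b = sc.GenomeBinning([("c", None, 30_000_000)], 1_000_000)
        s = sc.Structure(np.random.default_rng(0).uniform(0, 2, (30, 3)), b, 100.0)
        curve = sc.ps_curve(sc.distance_matrix(s), contact_threshold=50.0)
        assert np.all(curve.p == 1.0)

    def test_spread_structure_all_zero(self):
        b = sc.GenomeBinning([("c", None, 10_000_000)], 1_000_000)
        coords = np.arange(10)[:, None] * np.array([100.0, 0, 0])
        s = sc.Structure(coords, b, 2000.0)
        curve = sc.ps_curve(sc.distance_matrix(s), contact_threshold=8.0)
        assert np.all(curve.p == 0.0)

    def test_probabilities_bounded(self, ideal_chain_structure):
        s = ideal_chain_structure(1, 400, seed=2)
        curve = sc.ps_curve(sc.distance_matrix(s))
        assert np.all((curve.p >= 0) & (curve.p <= 1))
        assert np.all(np.diff(curve.s) > 0)

    def test_ideal_chain_slope_matches_closed_form(self, ideal_chain_structure):
        """Pooled unconfined random walks: fitted log-log slope within
        +/-0.3 of the ideal-chain exponent -3/2 (closed-form reference via
        the Maxwell CDF gives -1.37 over the default dilute fit window)."""
        s = ideal_chain_structure(4, 2000, seed=0)
        curve = sc.ps_curve(sc.distance_matrix(s), contact_threshold=8.0)
        assert -1.8 <= curve.slope <= -1.2
        # cross-check the closed-form oracle itself on the same window
        sep = np.logspace(np.log10(2), np.log10(1999), 500)
        P = maxwell.cdf(8.0, scale=np.sqrt(sep / 3.0))
        sel = (P > 0.002) & (P < 0.3)
        ref = np.polyfit(np.log10(sep[sel]), np.log10(P[sel]), 1)[0]
        assert curve.slope == pytest.approx(ref, abs=0.2)

    def test_pooled_counts_combine_correctly(self, ideal_chain_structure):
        """Pooling a curve with itself leaves P unchanged and doubles the
        counts; mismatched bins are rejected."""
        s = ideal_chain_structure(1, 300, seed=1)
        c = sc.ps_curve(sc.distance_matrix(s))
        pooled = sc.pool_ps_curves([c, c])
        assert np.allclose(pooled.p, c.p)
        assert np.array_equal(pooled.n_pairs, 2 * c.n_pairs)
        other = sc.ps_curve(sc.distance_matrix(ideal_chain_structure(1, 200, seed=2)))
        with pytest.raises(ValueError, match="bins"):
            sc.pool_ps_curves([c, other])

    def test_no_intra_pairs_errors(self):
        b = sc.GenomeBinning([("a", None, 900_000), ("b", None, 900_000)], 1_000_000)
        s = sc.Structure(np.zeros((2, 3)), b, 10.0)
        with pytest.raises(ValueError):
            sc.ps_curve(sc.distance_matrix(s))


class TestRadialProfile:
    def test_translation_invariance(self, two_chrom_binning, random_structure):
        s = random_structure(two_chrom_binning)
        r0 = sc.radial_profile(s).radial_distance.to_numpy()
        s2 = s.copy()
        s2.coords += np.array([5.0, -3.0, 2.0])
        r1 = sc.radial_profile(s2).radial_distance.to_numpy()
        assert np.allclose(r0, r1)

    def test_single_bead_zero(self):
        b = sc.GenomeBinning([("c", None, 500_000)], 1_000_000)
        s = sc.Structure(np.array([[3.0, 4.0, 5.0]]), b, 10.0)
        assert sc.radial_profile(s).radial_distance.iloc[0] == 0.0

    def test_shell_vs_core_ordering(self):
        """One chromosome clustered at the center, one on a spherical
        shell: per-chromosome mean radial distances reflect construction."""
        b = sc.GenomeBinning(
            [("core", None, 30_000_000), ("shell", None, 30_000_000)], 1_000_000
        )
        rng = np.random.default_rng(1)
        core = rng.normal(0, 0.5, (30, 3))
        v = rng.normal(size=(30, 3))
        shell = 10.0 * v / np.linalg.norm(v, axis=1)[:, None]
        coords = np.vstack([core, shell]) + 50.0
        s = sc.Structure(coords, b, 100.0)
        prof = sc.radial_profile(s)
        means = prof.groupby("chrom").radial_distance.mean()
        assert means["core"] < means["shell"]


class TestReproducibility:
    def test_duplicates_and_rotations_give_one(self, two_chrom_binning, random_structure):
        s = random_structure(two_chrom_binning, seed=5)
        th = 1.1
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rot = s.copy()
        rot.coords = (s.coords - s.coords.mean(0)) @ R.T + s.coords.mean(0)
        corr, summary = sc.reproducibility_correlation([s, s.copy(), rot])
        assert np.allclose(corr, 1.0)
        assert summary["mean"] == pytest.approx(1.0)

    def test_independent_structures_uncorrelated(self, two_chrom_binning, random_structure):
        structures = [random_structure(two_chrom_binning, seed=k) for k in range(6)]
        _corr, summary = sc.reproducibility_correlation(structures)
        assert abs(summary["mean"]) < 0.25

    def test_binning_mismatch_errors(self, two_chrom_binning, random_structure):
        other = sc.GenomeBinning([("x", None, 20_000_000)], 1_000_000)
        s1 = random_structure(two_chrom_binning)
        s2 = sc.Structure(np.zeros((20, 3)), other, 100.0)
        with pytest.raises(ValueError):
            sc.reproducibility_correlation([s1, s2])


class TestAnnotationRadialTest:
    def test_constructed_inner_shell(self):
        b = sc.GenomeBinning([("c", None, 60_000_000)], 1_000_000)
        rng = np.random.default_rng(0)
        inner = rng.normal(0, 1.0, (30, 3))
        outer = rng.normal(0, 1.0, (30, 3))
        outer = outer / np.linalg.norm(outer, axis=1)[:, None] * 12.0
        s = sc.Structure(np.vstack([inner, outer]) + 50.0, b, 100.0)
        labels = np.array([True] * 30 + [False] * 30)
        out = sc.annotation_radial_test(s, labels)
        assert out["mean_a"] < out["mean_b"]
        assert out["p_value"] < 1e-6

    def test_random_labels_not_significant(self):
        b = sc.GenomeBinning([("c", None, 60_000_000)], 1_000_000)
        rng = np.random.default_rng(3)
        s = sc.Structure(rng.uniform(0, 20, (60, 3)), b, 100.0)
        labels = rng.random(60) < 0.5
        out = sc.annotation_radial_test(s, labels)
        assert out["p_value"] > 0.01

    def test_single_group_errors(self, two_chrom_binning, random_structure):
        s = random_structure(two_chrom_binning)
        with pytest.raises(ValueError):
            sc.annotation_radial_test(s, np.ones(20, dtype=bool))


class TestCrossResolutionConcordance:
    def test_self_correlation_one(self, two_chrom_binning, random_structure):
        dm = sc.distance_matrix(random_structure(two_chrom_binning))
        assert sc.cross_resolution_concordance(dm, dm, "intra") == pytest.approx(1.0)
        assert sc.cross_resolution_concordance(dm, dm, "inter") == pytest.approx(1.0)

    def test_scaled_copy_correlation_one(self, two_chrom_binning, random_structure):
        s = random_structure(two_chrom_binning)
        dm = sc.distance_matrix(s)
        s2 = s.copy()
        s2.coords = s.coords * 2.5
        dm2 = sc.distance_matrix(
            sc.Structure(s2.coords, s.binning, s.box_side * 2.5)
        )
        assert sc.cross_resolution_concordance(dm, dm2, "intra") == pytest.approx(1.0)

    def test_independent_structures_near_zero(self, two_chrom_binning, random_structure):
        dms = [
            sc.distance_matrix(random_structure(two_chrom_binning, seed=k))
            for k in (1, 2)
        ]
        assert abs(sc.cross_resolution_concordance(*dms, "intra")) < 0.3

    def test_empty_scope_errors(self):
        b = sc.GenomeBinning([("c", None, 5_000_000)], 1_000_000)
        s = sc.Structure(np.random.default_rng(0).uniform(0, 5, (5, 3)), b, 25.0)
        dm = sc.distance_matrix(s)
        with pytest.raises(ValueError, match="inter"):
            sc.cross_resolution_concordance(dm, dm, "inter")
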