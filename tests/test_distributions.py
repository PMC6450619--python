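"""Distribution functions: bonded histograms, RDFs, the IMC matrix."""

import numpy as np
import pytest
from scipy import stats

from cginverse.distributions import (
    CorrelationMatrix,
    Distribution,
    DistributionError,
    DistributionSet,
    compute_rdf,
    estimate_correlation_matrix,
    histogram_bonded,
    torsion_values,
)
from cginverse.units import KB_KCAL

BOX = np.array([10.0, 10.0, 10.0])


class TestBondedHistograms:
    def test_single_distance_occupies_one_bin_at_density_inverse_width(self):
        frames = np.zeros((5, 2, 3))
        frames[:, 1, 0] = 0.503
        edges = np.arange(0.0, 1.0, 0.01)
        ds = histogram_bonded(frames, BOX, {"A-A": np.array([[0, 1]])}, "bond", edges)
        d = ds["A-A"]
        assert d.values.max() == pytest.approx(1.0 / d.bin_width)
        assert np.count_nonzero(d.values) == 1
        assert d.values.sum() * d.bin_width == pytest.approx(1.0)

    def test_angles_of_random_unit_vectors_follow_sine_density(self, rng):
        n = 100_000
        j = np.zeros((n, 3))
        i = rng.normal(size=(n, 3))
        k = rng.normal(size=(n, 3))
        i /= np.linalg.norm(i, axis=1)[:, None]
        k /= np.linalg.norm(k, axis=1)[:, None]
        pos = np.concatenate([i + 5, j + 5, k + 5], axis=0)[None]
        triples = np.column_stack([np.arange(n), np.arange(n) + n,
                                   np.arange(n) + 2 * n])
        edges = np.arange(0.0, 180.0 + 1e-9, 2.0)
        ds = histogram_bonded(pos, BOX, {"t": triples}, "angle", edges)
        d = ds["t"]
        centers = np.radians(d.centers)
        expected_p = np.sin(centers)
        expected_p /= expected_p.sum()
        counts = d.counts_mean
        chi2 = np.sum((counts - n * expected_p) ** 2 / (n * expected_p))
        # dof = bins - 1; generous threshold, derandomised by the seed
        assert chi2 < stats.chi2.ppf(0.999, len(counts) - 1)

    def test_mirrored_torsions_give_mirrored_histograms(self, rng):
        n = 2000
        pos = np.cumsum(rng.normal(scale=0.3, size=(n, 4, 3)), axis=1) + 5.0
        quads = np.array([[0, 1, 2, 3]])
        edges = np.arange(-180.0, 180.0 + 1e-9, 4.0)
        flat = pos.reshape(1, -1, 3)
        idx = np.arange(n * 4).reshape(n, 4)
        mirror = flat.copy()
        mirror[..., 2] *= -1.0
        d = histogram_bonded(flat, BOX, {"q": idx}, "torsion", edges)["q"]
        m = histogram_bonded(mirror, BOX, {"q": idx}, "torsion", edges)["q"]
        # phi -> -phi maps bin b to bin (n-1-b) on the symmetric grid
        assert d.counts_mean == pytest.approx(m.counts_mean[::-1])

    def test_torsion_sign_preserved_for_chiral_geometry(self):
        pos = np.array([[0.0, 0.3, 0], [0, 0, 0], [0.5, 0, 0], [0.5, 0.2, 0.25]])
        phi = torsion_values(pos[None][0], BOX, np.array([[0, 1, 2, 3]]))[0]
        assert abs(phi) > 5.0  # clearly off-plane: the sign is meaningful
        mirrored = pos.copy()
        mirrored[:, 2] *= -1
        phi_m = torsion_values(mirrored, BOX, np.array([[0, 1, 2, 3]]))[0]
        assert phi_m == pytest.approx(-phi)

    def test_bond_outside_grid_range_is_an_error(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 0] = 2.5
        edges = np.arange(0.0, 1.0, 0.01)
        with pytest.raises(DistributionError, match="outside grid range"):
            histogram_bonded(frames, BOX, {"A-A": np.array([[0, 1]])}, "bond", edges)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(DistributionError, match="empty"):
            histogram_bonded(np.empty((0, 2, 3)), BOX,
                             {"A-A": np.array([[0, 1]])}, "bond",
                             np.arange(0.0, 1.0, 0.01))

    def test_concatenation_preserves_normalization(self, rng):
        fa = 0.4 + 0.05 * rng.random((7, 2, 3))
        fb = 0.4 + 0.05 * rng.random((3, 2, 3))
        edges = np.arange(0.0, 1.0, 0.01)
        pairs = {"A-A": np.array([[0, 1]])}
        da = histogram_bonded(fa, BOX, pairs, "bond", edges)["A-A"]
        db = histogram_bonded(fb, BOX, pairs, "bond", edges)["A-A"]
        dab = histogram_bonded(np.concatenate([fa, fb]), BOX, pairs, "bond",
                               edges)["A-A"]
        merged = (da.values * da.n_samples + db.values * db.n_samples) / (
            da.n_samples + db.n_samples)
        assert dab.values == pytest.approx(merged)


class TestRDF:
    def test_ideal_gas_rdf_is_one(self, rng):
        frames = rng.random((40, 200, 3)) * BOX
        edges = np.arange(0.0, 3.0 + 1e-9, 0.05)
        g = compute_rdf(frames, BOX, ["A"] * 200, ("A", "A"), set(), edges)
        sel = g.centers > 0.2
        assert np.all(np.abs(g.values[sel] - 1.0) < 0.25)
        assert abs(g.values[sel].mean() - 1.0) < 0.01

    def test_two_fixed_beads_single_peak(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 2] = 0.77
        edges = np.arange(0.0, 2.0 + 1e-9, 0.01)
        g = compute_rdf(frames, BOX, ["A", "A"], ("A", "A"), set(), edges)
        occupied = np.nonzero(g.counts_mean)[0]
        assert len(occupied) == 1
        assert edges[occupied[0]] <= 0.77 < edges[occupied[0] + 1]

    def test_excluded_pair_contributes_nothing(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 2] = 0.77
        edges = np.arange(0.0, 2.0 + 1e-9, 0.01)
        g = compute_rdf(frames, BOX, ["A", "A"], ("A", "A"), {(0, 1)}, edges)
        assert g.counts_mean.sum() == 0

    def test_grid_beyond_half_box_rejected(self):
        with pytest.raises(DistributionError, match="half"):
            compute_rdf(np.zeros((1, 2, 3)), BOX, ["A", "A"], ("A", "A"),
                        set(), np.arange(0.0, 6.0, 0.1))

    def test_unknown_type_label_rejected(self):
        with pytest.raises(DistributionError, match="unknown"):
            compute_rdf(np.zeros((1, 2, 3)), BOX, ["A", "A"], ("A", "Z"),
                        set(), np.arange(0.0, 2.0, 0.1))

    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_counts_match_brute_force_distance_loop(self, n, rng):
        frames = rng.random((3, n, 3)) * BOX
        edges = np.arange(0.0, 4.0 + 1e-9, 0.1)
        excl = {(0, 1)} if n > 1 else set()
        g = compute_rdf(frames, BOX, ["A"] * n, ("A", "A"), excl, edges)
        brute = np.zeros(len(edges) - 1)
        for f in range(frames.shape[0]):
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) in excl:
                        continue
                    d = frames[f, j] - frames[f, i]
                    d -= np.round(d / BOX) * BOX
                    r = np.linalg.norm(d)
                    b = int(r // 0.1)
                    if b < len(brute):
                        brute[b] += 1
        assert g.counts_mean * frames.shape[0] == pytest.approx(brute)


class TestCorrelationMatrix:
    def mkset(self, frames_matrix):
        edges = np.arange(0.0, frames_matrix.shape[1] + 1.0)
        vals = np.maximum(frames_matrix.mean(axis=0), 0)
        d = Distribution("rdf", "A-A", edges, vals,
                         counts_mean=frames_matrix.mean(axis=0),
                         n_frames=frames_matrix.shape[0], frames=frames_matrix)
        return DistributionSet([d])

    def test_constant_vectors_give_zero_matrix(self):
        S = np.tile([3.0, 1.0, 2.0], (50, 1))
        A = estimate_correlation_matrix(self.mkset(S), 300.0)
        assert np.abs(A.matrix).max() == 0.0

    def test_estimator_is_symmetric(self, rng):
        S = rng.poisson(5.0, size=(200, 6)).astype(float)
        A = estimate_correlation_matrix(self.mkset(S), 300.0)
        assert A.matrix == pytest.approx(A.matrix.T)

    def test_matches_two_pass_covariance_oracle(self, rng):
        S = rng.multivariate_normal([5, 8, 3],
                                    [[2.0, 0.5, 0.1], [0.5, 1.0, -0.2],
                                     [0.1, -0.2, 0.8]], size=100)
        T = 303.0
        A = estimate_correlation_matrix(self.mkset(S), T)
        mean = S.mean(axis=0)
        cov = np.zeros((3, 3))
        for row in S:  # two-pass, biased (divide by n) covariance
            cov += np.outer(row - mean, row - mean)
        cov /= len(S)
        assert A.matrix == pytest.approx(-cov / (KB_KCAL * T), abs=1e-12)

    def test_single_frame_is_an_error(self):
        with pytest.raises(DistributionError, match="2 frames"):
            estimate_correlation_matrix(self.mkset(np.ones((1, 3))), 300.0)

    def test_independent_bins_converge_to_diagonal(self, rng):
        S = rng.poisson(20.0, size=(10_000, 4)).astype(float)
        A = estimate_correlation_matrix(self.mkset(S), 300.0)
        off = np.abs(A.matrix - np.diag(np.diag(A.matrix))).max()
        assert off < 0.05 * np.abs(np.diag(A.matrix)).min()

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(DistributionError, match="symmetric"):
            CorrelationMatrix(np.array([[1.0, 2.0], [0.0, 1.0]]),
                              [("a", 0), ("a", 1)])
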