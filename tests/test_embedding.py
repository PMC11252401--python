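import numpy as np
import pytest
from scipy.stats import pearsonr

from hippogradients.connectivity import ConnectivityMatrix, TimeSeries, connectivity_matrix
from hippogradients.embedding import (
    AffinityMatrix,
    corticocortical_gradients,
    diffusion_map_embed,
    hippocampal_gradients,
    joint_cross_species_embed,
    normalized_angle_affinity,
)


def dense_transition_oracle(S: AffinityMatrix, alpha: float, k: int):
    """Independent oracle: eigendecompose the (non-symmetrised) Markov
    transition operator directly with a general eigensolver."""
    W0 = S.values
    d = W0.sum(axis=1)
    W = W0 / np.outer(d**alpha, d**alpha)
    d2 = W.sum(axis=1)
    P = W / d2[:, None]
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestNormalizedAngleAffinity:
    def test_identical_rows_give_one(self):
        M = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        S = normalized_angle_affinity(M, sparsity=0.0)
        assert S.values[0, 1] == 1.0

    def test_orthogonal_rows_give_exactly_half(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        S = normalized_angle_affinity(M, sparsity=0.0)
        assert S.values[0, 1] == 0.5

    def test_opposite_rows_give_zero(self):
        M = np.array([[1.0, 2.0], [-1.0, -2.0]])
        S = normalized_angle_affinity(M, sparsity=0.0)
        # arccos has sqrt-precision at the domain edge
        assert S.values[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_invariants_on_random_input(self, rng):
        S = normalized_angle_affinity(rng.standard_normal((30, 40)), sparsity=0.7)
        V = S.values
        assert np.abs(V - V.T).max() < 1e-10
        assert V.min() >= 0.0 and V.max() <= 1.0
        assert np.allclose(np.diag(V), 1.0)

    def test_sparsification_zeroes_smallest_fraction(self):
        # after zeroing the smallest half, rows [1,2,3,4] and [0,0,3,4]
        # coincide, so their affinity is exactly 1
        M = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 3.0, 4.0]])
        S = normalized_angle_affinity(M, sparsity=0.5)
        assert S.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_zero_row_rejected_with_name(self):
        bad = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="1"):
            normalized_angle_affinity(bad, sparsity=0.0)


class TestDiffusionMapEmbed:
    def test_two_block_affinity_sign_separates_blocks(self):
        S = np.full((20, 20), 0.01)
        S[:10, :10] = 1.0
        S[10:, 10:] = 1.0
        np.fill_diagonal(S, 1.0)
        g = diffusion_map_embed(AffinityMatrix(S), 3)
        c1 = g.component(0)
        assert (np.sign(c1[:10]) == -np.sign(c1[10:])).all()

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((25, 30))
        S = normalized_angle_affinity(X, sparsity=0.0)
        perm = rng.permutation(25)
        Sp = AffinityMatrix(S.values[np.ix_(perm, perm)])
        g = diffusion_map_embed(S, 4)
        gp = diffusion_map_embed(Sp, 4)
        for i in range(4):
            r = abs(pearsonr(gp.component(i), g.component(i)[perm]).statistic)
            assert r > 0.999999

    def test_matches_dense_oracle(self, rng):
        """Recovered eigenpairs match a brute-force eigensolve of the same
        normalized operator."""
        for _ in range(10):
            n = int(rng.integers(10, 51))
            S = normalized_angle_affinity(rng.standard_normal((n, n + 5)), sparsity=0.3)
            g = diffusion_map_embed(S, 4, alpha=0.5)
            ev, evec = dense_transition_oracle(S, 0.5, 4)
            assert np.abs(ev[1:5] - g.eigenvalues).max() < 1e-8
            for i in range(4):
                r = abs(pearsonr(g.component(i), evec[:, i + 1]).statistic)
                assert r > 0.999

    def test_eigenvalues_strictly_below_one_and_sorted(self, rng):
        S = normalized_angle_affinity(rng.standard_normal((30, 35)), sparsity=0.5)
        g = diffusion_map_embed(S, 6)
        assert (g.eigenvalues < 1.0).all()
        assert (np.diff(g.eigenvalues) <= 1e-12).all()
        assert (g.eigenvalues >= 0.0).all()

    def test_stationary_measure_orthogonality(self, rng):
        S = normalized_angle_affinity(rng.standard_normal((30, 35)), sparsity=0.0)
        g = diffusion_map_embed(S, 5)
        W0 = S.values
        d = W0.sum(axis=1)
        W = W0 / np.outer(d**0.5, d**0.5)
        pi = W.sum(axis=1)
        pi = pi / pi.sum()
        comps = g.components / np.linalg.norm(g.components, axis=1, keepdims=True)
        G = (comps * pi[None, :]) @ comps.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6

    def test_sign_convention_largest_element_positive(self, rng):
        S = normalized_angle_affinity(rng.standard_normal((20, 25)), sparsity=0.0)
        g = diffusion_map_embed(S, 4)
        for c in g.components:
            assert c[np.argmax(np.abs(c))] > 0

    def test_disconnected_graph_reports_component_sizes(self):
        S = np.eye(6)
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="component sizes"):
            diffusion_map_embed(AffinityMatrix(S), 2)


class TestHippocampalGradients:
    def test_identical_rows_rejected(self):
        vals = np.tile(np.linspace(0, 1, 12), (8, 1))
        C = ConnectivityMatrix(vals, "hippocampal-vertex", "cortical-parcel")
        with pytest.raises(ValueError):
            hippocampal_gradients(C, 2)

    def test_scale_invariance(self, rng):
        vals = rng.standard_normal((20, 30))
        C1 = ConnectivityMatrix(vals, "hippocampal-vertex", "cortical-parcel")
        C2 = ConnectivityMatrix(2 * vals, "hippocampal-vertex", "cortical-parcel")
        g1 = hippocampal_gradients(C1, 3, sparsity=0.5)
        g2 = hippocampal_gradients(C2, 3, sparsity=0.5)
        assert np.allclose(g1.components, g2.components, atol=1e-10)


class TestJointEmbedding:
    def test_duplicated_species_identity(self, rng):
        """C_M = C_H means every parcel appears twice; the embedding must
        assign both copies identical gradient values."""
        for _ in range(5):
            M = rng.standard_normal((25, 15))
            C1 = ConnectivityMatrix(M, "hippocampal-vertex", "cortical-parcel", "H")
            C2 = ConnectivityMatrix(M.copy(), "hippocampal-vertex", "cortical-parcel", "M")
            gh, gm = joint_cross_species_embed(C1, C2, 4, sparsity=0.5)
            assert np.abs(gh.components - gm.components).max() < 1e-8

    def test_mismatched_hippocampal_dimension_rejected(self, rng):
        C1 = ConnectivityMatrix(rng.standard_normal((10, 5)),
                                "hippocampal-vertex", "cortical-parcel")
        C2 = ConnectivityMatrix(rng.standard_normal((12, 5)),
                                "hippocampal-vertex", "cortical-parcel")
        with pytest.raises(ValueError):
            joint_cross_species_embed(C1, C2, 2)

    def test_low_divergence_species_agree_on_joint_gradient(self, default_run):
        gh, gm = joint_cross_species_embed(default_run["C_h"], default_run["C_m"], 3)
        r = abs(pearsonr(gh.component(0), gm.component(0)).statistic)
        assert r > 0.9


class TestCorticoCorticalGradients:
    def test_networks_separate_at_low_noise(self, small_grid, rng):
        from hippogradients.synth import make_cortex, simulate_two_species

        ch = make_cortex(40, 4, "H", 0)
        cm = make_cortex(40, 4, "M", 0)
        dh, _ = simulate_two_species(
            small_grid, ch, cm, n_subjects=2, n_timepoints=200,
            noise_sd=0.05, seed=4,
        )
        g = corticocortical_gradients([ctx for _, ctx in dh.subjects], 3)
        # leading components separate networks: between-network spread of
        # network-mean values exceeds mean within-network spread
        comps = g.components[:2]
        labels = ch.network_label
        for c in comps:
            means = np.array([c[labels == k].mean() for k in range(1, 5)])
            within = np.mean([c[labels == k].std() for k in range(1, 5)])
            if means.std() > 2 * within:
                break
        else:
            pytest.fail("no leading component separates the planted networks")

    def test_single_subject_equals_identical_group(self, rng):
        vals = rng.standard_normal((15, 50))
        one = TimeSeries(vals, "cortical-parcel")
        g1 = corticocortical_gradients([one], 3, sparsity=0.5)
        g3 = corticocortical_gradients([one, one, one], 3, sparsity=0.5)
        assert np.allclose(g1.components, g3.components, atol=1e-10)
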