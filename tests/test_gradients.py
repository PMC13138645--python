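"""Parcellation, normalized-angle affinity, and diffusion-map embedding.

The embedding is cross-checked against an independent brute-force oracle
that forms the Markov operator explicitly and eigendecomposes it with the
generic nonsymmetric solver.
"""
import numpy as np
import pytest
from scipy import linalg as sla

import ggcflow as gf
from ggcflow.errors import ArgumentError, DataValidationError
from ggcflow.gradients import ConnectivityMatrix, _sparsify_rows


def dense_embedding_oracle(w, n_components, alpha=0.5):
    """Brute-force diffusion map: explicit P, nonsymmetric eigensolver."""
    w = np.asarray(w, dtype=float)
    d = w.sum(axis=1)
    w2 = w / np.outer(d**alpha, d**alpha)
    p = w2 / w2.sum(axis=1, keepdims=True)
    eigval, eigvec = sla.eig(p)
    order = np.argsort(-eigval.real)
    lam = eigval.real[order][1 : n_components + 1]
    psi = eigvec.real[:, order][:, 1 : n_components + 1]
    return psi * (lam / (1 - lam)), lam


def random_symmetric_affinity(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 1.0)
    return w


class TestSpatialParcellation:
    def test_two_blobs_perfect_split(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.05, (100, 3))
        b = rng.normal(0, 0.05, (100, 3)) + [1.0, 0, 0]
        coords = np.vstack([a, b])
        parc = gf.spatial_parcellation(coords, 2, seed=1)
        # brute-force check: each point assigned to its nearest centroid,
        # and the split separates the blobs exactly
        dists = np.linalg.norm(
            coords[:, None, :] - parc.centroids[None, :, :], axis=2
        )
        np.testing.assert_array_equal(parc.labels, dists.argmin(axis=1))
        assert len(set(parc.labels[:100])) == 1
        assert parc.labels[0] != parc.labels[100]

    def test_clusters_nonempty_and_deterministic(self, icosphere3):
        p1 = gf.spatial_parcellation(icosphere3.vertices, 40, seed=7)
        p2 = gf.spatial_parcellation(icosphere3.vertices, 40, seed=7)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        assert np.bincount(p1.labels, minlength=40).min() > 0

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ArgumentError):
            gf.spatial_parcellation(np.random.default_rng(0).random((5, 3)), 5, 0)


class TestProfileAffinity:
    def test_kernel_endpoints(self):
        # duplicate rows correlate at r=1 -> s=1; the kernel itself maps
        # r=0 -> 0.5 and r=-1 -> 0 (1 - arccos(r)/pi)
        assert 1 - np.arccos(1.0) / np.pi == pytest.approx(1.0)
        assert 1 - np.arccos(0.0) / np.pi == pytest.approx(0.5)
        assert 1 - np.arccos(-1.0) / np.pi == pytest.approx(0.0)
        rng = np.random.default_rng(3)
        c = rng.random((6, 6))
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 0.0)
        c[1] = c[0]
        c[:, 1] = c[:, 0]
        c[0, 1] = c[1, 0] = 0.0
        aff = gf.profile_affinity(ConnectivityMatrix(c), kept_fraction=1.0)
        assert aff.similarities[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(11)
        c = rng.random((50, 50))
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 0.0)
        kept = 0.10
        aff = gf.profile_affinity(ConnectivityMatrix(c), kept)
        sparse = _sparsify_rows(ConnectivityMatrix(c).counts, kept)
        expected = np.empty((50, 50))
        for i in range(50):
            for j in range(50):
                r = np.corrcoef(sparse[i], sparse[j])[0, 1]
                expected[i, j] = 1 - np.arccos(np.clip(r, -1, 1)) / np.pi
        np.testing.assert_allclose(aff.similarities, expected, atol=1e-12)

    def test_bounds_and_diagonal(self):
        aff = gf.profile_affinity(random_symmetric_affinity(30, 2) * 10, 0.2)
        s = aff.similarities
        assert (s >= 0).all() and (s <= 1).all()
        np.testing.assert_allclose(np.diag(s), 1.0)

    def test_constant_row_rejected(self):
        c = random_symmetric_affinity(5, 0)
        np.fill_diagonal(c, 0.0)
        c[2, :] = c[:, 2] = 0.0  # isolated node: constant (zero) profile
        with pytest.raises(DataValidationError, match="node"):
            gf.profile_affinity(ConnectivityMatrix(c), kept_fraction=1.0)


class TestDiffusionEmbedding:
    def test_path_graph_first_gradient_monotone(self):
        n = 30
        aff = np.eye(n)
        idx = np.arange(n - 1)
        aff[idx, idx + 1] = aff[idx + 1, idx] = 1.0
        grads = gf.diffusion_embedding(aff, 3)
        diffs = np.diff(grads.gradient(1))
        assert (diffs > 0).all() or (diffs < 0).all()

    @pytest.mark.parametrize("n", [50, 120, 200])
    def test_matches_dense_oracle(self, n):
        w = random_symmetric_affinity(n, seed=n)
        grads = gf.diffusion_embedding(w, 4)
        oracle, lam = dense_embedding_oracle(w, 4)
        np.testing.assert_allclose(grads.eigenvalues, lam, rtol=1e-8)
        for k in range(4):
            r = np.corrcoef(grads.gradients[:, k], oracle[:, k])[0, 1]
            assert abs(r) > 0.999

    def test_explained_variance_normalization(self):
        w = random_symmetric_affinity(25, 4)
        grads = gf.diffusion_embedding(w, 23)  # all nontrivial components
        ev = grads.explained_variance
        assert (np.diff(ev) <= 1e-12).all()
        assert (ev >= 0).all() and (ev <= 1).all()
        assert ev.sum() == pytest.approx(1.0)

    def test_disconnected_graph_rejected(self):
        w = np.eye(6)
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(DataValidationError, match="connected"):
            gf.diffusion_embedding(w, 2)

    def test_asymmetric_input_rejected(self):
        w = random_symmetric_affinity(10, 1)
        w[0, 1] += 0.5
        with pytest.raises(DataValidationError, match="symmetric"):
            gf.diffusion_embedding(w, 2)


class TestExtremalMask:
    def test_exact_decile_on_ramp(self):
        top, bottom = gf.extremal_mask(np.arange(100.0), 0.10)
        assert set(np.flatnonzero(top)) == set(range(90, 100))
        assert set(np.flatnonzero(bottom)) == set(range(10))

    def test_masks_disjoint_and_sized(self):
        rng = np.random.default_rng(9)
        vals = rng.random(137)
        top, bottom = gf.extremal_mask(vals, 0.10)
        k = int(np.ceil(0.10 * 137))
        assert top.sum() == bottom.sum() == k
        assert not (top & bottom).any()

    def test_constant_map_rejected(self):
        with pytest.raises(DataValidationError):
            gf.extremal_mask(np.ones(10), 0.1)

    @pytest.mark.parametrize("frac", [0.0, 0.5, 0.7])
    def test_fraction_bounds(self, frac):
        with pytest.raises(ArgumentError):
            gf.extremal_mask(np.arange(10.0), frac)


class TestRegionAverageMap:
    def test_constant_map(self):
        out = gf.region_average_map(np.full(6, 3.5), [0, 0, 1, 1, 2, 2])
        assert all(v == 3.5 for v in out.values())

    def test_two_region_arithmetic(self):
        out = gf.region_average_map([1.0, 3.0, 5.0, 7.0], [0, 0, 1, 1])
        assert out == {0: 2.0, 1: 6.0}

    def test_length_mismatch(self):
        with pytest.raises(ArgumentError):
            gf.region_average_map([1.0, 2.0], [0])


class TestConnectivityMatrixValidation:
    def test_symmetry_enforced_within_tolerance(self):
        c = np.array([[0.0, 1.0], [1.0 + 5e-10, 0.0]])
        cm = ConnectivityMatrix(c)
        np.testing.assert_array_equal(cm.counts, cm.counts.T)

    def test_asymmetry_beyond_tolerance_rejected(self):
        with pytest.raises(DataValidationError, match="symmetric"):
            ConnectivityMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonfinite_named(self):
        c = np.zeros((3, 3))
        c[1, 2] = c[2, 1] = np.nan
        with pytest.raises(DataValidationError, match=r"\(1, 2\)"):
            ConnectivityMatrix(c)
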