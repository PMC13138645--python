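"""Spin-test rotation sampling, remapping, and permutation p-values."""
import numpy as np
import pytest
from scipy import stats

import ggcflow as gf
from ggcflow.errors import ArgumentError, DataValidationError
from ggcflow.mesh import TriangleMesh


class TestSampleRotation:
    def test_orthogonal_unit_determinant(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            r = gf.sample_rotation(rng)
            assert np.abs(r @ r.T - np.eye(3)).max() < 1e-12
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        a = gf.sample_rotation(np.random.default_rng(42))
        b = gf.sample_rotation(np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_octant_uniformity(self):
        rng = np.random.default_rng(1)
        n = 20_000
        images = np.stack([gf.sample_rotation(rng)[:, 2] for _ in range(n)])
        octant = (
            (images[:, 0] > 0).astype(int) * 4
            + (images[:, 1] > 0).astype(int) * 2
            + (images[:, 2] > 0).astype(int)
        )
        counts = np.bincount(octant, minlength=8)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 / 8)
        assert (counts >= lo).all() and (counts <= hi).all()


class TestProjectToSphere:
    def test_icosphere_projection_is_identity(self, icosphere3):
        np.testing.assert_allclose(
            gf.project_to_sphere(icosphere3), icosphere3.vertices, atol=1e-12
        )

    def test_unit_norm_on_folded_surface(self, bumpy3):
        coords = gf.project_to_sphere(bumpy3)
        np.testing.assert_allclose(
            np.linalg.norm(coords, axis=1), 1.0, atol=1e-12
        )

    def test_translation_invariance(self, icosphere3):
        moved = TriangleMesh(icosphere3.vertices + [3.0, -1.0, 8.0], icosphere3.faces)
        np.testing.assert_allclose(
            gf.project_to_sphere(moved), gf.project_to_sphere(icosphere3),
            atol=1e-9,
        )


class TestSpinPermuteMap:
    def test_identity_rotation(self, icosphere3):
        coords = gf.project_to_sphere(icosphere3)
        values = icosphere3.vertices[:, 0] * 2 + icosphere3.vertices[:, 1]
        np.testing.assert_array_equal(
            gf.spin_permute_map(values, coords, np.eye(3)), values
        )

    def test_output_values_subset_of_input(self, icosphere3):
        coords = gf.project_to_sphere(icosphere3)
        values = np.arange(icosphere3.n_vertices, dtype=float)
        rot = gf.sample_rotation(np.random.default_rng(3))
        out = gf.spin_permute_map(values, coords, rot)
        assert set(out).issubset(set(values))

    def test_symmetry_axis_roundtrip_exact(self, icosphere3):
        # 72 deg rotation about a 5-fold icosahedral axis permutes vertices,
        # so the remap is an exact permutation and round-trips exactly
        axis = icosphere3.vertices[0] / np.linalg.norm(icosphere3.vertices[0])
        angle = 2 * np.pi / 5
        k = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
        coords = gf.project_to_sphere(icosphere3)
        values = np.arange(icosphere3.n_vertices, dtype=float)
        once = gf.spin_permute_map(values, coords, rot)
        assert sorted(once) == sorted(values)  # exact permutation
        back = gf.spin_permute_map(once, coords, rot.T)
        np.testing.assert_array_equal(back, values)

    def test_length_mismatch(self, icosphere3):
        coords = gf.project_to_sphere(icosphere3)
        with pytest.raises(ArgumentError):
            gf.spin_permute_map(np.ones(5), coords, np.eye(3))


class TestSpinPvalue:
    def test_pvalue_formula_floor_on_self_test(self, icosphere3, sphere_modes=None):
        modes = gf.solve_eigenmodes(icosphere3, 10)
        coords = gf.project_to_sphere(icosphere3)
        ref = modes.mode(4)
        null = gf.spin_pvalue(ref, ref, coords, n_perm=500, seed=11)
        assert null.p_spin == pytest.approx(1 / 501)
        assert null.r_obs == pytest.approx(1.0)

    def test_formula_holds_exactly(self, icosphere3):
        modes = gf.solve_eigenmodes(icosphere3, 10)
        coords = gf.project_to_sphere(icosphere3)
        rng = np.random.default_rng(0)
        probe = rng.normal(size=icosphere3.n_vertices)
        null = gf.spin_pvalue(probe, modes.mode(3), coords, n_perm=200, seed=5)
        exceed = int(np.count_nonzero(np.abs(null.r_null) >= null.r_obs))
        assert null.p_spin == (exceed + 1) / 201
        assert 1 / 201 <= null.p_spin <= 1.0

    def test_deterministic_given_seed(self, icosphere3):
        coords = gf.project_to_sphere(icosphere3)
        rng = np.random.default_rng(2)
        probe = rng.normal(size=icosphere3.n_vertices)
        ref = coords[:, 2]
        a = gf.spin_pvalue(probe, ref, coords, 100, seed=9)
        b = gf.spin_pvalue(probe, ref, coords, 100, seed=9)
        assert a.p_spin == b.p_spin
        np.testing.assert_array_equal(a.r_null, b.r_null)

    def test_permuted_distribution_close_to_original(self, icosphere3):
        # NN remapping duplicates some values; the empirical distribution
        # should still track the original within KS distance 0.05
        coords = gf.project_to_sphere(icosphere3)
        rng = np.random.default_rng(4)
        values = np.sin(3 * coords[:, 0]) + coords[:, 1]
        rot = gf.sample_rotation(rng)
        permuted = gf.spin_permute_map(values, coords, rot)
        ks = stats.ks_2samp(values, permuted).statistic
        assert ks < 0.05

    def test_constant_map_rejected(self, icosphere3):
        coords = gf.project_to_sphere(icosphere3)
        with pytest.raises(DataValidationError):
            gf.spin_pvalue(
                np.ones(icosphere3.n_vertices), coords[:, 2], coords, 10, seed=0
            )

    def test_stronger_alignment_never_increases_median_p(self, icosphere3):
        modes = gf.solve_eigenmodes(icosphere3, 10)
        coords = gf.project_to_sphere(icosphere3)
        ref = modes.mode(4)
        perms = gf.spin_permutations(coords, 200, seed=77)
        median_p = []
        for noise in (0.1, 1.0, 4.0):
            ps = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                probe = ref + noise * rng.normal(size=len(ref)) * ref.std()
                ps.append(
                    gf.spin_pvalue(
                        probe, ref, coords, 200, seed=77, permutations=perms
                    ).p_spin
                )
            median_p.append(np.median(ps))
        assert median_p[0] <= median_p[1] <= median_p[2]


def test_spin_permutations_shape_and_determinism(icosphere3):
    coords = gf.project_to_sphere(icosphere3)
    a = gf.spin_permutations(coords, 7, seed=3)
    b = gf.spin_permutations(coords, 7, seed=3)
    assert a.shape == (7, icosphere3.n_vertices)
    np.testing.assert_array_equal(a, b)
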