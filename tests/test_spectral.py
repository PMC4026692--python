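import numpy as np
import pytest

from shapedx.io import BinaryMask
from shapedx.spectral import (
    assemble_dirichlet_laplacian,
    compute_eigenvalues,
    invariant_features,
    spectral_descriptor,
    unit_ball_eigenvalues,
)
from conftest import ball_mask, cube_mask


def _single_voxel_mask(spacing):
    voxels = np.zeros((3, 3, 3), np.uint8)
    voxels[1, 1, 1] = 1
    return BinaryMask(voxels=voxels, spacing=spacing)


class TestOperatorAssembly:
    def test_single_voxel_stencil_center(self):
        op = assemble_dirichlet_laplacian(_single_voxel_mask((1, 1, 1)), min_voxels=1)
        assert op.matrix.shape == (1, 1)
        assert op.matrix[0, 0] == pytest.approx(6.0)

    def test_single_voxel_anisotropic_spacing(self):
        op = assemble_dirichlet_laplacian(_single_voxel_mask((1, 1, 2)), min_voxels=1)
        assert op.matrix[0, 0] == pytest.approx(2 + 2 + 2 / 4)  # 4.5

    def test_two_adjacent_voxels(self):
        voxels = np.zeros((3, 3, 4), np.uint8)
        voxels[1, 1, 1] = voxels[1, 1, 2] = 1
        op = assemble_dirichlet_laplacian(
            BinaryMask(voxels=voxels, spacing=(1, 1, 1)), min_voxels=1)
        dense = op.matrix.toarray()
        np.testing.assert_allclose(dense, [[6, -1], [-1, 6]])

    def test_operator_symmetric_positive_definite(self):
        mask = ball_mask(4.0)
        op = assemble_dirichlet_laplacian(mask, min_voxels=10)
        A = op.matrix.toarray()
        np.testing.assert_allclose(A, A.T)
        assert np.linalg.eigvalsh(A).min() > 0

    def test_disconnected_stray_voxels_dropped(self):
        voxels = np.zeros((20, 20, 20), np.uint8)
        voxels[2:7, 2:7, 2:7] = 1  # 125-voxel block
        voxels[15, 15, 15:18] = 1  # stray 3-voxel bar, >1% of foreground
        with pytest.warns(UserWarning, match="largest 6-connected"):
            op = assemble_dirichlet_laplacian(
                BinaryMask(voxels=voxels, spacing=(1, 1, 1)), min_voxels=10)
        assert op.matrix.shape[0] == 125
        assert op.n_dropped == 3

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="voxels"):
            assemble_dirichlet_laplacian(_single_voxel_mask((1, 1, 1)),
                                         min_voxels=200)


class TestEigenvalues:
    def test_n_must_be_below_dimension(self):
        op = assemble_dirichlet_laplacian(ball_mask(3.0), min_voxels=10)
        with pytest.raises(ValueError, match="matrix dimension"):
            compute_eigenvalues(op, n=op.n)

    def test_dense_sparse_equivalence_small_domain(self):
        """Sparse path matches a full dense eigendecomposition on <=300 voxels."""
        mask = ball_mask(4.0)  # 257 voxels
        op = assemble_dirichlet_laplacian(mask, min_voxels=10)
        assert op.n <= 300
        sparse_vals = compute_eigenvalues(op, n=20)
        dense_vals = np.linalg.eigvalsh(op.matrix.toarray())[:20]
        np.testing.assert_allclose(sparse_vals, dense_vals, rtol=1e-8)

    def test_cube_spectrum_closed_form_small(self):
        """Dirichlet box eigenvalues pi^2 (l^2+m^2+n^2)/L^2 at modest resolution."""
        side = 20
        op = assemble_dirichlet_laplacian(cube_mask(side), min_voxels=10)
        vals = compute_eigenvalues(op, n=4)
        L = side + 1.0  # Dirichlet zeros sit half a stencil outside the grid
        exact1 = 3 * np.pi**2 / L**2
        exact2 = 6 * np.pi**2 / L**2
        assert vals[0] == pytest.approx(exact1, rel=0.02)
        np.testing.assert_allclose(vals[1:4], exact2, rtol=0.02)

    def test_axis_permutation_preserves_spectrum_exactly(self):
        rng = np.random.default_rng(0)
        voxels = (rng.random((9, 10, 11)) > 0.35).astype(np.uint8)
        from scipy import ndimage

        lab, _ = ndimage.label(voxels)
        voxels = (lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1).astype(np.uint8)
        mask = BinaryMask(voxels=voxels, spacing=(1, 1, 1))
        op = assemble_dirichlet_laplacian(mask, min_voxels=10)
        vals = compute_eigenvalues(op, n=10)
        permuted = BinaryMask(voxels=np.transpose(voxels, (2, 0, 1)),
                              spacing=(1, 1, 1))
        vals_p = compute_eigenvalues(
            assemble_dirichlet_laplacian(permuted, min_voxels=10), n=10)
        np.testing.assert_allclose(vals, vals_p, rtol=1e-9)

    def test_rotation_90_degrees_preserves_spectrum(self):
        mask = ball_mask(5.0)
        voxels = mask.voxels
        voxels[0:2, 5, 5] = 1  # break spherical symmetry with a small stalk
        mask = BinaryMask(voxels=voxels, spacing=(1, 1, 1))
        vals = compute_eigenvalues(
            assemble_dirichlet_laplacian(mask, min_voxels=10), n=8)
        rot = BinaryMask(voxels=np.rot90(voxels, axes=(0, 1)).copy(),
                         spacing=(1, 1, 1))
        vals_r = compute_eigenvalues(
            assemble_dirichlet_laplacian(rot, min_voxels=10), n=8)
        np.testing.assert_allclose(vals, vals_r, rtol=1e-9)

    def test_domain_monotonicity_for_concentric_balls(self):
        """Eigenvalues of a sub-ball dominate those of the containing ball."""
        inner = compute_eigenvalues(
            assemble_dirichlet_laplacian(ball_mask(6.0), min_voxels=10), n=10)
        outer = compute_eigenvalues(
            assemble_dirichlet_laplacian(ball_mask(9.0), min_voxels=10), n=10)
        assert (inner >= outer - 1e-12).all()

    def test_eigenvalues_scale_inverse_square_with_spacing(self):
        mask = ball_mask(6.0)
        op1 = assemble_dirichlet_laplacian(mask, min_voxels=10)
        mask2 = BinaryMask(voxels=mask.voxels, spacing=(2.0, 2.0, 2.0))
        op2 = assemble_dirichlet_laplacian(mask2, min_voxels=10)
        v1 = compute_eigenvalues(op1, n=12)
        v2 = compute_eigenvalues(op2, n=12)
        np.testing.assert_allclose(v1, 4 * v2, rtol=1e-9)


class TestUnitBallReference:
    def test_first_eigenvalue_is_pi_squared(self):
        d = unit_ball_eigenvalues(10)
        assert d[0] == pytest.approx(np.pi**2, rel=1e-12)

    def test_multiplicities_and_ordering(self):
        d = np.array(unit_ball_eigenvalues(30))
        assert (np.diff(d) >= -1e-12).all()
        # second distinct eigenvalue: first zero of j_1 (~4.4934), multiplicity 3
        from scipy.optimize import brentq
        from scipy.special import spherical_jn

        z11 = brentq(lambda x: spherical_jn(1, x), 4.0, 5.0)
        np.testing.assert_allclose(d[1:4], z11**2, rtol=1e-10)


class TestInvariantFeatures:
    def test_feature_lengths_and_default_n(self):
        lam = np.cumsum(np.linspace(1.0, 2.0, 100))
        for family in ("F1", "F2", "F3"):
            assert len(invariant_features(lam, family, n=100)) == 99

    def test_f1_f2_in_unit_interval(self):
        lam = np.sort(np.random.default_rng(2).uniform(1, 50, size=40))
        for family in ("F1", "F2"):
            f = invariant_features(lam, family, n=40)
            assert ((f > 0) & (f <= 1)).all()

    def test_f2_is_consecutive_ratios(self):
        lam = np.array([2.0, 4.0, 8.0, 10.0])
        np.testing.assert_allclose(invariant_features(lam, "F2"),
                                   [0.5, 0.5, 0.8])

    def test_f1_is_ratios_to_first(self):
        lam = np.array([2.0, 4.0, 8.0, 10.0])
        np.testing.assert_allclose(invariant_features(lam, "F1"),
                                   [0.5, 0.25, 0.2])

    def test_f3_zero_for_exact_sphere_spectrum(self):
        lam = np.array(unit_ball_eigenvalues(50))
        f3 = invariant_features(lam, "F3", n=50)
        np.testing.assert_allclose(f3, 0.0, atol=1e-12)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            invariant_features(np.array([0.0, 1.0, 2.0]), "F2")

    def test_digitized_ball_f3_small_at_modest_resolution(self):
        desc = spectral_descriptor(ball_mask(10.0), family="F3", n=21,
                                   min_voxels=100)
        assert np.abs(desc.features[:20]).max() <= 0.05

    def test_scale_invariance_of_ratio_features(self):
        """Same digitized shape at 1.5x physical size: F2 agrees entrywise."""
        f_small = spectral_descriptor(ball_mask(9.0), family="F2", n=15,
                                      min_voxels=100).features
        f_large = spectral_descriptor(ball_mask(13.5), family="F2", n=15,
                                      min_voxels=100).features
        np.testing.assert_allclose(f_small, f_large, rtol=0.03)
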