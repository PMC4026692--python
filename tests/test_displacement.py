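import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapedx.displacement import (
    CorrespondencePair,
    DisplacementField,
    displacement_field,
    partition_surface,
    patch_features,
    patch_group_difference,
    rigid_align,
)
from shapedx.io import SurfaceMesh
from conftest import icosphere_mesh


def _rotated(mesh: SurfaceMesh, rotation: Rotation, translation) -> SurfaceMesh:
    return SurfaceMesh(vertices=rotation.apply(mesh.vertices) + translation,
                       faces=mesh.faces)


class TestRigidAlign:
    def test_identity_for_identical_point_sets(self):
        pts = icosphere_mesh(1).vertices
        tf = rigid_align(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_known_rotation_and_translation(self):
        pts = icosphere_mesh(1).vertices
        rot = Rotation.from_euler("z", 30, degrees=True)
        t = np.array([1.0, 2.0, 3.0])
        moved = rot.apply(pts) + t
        tf = rigid_align(pts, moved)
        np.testing.assert_allclose(tf.rotation, rot.as_matrix(), atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-9)
        np.testing.assert_allclose(tf.apply(pts), moved, atol=1e-9)

    def test_reflection_yields_proper_rotation_with_residual(self):
        pts = icosphere_mesh(1).vertices
        # perturb so the set has no mirror symmetry, then reflect
        rng = np.random.default_rng(3)
        pts = pts + rng.normal(0, 0.05, pts.shape)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tf = rigid_align(pts, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)
        residual = np.linalg.norm(tf.apply(pts) - mirrored)
        assert residual > 0.1

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="degenerate"):
            rigid_align(pts, pts + 1.0)


class TestDisplacementField:
    def test_identical_surfaces_give_zero_field(self):
        mesh = icosphere_mesh(2)
        field = displacement_field(CorrespondencePair(mesh, mesh))
        np.testing.assert_allclose(field.magnitudes, 0.0, atol=1e-12)

    def test_translation_removed_by_prealignment(self):
        mesh = icosphere_mesh(2)
        shifted = SurfaceMesh(mesh.vertices + np.array([3.0, 0, 0]), mesh.faces)
        pair = CorrespondencePair(mesh, shifted)
        aligned = displacement_field(pair, prealign=True)
        np.testing.assert_allclose(aligned.magnitudes, 0.0, atol=1e-9)
        raw = displacement_field(pair, prealign=False)
        np.testing.assert_allclose(raw.magnitudes, 3.0, atol=1e-12)

    def test_rigid_motion_invariance_with_prealign(self):
        """Any rigid motion of the target leaves the field unchanged (<=1e-6 mm)."""
        template = icosphere_mesh(2, radius=10.0)
        rng = np.random.default_rng(7)
        target = SurfaceMesh(
            template.vertices + rng.normal(0, 0.3, template.vertices.shape),
            template.faces)
        base = displacement_field(CorrespondencePair(template, target))
        rot = Rotation.from_euler("xyz", [17, -40, 63], degrees=True)
        moved = _rotated(target, rot, np.array([5.0, -2.0, 11.0]))
        after = displacement_field(CorrespondencePair(template, moved))
        np.testing.assert_allclose(after.magnitudes, base.magnitudes, atol=1e-6)

    def test_radial_inflation_recovered_with_sign(self):
        template = icosphere_mesh(2, radius=10.0)
        target = icosphere_mesh(2, radius=10.5)
        field = displacement_field(CorrespondencePair(template, target),
                                   prealign=False)
        np.testing.assert_allclose(field.magnitudes, 0.5, atol=1e-9)
        np.testing.assert_allclose(field.signed, 0.5, atol=1e-3)

    def test_vertex_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="vertex count"):
            CorrespondencePair(icosphere_mesh(1), icosphere_mesh(2))

    def test_signed_bounded_by_magnitude(self):
        with pytest.raises(ValueError, match="signed"):
            DisplacementField(magnitudes=np.array([1.0]), signed=np.array([1.5]))


class TestPartition:
    def test_single_patch_contains_all_vertices(self):
        mesh = icosphere_mesh(1)
        part = partition_surface(mesh, n_patches=1, seed=0)
        assert set(part.assignment) == {0}

    def test_one_patch_per_vertex(self):
        mesh = icosphere_mesh(1)
        part = partition_surface(mesh, n_patches=mesh.n_vertices, seed=0)
        assert len(set(part.assignment)) == mesh.n_vertices

    def test_too_many_patches_rejected(self):
        mesh = icosphere_mesh(1)
        with pytest.raises(ValueError, match="exceeds vertex count"):
            partition_surface(mesh, n_patches=mesh.n_vertices + 1, seed=0)

    def test_reproducible_for_fixed_seed_and_patches_nonempty(self):
        mesh = icosphere_mesh(3)
        p1 = partition_surface(mesh, n_patches=40, seed=11)
        p2 = partition_surface(mesh, n_patches=40, seed=11)
        np.testing.assert_array_equal(p1.assignment, p2.assignment)
        assert np.bincount(p1.assignment, minlength=40).min() >= 1

    def test_vertices_nearest_own_centroid(self):
        mesh = icosphere_mesh(2)
        part = partition_surface(mesh, n_patches=12, seed=5)
        d = np.linalg.norm(mesh.vertices[:, None] - part.centroids[None], axis=2)
        np.testing.assert_array_equal(np.argmin(d, axis=1), part.assignment)


class TestPatchFeatures:
    def test_constant_field_gives_constant_features(self):
        mesh = icosphere_mesh(2)
        part = partition_surface(mesh, n_patches=10, seed=0)
        feats = patch_features(np.full(mesh.n_vertices, 2.5), part)
        np.testing.assert_allclose(feats, 2.5)

    def test_single_patch_is_global_mean(self):
        mesh = icosphere_mesh(2)
        part = partition_surface(mesh, n_patches=1, seed=0)
        field = np.random.default_rng(0).random(mesh.n_vertices)
        np.testing.assert_allclose(patch_features(field, part), field.mean())

    def test_matches_bruteforce_means_and_bounds(self):
        mesh = icosphere_mesh(2)
        part = partition_surface(mesh, n_patches=15, seed=1)
        field = np.random.default_rng(2).random(mesh.n_vertices)
        feats = patch_features(field, part)
        brute = np.array([field[part.assignment == p].mean() for p in range(15)])
        np.testing.assert_allclose(feats, brute, atol=1e-12)
        assert (feats >= field.min() - 1e-12).all()
        assert (feats <= field.max() + 1e-12).all()

    def test_patch_means_conserve_global_mean(self):
        mesh = icosphere_mesh(3)
        part = partition_surface(mesh, n_patches=25, seed=2)
        field = np.random.default_rng(3).random(mesh.n_vertices)
        feats = patch_features(field, part)
        counts = np.bincount(part.assignment, minlength=25)
        weighted = (feats * counts).sum() / counts.sum()
        assert weighted == pytest.approx(field.mean(), abs=1e-9)

    def test_length_mismatch_rejected(self):
        mesh = icosphere_mesh(1)
        part = partition_surface(mesh, n_patches=3, seed=0)
        with pytest.raises(ValueError, match="length"):
            patch_features(np.zeros(mesh.n_vertices + 1), part)


class TestGroupDifference:
    def test_null_calibration_flag_rate(self):
        """Same-distribution groups: BH at q=0.05 flags <=5% of patches on average."""
        rng = np.random.default_rng(42)
        n_reps, n_patches = 300, 40
        flagged = 0
        for _ in range(n_reps):
            feats = rng.normal(0, 1, size=(24, n_patches))
            labels = np.array(["a"] * 12 + ["b"] * 12)
            res = patch_group_difference(feats, labels, ("a", "b"))
            flagged += res["significant"].sum()
        assert flagged / (n_reps * n_patches) <= 0.05

    def test_large_shift_detected(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(0, 1, size=(40, 30))
        feats[:20, 7] += 10.0  # one patch shifted by 10 SD in group a
        labels = np.array(["a"] * 20 + ["b"] * 20)
        res = patch_group_difference(feats, labels, ("a", "b"))
        assert res["significant"][7]
        assert res["t"][7] > 0

    def test_duplicated_groups_give_zero_statistics(self):
        feats = np.random.default_rng(2).normal(size=(10, 8))
        doubled = np.vstack([feats, feats])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = patch_group_difference(doubled, labels, ("a", "b"))
        np.testing.assert_allclose(res["t"], 0.0, atol=1e-12)
        assert not res["significant"].any()

    def test_single_subject_group_rejected(self):
        feats = np.zeros((3, 4))
        labels = np.array(["a", "b", "b"])
        with pytest.raises(ValueError, match=">= 2 subjects"):
            patch_group_difference(feats, labels, ("a", "b"))
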