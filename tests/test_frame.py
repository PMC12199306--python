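"""Principal-component frames: eigendecomposition, orientation, chirality."""

import numpy as np
import pytest

from hypershape import (
    FixtureSpec,
    build_frame,
    build_hypershape,
    center,
    enforce_chirality,
    generate,
    orient_axes,
    principal_axes,
)
from .conftest import random_rigid_motion, reflect


def frame_1d(projections, tolerance=1e-4):
    scores = np.asarray(projections, float).reshape(-1, 1)
    return orient_axes(np.eye(1), np.array([1.0]), scores, np.zeros(1), tolerance)


class TestCenter:
    def test_two_point_example(self):
        centered, centroid = center(np.array([[0.0], [2.0]]))
        assert centered.tolist() == [[-1.0], [1.0]]
        assert centroid.tolist() == [1.0]

    def test_single_atom_all_zero(self):
        centered, _ = center(np.array([[3.0, -1.0, 2.0]]))
        assert np.all(centered == 0.0)

    def test_column_means_vanish(self):
        rng = np.random.default_rng(0)
        centered, _ = center(rng.normal(size=(17, 5)))
        assert np.abs(centered.mean(axis=0)).max() < 1e-12


class TestPrincipalAxes:
    def test_collinear_cloud_rank_one(self):
        pts = np.array([[x, 0.0, 0.0] for x in (-2.0, -0.5, 1.0, 1.5)])
        centered, _ = center(pts)
        axes, eigenvalues, degenerate = principal_axes(centered)
        assert not degenerate
        assert abs(abs(axes[0, 0]) - 1.0) < 1e-12
        assert eigenvalues[0] > 0
        assert np.allclose(eigenvalues[1:], 0.0, atol=1e-12)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(42)
        centered, _ = center(rng.normal(size=(50, 4)))
        axes, eigenvalues, _ = principal_axes(centered)
        _, singular, vt = np.linalg.svd(centered, full_matrices=False)
        assert np.allclose(eigenvalues, singular**2 / 50, atol=1e-8)
        for k in range(4):  # eigenvectors defined up to sign
            assert min(np.linalg.norm(axes[:, k] - vt[k]),
                       np.linalg.norm(axes[:, k] + vt[k])) < 1e-8

    def test_regular_tetrahedron_isotropic(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        _, eigenvalues, _ = principal_axes(center(pts)[0])
        assert np.allclose(eigenvalues, eigenvalues[0])

    def test_single_point_degenerate_identity(self):
        axes, eigenvalues, degenerate = principal_axes(np.zeros((1, 3)))
        assert degenerate
        assert np.array_equal(axes, np.eye(3))
        assert np.all(eigenvalues == 0.0)


class TestOrientationCascade:
    def test_largest_projection_negative_flips(self):
        frame = frame_1d([-3.0, 1.0, 2.0])
        assert frame.n_c == 1
        assert frame.scores[:, 0].tolist() == [3.0, -1.0, -2.0]

    def test_symmetric_pair_defers_to_next_level(self):
        frame = frame_1d([-2.0, 2.0, -1.0])
        assert frame.n_c == 1
        assert frame.scores[:, 0].tolist() == [2.0, -2.0, 1.0]

    def test_fully_paired_scores_undetermined(self):
        frame = frame_1d([-2.0, -1.0, 1.0, 2.0])
        assert frame.n_c == 0
        assert frame.undetermined_axes == frozenset({0})

    def test_positive_largest_no_flip(self):
        frame = frame_1d([3.0, -1.0, 2.0])
        assert frame.n_c == 0

    def test_determinant_identity_on_random_clouds(self):
        for seed in range(200):
            mol = generate(FixtureSpec("random_cloud", seed=seed, n_atoms=8))
            frame = build_frame(build_hypershape(mol, "default6d"))
            assert frame.det_f == frame.det_i * (-1) ** frame.n_c

    def test_linear_symmetric_molecule_pc1_undetermined(self, linear_symmetric):
        frame = build_frame(build_hypershape(linear_symmetric, "3d"))
        assert 0 in frame.undetermined_axes


class TestFrameInvariances:
    def test_rigid_motion_leaves_eigenvalues_and_scores(self, random_cloud):
        shape = build_hypershape(random_cloud, "default6d")
        reference = build_frame(shape)
        rng = np.random.default_rng(7)
        for _ in range(20):
            rotation, translation = random_rigid_motion(rng)
            moved = random_cloud.with_coordinates(
                random_cloud.coordinates @ rotation.T + translation
            )
            frame = build_frame(build_hypershape(moved, "default6d"))
            assert np.allclose(frame.eigenvalues, reference.eigenvalues, atol=1e-8)
            assert np.allclose(frame.scores, reference.scores, atol=1e-8)

    def test_atom_permutation_invariance(self, random_cloud):
        reference = build_frame(build_hypershape(random_cloud, "default6d"))
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(random_cloud))
        from hypershape import Molecule

        permuted = Molecule([random_cloud.atoms[i] for i in perm], name="perm")
        frame = build_frame(build_hypershape(permuted, "default6d"))
        assert np.allclose(frame.axes, reference.axes, atol=1e-10)
        assert np.allclose(frame.eigenvalues, reference.eigenvalues, atol=1e-10)
        assert np.allclose(frame.scores, reference.scores[perm], atol=1e-10)

    def test_mirror_gives_identical_score_multisets(self, chiral_tetrahedron):
        mirrored = reflect(chiral_tetrahedron)
        f1 = build_frame(build_hypershape(chiral_tetrahedron, "3d"))
        f2 = build_frame(build_hypershape(mirrored, "3d"))
        for k in range(3):
            assert np.allclose(np.sort(f1.scores[:, k]), np.sort(f2.scores[:, k]),
                               atol=1e-10)


class TestChirality:
    def test_positive_determinant_is_noop(self, random_cloud):
        shape = build_hypershape(random_cloud, "3d")
        frame = build_frame(shape)
        if frame.det_f == -1:
            frame = enforce_chirality(frame)
        axes_before = frame.axes.copy()
        enforced = enforce_chirality(frame)
        assert enforced.chirality_enforced
        assert np.array_equal(enforced.axes, axes_before)

    def test_bookkeeping_example(self):
        # a single flip turns det -1 into +1: det_f = det_i * (-1)^n_c
        frame = frame_1d([-3.0, 1.0, 2.0])
        assert frame.det_i == 1 and frame.n_c == 1 and frame.det_f == -1

    def test_mirror_pair_gets_exactly_one_extra_flip(self, chiral_tetrahedron):
        mirrored = reflect(chiral_tetrahedron)
        frames = [
            build_frame(build_hypershape(m, "3d"), chirality=True)
            for m in (chiral_tetrahedron, mirrored)
        ]
        assert all(f.det_f == 1 for f in frames)
        assert all(f.chirality_enforced for f in frames)
        # reference points (max positive projections) now differ
        maxima = [f.scores.max(axis=0) for f in frames]
        assert not np.allclose(maxima[0], maxima[1], atol=1e-8)

    def test_determinant_plus_one_for_generic_clouds(self):
        for seed in range(30):
            mol = generate(FixtureSpec("random_cloud", seed=seed, n_atoms=7))
            frame = build_frame(build_hypershape(mol, "3d"), chirality=True)
            if not frame.undetermined_axes:
                assert round(float(np.linalg.det(frame.axes))) == 1

    def test_refused_with_warning_for_symmetric_cloud(self, linear_symmetric):
        shape = build_hypershape(linear_symmetric, "3d")
        with pytest.warns(UserWarning, match="chirality not applicable"):
            frame = build_frame(shape, chirality=True)
        assert not frame.chirality_enforced
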