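"""Reference points, distance distributions, moments, and fingerprint assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypershape import (
    FixtureSpec,
    Molecule,
    build_frame,
    build_hypershape,
    distance_distributions,
    generate,
    hsr_fingerprint,
    molecule_fingerprint,
    moment_triplet,
    reference_points,
    similarity_score,
)
from hypershape.fingerprint import fingerprints_to_csv, fingerprints_to_json
from .conftest import random_rigid_motion, reflect


class TestReferencePoints:
    def test_one_dimensional_example(self):
        from hypershape import orient_axes

        frame = orient_axes(np.eye(1), np.array([1.0]),
                            np.array([[-3.0], [1.0], [2.0]]), np.zeros(1))
        refs = reference_points(frame)
        assert refs.tolist() == [[0.0], [3.0]]  # centre, then +max projection

    def test_single_atom_all_at_origin(self):
        mol = Molecule([generate(FixtureSpec("random_cloud", seed=0, n_atoms=3)).atoms[0]])
        frame = build_frame(build_hypershape(mol, "3d"))
        assert np.all(reference_points(frame) == 0.0)

    def test_matches_brute_force_projection_oracle(self, random_cloud):
        frame = build_frame(build_hypershape(random_cloud, "3d"))
        refs = reference_points(frame)
        for k in range(3):
            brute = max(float(np.dot(row, frame.axes[:, k]))
                        for row in (random_cloud.coordinates - frame.centroid))
            assert refs[k + 1, k] == pytest.approx(brute, abs=1e-10)

    def test_scale_factor_moves_noncentre_points(self, random_cloud):
        frame = build_frame(build_hypershape(random_cloud, "3d"))
        assert np.allclose(reference_points(frame, scale=2.0),
                           2.0 * reference_points(frame))


class TestDistanceDistributions:
    def test_two_point_symmetric(self):
        dists = distance_distributions(np.array([[-1.0], [1.0]]), np.array([[0.0]]))
        assert dists.tolist() == [[1.0, 1.0]]

    def test_degenerate_axis_duplicates_centre_distribution(self, planar_cloud):
        frame = build_frame(build_hypershape(planar_cloud, "3d"))
        refs = reference_points(frame)
        dists = distance_distributions(frame.scores, refs)
        assert np.allclose(refs[3], 0.0)  # z axis of a planar cloud is empty
        assert np.allclose(dists[3], dists[0], atol=1e-12)

    def test_matches_double_loop_oracle(self, random_cloud):
        frame = build_frame(build_hypershape(random_cloud, "default6d"))
        refs = reference_points(frame)
        dists = distance_distributions(frame.scores, refs)
        for j, ref in enumerate(refs):
            for i, row in enumerate(frame.scores):
                expected = math.sqrt(sum((a - b) ** 2 for a, b in zip(ref, row)))
                assert dists[j, i] == pytest.approx(expected, abs=1e-12)


class TestMomentTriplet:
    @pytest.mark.parametrize(
        "distances,expected",
        [
            ([1, 1, 1, 1], (1.0, 0.0, 0.0)),
            ([0, 2], (1.0, 1.0, 0.0)),
            ([0, 0, 3], (1.0, math.sqrt(2), 2 / 2**1.5)),
        ],
    )
    def test_printed_examples(self, distances, expected):
        triplet = moment_triplet(distances)
        assert triplet.as_tuple() == pytest.approx(expected, abs=1e-12)

    def test_cbrt_convention(self):
        # third central moment of [0,0,3] is 2 => cbrt(2)
        assert moment_triplet([0, 0, 3], "cbrt").skewness == pytest.approx(2 ** (1 / 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            moment_triplet([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=30))
    def test_matches_scipy_population_moments(self, values):
        from scipy import stats

        triplet = moment_triplet(values)
        arr = np.asarray(values)
        assert triplet.mean == pytest.approx(arr.mean(), abs=1e-9)
        assert triplet.std == pytest.approx(arr.std(), abs=1e-9)
        if triplet.std > 1e-6:
            assert triplet.skewness == pytest.approx(
                stats.skew(arr, bias=True), abs=1e-7
            )


class TestFingerprintAssembly:
    def test_lengths(self, random_cloud):
        assert len(molecule_fingerprint(random_cloud, "default6d")) == 21
        assert len(molecule_fingerprint(random_cloud, "3d")) == 12

    def test_centre_triplet_comes_first(self, random_cloud):
        shape = build_hypershape(random_cloud, "3d")
        frame = build_frame(shape)
        refs = reference_points(frame)
        dists = distance_distributions(frame.scores, refs)
        fp = hsr_fingerprint(shape)
        assert fp.values[:3] == pytest.approx(moment_triplet(dists[0]).as_tuple())

    def test_rigid_motion_invariance(self, random_cloud):
        reference = molecule_fingerprint(random_cloud, "default6d")
        rng = np.random.default_rng(123)
        for _ in range(25):
            rotation, translation = random_rigid_motion(rng)
            moved = random_cloud.with_coordinates(
                random_cloud.coordinates @ rotation.T + translation
            )
            fp = molecule_fingerprint(moved, "default6d")
            assert np.abs(fp.values - reference.values).max() < 1e-8

    def test_atom_permutation_invariance(self, random_cloud):
        reference = molecule_fingerprint(random_cloud, "default6d")
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(random_cloud))
        permuted = Molecule([random_cloud.atoms[i] for i in perm], name="perm")
        assert np.abs(molecule_fingerprint(permuted, "default6d").values
                      - reference.values).max() < 1e-10

    def test_reflection_invariance_without_chirality(self, chiral_tetrahedron):
        fp1 = molecule_fingerprint(chiral_tetrahedron, "3d")
        fp2 = molecule_fingerprint(reflect(chiral_tetrahedron), "3d")
        assert np.abs(fp1.values - fp2.values).max() < 1e-10

    def test_reflection_sensitivity_with_chirality(self, chiral_tetrahedron):
        fp1 = molecule_fingerprint(chiral_tetrahedron, "3d", chirality=True)
        fp2 = molecule_fingerprint(reflect(chiral_tetrahedron), "3d", chirality=True)
        assert similarity_score(fp1, fp2).score < 1.0

    def test_undetermined_axis_sign_is_immaterial(self, linear_symmetric):
        """Flipping a mirror-symmetric PC's sign leaves the fingerprint unchanged."""
        shape = build_hypershape(linear_symmetric, "3d")
        frame = build_frame(shape)
        assert frame.undetermined_axes
        fp = hsr_fingerprint(shape)
        for axis in frame.undetermined_axes:
            flipped = build_frame(shape)
            flipped.axes[:, axis] *= -1
            flipped.scores[:, axis] *= -1
            refs = reference_points(flipped)
            dists = distance_distributions(flipped.scores, refs)
            values = np.concatenate(
                [moment_triplet(row).as_tuple() for row in dists]
            )
            assert np.abs(values - fp.values).max() < 1e-10


def test_serialization_roundtrip(tmp_path, random_cloud, planar_cloud):
    import json

    import pandas as pd

    fps = [molecule_fingerprint(m, "3d") for m in (random_cloud, planar_cloud)]
    csv_path, json_path = tmp_path / "fps.csv", tmp_path / "fps.json"
    fingerprints_to_csv(fps, csv_path)
    fingerprints_to_json(fps, json_path)
    table = pd.read_csv(csv_path)
    assert list(table["name"]) == [fp.name for fp in fps]
    assert table.filter(like="v").shape == (2, 12)
    payload = json.loads(json_path.read_text())
    assert payload[0]["values"] == pytest.approx(list(fps[0].values))
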