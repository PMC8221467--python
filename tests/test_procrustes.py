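"""Superimposition primitives: centroid size, Kabsch rotation, GPA, distances."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import craniomix as cm
from craniomix.procrustes import (
    DegenerateConfigurationError,
    gpa,
    gpa_objective,
    optimal_rotation,
)
from conftest import random_similarity


def brute_force_centroid_size(coords):
    """Independent double-loop computation of the centroid-size definition."""
    k = len(coords)
    centroid = [sum(c[d] for c in coords) / k for d in range(3)]
    total = 0.0
    for c in coords:
        for d in range(3):
            total += (c[d] - centroid[d]) ** 2
    return total**0.5


class TestCentroidSize:
    def test_closed_form_square(self):
        coords = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]
        assert cm.centroid_size(np.array(coords, float)) == pytest.approx(2.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_homogeneous_in_scale(self, c):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((34, 3))
        assert cm.centroid_size(c * x) == pytest.approx(c * cm.centroid_size(x), rel=1e-9)

    def test_matches_brute_force(self, rng):
        x = rng.standard_normal((34, 3))
        assert cm.centroid_size(x) == pytest.approx(brute_force_centroid_size(x), rel=1e-12)

    def test_coincident_landmarks_give_zero_and_raise_downstream(self):
        flat = np.ones((5, 3))
        assert cm.centroid_size(flat) == 0.0
        with pytest.raises(DegenerateConfigurationError):
            cm.procrustes_distance(flat, np.eye(3, 3))


def rotation_about_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestOptimalRotation:
    def test_identity_for_equal_inputs(self, rng):
        A = rng.standard_normal((10, 3))
        A -= A.mean(0)
        np.testing.assert_allclose(optimal_rotation(A, A), np.eye(3), atol=1e-10)

    def test_recovers_constructed_rotation(self, rng):
        A = rng.standard_normal((10, 3))
        A -= A.mean(0)
        R = rotation_about_z(np.pi / 2)
        B = A @ R
        R_hat = optimal_rotation(A, B)
        np.testing.assert_allclose(A @ R_hat, B, atol=1e-10)

    def test_always_proper_rotation(self, rng):
        for _ in range(20):
            A = rng.standard_normal((8, 3))
            B = rng.standard_normal((8, 3))
            A -= A.mean(0)
            B -= B.mean(0)
            R = optimal_rotation(A, B)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-10)

    def test_beats_random_search(self, rng):
        """Kabsch objective is never worse than 1,000 random rotations."""
        from craniomix.simulate import _random_rotation

        A = rng.standard_normal((12, 3))
        B = rng.standard_normal((12, 3))
        A -= A.mean(0)
        B -= B.mean(0)
        best = np.sum((A @ optimal_rotation(A, B) - B) ** 2)
        rand = min(
            np.sum((A @ _random_rotation(rng) - B) ** 2) for _ in range(1000)
        )
        assert best <= rand + 1e-12

    def test_degenerate_rank_errors(self):
        line = np.outer(np.arange(5.0) - 2.0, [1.0, 0, 0])
        with pytest.raises(DegenerateConfigurationError):
            optimal_rotation(line, line)


class TestGPA:
    def test_identical_configs_align_exactly(self, rng):
        x = rng.standard_normal((10, 3))
        res = gpa(np.stack([x, x.copy()]))
        np.testing.assert_allclose(res.aligned[0], res.aligned[1], atol=1e-12)
        assert cm.procrustes_distance(res.aligned[0], res.aligned[1]) < 1e-10

    def test_unit_centroid_size_and_centered(self, study):
        _, dataset, _ = study
        res = gpa(dataset)
        for a in res.aligned:
            assert abs(cm.centroid_size(a) - 1.0) < 1e-9
            np.testing.assert_allclose(a.mean(0), 0.0, atol=1e-9)
        np.testing.assert_allclose(res.consensus, res.aligned.mean(0), atol=1e-12)

    def test_invariant_to_similarity_transforms(self, rng):
        """One shape under random similarity transforms aligns to a single point."""
        x = rng.standard_normal((15, 3))
        arr = np.stack([random_similarity(x, rng) for _ in range(8)])
        res = gpa(arr)
        for a in res.aligned:
            np.testing.assert_allclose(a, res.aligned[0], atol=1e-8)

    def test_gpa_output_invariant_to_input_transforms(self, rng):
        arr = rng.standard_normal((6, 10, 3))
        res1 = gpa(arr)
        transformed = np.stack([random_similarity(a, rng) for a in arr])
        res2 = gpa(transformed)
        R = optimal_rotation(res2.consensus, res1.consensus)
        np.testing.assert_allclose(res2.aligned @ R, res1.aligned, atol=1e-8)

    def test_objective_non_increasing_over_iterations(self, rng):
        arr = rng.standard_normal((10, 12, 3))
        objectives = []
        for iters in range(1, 8):
            res = gpa(arr, tol=0.0, max_iter=iters)
            objectives.append(gpa_objective(res))
        assert all(b <= a + 1e-12 for a, b in zip(objectives, objectives[1:]))

    def test_consensus_recovers_generating_mean(self, rng):
        """Noisy copies of one shape: consensus close to the aligned true mean."""
        true = rng.standard_normal((20, 3))
        true -= true.mean(0)
        true /= cm.centroid_size(true)
        sd = 0.002
        arr = np.stack([true + rng.standard_normal((20, 3)) * sd for _ in range(5)])
        res = gpa(arr)
        d = cm.procrustes_distance(res.consensus, true)
        # consensus error ~ sd*sqrt(3k/n); allow a generous factor
        assert d < 5 * sd * np.sqrt(3 * 20 / 5)

    def test_nonconvergence_flagged(self, rng):
        arr = rng.standard_normal((5, 8, 3))
        res = gpa(arr, tol=0.0, max_iter=3)
        assert not res.converged and res.iterations == 3


class TestProcrustesDistance:
    def test_zero_for_identical(self, rng):
        x = rng.standard_normal((10, 3))
        assert cm.procrustes_distance(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        for _ in range(10):
            a, b = rng.standard_normal((2, 10, 3))
            assert cm.procrustes_distance(a, b) == pytest.approx(
                cm.procrustes_distance(b, a), abs=1e-12
            )

    def test_similarity_invariant(self, rng):
        a, b = rng.standard_normal((2, 10, 3))
        d0 = cm.procrustes_distance(a, b)
        assert cm.procrustes_distance(random_similarity(a, rng), b) == pytest.approx(d0, abs=1e-9)

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(100):
            a, b, c = rng.standard_normal((3, 8, 3))
            dab = cm.procrustes_distance(a, b)
            dbc = cm.procrustes_distance(b, c)
            dac = cm.procrustes_distance(a, c)
            assert dac <= dab + dbc + 1e-10
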