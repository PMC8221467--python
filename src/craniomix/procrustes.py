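"""Generalized Procrustes analysis and Procrustes distances.

Superimposition removes translation (centering), size (each configuration
fixed at unit centroid size) and orientation (Kabsch rotations, proper
rotations only).  The iterative GPA aligns all configurations to a running
consensus until the consensus stabilises.  Reflections are never allowed
here; bilateral symmetry is handled by :mod:`craniomix.symmetry`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LandmarkConfiguration, ShapeDataset


class DegenerateConfigurationError(ValueError):
    """Raised when a configuration has no usable shape (coincident/collinear points)."""


def _coords_of(obj) -> np.ndarray:
    if isinstance(obj, LandmarkConfiguration):
        return obj.coords
    return np.asarray(obj, dtype=float)


def centroid_size(config) -> float:
    """Square root of summed squared landmark deviations from the centroid."""
    x = _coords_of(config)
    centered = x - x.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_scale(x: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size; error on degenerate input."""
    centered = x - x.mean(axis=0)
    size = np.sqrt(np.sum(centered**2))
    if size <= 0 or not np.isfinite(size):
        raise DegenerateConfigurationError("all landmarks coincident: centroid size is 0")
    return centered / size


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising ||A @ R - B||_F for centered A, B.

    The closed-form Kabsch solution: SVD of the cross-covariance A.T @ B,
    with the smallest singular direction sign-corrected so that reflections
    are excluded.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"expected matching k x 3 matrices, got {A.shape} and {B.shape}")
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    # rank < 2 input leaves the rotation underdetermined; it shows up as a
    # rank-deficient cross-covariance
    if s[0] <= 0 or s[1] <= 1e-12 * s[0]:
        raise DegenerateConfigurationError("rank < 2 configuration has no unique rotation")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


@dataclass
class GPAResult:
    """Aligned shapes (unit centroid size, common orientation) and their consensus."""

    aligned: np.ndarray  # (n, k, 3)
    consensus: np.ndarray  # (k, 3)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]


def gpa(dataset, tol: float = 1e-10, max_iter: int = 100) -> GPAResult:
    """Generalized Procrustes analysis of >= 2 configurations.

    Each configuration is centered and fixed at unit centroid size, then
    iteratively rotated onto the mean of the aligned set.  Iteration stops
    when the root-mean-square change of the consensus falls below ``tol``.
    """
    if isinstance(dataset, ShapeDataset):
        arr = dataset.coords_array()
    else:
        arr = np.asarray(dataset, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2 or arr.shape[2] != 3:
        raise ValueError(f"need an (n>=2, k, 3) array, got {arr.shape}")
    n = arr.shape[0]
    sizes = np.empty(n)
    aligned = np.empty_like(arr)
    for i in range(n):
        centered = arr[i] - arr[i].mean(axis=0)
        sizes[i] = np.sqrt(np.sum(centered**2))
        if sizes[i] <= 0:
            raise DegenerateConfigurationError(
                f"configuration {i} is degenerate (centroid size 0)"
            )
        aligned[i] = centered / sizes[i]

    consensus = aligned[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = aligned[i] @ optimal_rotation(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    return GPAResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(A, B) -> float:
    """Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, B is optimally
    rotated onto A, and the root summed squared coordinate difference is
    returned.  This is a pairwise (two-configuration) superimposition,
    independent of any joint GPA.
    """
    a = _center_scale(_coords_of(A))
    b = _center_scale(_coords_of(B))
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape[0]} vs {b.shape[0]}")
    R = optimal_rotation(b, a)
    return float(np.sqrt(np.sum((b @ R - a) ** 2)))


def gpa_objective(result: GPAResult) -> float:
    """Sum of squared distances of aligned configurations to the consensus."""
    return float(np.sum((result.aligned - result.consensus) ** 2))
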