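"""Ordination of Procrustes shape coordinates: PCA and canonical variates.

Procrustes coordinates are rank-deficient (superimposition and
symmetrization remove degrees of freedom), so CVA is computed inside the
non-null PCA subspace before eigen-solving the between/within problem —
the standard guard for p >> n shape data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg


@dataclass
class PCAResult:
    """Principal components of flattened (3k-vector) shape coordinates."""

    scores: np.ndarray  # (n, m)
    components: np.ndarray  # (m, p) orthonormal rows
    variance_fractions: np.ndarray  # (m,)
    mean_vector: np.ndarray  # (p,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.mean_vector + self.scores @ self.components


def _as_matrix(data) -> np.ndarray:
    """Accept a ShapeDataset, an (n,k,3) array, or an (n,p) matrix."""
    if hasattr(data, "coords_array"):
        data = data.coords_array()
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    return arr


def pca(data, rank_tol: float = 1e-9) -> PCAResult:
    """PCA by SVD of the centered data; m = numerical rank.

    Components with singular value below ``rank_tol`` times the largest are
    discarded, so the retained variance fractions sum to 1.
    """
    X = _as_matrix(data)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs n >= 3 specimens, got {n}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > rank_tol * (s[0] if s.size else 0.0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    # sign convention: largest-magnitude loading of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    var = s**2
    return PCAResult(
        scores=U * s,
        components=Vt,
        variance_fractions=var / var.sum(),
        mean_vector=mean,
    )


@dataclass
class CVAResult:
    """Canonical variates maximising between- over within-group variance."""

    cv_scores: np.ndarray  # (n, g-1)
    cv_variance_fractions: np.ndarray  # (g-1,)
    group_means_cv: np.ndarray  # (g, g-1)
    group_labels: np.ndarray  # (g,) label of each row of group_means_cv
    eigenvalues: np.ndarray  # (g-1,)

    @property
    def n_variates(self) -> int:
        return self.cv_scores.shape[1]


def _scatter_matrices(X: np.ndarray, labels: np.ndarray):
    """Within (pooled, unscaled SSCP) and between SSCP matrices."""
    groups = pd_unique(labels)
    grand = X.mean(axis=0)
    p = X.shape[1]
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for g in groups:
        Xg = X[labels == g]
        mg = Xg.mean(axis=0)
        d = Xg - mg
        W += d.T @ d
        dm = (mg - grand)[:, None]
        B += Xg.shape[0] * (dm @ dm.T)
    return W, B, groups


def pd_unique(labels: np.ndarray) -> np.ndarray:
    """Unique labels in order of first appearance."""
    labels = np.asarray(labels)
    _, idx = np.unique(labels, return_index=True)
    return labels[np.sort(idx)]


def cva(features, labels, rank_tol: float = 1e-9) -> CVAResult:
    """Canonical variates analysis of n x m features against group labels.

    The features are first projected onto their non-null PCA subspace
    (singular value > rank_tol x largest), then the symmetric-definite
    generalized eigenproblem B v = lambda W v is solved with the pooled
    within-group covariance W (divisor n - g).  Scores have unit pooled
    within-group variance on each canonical axis.
    """
    X = _as_matrix(features)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on n")
    groups = pd_unique(labels)
    counts = np.array([(labels == g).sum() for g in groups])
    if (counts >= 2).sum() < 2:
        raise ValueError("CVA needs >= 2 groups with >= 2 members each")
    if np.any(counts < 2):
        bad = [str(g) for g, c in zip(groups, counts) if c < 2]
        raise ValueError(f"groups with < 2 members: {bad}")
    n, g = X.shape[0], len(groups)

    # rank guard: work inside the non-null PCA subspace
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > rank_tol * (s[0] if s.size else 0.0)
    basis = Vt[keep]  # (r, m)
    Z = Xc @ basis.T  # (n, r)

    W, B, _ = _scatter_matrices(Z, labels)
    W_cov = W / (n - g)
    try:
        evals, evecs = scipy.linalg.eigh(B, W_cov)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "within-group scatter singular even after the rank guard; "
            "reduce dimensionality (e.g. retain fewer PCs) before CVA"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_cv = min(g - 1, Z.shape[1])
    evals = np.clip(evals[order][:n_cv], 0.0, None)
    A = evecs[:, order][:, :n_cv]  # columns: canonical axes in Z-space

    # sign convention: largest-magnitude loading (in the input feature space) positive
    loadings = basis.T @ A  # (m, n_cv)
    for j in range(n_cv):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            A[:, j] *= -1.0

    scores = Z @ A
    group_means = np.stack([scores[labels == gl].mean(axis=0) for gl in groups])
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return CVAResult(
        cv_scores=scores,
        cv_variance_fractions=fractions,
        group_means_cv=group_means,
        group_labels=groups,
        eigenvalues=evals,
    )
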