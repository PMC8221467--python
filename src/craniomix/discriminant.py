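"""Pooled-covariance Gaussian linear discriminant core.

Shared by the stepwise PC-reduction cross-validation (multi-group) and the
two-source ancestry attribution.  Classes share one pooled covariance; the
posterior for class c at x is softmax over
``-(x - mu_c)' Sigma^-1 (x - mu_c)/2 + log prior_c``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .ordination import pd_unique


class SingularCovarianceError(ValueError):
    """Pooled within-class covariance is singular; reduce dimensionality first."""


def pooled_fit(X: np.ndarray, labels: np.ndarray):
    """Class means and pooled within-class covariance (divisor n - g)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = pd_unique(labels)
    n, m = X.shape
    g = len(classes)
    if n - g < 1:
        raise ValueError("not enough observations to pool a covariance")
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    S = np.zeros((m, m))
    for i, c in enumerate(classes):
        d = X[labels == c] - means[i]
        S += d.T @ d
    cov = S / (n - g)
    return classes, means, cov


def log_posteriors(
    X: np.ndarray, means: np.ndarray, cov: np.ndarray, priors: np.ndarray
) -> np.ndarray:
    """Log posterior of each class for each row of X (shared covariance)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    try:
        cho = scipy.linalg.cho_factor(cov)
    except scipy.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            "pooled covariance is singular; apply PC reduction before the LDA"
        ) from exc
    scores = np.empty((X.shape[0], means.shape[0]))
    for i, mu in enumerate(means):
        d = X - mu
        sol = scipy.linalg.cho_solve(cho, d.T)
        scores[:, i] = -0.5 * np.einsum("ij,ji->i", d, sol) + np.log(priors[i])
    scores -= scores.max(axis=1, keepdims=True)
    return scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))


def posteriors(X, means, cov, priors) -> np.ndarray:
    return np.exp(log_posteriors(X, means, cov, priors))


def loo_accuracy(X: np.ndarray, labels: np.ndarray, priors: str = "uniform") -> float:
    """Leave-one-out correct-classification fraction of the pooled-covariance LDA.

    Deterministic (no randomness): each specimen is classified by the model
    refitted on the remaining n - 1.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        cls_f, means, cov = pooled_fit(X[mask], labels[mask])
        if priors == "uniform":
            pri = np.full(len(cls_f), 1.0 / len(cls_f))
        else:
            lab_f = labels[mask]
            pri = np.array([(lab_f == c).mean() for c in cls_f])
        lp = log_posteriors(X[i : i + 1], means, cov, pri)
        if cls_f[np.argmax(lp[0])] == labels[i]:
            correct += 1
    return correct / n
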