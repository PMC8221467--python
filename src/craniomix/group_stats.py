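"""Group comparison on retained PCs: stepwise PC reduction and Wilks MANOVA.

The stepwise reduction (Baylac-Friess style) adds variance-ordered PCs one
at a time, scoring each prefix by leave-one-out cross-validated LDA
classification, and stops as soon as the percentage drops below its
running maximum — guarding a p >> n shape analysis against noise
dimensions.  MANOVA uses Wilks' lambda with Rao's F approximation and the
multivariate partial eta squared ``1 - lambda**(1/s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from . import discriminant
from .ordination import PCAResult, _as_matrix, _scatter_matrices, pd_unique


@dataclass
class PCReductionResult:
    """Outcome of the stepwise cross-validated PC selection."""

    retained_indices: list[int]
    cv_curve: list[tuple[int, float]]  # (n_pcs, LOOCV correct %)
    retained_variance_fraction: float

    @property
    def n_retained(self) -> int:
        return len(self.retained_indices)


def baylac_friess_reduce(
    scores, labels, variance_fractions=None, max_pcs: int | None = None
) -> PCReductionResult:
    """Stepwise selection of a variance-ordered PC prefix by LOOCV LDA.

    Parameters
    ----------
    scores : PCAResult or (n, m) score matrix, columns in variance order.
    labels : group labels used by the leave-one-out LDA (all groups enter
        the cross-validation).
    variance_fractions : per-PC variance fractions; taken from the
        PCAResult when one is supplied.

    For j = 1, 2, ... the leave-one-out correct-classification percentage
    of an LDA on the first j PCs is computed; the search ends at the first
    strict drop below the running maximum (ties extend the search) and the
    shortest prefix achieving the maximum is retained.
    """
    if isinstance(scores, PCAResult):
        variance_fractions = scores.variance_fractions
        X = scores.scores
    else:
        X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(pd_unique(labels)) < 2:
        raise ValueError("PC reduction needs >= 2 groups")
    m = X.shape[1]
    if m < 2:
        raise ValueError("need at least 2 PCs to run the stepwise reduction")
    if max_pcs is not None:
        m = min(m, max_pcs)
    # LDA needs an invertible pooled covariance: j must stay below n - g
    m = min(m, X.shape[0] - len(pd_unique(labels)) - 1)

    curve: list[tuple[int, float]] = []
    best_pct = -np.inf
    best_j = 0
    for j in range(1, m + 1):
        pct = 100.0 * discriminant.loo_accuracy(X[:, :j], labels)
        curve.append((j, pct))
        if pct > best_pct:
            best_pct = pct
            best_j = j
        elif pct < best_pct:
            break  # percentage began to drop
    retained = list(range(best_j))
    var_frac = (
        float(np.sum(variance_fractions[:best_j]))
        if variance_fractions is not None
        else float("nan")
    )
    return PCReductionResult(
        retained_indices=retained, cv_curve=curve, retained_variance_fraction=var_frac
    )


@dataclass
class WilksResult:
    """Wilks' lambda MANOVA with Rao's F approximation."""

    lambda_: float
    F: float
    df1: int
    df2: float
    p: float
    partial_eta_sq: float
    groups: tuple = field(default_factory=tuple)

    def __iter__(self):  # convenient unpacking in tables
        yield from (self.lambda_, self.F, self.df1, self.df2, self.p, self.partial_eta_sq)


def wilks_manova(features, labels) -> WilksResult:
    """One-way MANOVA: lambda = det(W) / det(W + B), F via Rao's approximation."""
    X = _as_matrix(features)
    labels = np.asarray(labels)
    groups = pd_unique(labels)
    g = len(groups)
    if g < 2:
        raise ValueError("MANOVA needs >= 2 groups")
    n, p = X.shape
    if n - g <= p:
        warnings.warn(
            f"n - g = {n - g} <= {p} features: within-group scatter is (near) singular",
            stacklevel=2,
        )
    W, B, _ = _scatter_matrices(X, labels)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        raise ValueError("singular scatter matrix: cannot form Wilks' lambda")
    lam = float(np.exp(logdet_w - logdet_t))
    lam = min(lam, 1.0)

    q = g - 1  # hypothesis df
    if p**2 + q**2 - 5 > 0:
        s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
    else:
        s = 1.0
    df1 = p * q
    mr = (n - 1) - (p + q + 1) / 2.0
    df2 = mr * s - (p * q) / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    if lam_s <= 0:
        F = np.inf
    else:
        F = ((1.0 - lam_s) / lam_s) * (df2 / df1)
    F = max(F, 0.0)
    pval = float(scipy.stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = 1.0 - lam_s
    return WilksResult(
        lambda_=lam,
        F=float(F),
        df1=int(df1),
        df2=float(df2),
        p=pval,
        partial_eta_sq=float(eta),
        groups=tuple(str(x) for x in groups),
    )


def pairwise_manova(
    features,
    labels,
    pairs: list[tuple] | None = None,
    correction: str | None = None,
) -> list[WilksResult]:
    """Two-group MANOVAs for each requested pair on the same feature space.

    ``correction`` may be 'bonferroni' or 'holm' to adjust the p values
    across the pairs; by default none is applied.
    """
    X = _as_matrix(features)
    labels = np.asarray(labels)
    present = set(str(x) for x in pd_unique(labels))
    if pairs is None:
        uniq = list(pd_unique(labels))
        pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]
    results = []
    for a, b in pairs:
        if str(a) not in present or str(b) not in present:
            raise ValueError(f"unknown group in pair ({a}, {b})")
        mask = (labels == a) | (labels == b)
        results.append(wilks_manova(X[mask], labels[mask]))
    if correction is not None:
        ps = np.array([r.p for r in results])
        if correction == "bonferroni":
            adj = np.minimum(ps * len(ps), 1.0)
        elif correction == "holm":
            order = np.argsort(ps)
            adj = np.empty_like(ps)
            running = 0.0
            for rank, i in enumerate(order):
                running = max(running, ps[i] * (len(ps) - rank))
                adj[i] = min(running, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        for r, a in zip(results, adj):
            r.p = float(a)
    return results
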