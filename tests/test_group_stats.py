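"""Stepwise PC reduction and Wilks-lambda MANOVA."""

import numpy as np
import pytest
import scipy.stats

import craniomix as cm
from craniomix import group_stats
from craniomix.group_stats import baylac_friess_reduce, pairwise_manova, wilks_manova
from craniomix.ordination import _scatter_matrices


class TestReduction:
    def test_stops_at_first_drop(self, monkeypatch):
        """cv curve 60, 70, 65 -> first 2 PCs retained and the scan stops."""
        pcts = iter([60.0, 70.0, 65.0, 99.0])

        monkeypatch.setattr(
            group_stats.discriminant, "loo_accuracy", lambda X, labels: next(pcts) / 100.0
        )
        X = np.random.default_rng(0).standard_normal((40, 10))
        labels = np.repeat(["a", "b"], 20)
        res = baylac_friess_reduce(X, labels)
        assert res.retained_indices == [0, 1]
        assert [p for _, p in res.cv_curve] == [60.0, 70.0, 65.0]

    def test_ties_extend_the_search(self, monkeypatch):
        pcts = iter([60.0, 70.0, 70.0, 80.0, 75.0])
        monkeypatch.setattr(
            group_stats.discriminant, "loo_accuracy", lambda X, labels: next(pcts) / 100.0
        )
        X = np.random.default_rng(0).standard_normal((40, 5))
        labels = np.repeat(["a", "b"], 20)
        res = baylac_friess_reduce(X, labels)
        assert res.retained_indices == [0, 1, 2, 3]

    def test_monotone_curve_retains_all(self, monkeypatch):
        monkeypatch.setattr(
            group_stats.discriminant,
            "loo_accuracy",
            lambda X, labels: 0.5 + 0.01 * X.shape[1],
        )
        X = np.random.default_rng(0).standard_normal((40, 6))
        labels = np.repeat(["a", "b"], 20)
        res = baylac_friess_reduce(X, labels)
        assert res.retained_indices == list(range(6))

    def test_deterministic_and_bounded(self, rng):
        X = rng.standard_normal((30, 8))
        labels = np.repeat(["a", "b", "c"], 10)
        X[labels == "b", 0] += 2.0
        r1 = baylac_friess_reduce(X, labels)
        r2 = baylac_friess_reduce(X, labels)
        assert r1.cv_curve == r2.cv_curve
        assert 1 <= r1.n_retained <= 8
        assert all(0.0 <= p <= 100.0 for _, p in r1.cv_curve)

    def test_variance_fraction_from_pca_result(self, small_sources):
        params, dataset, _ = small_sources
        sym = cm.symmetrize(dataset, params.scheme)
        p = cm.pca(sym)
        res = baylac_friess_reduce(p, sym.groups())
        expected = float(np.sum(p.variance_fractions[: res.n_retained]))
        assert res.retained_variance_fraction == pytest.approx(expected)

    def test_needs_two_groups(self, rng):
        with pytest.raises(ValueError, match="2 groups"):
            baylac_friess_reduce(rng.standard_normal((10, 4)), np.repeat(["a"], 10))


class TestWilksManova:
    def test_identical_group_means_give_lambda_one(self):
        base = np.random.default_rng(3).standard_normal((4, 3))
        X = np.vstack([base, base])  # two groups with the same sample mean
        labels = np.repeat(["a", "b"], 4)
        r = wilks_manova(X, labels)
        assert r.lambda_ == pytest.approx(1.0, abs=1e-12)
        assert r.F == pytest.approx(0.0, abs=1e-9)
        assert r.partial_eta_sq == pytest.approx(0.0, abs=1e-9)

    def test_one_dimensional_reduces_to_anova(self, rng):
        groups = [rng.standard_normal(15) + d for d in (0.0, 0.6, -0.3)]
        X = np.concatenate(groups)[:, None]
        labels = np.repeat(["a", "b", "c"], 15)
        r = wilks_manova(X, labels)
        F, p = scipy.stats.f_oneway(*groups)
        assert r.F == pytest.approx(F, rel=1e-10)
        assert r.p == pytest.approx(p, rel=1e-9)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        sst = ((X - X.mean()) ** 2).sum()
        assert r.lambda_ == pytest.approx(ssw / sst, rel=1e-12)

    def test_matches_determinant_ratio_oracle(self, rng):
        n, p, g = 30, 4, 3
        X = rng.standard_normal((n, p))
        labels = np.repeat(["a", "b", "c"], 10)
        X[labels == "c"] += 0.7
        r = wilks_manova(X, labels)
        W, B, _ = _scatter_matrices(X, labels)
        lam = np.linalg.det(W) / np.linalg.det(W + B)
        assert r.lambda_ == pytest.approx(lam, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        import pandas as pd
        from statsmodels.multivariate.manova import MANOVA

        n, p = 45, 3
        X = rng.standard_normal((n, p))
        labels = np.repeat(["a", "b", "c"], 15)
        X[labels == "b"] += 0.5
        r = wilks_manova(X, labels)
        df = pd.DataFrame(X, columns=["x0", "x1", "x2"])
        df["grp"] = labels
        tbl = MANOVA.from_formula("x0 + x1 + x2 ~ grp", data=df).mv_test()
        row = tbl.results["grp"]["stat"].loc["Wilks' lambda"]
        assert r.lambda_ == pytest.approx(float(row["Value"]), abs=1e-10)
        assert r.F == pytest.approx(float(row["F Value"]), rel=1e-8)
        assert r.p == pytest.approx(float(row["Pr > F"]), abs=1e-10)

    def test_partial_eta_sq_definition(self, rng):
        X = rng.standard_normal((40, 4))
        labels = np.repeat(["a", "b"], 20)
        X[labels == "b"] += 0.4
        r = wilks_manova(X, labels)
        # for g=2 Rao's exponent s=1, so eta_p^2 = 1 - lambda
        assert r.partial_eta_sq == pytest.approx(1.0 - r.lambda_, abs=1e-12)

    def test_warns_when_underdetermined(self, rng):
        X = rng.standard_normal((8, 6))
        labels = np.repeat(["a", "b"], 4)
        with pytest.warns(UserWarning, match="singular"):
            wilks_manova(X, labels)


class TestPairwise:
    def test_all_six_pairs_in_requested_order(self, rng):
        X = rng.standard_normal((40, 3))
        labels = np.repeat(["a", "b", "c", "d"], 10)
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        res = pairwise_manova(X, labels, pairs)
        assert len(res) == 6
        assert [r.groups for r in res] == [p for p in pairs]

    def test_unknown_group_errors(self, rng):
        X = rng.standard_normal((20, 3))
        labels = np.repeat(["a", "b"], 10)
        with pytest.raises(ValueError, match="unknown group"):
            pairwise_manova(X, labels, [("a", "z")])

    def test_null_type_one_error_calibrated(self, rng):
        """Same distribution relabelled half/half: p uniform enough that the
        rejection rate at alpha=0.05 stays inside binomial bounds (500 reps)."""
        reps, alpha, m = 500, 0.05, 4
        hits = 0
        for _ in range(reps):
            X = rng.standard_normal((40, m))
            labels = np.repeat(["a", "b"], 20)
            if pairwise_manova(X, labels, [("a", "b")])[0].p < alpha:
                hits += 1
        lo, hi = scipy.stats.binom.interval(0.99, reps, alpha)
        assert lo <= hits <= hi

    def test_lambda_near_one_for_large_null_groups(self, rng):
        X = rng.standard_normal((400, 3))
        labels = np.repeat(["a", "b"], 200)
        r = pairwise_manova(X, labels, [("a", "b")])[0]
        assert r.lambda_ > 0.95

    def test_bonferroni_correction_optional(self, rng):
        X = rng.standard_normal((30, 2))
        labels = np.repeat(["a", "b", "c"], 10)
        raw = pairwise_manova(X, labels)
        adj = pairwise_manova(X, labels, correction="bonferroni")
        for r0, r1 in zip(raw, adj):
            assert r1.p == pytest.approx(min(1.0, r0.p * 3), abs=1e-12)
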