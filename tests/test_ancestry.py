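"""Two-source LDA attribution: posteriors, threshold rule, group summaries."""

import numpy as np
import pytest

import craniomix as cm
from craniomix.ancestry import (
    AttributionLabel,
    IndividualAttribution,
    attribute,
    attribute_individuals,
    fit_lda,
    predict_posteriors,
    summarize,
)
from craniomix.discriminant import SingularCovarianceError

DAN, BRIT = "DANISH", "PREMED_BRITISH"


def two_clouds(rng, delta, n=50, m=3):
    """Two Gaussian clouds separated by Mahalanobis distance delta along axis 0."""
    X = rng.standard_normal((2 * n, m))
    labels = np.array([DAN] * n + [BRIT] * n)
    X[labels == DAN, 0] += delta
    return X, labels


class TestFitLDA:
    def test_well_separated_sources_classify_accurately(self, rng):
        X, labels = two_clouds(rng, delta=6.0)
        model = fit_lda(X, labels)
        assert model.loocv_accuracy >= 0.95

    def test_identical_classes_are_at_chance(self, rng):
        X, labels = two_clouds(rng, delta=0.0, n=100)
        model = fit_lda(X, labels)
        assert abs(model.loocv_accuracy - 0.5) < 0.15  # binomial noise at n=200

    def test_one_feature_boundary_is_midpoint(self):
        X = np.array([[0.0], [1.0], [4.0], [5.0]])
        labels = np.array([DAN, DAN, BRIT, BRIT])
        model = fit_lda(X, labels)
        mid = predict_posteriors(model, [[2.5]])[0]
        np.testing.assert_allclose(mid, [0.5, 0.5], atol=1e-12)
        assert predict_posteriors(model, [[2.4]])[0][0] > 0.5
        assert predict_posteriors(model, [[2.6]])[0][1] > 0.5

    def test_rejects_wrong_class_structure(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(ValueError, match="expected exactly"):
            fit_lda(X, np.array([DAN] * 3 + ["OTHER"] * 3))

    def test_singular_covariance_instructs_reduction(self, rng):
        X = rng.standard_normal((6, 10))  # n << m
        labels = np.array([DAN] * 3 + [BRIT] * 3)
        with pytest.warns(UserWarning):
            with pytest.raises(SingularCovarianceError, match="PC reduction"):
                fit_lda(X, labels)


class TestPosteriors:
    def test_pairs_sum_to_one(self, rng):
        X, labels = two_clouds(rng, delta=2.0)
        model = fit_lda(X, labels)
        post = predict_posteriors(model, rng.standard_normal((20, 3)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_point_at_class_mean_of_distant_classes(self, rng):
        X, labels = two_clouds(rng, delta=10.0, n=100)
        model = fit_lda(X, labels)
        post = predict_posteriors(model, model.class_means)
        assert post[0, 0] > 0.99  # Danish mean -> Danish posterior
        assert post[1, 1] > 0.99

    def test_invariant_under_linear_transforms(self, rng):
        """Posteriors unchanged by any invertible linear map of train+test features."""
        X, labels = two_clouds(rng, delta=2.0, n=30, m=4)
        T = rng.standard_normal((10, 4))
        base = predict_posteriors(fit_lda(X, labels), T)
        for _ in range(20):
            A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
            b = rng.standard_normal(4)
            post = predict_posteriors(fit_lda(X @ A + b, labels), T @ A + b)
            np.testing.assert_allclose(post, base, atol=1e-7)

    def test_dimension_mismatch_errors(self, rng):
        X, labels = two_clouds(rng, delta=1.0)
        model = fit_lda(X, labels)
        with pytest.raises(ValueError, match="dimension"):
            predict_posteriors(model, rng.standard_normal((5, 7)))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, labels = two_clouds(rng, delta=1.5, m=5)
        model = fit_lda(X, labels)
        ours = predict_posteriors(model, X)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, labels)
        # sklearn orders classes alphabetically: DANISH, PREMED_BRITISH
        np.testing.assert_allclose(ours, sk.predict_proba(X), atol=1e-8)


class TestThresholdRule:
    @pytest.mark.parametrize(
        "pair,expected",
        [
            ((0.63, 0.37), AttributionLabel.DANISH),
            ((0.55, 0.45), AttributionLabel.DANISH),  # >= 55% attributes
            ((0.54, 0.46), AttributionLabel.UNATTRIBUTABLE),  # both <= 54%
            ((0.46, 0.54), AttributionLabel.UNATTRIBUTABLE),
            ((0.30, 0.70), AttributionLabel.PREMED_BRITISH),
        ],
    )
    def test_rule(self, pair, expected):
        assert attribute(np.array(pair)) is expected

    def test_posteriors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            attribute(np.array([0.7, 0.7]))


class TestSummarize:
    def test_counts_to_percentages(self):
        """17 Danish, 7 British, 3 unattributable of 27 -> 63/26/11."""
        indiv = (
            [IndividualAttribution(f"d{i}", 0.8, 0.2, AttributionLabel.DANISH) for i in range(17)]
            + [IndividualAttribution(f"b{i}", 0.2, 0.8, AttributionLabel.PREMED_BRITISH) for i in range(7)]
            + [IndividualAttribution(f"u{i}", 0.5, 0.5, AttributionLabel.UNATTRIBUTABLE) for i in range(3)]
        )
        rep = summarize(indiv, "EARLY_AS")
        assert round(rep.pct_danish) == 63
        assert round(rep.pct_british) == 26
        assert round(rep.pct_unknown) == 11
        assert rep.pct_danish + rep.pct_british + rep.pct_unknown == pytest.approx(100.0)

    def test_all_unattributable(self):
        indiv = [
            IndividualAttribution(f"u{i}", 0.5, 0.5, AttributionLabel.UNATTRIBUTABLE)
            for i in range(5)
        ]
        rep = summarize(indiv)
        assert (rep.pct_danish, rep.pct_british, rep.pct_unknown) == (0.0, 0.0, 100.0)

    def test_mean_posteriors_are_arithmetic_means(self):
        indiv = [
            IndividualAttribution("a", 0.9, 0.1, AttributionLabel.DANISH),
            IndividualAttribution("b", 0.5, 0.5, AttributionLabel.UNATTRIBUTABLE),
        ]
        rep = summarize(indiv)
        assert rep.mean_posterior_danish == pytest.approx(0.7)
        assert rep.mean_posterior_british == pytest.approx(0.3)

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="empty"):
            summarize([])

    def test_attribute_individuals_end_to_end(self, rng):
        X, labels = two_clouds(rng, delta=4.0)
        model = fit_lda(X, labels)
        targets = rng.standard_normal((10, 3))
        targets[:5, 0] += 4.0  # Danish-like
        out = attribute_individuals(model, targets, [f"t{i}" for i in range(10)])
        assert len(out) == 10
        assert sum(a.label is AttributionLabel.DANISH for a in out[:5]) >= 4
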