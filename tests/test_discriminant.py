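"""Gaussian discriminant model: densities, scores, prediction, grids.

Independent oracles: scipy.stats.multivariate_normal for densities and
scikit-learn's discriminant-analysis estimators for end-to-end
predictions.
"""

import json

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from velquant.discriminant import (
    GaussianDiscriminant,
    GaussianDiscriminantResults,
    fit_gaussian_classes,
    gaussian_density,
    lda_score,
    qda_score,
)
from velquant.exceptions import SingularCovarianceError
from velquant.synthetic import ClassGaussianSpec, gen_feature_dataset


def random_results(rng, K=3, k=2):
    """A random positive-definite fitted-model stand-in."""
    means = rng.normal(0, 2, size=(K, k))
    covs = np.empty((K, k, k))
    for i in range(K):
        a = rng.normal(size=(k, k))
        covs[i] = a @ a.T + 0.3 * np.eye(k)
    weights = rng.uniform(0.5, 2.0, size=K)
    counts = np.full(K, 100)
    pooled = covs.mean(axis=0)
    return GaussianDiscriminantResults(
        model=None,
        means=means,
        covariances=covs,
        pooled_covariance=pooled,
        priors=weights / weights.sum(),
        counts=counts,
        regularization=0.0,
        class_order=tuple(f"C{i}" for i in range(K)),
    )


class TestGaussianDensity:
    def test_at_mean_identity_covariance(self):
        assert gaussian_density(
            np.zeros(2), np.zeros(2), np.eye(2)
        ) == pytest.approx(1.0 / (2 * np.pi))

    def test_univariate_standard_normal(self):
        val = gaussian_density(np.array([1.0]), np.array([0.0]), np.array([[1.0]]))
        assert val == pytest.approx(np.exp(-0.5) / np.sqrt(2 * np.pi))

    def test_integrates_to_one(self):
        cov = np.array([[1.0, 0.3], [0.3, 2.0]])
        xs = np.linspace(-6, 6, 401)
        xx, yy = np.meshgrid(xs, xs)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        dens = gaussian_density(pts, np.zeros(2), cov).reshape(xx.shape)
        integral = np.trapezoid(np.trapezoid(dens, xs, axis=1), xs)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_matches_scipy(self, rng):
        mean = rng.normal(size=3)
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        x = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            gaussian_density(x, mean, cov),
            multivariate_normal(mean, cov).pdf(x),
            rtol=1e-10,
        )

    def test_singular_covariance_raises(self):
        with pytest.raises(SingularCovarianceError):
            gaussian_density(np.zeros(2), np.zeros(2), np.zeros((2, 2)))


class TestFit:
    def test_repeated_point_class_is_singular(self):
        feats = np.array([[1.0, 1.0]] * 3 + [[2.0, 2.0]] * 3)
        labels = ["a"] * 3 + ["b"] * 3
        with pytest.raises(SingularCovarianceError):
            GaussianDiscriminant(feats, labels).fit(regularization=0.0)
        # ridge rescues the degenerate fit
        res = GaussianDiscriminant(feats, labels).fit(regularization=1e-3)
        assert res.predict(np.array([1.0, 1.0])) == "a"

    def test_class_with_single_sample_rejected(self):
        feats = np.array([[0.0, 0.0], [1.0, 1.0], [1.1, 0.9]])
        with pytest.raises(ValueError):
            GaussianDiscriminant(feats, ["a", "b", "b"]).fit()

    def test_estimators_and_priors(self, rng):
        n = (40, 34, 38)
        feats, labels = [], []
        for label, count, center in zip(("N", "M", "PM"), n, (0.0, 3.0, 6.0)):
            feats.append(rng.normal(center, 1.0, size=(count, 2)))
            labels += [label] * count
        res = GaussianDiscriminant(np.vstack(feats), labels).fit()
        np.testing.assert_allclose(res.priors, np.array(n) / 112)
        np.testing.assert_allclose(res.means[0], feats[0].mean(axis=0))
        np.testing.assert_allclose(
            res.covariances[1], np.cov(feats[1], rowvar=False, ddof=1)
        )
        # pooled covariance is the (n_c - 1)-weighted average
        expected = sum(
            (c - 1) * np.cov(f, rowvar=False, ddof=1) for c, f in zip(n, feats)
        ) / sum(c - 1 for c in n)
        np.testing.assert_allclose(res.pooled_covariance, expected)

    def test_parameter_recovery_from_generator(self):
        spec = ClassGaussianSpec("N", (1.1, 0.4), ((0.04, 0.02), (0.02, 0.09)))
        other = ClassGaussianSpec("M", (0.6, 0.8), ((0.05, -0.01), (-0.01, 0.03)))
        n = 10_000
        df = gen_feature_dataset([spec, other], n, seed=77)
        res = fit_gaussian_classes(df)
        for i, s in enumerate((spec, other)):
            se = np.sqrt(np.diag(s.covariance_array) / n)
            assert np.all(np.abs(res.means[i] - s.mean_array) < 3 * se)
            rel = np.abs(res.covariances[i] - s.covariance_array) / np.abs(
                s.covariance_array
            )
            assert rel.max() < 0.10

    def test_canonical_class_order(self):
        feats = np.zeros((6, 2)) + np.arange(6)[:, None]
        res = GaussianDiscriminant(feats, ["PM", "M", "N", "PM", "M", "N"]).fit(
            regularization=1e-6
        )
        assert res.classes == ("N", "M", "PM")


class TestScores:
    def test_qda_score_at_mean_equal_priors(self):
        res = GaussianDiscriminantResults(
            model=None,
            means=np.array([[0.0, 0.0], [3.0, 0.0]]),
            covariances=np.stack([np.eye(2)] * 2),
            pooled_covariance=np.eye(2),
            priors=np.array([0.5, 0.5]),
            counts=np.array([10, 10]),
            regularization=0.0,
            class_order=("a", "b"),
        )
        assert qda_score(np.zeros(2), res, 0) == pytest.approx(np.log(0.5))

    def test_qda_score_is_log_posterior_up_to_constant(self, rng):
        """delta_n(x) - log(pi_n f_n(x)) must be the same constant
        (k/2 log 2 pi) for every class, with f_n from scipy."""
        res = random_results(rng)
        x = rng.normal(size=(50, 2))
        sc = res.qda_scores(x)
        for i in range(3):
            logpf = np.log(res.priors[i]) + multivariate_normal(
                res.means[i], res.covariances[i]
            ).logpdf(x)
            np.testing.assert_allclose(
                sc[:, i] - logpf, np.log(2 * np.pi), rtol=1e-10
            )

    def test_lda_midpoint_is_boundary(self):
        res = GaussianDiscriminantResults(
            model=None,
            means=np.array([[0.0, 0.0], [4.0, 0.0]]),
            covariances=np.stack([np.eye(2)] * 2),
            pooled_covariance=np.eye(2),
            priors=np.array([0.5, 0.5]),
            counts=np.array([10, 10]),
            regularization=0.0,
            class_order=("a", "b"),
        )
        mid = res.lda_scores(np.array([2.0, 0.0]))
        assert mid[0] == pytest.approx(mid[1])
        closer = res.lda_scores(np.array([1.0, 0.0]))
        assert closer[0] > closer[1]
        # tie goes to the lowest class index
        assert res.predict(np.array([2.0, 0.0]), mode="lda") == "a"

    def test_lda_argmax_matches_pooled_density_oracle(self, rng):
        res = random_results(rng)
        x = rng.normal(0, 2, size=(1000, 2))
        ours = res.lda_scores(x).argmax(axis=1)
        oracle = np.column_stack(
            [
                np.log(res.priors[i])
                + multivariate_normal(res.means[i], res.pooled_covariance).logpdf(x)
                for i in range(3)
            ]
        ).argmax(axis=1)
        np.testing.assert_array_equal(ours, oracle)

    def test_equal_covariances_collapse_qda_to_lda(self, rng):
        res = random_results(rng).with_pooled_covariances()
        x = rng.normal(0, 2, size=(200, 2))
        dq = res.qda_scores(x)
        dl = res.lda_scores(x)
        # score differences between classes agree exactly
        np.testing.assert_allclose(
            dq - dq[:, :1], dl - dl[:, :1], atol=1e-10
        )
        assert lda_score(x[0], res, 1) - lda_score(x[0], res, 0) == pytest.approx(
            qda_score(x[0], res, 1) - qda_score(x[0], res, 0)
        )


class TestPredictPosterior:
    def test_means_predicted_to_own_class(self, well_separated_specs):
        df = gen_feature_dataset(well_separated_specs, 200, seed=2)
        res = fit_gaussian_classes(df)
        for spec in well_separated_specs:
            for mode in ("lda", "qda"):
                assert res.predict(spec.mean_array, mode=mode) == spec.class_label

    def test_posterior_sums_to_one_and_matches_predict(self, rng):
        res = random_results(rng)
        x = rng.normal(0, 2, size=(300, 2))
        for mode in ("lda", "qda"):
            post = res.posterior(x, mode=mode)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_array_equal(
                np.asarray(res.classes, dtype=object)[post.argmax(axis=1)],
                res.predict(x, mode=mode),
            )

    def test_symmetric_midpoint_posterior_half(self):
        res = GaussianDiscriminantResults(
            model=None,
            means=np.array([[0.0, 0.0], [4.0, 0.0]]),
            covariances=np.stack([np.eye(2)] * 2),
            pooled_covariance=np.eye(2),
            priors=np.array([0.5, 0.5]),
            counts=np.array([10, 10]),
            regularization=0.0,
            class_order=("a", "b"),
        )
        np.testing.assert_allclose(
            res.posterior(np.array([2.0, 0.0]), mode="qda"), [0.5, 0.5]
        )
        far = res.posterior(np.array([-20.0, 0.0]), mode="qda")
        assert far[0] > 1 - 1e-12

    def test_qda_beats_lda_under_heteroscedasticity(self, heteroscedastic_specs):
        """Monte-Carlo: with overlapping means and strongly unequal
        covariances the quadratic rule should win on average."""
        wins = 0
        for seed in range(20):
            train = gen_feature_dataset(heteroscedastic_specs, 1000, seed=seed)
            test = gen_feature_dataset(heteroscedastic_specs, 1000, seed=10_000 + seed)
            res = fit_gaussian_classes(train)
            x = test[["intensity", "sd"]].to_numpy()
            y = test["label"].to_numpy()
            acc_q = (res.predict(x, mode="qda") == y).mean()
            acc_l = (res.predict(x, mode="lda") == y).mean()
            wins += acc_q >= acc_l
        assert wins >= 18

    def test_affine_invariance_of_predictions(self, rng, well_separated_specs):
        df = gen_feature_dataset(well_separated_specs, 100, seed=9)
        x = df[["intensity", "sd"]].to_numpy()
        y = df[["label"]].to_numpy().ravel()
        test = rng.normal(0.9, 0.4, size=(200, 2))
        a = np.array([[2.0, 0.3], [-0.1, 1.5]])
        b = np.array([5.0, -2.0])
        for mode in ("lda", "qda"):
            base = GaussianDiscriminant(x, y).fit().predict(test, mode=mode)
            mapped = (
                GaussianDiscriminant(x @ a.T + b, y)
                .fit()
                .predict(test @ a.T + b, mode=mode)
            )
            np.testing.assert_array_equal(base, mapped)

    def test_dimension_mismatch(self, rng):
        res = random_results(rng)
        with pytest.raises(ValueError):
            res.predict(np.zeros(3))


class TestSklearnCrossCheck:
    def test_qda_predictions_match_sklearn(self, rng):
        sklearn_qda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).QuadraticDiscriminantAnalysis
        x = rng.normal(size=(300, 2))
        y = np.where(x[:, 0] + 0.5 * rng.normal(size=300) > 0, "b", "a")
        x[y == "b"] *= 1.8
        res = GaussianDiscriminant(x, y).fit()
        clf = sklearn_qda(reg_param=0.0, store_covariance=True).fit(x, y)
        pts = rng.normal(size=(500, 2)) * 1.4
        np.testing.assert_array_equal(
            res.predict(pts, mode="qda"), clf.predict(pts)
        )

    def test_lda_predictions_match_sklearn_balanced(self, rng):
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        x = np.vstack(
            [rng.normal(0, 1, size=(150, 2)), rng.normal(2.0, 1, size=(150, 2))]
        )
        y = np.array(["a"] * 150 + ["b"] * 150)
        res = GaussianDiscriminant(x, y).fit()
        clf = sklearn_lda().fit(x, y)
        pts = rng.normal(1.0, 2.0, size=(500, 2))
        np.testing.assert_array_equal(res.predict(pts, mode="lda"), clf.predict(pts))


class TestDecisionGrid:
    @staticmethod
    def boundary_points(grid):
        """Midpoints of horizontally adjacent grid cells with different
        labels."""
        pts = []
        for row in range(grid.label_index.shape[0]):
            for col in range(grid.label_index.shape[1] - 1):
                if grid.label_index[row, col] != grid.label_index[row, col + 1]:
                    pts.append(
                        (0.5 * (grid.x[col] + grid.x[col + 1]), grid.y[row])
                    )
        return np.array(pts)

    def two_class_results(self, cov_a, cov_b, mean_b=(4.0, 0.0)):
        covs = np.stack([np.asarray(cov_a, float), np.asarray(cov_b, float)])
        return GaussianDiscriminantResults(
            model=None,
            means=np.array([[0.0, 0.0], list(mean_b)]),
            covariances=covs,
            pooled_covariance=covs.mean(axis=0),
            priors=np.array([0.5, 0.5]),
            counts=np.array([50, 50]),
            regularization=0.0,
            class_order=("a", "b"),
        )

    def test_lda_boundary_is_straight(self):
        cov = np.array([[1.0, 0.4], [0.4, 2.0]])
        res = self.two_class_results(cov, cov)
        grid = res.decision_grid(
            bounds=((-4, 8), (-6, 6)), resolution=500, mode="lda"
        )
        pts = self.boundary_points(grid)
        assert len(pts) > 50
        # straight-line fit x = a + b*y: boundary nodes must be collinear
        coeff = np.polyfit(pts[:, 1], pts[:, 0], 1)
        pred = np.polyval(coeff, pts[:, 1])
        ss_res = np.sum((pts[:, 0] - pred) ** 2)
        ss_tot = np.sum((pts[:, 0] - pts[:, 0].mean()) ** 2) + 1e-30
        assert 1 - ss_res / ss_tot > 0.999

    def test_concentric_qda_boundary_is_closed_curve(self):
        res = self.two_class_results(
            0.25 * np.eye(2), 4.0 * np.eye(2), mean_b=(0.0, 0.0)
        )
        grid = res.decision_grid(bounds=((-6, 6), (-6, 6)), resolution=201, mode="qda")
        # inner class wins at the shared mean, outer class at the rim:
        # the boundary encloses the center
        assert grid.label_index[100, 100] == 0
        rim = np.concatenate(
            [grid.label_index[0], grid.label_index[-1],
             grid.label_index[:, 0], grid.label_index[:, -1]]
        )
        assert (rim == 1).all()

    def test_grid_argmax_matches_density_oracle(self, rng):
        res = random_results(rng)
        grid = res.decision_grid(bounds=((-4, 4), (-4, 4)), resolution=40, mode="qda")
        oracle_dens = np.stack(
            [
                res.priors[i]
                * multivariate_normal(res.means[i], res.covariances[i]).pdf(
                    np.stack(np.meshgrid(grid.x, grid.y), axis=-1)
                )
                for i in range(3)
            ]
        )
        np.testing.assert_array_equal(grid.label_index, oracle_dens.argmax(axis=0))

    def test_non_2d_model_rejected(self, rng):
        res = random_results(rng, k=3)
        with pytest.raises(ValueError):
            res.decision_grid(bounds=((0, 1), (0, 1)))


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, rng, well_separated_specs):
        df = gen_feature_dataset(well_separated_specs, 100, seed=4)
        res = fit_gaussian_classes(df)
        text = res.to_json()
        loaded = GaussianDiscriminantResults.from_json(text)
        pts = rng.normal(1.0, 0.5, size=(100, 2))
        for mode in ("lda", "qda"):
            np.testing.assert_array_equal(
                res.predict(pts, mode=mode), loaded.predict(pts, mode=mode)
            )
        assert json.loads(text)["classes"] == list(res.classes)

    def test_summary_mentions_classes(self, well_separated_specs):
        df = gen_feature_dataset(well_separated_specs, 50, seed=4)
        text = fit_gaussian_classes(df).summary()
        for cls_label in ("N", "M", "PM"):
            assert cls_label in text
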