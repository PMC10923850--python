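import numpy as np
import pytest

from treestrat import (
    FitConfig,
    InvalidInputError,
    ShapeError,
    cohort_relatedness,
    consistency_test,
    exact_shapley_modules,
    fit,
    jaccard_similarity,
    mean_abs_shap_by_subset,
    random_planted_truth,
    sample_dataset,
)

from .oracles import permutation_shapley


@pytest.fixture(scope="module")
def five_module_model():
    truth = random_planted_truth([1, 1, 1, 1, 1], seed=13)
    ds = sample_dataset(truth, mode="exhaustive", replicate=4)
    return fit(ds, truth.topology, FitConfig(seed=0)), ds


class TestExactShapley:
    def test_efficiency_identity(self, fitted_model, exhaustive_dataset):
        report = exact_shapley_modules(fitted_model, exhaustive_dataset.X)
        risks = fitted_model.predict(exhaustive_dataset.X)["risk"].to_numpy()
        residual = report.base_value + report.values.sum(axis=1) - risks
        assert np.abs(residual).max() < 1e-12

    def test_single_module_attribution(self):
        truth = random_planted_truth([2], seed=7)
        ds = sample_dataset(truth, mode="exhaustive")
        model = fit(ds, truth.topology, FitConfig(seed=0))
        report = exact_shapley_modules(model, ds.X)
        risks = model.predict(ds.X)["risk"].to_numpy()
        assert np.allclose(report.values[:, 0], risks - report.base_value)

    def test_null_player_gets_zero(self):
        """A module whose output never changes the aggregated result is a
        null player and must receive zero attribution everywhere."""
        truth = random_planted_truth([2, 2], seed=11)
        # overwrite the output lookup to ignore module 1's bit
        lookup = truth.output_lookup.copy()
        lookup[:] = np.array([0, 1, 0, 1])
        truth.output_lookup = lookup
        ds = sample_dataset(truth, mode="exhaustive", replicate=2)
        model = fit(ds, truth.topology, FitConfig(seed=0))
        report = exact_shapley_modules(model, ds.X)
        assert np.abs(report.values[:, 0]).max() < 1e-12

    def test_matches_permutation_oracle(self, five_module_model):
        model, ds = five_module_model
        rng = np.random.default_rng(0)
        rows = rng.choice(len(ds.X), size=6, replace=False)
        report = exact_shapley_modules(model, ds.X[rows])
        for i, row in enumerate(rows):
            oracle = permutation_shapley(model, ds.X[row])
            assert np.allclose(report.values[i], oracle, atol=1e-12)

    def test_symmetric_players_equal_attribution(self):
        """Two modules with identical marginal contributions share payout:
        an OR aggregation of two identity modules is symmetric in them."""
        from treestrat import PlantedTruth, TreeTopology

        topo = TreeTopology.from_sizes([1, 1])
        truth = PlantedTruth(
            topo,
            [np.array([0, 1]), np.array([0, 1])],
            np.array([0, 1, 1, 1]),  # OR of the two module bits
            np.full(2, 0.5),
        )
        ds = sample_dataset(truth, mode="exhaustive", replicate=3, seed=0)
        model = fit(ds, truth.topology, FitConfig(seed=0))
        sym_rows = np.array([[1, 1], [0, 0]])
        report = exact_shapley_modules(model, sym_rows)
        assert np.allclose(report.values[:, 0], report.values[:, 1], atol=1e-12)


class TestMeanAbsBySubset:
    def test_identical_attributions(self):
        values = np.full((10, 3), 0.25)
        means = mean_abs_shap_by_subset(values, [range(5), range(5, 10)])
        assert np.allclose(means, 0.25)

    def test_signed_values_use_absolute(self):
        values = np.array([[1.0, -1.0], [-1.0, 1.0]])
        means = mean_abs_shap_by_subset(values, [[0, 1]])
        assert np.allclose(means, 1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(40, 5))
        subsets = [rng.choice(40, size=10, replace=False) for _ in range(4)]
        means = mean_abs_shap_by_subset(values, subsets)
        for i, idx in enumerate(subsets):
            assert np.allclose(means[i], np.abs(values[idx]).mean(axis=0))

    def test_empty_subset_rejected(self):
        with pytest.raises(InvalidInputError):
            mean_abs_shap_by_subset(np.ones((4, 2)), [[0], []])


class TestConsistencyTest:
    def test_rank_conservation(self):
        rng = np.random.default_rng(0)
        data = np.abs(rng.normal(size=(80, 5)))
        result = consistency_test(data, alpha=0.1)
        assert result.average_ranks.sum() == pytest.approx(5 * 6 / 2)

    def test_shifted_module_rejected(self):
        rng = np.random.default_rng(1)
        data = np.abs(rng.normal(size=(80, 4)))
        data[:, 0] += 10.0
        result = consistency_test(data, alpha=0.1)
        involving = result.pairwise[
            (result.pairwise["module_a"] == "module1")
            | (result.pairwise["module_b"] == "module1")
        ]
        assert involving["reject"].all()
        assert result.average_ranks["module1"] == pytest.approx(1.0)

    def test_null_rejection_rate_below_alpha(self):
        """Identically distributed modules: pairwise rejections stay at or
        below the significance level (family-wise control makes them rarer)."""
        rng = np.random.default_rng(2)
        rejections, pairs = 0, 0
        for _ in range(100):
            data = np.abs(rng.normal(size=(80, 5)))
            result = consistency_test(data, alpha=0.1)
            rejections += int(result.pairwise["reject"].sum())
            pairs += len(result.pairwise)
        assert rejections / pairs <= 0.1

    def test_needs_two_subsets(self):
        with pytest.raises(InvalidInputError):
            consistency_test(np.ones((1, 3)))


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 1, 0), (1, 1, 0), 1.0),
            ((1, 0, 0), (0, 1, 1), 0.0),
            ((1, 1, 0), (1, 0, 1), 1 / 3),
        ],
    )
    def test_examples(self, a, b, expected):
        assert jaccard_similarity(a, b) == pytest.approx(expected)

    def test_both_empty_convention(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert jaccard_similarity((0, 0), (0, 0)) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            jaccard_similarity((0, 1), (0, 1, 1))


class TestCohortRelatedness:
    def test_identical_cohorts_mean_one(self):
        X = np.array([[1, 0, 1], [1, 0, 1], [1, 0, 1]])
        mean, (lo, hi) = cohort_relatedness(X, X)
        assert mean == 1.0
        assert lo <= mean <= hi

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        A = rng.integers(0, 2, size=(3, 6))
        B = rng.integers(0, 2, size=(3, 6))
        # make supports non-empty so the pairwise ratio is well defined
        A[:, 0] = 1
        B[:, 1] = 1
        mean, _ = cohort_relatedness(A, B)
        sims = [jaccard_similarity(a, b) for a in A for b in B]
        assert mean == pytest.approx(np.mean(sims))

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidInputError):
            cohort_relatedness(np.empty((0, 3)), np.ones((2, 3)))


class TestStabilityAcrossCohorts:
    def test_importance_order_correlates_across_shifted_cohorts(self):
        """Module importance orderings from the same planted truth stay
        positively rank-correlated across case-mix-shifted cohorts."""
        from scipy.stats import spearmanr

        from treestrat import make_shifted_cohorts

        truth = random_planted_truth([3, 2, 2], seed=17, prevalences=0.5)
        ds = sample_dataset(truth, mode="exhaustive", replicate=4)
        model = fit(ds, truth.topology, FitConfig(seed=0))
        cohorts = make_shifted_cohorts(
            truth, 3, 0.15, 1500, seed=5, compute_relatedness=False
        )
        profiles = [
            exact_shapley_modules(model, c.X[:400]).mean_abs()
            for c in cohorts.datasets
        ]
        rho01 = spearmanr(profiles[0], profiles[1]).statistic
        rho02 = spearmanr(profiles[0], profiles[2]).statistic
        assert rho01 > 0 and rho02 > 0
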