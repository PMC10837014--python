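"""Joint-regression estimation: hand oracles, invariants, missing-data paths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reactnorm import (
    DataError,
    InvalidArgumentError,
    PhenotypeMatrix,
    SingularDesignError,
    compute_environment_means,
    fit_joint_regression,
    two_env_parameters,
)


class TestEnvironmentMeans:
    def test_constant_data_centres_to_zero(self):
        pheno = PhenotypeMatrix(["a", "b"], ["E1", "E2", "E3"],
                                np.full((2, 3), 7.5))
        means = compute_environment_means(pheno)
        assert means.grand_mean == pytest.approx(7.5)
        np.testing.assert_allclose(means.centered, 0.0)

    def test_hand_arithmetic(self, tiny_pheno):
        means = compute_environment_means(tiny_pheno)
        np.testing.assert_allclose(means.raw_means, [2.0, 3.0, 4.0])
        assert means.grand_mean == pytest.approx(3.0)
        np.testing.assert_allclose(means.centered, [-1.0, 0.0, 1.0])

    def test_centered_sums_to_zero_on_subset(self, tiny_pheno):
        means = compute_environment_means(tiny_pheno, ["A", "C"])
        assert means.centered.sum() == pytest.approx(0.0, abs=1e-12)

    def test_empty_subset_rejected(self, tiny_pheno):
        with pytest.raises(InvalidArgumentError):
            compute_environment_means(tiny_pheno, [])

    def test_all_missing_environment_is_a_data_error(self):
        vals = np.array([[1.0, np.nan, 3.0], [2.0, np.nan, 4.0],
                         [3.0, np.nan, 6.0]])
        pheno = PhenotypeMatrix(["a", "b", "c"], ["E1", "E2", "E3"], vals)
        with pytest.raises(DataError, match="E2"):
            compute_environment_means(pheno, ["E1", "E2"])
        # the other environments remain usable
        compute_environment_means(pheno, ["E1", "E3"])


class TestJointRegression:
    def test_hand_ols(self):
        # genotype 1: I=(-1,0,1), Y=(10,12,17) -> slope 3.5, intercept 13
        pheno = PhenotypeMatrix(["g1", "flat"], ["A", "B", "C"],
                                np.array([[10.0, 12.0, 17.0], [0.0, 0.0, 0.0]]))
        from reactnorm import EnvironmentMeanVector
        I = EnvironmentMeanVector(["A", "B", "C"], np.array([-1.0, 0.0, 1.0]), 0.0)
        norms = fit_joint_regression(pheno, I)
        assert norms.slopes[0] == pytest.approx(3.5)
        assert norms.intercepts[0] == pytest.approx(13.0)
        assert norms.slopes[1] == pytest.approx(0.0)

    def test_noise_free_recovery(self, noiseless_scenario):
        _, pheno, truth = noiseless_scenario
        I = compute_environment_means(pheno)
        norms = fit_joint_regression(pheno, I)
        np.testing.assert_allclose(norms.intercepts, truth.intercepts, rtol=1e-9)
        np.testing.assert_allclose(norms.slopes, truth.slopes, rtol=1e-9)

    def test_population_mean_slope_is_one(self, rng):
        vals = rng.normal(50.0, 10.0, size=(12, 6))
        pheno = PhenotypeMatrix([f"g{i}" for i in range(12)],
                                [f"E{j}" for j in range(6)], vals)
        I = compute_environment_means(pheno)
        norms = fit_joint_regression(pheno, I)
        assert norms.slopes.mean() == pytest.approx(1.0, abs=1e-8)
        assert norms.intercepts.mean() == pytest.approx(I.grand_mean, abs=1e-8)

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(5):
            vals = rng.normal(0.0, 1.0, size=(5, 5))
            pheno = PhenotypeMatrix([f"g{i}" for i in range(5)],
                                    [f"E{j}" for j in range(5)], vals)
            I = compute_environment_means(pheno)
            norms = fit_joint_regression(pheno, I)
            X = np.column_stack([np.ones(5), I.centered])
            for i in range(5):
                a, b = np.linalg.solve(X.T @ X, X.T @ vals[i])
                assert norms.intercepts[i] == pytest.approx(a, abs=1e-10)
                assert norms.slopes[i] == pytest.approx(b, abs=1e-10)

    def test_residuals_orthogonal_and_centred(self, scenario):
        _, pheno, _ = scenario
        I = compute_environment_means(pheno)
        norms = fit_joint_regression(pheno, I)
        np.testing.assert_allclose(norms.residuals.sum(axis=1), 0.0, atol=1e-7)
        np.testing.assert_allclose(norms.residuals @ I.centered, 0.0, atol=1e-5)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(shift=st.floats(-1e3, 1e3), scale=st.floats(0.01, 100.0))
    def test_affine_equivariance(self, shift, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(20.0, 5.0, size=(6, 5))
        base = PhenotypeMatrix([f"g{i}" for i in range(6)],
                               [f"E{j}" for j in range(5)], vals)
        moved = PhenotypeMatrix(base.genotype_ids, base.environment_ids,
                                vals * scale + shift)
        n0 = fit_joint_regression(base, compute_environment_means(base))
        n1 = fit_joint_regression(moved, compute_environment_means(moved))
        np.testing.assert_allclose(n1.slopes, n0.slopes, atol=1e-8, rtol=1e-8)
        np.testing.assert_allclose(n1.intercepts, n0.intercepts * scale + shift,
                                   rtol=1e-8, atol=1e-6)

    def test_two_envs_redirects_to_pair_rule(self, tiny_pheno):
        I = compute_environment_means(tiny_pheno, ["A", "B"])
        with pytest.raises(InvalidArgumentError, match="two_env"):
            fit_joint_regression(tiny_pheno, I)

    def test_identical_means_singular(self):
        pheno = PhenotypeMatrix(["a", "b"], ["E1", "E2", "E3"],
                                np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]]))
        from reactnorm import EnvironmentMeanVector
        I = EnvironmentMeanVector(["E1", "E2", "E3"], np.full(3, 1.5), 1.5)
        with pytest.raises(SingularDesignError):
            fit_joint_regression(pheno, I)

    def test_missing_values_fit_on_available_environments(self):
        vals = np.array([[10.0, 12.0, 17.0, 20.0],
                         [10.0, np.nan, 14.0, 16.0],
                         [5.0, 6.0, np.nan, np.nan]])
        pheno = PhenotypeMatrix(["full", "part", "thin"],
                                ["A", "B", "C", "D"], vals)
        I = compute_environment_means(pheno)
        norms = fit_joint_regression(pheno, I)
        assert "thin" not in norms.genotype_ids  # only 2 observations
        i = norms.genotype_ids.index("part")
        m = ~np.isnan(vals[1])
        b, a = np.polyfit(I.centered[m], vals[1, m], 1)
        assert norms.slopes[i] == pytest.approx(b)
        assert norms.n_env_used[i] == 3


class TestTwoEnvRule:
    def test_flat_reaction_norm(self):
        pheno = PhenotypeMatrix(["g1", "g2"], ["A", "B"],
                                np.array([[5.0, 5.0], [1.0, 9.0]]))
        norms = two_env_parameters(pheno, ["A", "B"])
        i = norms.genotype_ids.index("g1")
        assert norms.intercepts[i] == pytest.approx(5.0)
        assert norms.slopes[i] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # Y=(10,14) at I=(-2,2): intercept 12, slope 1
        from reactnorm import EnvironmentMeanVector
        pheno = PhenotypeMatrix(["g1", "g2"], ["A", "B"],
                                np.array([[10.0, 14.0], [14.0, 10.0]]))
        I = EnvironmentMeanVector(["A", "B"], np.array([-2.0, 2.0]), 0.0)
        norms = two_env_parameters(pheno, ["A", "B"], I)
        assert norms.intercepts[0] == pytest.approx(12.0)
        assert norms.slopes[0] == pytest.approx(1.0)
        assert norms.slopes[1] == pytest.approx(-1.0)

    def test_slopes_perfectly_correlate_with_raw_differences(self, rng):
        vals = rng.normal(30.0, 4.0, size=(15, 2))
        pheno = PhenotypeMatrix([f"g{i}" for i in range(15)], ["A", "B"], vals)
        norms = two_env_parameters(pheno, ["A", "B"])
        means = compute_environment_means(pheno)
        hi, lo = (("B", 1), ("A", 0)) if means.centered[1] > means.centered[0] else (("A", 0), ("B", 1))
        diffs = vals[:, hi[1]] - vals[:, lo[1]]
        assert np.corrcoef(norms.slopes, diffs)[0, 1] == pytest.approx(1.0)

    def test_ordering_by_environmental_mean(self):
        # environments given high-mean-first must be reordered internally
        pheno = PhenotypeMatrix(["g1", "g2"], ["hi", "lo"],
                                np.array([[20.0, 10.0], [22.0, 12.0]]))
        norms = two_env_parameters(pheno, ["hi", "lo"])
        assert norms.environment_ids == ["lo", "hi"]
        assert np.all(norms.slopes > 0)

    def test_identical_means_rejected(self):
        pheno = PhenotypeMatrix(["g1", "g2"], ["A", "B"],
                                np.array([[5.0, 5.0], [7.0, 7.0]]))
        with pytest.raises(SingularDesignError):
            two_env_parameters(pheno, ["A", "B"])

    def test_missing_genotypes_excluded(self):
        vals = np.array([[1.0, 2.0, 2.0], [np.nan, 3.0, 4.0], [2.0, 4.0, 9.0]])
        pheno = PhenotypeMatrix(["a", "b", "c"], ["A", "B", "C"], vals)
        norms = two_env_parameters(pheno, ["A", "B"])
        assert norms.genotype_ids == ["a", "c"]
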