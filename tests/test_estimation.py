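"""Maxvar estimation: standardization, weights, scores, Sigma-hat."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from cca.errors import DegenerateBlockError, SpecificationError
from cca.estimation import (
    DataMatrix,
    composite_correlations,
    composite_scores,
    estimate,
    inverse_sqrt,
    maxvar_weights,
    standardize,
)
from cca.model import CompositeModelSpec
from cca.simulation import draw_sample

from conftest import equicorr, random_pd


class TestStandardize:
    def test_zero_mean_unit_variance_1_over_n(self):
        x = standardize(np.array([[1.0], [2.0], [3.0]]))
        assert x.mean() == pytest.approx(0.0, abs=1e-15)
        assert (x**2).mean() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        x = standardize(rng.standard_normal((50, 4)))
        np.testing.assert_allclose(standardize(x), x, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(DegenerateBlockError):
            standardize(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))

    def test_dataframe_round_trip_keeps_labels(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [0.0, 1.0, -1.0]})
        out = standardize(df)
        assert list(out.columns) == ["a", "b"]


class TestInverseSqrt:
    def test_identity(self):
        np.testing.assert_allclose(inverse_sqrt(np.eye(3)), np.eye(3), atol=1e-14)

    def test_diagonal_closed_form(self):
        np.testing.assert_allclose(
            inverse_sqrt(np.diag([4.0, 9.0])), np.diag([0.5, 1.0 / 3.0]), atol=1e-14
        )

    def test_multiply_back_random_pd(self):
        rng = np.random.default_rng(11)
        m = random_pd(rng, 5)
        r = inverse_sqrt(m)
        np.testing.assert_allclose(r @ m @ r, np.eye(5), atol=1e-10)
        np.testing.assert_allclose(r, r.T, atol=1e-12)

    def test_non_pd_reports_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(Exception, match="eigenvalue"):
            inverse_sqrt(bad)


class TestMaxvarWeights:
    def test_population_model1_recovery(self, model1):
        sol = maxvar_weights(model1.sigma.sigma, model1.spec)
        np.testing.assert_allclose(sol.weights["c1"], [0.6, 0.2, 0.4], atol=1e-8)
        np.testing.assert_allclose(sol.weights["c2"], [0.4, 0.2, 0.6], atol=1e-8)

    def test_two_singleton_blocks_reproduce_indicator_correlation(self):
        spec = CompositeModelSpec({"a": ["x"], "b": ["y"]})
        S = np.array([[1.0, 0.42], [0.42, 1.0]])
        sol = maxvar_weights(S, spec)
        np.testing.assert_allclose(sol.weights["a"], [1.0])
        np.testing.assert_allclose(sol.weights["b"], [1.0])
        c = composite_correlations(S, sol.weights, spec)
        assert c.loc["a", "b"] == pytest.approx(0.42, abs=1e-12)

    def test_two_blocks_match_first_canonical_correlation(self, two_block_spec):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((400, 6))
        x[:, 3:] += 0.5 * x[:, :3]
        xs = standardize(x)
        S = xs.T @ xs / len(xs)
        sol = maxvar_weights(S, two_block_spec)
        c = composite_correlations(S, sol.weights, two_block_spec)
        # independent oracle: first canonical correlation of the two blocks
        s11, s22, s12 = S[:3, :3], S[3:, 3:], S[:3, 3:]
        m = inverse_sqrt(s11) @ s12 @ inverse_sqrt(s22)
        rho1 = scipy.linalg.svdvals(m)[0]
        assert c.loc["c1", "c2"] == pytest.approx(rho1, abs=1e-10)

    def test_unit_variance_constraint_every_block(self, two_block_spec):
        rng = np.random.default_rng(19)
        xs = standardize(rng.standard_normal((200, 6)))
        S = xs.T @ xs / len(xs)
        sol = maxvar_weights(S, two_block_spec)
        for name, sl in zip(
            [n for n, _ in two_block_spec.unified_blocks()],
            two_block_spec.block_slices(),
        ):
            w = sol.weights[name]
            assert w @ S[sl, sl] @ w == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_largest_entry_positive(self, two_block_spec):
        rng = np.random.default_rng(23)
        xs = standardize(rng.standard_normal((300, 6)))
        S = xs.T @ xs / len(xs)
        sol = maxvar_weights(S, two_block_spec)
        for w in sol.weights.values():
            assert w[np.argmax(np.abs(w))] > 0


class TestCompositeScores:
    def test_singleton_weight_one_returns_the_column(self):
        spec = CompositeModelSpec({"a": ["x"], "b": ["y"]})
        xs = standardize(np.random.default_rng(2).standard_normal((30, 2)))
        df = pd.DataFrame(xs, columns=["x", "y"])
        scores = composite_scores(df, {"a": [1.0], "b": [1.0]}, spec)
        np.testing.assert_allclose(scores["a"], df["x"])

    def test_score_variance_equals_quadratic_form(self, two_block_spec):
        rng = np.random.default_rng(5)
        xs = standardize(rng.standard_normal((150, 6)))
        S = xs.T @ xs / len(xs)
        sol = maxvar_weights(S, two_block_spec)
        df = pd.DataFrame(xs, columns=two_block_spec.indicator_names)
        scores = composite_scores(df, sol.weights, two_block_spec)
        for name, sl in zip(["c1", "c2"], two_block_spec.block_slices()):
            w = sol.weights[name]
            v = (scores[name] ** 2).mean() - scores[name].mean() ** 2
            assert v == pytest.approx(w @ S[sl, sl] @ w, abs=1e-10)

    def test_population_weights_give_unit_variance_scores_large_sample(self, model1):
        x = draw_sample(model1.sigma, 10_000, seed=99)
        df = pd.DataFrame(x, columns=model1.spec.indicator_names)
        scores = composite_scores(df, model1.params.weights, model1.spec)
        for c in ("c1", "c2"):
            assert scores[c].var(ddof=0) == pytest.approx(1.0, abs=0.05)


class TestEstimate:
    def test_perfect_fit_on_population_matrices(self, model1, model4):
        for entry in (model1, model4):
            r = estimate(entry.sigma.sigma, entry.spec)
            np.testing.assert_allclose(
                r.sigma_hat.to_numpy(), entry.sigma.sigma, atol=1e-10
            )

    def test_model1_loadings(self, model1):
        r = estimate(model1.sigma.sigma, model1.spec)
        np.testing.assert_allclose(r.loadings["c1"], [0.9, 0.7, 0.8], atol=1e-8)

    def test_sampling_recovery_within_three_standard_errors(self, model1):
        n = 500
        x = draw_sample(model1.sigma, n, seed=1234)
        r = estimate(x, model1.spec)
        rho = r.composite_corr.loc["c1", "c2"]
        se = (1 - 0.3**2) / np.sqrt(n)
        assert abs(rho - 0.3) < 3 * se

    def test_permutation_equivariance(self, model1):
        x = draw_sample(model1.sigma, 300, seed=8)
        df = pd.DataFrame(x, columns=model1.spec.indicator_names)
        base = estimate(df, model1.spec)
        permuted_spec = CompositeModelSpec(
            {"c1": ["x13", "x11", "x12"], "c2": ["x22", "x23", "x21"]}
        )
        perm = estimate(df, permuted_spec)
        np.testing.assert_allclose(
            perm.weights["c1"],
            [base.weights["c1"][2], base.weights["c1"][0], base.weights["c1"][1]],
            atol=1e-10,
        )
        np.testing.assert_allclose(
            perm.composite_corr.to_numpy(), base.composite_corr.to_numpy(), atol=1e-10
        )
        np.testing.assert_allclose(
            perm.sigma_hat.loc[list(model1.spec.indicator_names),
                               list(model1.spec.indicator_names)].to_numpy(),
            base.sigma_hat.to_numpy(),
            atol=1e-10,
        )

    def test_isolated_model_rejected(self):
        spec = CompositeModelSpec({"c": ["x1", "x2", "x3"]})
        xs = standardize(np.random.default_rng(4).standard_normal((50, 3)))
        with pytest.raises(SpecificationError, match="isolated"):
            estimate(xs, spec)


class TestDataMatrix:
    def test_requires_more_rows_than_columns(self):
        with pytest.raises(Exception, match="observations"):
            DataMatrix(pd.DataFrame(np.zeros((3, 5))))

    def test_missing_values_located(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 2)),
                          columns=["a", "b"])
        df.iloc[4, 1] = np.nan
        with pytest.raises(Exception, match="column 'b'"):
            DataMatrix(df)
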