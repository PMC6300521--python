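"""Composite-model structure: loadings, model-implied matrices, df counting."""

import itertools

import numpy as np
import pytest

from cca.errors import ConditioningError, DegenerateBlockError, SpecificationError
from cca.model import (
    CompositeModelSpec,
    PopulationModelParams,
    check_identification,
    composite_loadings,
    composite_variance,
    degrees_of_freedom,
    model_implied_covariance,
    rescale_weights,
)

from conftest import equicorr


class TestSpecInvariants:
    def test_indicator_assigned_twice_rejected(self):
        with pytest.raises(SpecificationError, match="more than once"):
            CompositeModelSpec({"a": ["x1", "x2"], "b": ["x2", "x3"]})

    def test_indicator_cannot_also_be_free(self):
        with pytest.raises(SpecificationError, match="free variable"):
            CompositeModelSpec({"a": ["x1", "x2"]}, free_variables=["x2"])

    def test_empty_block_rejected(self):
        with pytest.raises(SpecificationError, match="no indicators"):
            CompositeModelSpec({"a": []})

    def test_column_order_blocks_then_free(self, fig2_spec):
        assert fig2_spec.indicator_names == ("x1", "x2", "y", "z")
        assert fig2_spec.K == 4 and fig2_spec.J == 1 and fig2_spec.n_free == 2


class TestLoadingsAndVariance:
    @pytest.mark.parametrize(
        "w, expected",
        [
            ([0.6, 0.2, 0.4], [0.9, 0.7, 0.8]),
            ([0.4, 0.2, 0.6], [0.8, 0.7, 0.9]),
        ],
    )
    def test_loadings_equicorrelated_block(self, w, expected):
        lam = composite_loadings(np.array(w), equicorr(3, 0.5))
        np.testing.assert_allclose(lam, expected, atol=1e-12)

    def test_singleton_block_identity(self):
        np.testing.assert_allclose(composite_loadings([1.0], np.eye(1)), [1.0])

    @pytest.mark.parametrize(
        "w, s, expected",
        [
            ([0.6, 0.2, 0.4], equicorr(3, 0.5), 1.0),
            ([1.0], np.eye(1), 1.0),
            ([0.5, 0.5], np.eye(2), 0.5),
        ],
    )
    def test_composite_variance(self, w, s, expected):
        assert composite_variance(np.array(w), s) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(SpecificationError):
            composite_loadings([0.5, 0.5], equicorr(3, 0.5))


class TestRescaleWeights:
    def test_rescaling_recovers_normalized_vector(self):
        w = rescale_weights([1.2, 0.4, 0.8], equicorr(3, 0.5))
        np.testing.assert_allclose(w, [0.6, 0.2, 0.4], atol=1e-12)

    def test_idempotent_on_normalized_weights(self):
        w0 = np.array([0.6, 0.2, 0.4])
        np.testing.assert_allclose(rescale_weights(w0, equicorr(3, 0.5)), w0, atol=1e-12)

    def test_zero_weights_degenerate(self):
        with pytest.raises(DegenerateBlockError):
            rescale_weights([0.0, 0.0, 0.0], equicorr(3, 0.5))


class TestModelImpliedCovariance:
    def test_model1_cross_block_entry(self, model1_params):
        mic = model_implied_covariance(model1_params)
        # rho * lambda_1[0] * lambda_2[0] = 0.3 * 0.9 * 0.8
        assert mic.loc("x11", "x21") == pytest.approx(0.216, abs=1e-12)
        assert mic.loc("x11", "x12") == pytest.approx(0.5, abs=1e-12)

    def test_single_block_returns_intra_matrix(self):
        spec = CompositeModelSpec({"c": ["a1", "a2", "a3"]})
        s = equicorr(3, 0.3)
        params = PopulationModelParams(
            spec=spec,
            weights={"c": rescale_weights([1.0, 1.0, 1.0], s)},
            composite_corr=np.eye(1),
            intra_block_corr={"c": s},
        )
        np.testing.assert_allclose(model_implied_covariance(params).sigma, s, atol=1e-14)

    def test_symmetry_and_rank_one_minors(self, model4):
        sigma = model4.sigma.sigma
        np.testing.assert_array_equal(sigma, sigma.T)
        slices = model4.spec.block_slices()
        for j, l in itertools.combinations(range(len(slices)), 2):
            off = sigma[slices[j], slices[l]]
            rows, cols = off.shape
            for r1, r2 in itertools.combinations(range(rows), 2):
                for c1, c2 in itertools.combinations(range(cols), 2):
                    minor = off[r1, c1] * off[r2, c2] - off[r1, c2] * off[r2, c1]
                    assert abs(minor) < 1e-12

    def test_free_variable_covariance_distributes_through_loadings(self):
        spec = CompositeModelSpec({"c": ["x1", "x2"]}, free_variables=["y"])
        s = equicorr(2, 0.4)
        w = rescale_weights([1.0, 1.0], s)
        params = PopulationModelParams(
            spec=spec,
            weights={"c": w},
            composite_corr=np.eye(1),
            intra_block_corr={"c": s},
            free_composite_corr=np.array([[0.5]]),
        )
        mic = model_implied_covariance(params)
        lam = composite_loadings(w, s)
        assert mic.loc("y", "x1") == pytest.approx(0.5 * lam[0], abs=1e-12)
        assert mic.loc("y", "x2") == pytest.approx(0.5 * lam[1], abs=1e-12)

    def test_non_pd_composite_corr_names_condition(self):
        with pytest.raises(ConditioningError, match="condition \\(ii\\)"):
            PopulationModelParams(
                spec=CompositeModelSpec({"a": ["x1"], "b": ["x2"]}),
                weights={"a": [1.0], "b": [1.0]},
                composite_corr=np.array([[1.0, 1.2], [1.2, 1.0]]),
                intra_block_corr={"a": np.eye(1), "b": np.eye(1)},
            )

    def test_non_pd_intra_block_names_condition(self):
        bad = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ConditioningError, match="condition \\(i\\)"):
            PopulationModelParams(
                spec=CompositeModelSpec({"a": ["x1", "x2"], "b": ["x3"]}),
                weights={"a": [0.5, 0.5], "b": [1.0]},
                composite_corr=equicorr(2, 0.3),
                intra_block_corr={"a": bad, "b": np.eye(1)},
            )

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(SpecificationError, match="variance"):
            PopulationModelParams(
                spec=CompositeModelSpec({"a": ["x1", "x2"], "b": ["x3"]}),
                weights={"a": [1.0, 1.0], "b": [1.0]},
                composite_corr=equicorr(2, 0.3),
                intra_block_corr={"a": equicorr(2, 0.5), "b": np.eye(1)},
            )


class TestDegreesOfFreedom:
    def test_one_composite_two_free_variables(self, fig2_spec):
        rep = degrees_of_freedom(fig2_spec)
        assert rep.df == 1
        assert rep.terms == (6, 0, 2, 1, 1, 2, 1)
        assert rep.status == "over-identified"

    def test_two_three_indicator_composites(self, two_block_spec):
        rep = degrees_of_freedom(two_block_spec)
        assert rep.df == 15 - 1 - 0 - 0 - 6 - 6 + 2 == 4

    def test_just_identified_two_indicator_composite_one_free(self):
        spec = CompositeModelSpec({"c": ["x1", "x2"]}, free_variables=["y"])
        rep = degrees_of_freedom(spec)
        assert rep.df == 0 and rep.status == "just-identified"

    def test_invariant_under_block_and_indicator_permutation(self, two_block_spec):
        permuted = CompositeModelSpec(
            {"c2": ["x23", "x21", "x22"], "c1": ["x12", "x13", "x11"]}
        )
        assert degrees_of_freedom(permuted).df == degrees_of_freedom(two_block_spec).df

    def test_all_singleton_blocks_no_free_variables(self):
        # K singleton blocks: only the K(K-1)/2 composite correlations are
        # free, and weights cancel against blocks, so df = 0.
        spec = CompositeModelSpec({f"c{i}": [f"x{i}"] for i in range(4)})
        rep = degrees_of_freedom(spec)
        assert rep.df == 0
        assert rep.term_breakdown["weights"] == rep.term_breakdown["blocks"] == 4


class TestIdentification:
    def test_fig2_model_connected_and_over_identified(self, fig2_spec):
        sigma = equicorr(4, 0.2)
        rep = check_identification(fig2_spec, sigma)
        assert rep.isolated_blocks == () and rep.status == "over-identified"

    def test_single_block_without_neighbors_is_isolated(self):
        spec = CompositeModelSpec({"c": ["x1", "x2", "x3"]})
        rep = check_identification(spec)
        assert rep.isolated_blocks == ("c",)
        assert rep.status == "under-identified"

    def test_zero_cross_covariance_block_flagged(self, two_block_spec):
        sigma = np.eye(6)
        sigma[:3, :3] = equicorr(3, 0.5)
        sigma[3:, 3:] = equicorr(3, 0.5)
        rep = check_identification(two_block_spec, sigma)
        assert set(rep.isolated_blocks) == {"c1", "c2"}
        assert rep.status == "under-identified"

    def test_three_connected_composites_not_isolated(self, model4):
        rep = check_identification(model4.spec, model4.sigma)
        assert rep.isolated_blocks == ()
        assert rep.status == "over-identified"
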