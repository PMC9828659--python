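import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import trapvol as tv
from trapvol.exceptions import (
    ContractViolationError,
    DegenerateInputError,
    InvalidInputError,
    InvalidParameterError,
    NegativeVarianceWarning,
)
from trapvol.variance import _var_m1


class TestCovariogram:
    @pytest.mark.parametrize(
        "areas,expected",
        [
            ((0, 5, 0), (25.0, 0.0, 0.0)),
            ((0, 2, 3, 0), (13.0, 6.0, 0.0)),
            ((0, 0, 0, 0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_examples(self, areas, expected):
        g = tv.covariogram(areas, 2)
        np.testing.assert_allclose(g.values, expected)

    def test_lag_bound(self):
        with pytest.raises(InvalidParameterError):
            tv.covariogram((0, 1, 0), 3)

    @given(
        areas=arrays(np.float64, st.integers(3, 15), elements=st.floats(0.0, 50.0))
    )
    def test_cauchy_schwarz(self, areas):
        g = tv.covariogram(areas, 2).values
        assert g[0] >= 0
        assert g[1] <= g[0] + 1e-9 and g[2] <= g[0] + 1e-9


class TestGammaMoments:
    @given(
        T=st.floats(0.1, 5.0),
        n=st.integers(2, 10),
        i=st.integers(1, 2),
        j=st.integers(1, 5),
    )
    def test_constant_gap_identity(self, T, n, i, j):
        """gamma_{i,j} = i^j T^(j-1) exactly for constant gaps."""
        gaps = np.full(n, T)
        expect = i**j * T ** (j - 1)
        assert tv.gamma_moment(gaps, i, j) == pytest.approx(expect, rel=1e-12)

    def test_hand_examples(self):
        assert tv.gamma_moment((1.0, 3.0), 1, 2) == pytest.approx(2.5)
        assert tv.gamma_moment((1.0, 3.0), 2, 1) == pytest.approx(2.0)

    def test_lag_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            tv.gamma_moment((1.0, 1.0), 3, 2)


class TestThicknessMoments:
    def test_perturbed_hand_example(self):
        pm = tv.perturbed_moments((1.0, 1.0, 2.0))
        assert pm.T_hat == pytest.approx(4 / 3)
        assert pm.theta2 == pytest.approx(2 / 9)

    def test_constant_gaps_degenerate(self):
        pm = tv.perturbed_moments((2.0, 2.0, 2.0), refined=True)
        assert pm.theta2 == 0.0 and pm.theta4 == 0.0
        # refined corrections are no-ops when theta2 = 0
        assert pm.T2_refined == pytest.approx(pm.T_hat**2, rel=1e-14)
        assert pm.theta2_refined == 0.0

    def test_refined_corrections(self):
        pm = tv.perturbed_moments((1.0, 1.0, 2.0), refined=True)
        n = 3
        assert pm.theta2_refined == pytest.approx(pm.theta2 * n * n / (n * n - 1))
        assert pm.T2_refined == pytest.approx(pm.T_hat**2 - pm.theta2 / (n * n - 1))

    def test_cumulative_hand_example(self):
        nu = tv.cumulative_moments((1.0, 1.0, 2.0))
        assert nu[0] == pytest.approx(4 / 3)  # equals T^ from the perturbed set
        assert nu[1] == pytest.approx(2.0)
        assert nu[2] == pytest.approx(10 / 3)

    def test_constant_gaps_powers(self):
        nu = tv.cumulative_moments((0.5, 0.5))
        np.testing.assert_allclose(nu, [0.5**j for j in range(1, 6)], rtol=1e-14)

    def test_empty_errors(self):
        with pytest.raises(InvalidInputError):
            tv.cumulative_moments(())
        with pytest.raises(InvalidInputError):
            tv.perturbed_moments((1.0,))


class TestWorkedVarianceExamples:
    """Hand-computed values for the small (0,2,3,0) series."""

    def test_model_free(self, equidistant_series, toy_series):
        assert tv.varest_model_free(equidistant_series, 0).value == pytest.approx(1.25)
        assert tv.varest_model_free(equidistant_series, 1).value == pytest.approx(0.0625)
        assert tv.varest_model_free(toy_series, 0).value == pytest.approx(3.125)

    def test_perturbed(self, toy_series, equidistant_series):
        assert tv.varest_perturbed(toy_series, 0).value == pytest.approx(55 / 18)
        # refined flag is a no-op at constant gaps
        plain = tv.varest_perturbed(equidistant_series, 0).value
        refined = tv.varest_perturbed(equidistant_series, 0, refined=True).value
        assert refined == pytest.approx(plain, rel=1e-14)

    def test_cumulative(self, toy_series, equidistant_series):
        assert tv.varest_cumulative(toy_series, 0).value == pytest.approx(3.125)
        assert tv.varest_cumulative(equidistant_series, 1).value == pytest.approx(0.0625)

    def test_equidistant(self):
        areas = (0, 2, 3, 0)
        assert tv.varest_equidistant(areas, 1.0, 0).value == pytest.approx(1.25)
        assert tv.varest_equidistant(areas, 1.0, 1).value == pytest.approx(0.0625)

    @given(T=st.floats(0.1, 4.0))
    def test_m0_to_m1_ratio_is_twenty(self, T):
        areas = (0, 2, 3, 0)
        v0 = tv.varest_equidistant(areas, T, 0).value
        v1 = tv.varest_equidistant(areas, T, 1).value
        assert v0 == pytest.approx(20 * v1, rel=1e-12)


class TestEquidistantReductions:
    @given(
        areas=arrays(np.float64, st.integers(2, 10), elements=st.floats(0.0, 20.0)),
        T=st.floats(0.05, 5.0),
        m=st.integers(0, 1),
    )
    def test_all_estimators_reduce_to_classical(self, areas, T, m):
        """With constant gaps every estimator equals the classical form."""
        full = np.concatenate([[0.0], areas, [0.0]])
        positions = np.arange(len(full)) * T
        series = tv.SectionSeries(positions, full)
        reference = tv.varest_equidistant(full, T, m).value
        for fn in (tv.varest_model_free, tv.varest_perturbed, tv.varest_cumulative):
            assert fn(series, m).value == pytest.approx(
                reference, rel=1e-12, abs=1e-12
            )


class TestDropoutContracts:
    def test_model_specific_estimators_refuse_dropouts(self, toy_series):
        thinned = tv.SectionSeries(
            toy_series.positions, toy_series.areas, dropout_applied=True
        )
        with pytest.raises(ContractViolationError):
            tv.varest_perturbed(thinned, 0)
        with pytest.raises(ContractViolationError):
            tv.varest_cumulative(thinned, 1)

    def test_after_dropout_delegates_to_model_free(self, toy_series):
        thinned = tv.SectionSeries(
            toy_series.positions, toy_series.areas, dropout_applied=True
        )
        assert tv.varest_after_dropout(thinned, 0).value == pytest.approx(3.125)
        assert (
            tv.varest_after_dropout(toy_series, 1).value
            == tv.varest_model_free(toy_series, 1).value
        )

    def test_minimal_thinned_series(self):
        small = tv.SectionSeries(
            np.array([0.0, 1.0, 5.0]), np.array([0.0, 4.0, 0.0]),
            dropout_applied=True,
        )
        assert np.isfinite(tv.varest_after_dropout(small, 0).value)


class TestConservativeBound:
    def test_doubles_and_flags(self, equidistant_series):
        est = tv.varest_model_free(equidistant_series, 1)
        bounded = tv.conservative_bound(est)
        assert bounded.value == pytest.approx(2 * est.value)
        assert bounded.conservative and not est.conservative

    def test_rejects_zero_oriented(self, equidistant_series):
        est = tv.varest_model_free(equidistant_series, 0)
        with pytest.raises(InvalidParameterError):
            tv.conservative_bound(est)


class TestGuards:
    def test_degenerate_gamma_denominator(self):
        g = np.array([1.0, 0.5, 0.2])
        gam = {(1, 2): 1.0, (2, 2): 2.0, (1, 3): 1.0, (2, 3): 2.0, (1, 5): 1.0}
        with pytest.raises(DegenerateInputError):
            _var_m1(g, gam)

    def test_negative_estimate_clamped_with_warning(self):
        # short, sharply peaked series for which the m=1 combination is negative
        series = tv.SectionSeries(
            np.array([0.05882522, 3.45456036, 3.70969571, 3.82884072,
                      3.87170476, 3.92478016]),
            np.array([0.0, 0.74382006, 4.86314407, 4.44967778, 4.11186914, 0.0]),
        )
        with pytest.warns(NegativeVarianceWarning):
            est = tv.varest_model_free(series, 1)
        assert est.value == 0.0

    def test_too_short_series(self):
        tiny = tv.SectionSeries(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        with pytest.raises((InvalidInputError, ContractViolationError)):
            tv.varest_model_free(tiny, 0)
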