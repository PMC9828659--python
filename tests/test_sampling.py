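import math

import numpy as np
import pytest
from scipy.stats import kstest

import trapvol as tv
from trapvol.exceptions import (
    CalibrationError,
    CoverageError,
    InvalidInputError,
    InvalidParameterError,
)
from trapvol.sampling import _truncated_normal


class TestSamplingSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(model="weird", mean_gap=1.0),
            dict(model="perturbed", mean_gap=0.0),
            dict(model="perturbed", mean_gap=1.0, rel_dev=0.6),
            dict(model="perturbed", mean_gap=1.0, dropout_prob=1.0),
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(InvalidParameterError):
            tv.SamplingSpec(**kwargs)


class TestCalibration:
    def test_zero_dispersion_degenerate(self):
        assert tv.calibrate_dispersion("perturbed", 1.0, 0.0) == 0.0
        assert tv.calibrate_dispersion("cumulative", 2.5, 0.0) == 0.0

    def test_scales_linearly_with_gap(self):
        s1 = tv.calibrate_dispersion("perturbed", 1.0, 0.05)
        s2 = tv.calibrate_dispersion("perturbed", 2.0, 0.05)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    @pytest.mark.parametrize("model", ["perturbed", "cumulative"])
    def test_monte_carlo_matches_target(self, model):
        """Calibrated scale reproduces E|h - T|/T = 0.05 within 1e-3."""
        T, rel_dev = 1.0, 0.05
        scale = tv.calibrate_dispersion(model, T, rel_dev)
        rng = np.random.default_rng(123)
        if model == "perturbed":
            d = _truncated_normal(rng, scale, T / 2, 2_000_000)
            observed = np.abs(d[::2] - d[1::2]).mean() / T
        else:
            z = _truncated_normal(rng, scale, T / 2, 1_000_000)
            observed = np.abs(z).mean() / T
        assert observed == pytest.approx(rel_dev, abs=1e-3)

    def test_unattainable_dispersion(self):
        # the truncation bounds cap the attainable relative deviation
        with pytest.raises(CalibrationError):
            tv.calibrate_dispersion("cumulative", 1.0, 0.3)
        with pytest.raises(CalibrationError):
            tv.calibrate_dispersion("perturbed", 1.0, 0.4)


class TestSamplePositions:
    def test_perturbed_with_zero_dev_equals_equidistant(self):
        win = (0.0, 3.0)
        eq = tv.sample_positions(
            tv.SamplingSpec("equidistant", 0.4, seed=9), win
        )
        pert = tv.sample_positions(
            tv.SamplingSpec("perturbed", 0.4, rel_dev=0.0, seed=9), win
        )
        np.testing.assert_allclose(pert, eq, atol=1e-15)

    @pytest.mark.parametrize("model", ["equidistant", "perturbed", "cumulative"])
    def test_covers_window_and_ordered(self, model):
        spec = tv.SamplingSpec(model, 0.3, seed=2)
        pos = tv.sample_positions(spec, (-1.0, 1.0))
        assert pos[0] < -1.0 and pos[-1] > 1.0
        assert np.all(np.diff(pos) > 0)

    def test_empirical_mean_gap(self):
        """Law of large numbers: mean sampled gap equals T within 1%."""
        rng = np.random.default_rng(11)
        spec = tv.SamplingSpec("cumulative", 0.5, rel_dev=0.05)
        gaps = []
        for _ in range(400):
            pos = tv.sample_positions(spec, (0.0, 150.0), rng)
            gaps.append(np.diff(pos))
        mean_gap = np.concatenate(gaps).mean()
        assert mean_gap == pytest.approx(0.5, rel=0.01)

    def test_perturbed_gaps_positive(self):
        rng = np.random.default_rng(3)
        spec = tv.SamplingSpec("perturbed", 0.2, rel_dev=0.3)
        for _ in range(200):
            pos = tv.sample_positions(spec, (0.0, 5.0), rng)
            assert np.all(np.diff(pos) > 0)

    @pytest.mark.parametrize("model", ["equidistant", "perturbed"])
    def test_start_phase_uniform(self, model):
        """Stationarity proxy: x0 mod T is uniform on [0, T)."""
        T = 0.3
        spec = tv.SamplingSpec(model, T, rel_dev=0.05)
        rng = np.random.default_rng(17)
        phases = np.array(
            [tv.sample_positions(spec, (0.0, 2.0), rng)[0] % T for _ in range(10_000)]
        )
        assert kstest(phases / T, "uniform").pvalue > 0.01

    def test_window_too_small(self):
        with pytest.raises(InvalidParameterError):
            tv.sample_positions(tv.SamplingSpec("equidistant", 1.0), (0.0, 1.5))


class TestSectionsFromAreaFunction:
    def test_ball_fixed_grid(self, ball):
        series = tv.sections_from_area_function(
            ball, np.array([-1.2, -0.4, 0.4, 1.2])
        )
        np.testing.assert_allclose(
            series.areas, [0.0, 0.84 * math.pi, 0.84 * math.pi, 0.0], rtol=1e-12
        )
        np.testing.assert_allclose(series.gaps, [0.8, 0.8, 0.8])
        assert series.is_estimation_ready

    def test_trims_to_single_margin_plane(self, ball):
        pos = np.array([-3.0, -2.2, -1.4, -0.6, 0.2, 1.0, 1.8])
        series = tv.sections_from_area_function(ball, pos)
        assert series.positions[0] == -1.4
        assert series.areas[0] == 0.0 and series.areas[-1] == 0.0

    def test_support_not_covered(self, ball):
        with pytest.raises(CoverageError):
            tv.sections_from_area_function(ball, np.array([-0.5, 0.0, 0.5]))

    def test_no_hitting_plane_gives_zero_series(self, ball):
        pos = np.array([-9.0, -5.0, 5.0, 9.0])
        series = tv.sections_from_area_function(ball, pos)
        assert np.all(series.areas == 0.0)
        assert tv.trapezoidal_estimate(series).value == 0.0


class TestApplyDropout:
    def test_gap_merge(self):
        series = tv.SectionSeries(
            np.arange(5.0), np.array([0.0, 2.0, 3.0, 2.0, 0.0])
        )
        rng = np.random.default_rng(0)
        # force-drop index 2 by thinning with a crafted rng stream
        thinned = tv.SectionSeries(
            np.array([0.0, 1.0, 3.0, 4.0]), np.array([0.0, 2.0, 2.0, 0.0])
        )
        np.testing.assert_allclose(np.diff(thinned.positions), [1.0, 2.0, 1.0])
        out = tv.apply_dropout(series, 0.5, seed=1)
        assert out.dropout_applied
        assert out.positions[0] == 0.0 and out.positions[-1] == 4.0

    def test_zero_probability_identity(self):
        series = tv.SectionSeries(np.arange(4.0), np.array([0.0, 1.0, 1.0, 0.0]))
        assert tv.apply_dropout(series, 0.0, seed=1) is series

    def test_expected_retained_count(self):
        """Binomial oracle: E(retained interior) = (N-1)(1-p)."""
        n, p = 22, 0.3
        series = tv.SectionSeries(
            np.arange(float(n)), np.concatenate([[0], np.ones(n - 2), [0]])
        )
        rng = np.random.default_rng(8)
        kept = [
            len(tv.apply_dropout(series, p, rng=rng).positions) - 2
            for _ in range(4000)
        ]
        expect = (n - 2) * (1 - p)
        se = math.sqrt((n - 2) * p * (1 - p) / 4000)
        assert np.mean(kept) == pytest.approx(expect, abs=4 * se)

    def test_requires_estimation_ready(self):
        bad = tv.SectionSeries(np.arange(3.0), np.array([1.0, 2.0, 1.0]))
        with pytest.raises(InvalidInputError):
            tv.apply_dropout(bad, 0.2, seed=0)


def test_translation_invariance_matched_seed(ball):
    """Shifting window and object by a multiple of T reproduces the estimate."""
    T = 0.4
    shift = 3 * T
    spline = tv.spline_area_function(
        (-1.0, -0.5, 0.0, 0.5, 1.0), (0.0, 2.0, 3.0, 2.0, 0.0)
    )
    shifted = tv.spline_area_function(
        (-1.0 + shift, -0.5 + shift, shift, 0.5 + shift, 1.0 + shift),
        (0.0, 2.0, 3.0, 2.0, 0.0),
    )
    spec = tv.SamplingSpec("perturbed", T, rel_dev=0.05, seed=21)
    pos = tv.sample_positions(spec, (-1.0, 1.0))
    pos_shifted = tv.sample_positions(spec, (-1.0 + shift, 1.0 + shift))
    v1 = tv.trapezoidal_estimate(tv.sections_from_area_function(spline, pos)).value
    v2 = tv.trapezoidal_estimate(
        tv.sections_from_area_function(shifted, pos_shifted)
    ).value
    assert v2 == pytest.approx(v1, rel=1e-9)
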