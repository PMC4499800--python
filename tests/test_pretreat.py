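import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plstraj.errors import DegenerateSpectrumError, ParameterError, ShapeError
from plstraj.pretreat import (
    PretreatmentSpec,
    PretreatmentStep,
    apply_pipeline,
    apply_savgol,
    parse_pretreatment,
    savgol_coefficients,
    snv,
)


class TestSNV:
    def test_worked_example(self):
        out = snv(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        np.testing.assert_allclose(
            out[0], [-1.2649, -0.6325, 0.0, 0.6325, 1.2649], atol=1e-4
        )

    def test_idempotent_on_standardized_rows(self, rng):
        X = snv(rng.normal(size=(4, 30)))
        np.testing.assert_allclose(snv(X), X, atol=1e-12)

    def test_constant_row_raises_with_location(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 2.0, 2.0]])
        with pytest.raises(DegenerateSpectrumError, match="row 1"):
            snv(X)

    def test_rows_standardized(self, rng):
        out = snv(rng.normal(size=(10, 25)))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-10)

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 50),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        """SNV removes exactly the multiplicative-scatter-plus-offset artifact."""
        X = np.random.default_rng(seed).normal(size=(3, 20))
        np.testing.assert_allclose(snv(a * X + b), snv(X), atol=1e-8)


class TestSavgolCoefficients:
    def test_classic_quadratic_smoother(self):
        np.testing.assert_allclose(
            savgol_coefficients(5, 2, 0),
            np.array([-3.0, 12.0, 17.0, 12.0, -3.0]) / 35.0,
            atol=1e-10,
        )

    @pytest.mark.parametrize("window", [5, 7, 9])
    @pytest.mark.parametrize("poly", [2, 3])
    @pytest.mark.parametrize("deriv", [0, 1, 2])
    def test_against_brute_force_least_squares(self, window, poly, deriv):
        """Weights must reproduce a per-window polynomial fit + differentiation."""
        from math import factorial

        rng = np.random.default_rng(window * 10 + poly + deriv)
        for position in (0, window // 2, window - 1):
            coef = savgol_coefficients(window, poly, deriv, position)
            f = rng.normal(size=window)
            x = np.arange(window) - position
            beta = np.polynomial.polynomial.polyfit(x, f, poly)
            expected = factorial(deriv) * beta[deriv]
            assert coef @ f == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_scipy(self):
        from scipy.signal import savgol_coeffs

        for window, poly, deriv in [(5, 2, 0), (9, 2, 1), (9, 2, 2), (7, 3, 1)]:
            ours = savgol_coefficients(window, poly, deriv)
            theirs = savgol_coeffs(window, poly, deriv=deriv, use="dot")
            np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_smoothing_weights_sum_to_one(self):
        assert savgol_coefficients(9, 2, 0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_derivative_weights_sum_to_zero(self):
        assert savgol_coefficients(9, 2, 1).sum() == pytest.approx(0.0, abs=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            savgol_coefficients(4, 2, 0)
        with pytest.raises(ParameterError):
            savgol_coefficients(5, 2, 3)


class TestApplySavgol:
    def test_quadratic_invariance_including_edges(self):
        i = np.arange(40, dtype=float)
        X = np.vstack([3.0 + 0.5 * i - 0.01 * i**2, 1.0 - 0.2 * i + 0.03 * i**2])
        step = PretreatmentStep("SG", window=9)
        np.testing.assert_allclose(apply_savgol(X, step), X, atol=1e-9)

    def test_first_derivative_of_linear_signal(self):
        X = np.tile(0.7 * np.arange(30.0), (3, 1))
        step = PretreatmentStep("SG", window=9, deriv_order=1)
        np.testing.assert_allclose(apply_savgol(X, step, spacing=1.0), 0.7, atol=1e-9)
        # physical spacing rescales the derivative
        np.testing.assert_allclose(apply_savgol(X, step, spacing=2.0), 0.35, atol=1e-9)

    def test_second_derivative_of_linear_signal_is_zero(self):
        X = np.tile(1.0 - 0.3 * np.arange(30.0), (2, 1))
        step = PretreatmentStep("SG", window=9, poly_order=2, deriv_order=2)
        np.testing.assert_allclose(apply_savgol(X, step), 0.0, atol=1e-9)

    def test_matches_scipy_interp_mode(self, rng):
        from scipy.signal import savgol_filter

        X = rng.normal(size=(4, 60))
        for deriv in (0, 1, 2):
            step = PretreatmentStep("SG", window=9, deriv_order=deriv)
            ours = apply_savgol(X, step, spacing=2.0)
            theirs = savgol_filter(X, 9, 2, deriv=deriv, delta=2.0, axis=1, mode="interp")
            np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_too_few_channels(self):
        with pytest.raises(ShapeError):
            apply_savgol(np.ones((2, 5)), PretreatmentStep("SG", window=9))


class TestLabelsAndPipeline:
    @pytest.mark.parametrize(
        "label", ["raw", "SNV", "SG(9)", "1D+SG(9)", "2D+SG(9)", "1D+SG(9)+SNV", "SNV+SG(7)"]
    )
    def test_label_round_trip(self, label):
        assert parse_pretreatment(label).label == label

    def test_derivative_fuses_with_sg(self):
        spec = parse_pretreatment("2D+SG(9)")
        assert len(spec.steps) == 1
        assert spec.steps[0] == PretreatmentStep("SG", window=9, poly_order=2, deriv_order=2)

    def test_fused_equals_direct_savgol(self, rng):
        X = rng.normal(size=(3, 40))
        spec = parse_pretreatment("2D+SG(9)")
        direct = apply_savgol(X, PretreatmentStep("SG", 9, 2, 2), spacing=2.0)
        np.testing.assert_array_equal(apply_pipeline(X, spec, spacing=2.0), direct)

    @pytest.mark.parametrize("label", ["1D", "3D+SG(9)", "1D+SNV", "SG(4)", "bogus"])
    def test_invalid_labels_rejected(self, label):
        with pytest.raises(ParameterError):
            parse_pretreatment(label)

    def test_empty_spec_is_identity(self, rng):
        X = rng.normal(size=(2, 15))
        np.testing.assert_array_equal(apply_pipeline(X, PretreatmentSpec()), X)

    def test_step_order_matters(self):
        # a sloped baseline makes SNV-then-derivative differ from the reverse
        i = np.arange(40, dtype=float)
        X = np.vstack([np.exp(-((i - 20) ** 2) / 18.0) + 0.05 * i,
                       2 * np.exp(-((i - 20) ** 2) / 18.0) + 0.02 * i])
        a = apply_pipeline(X, parse_pretreatment("SNV+1D+SG(9)"))
        b = apply_pipeline(X, parse_pretreatment("1D+SG(9)+SNV"))
        assert np.max(np.abs(a - b)) > 1e-3

    def test_pipeline_preserves_shape(self, rng):
        X = rng.normal(size=(5, 33))
        for label in ["raw", "SNV", "SG(5)", "1D+SG(9)+SNV", "2D+SG(9)"]:
            assert apply_pipeline(X, parse_pretreatment(label)).shape == X.shape
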