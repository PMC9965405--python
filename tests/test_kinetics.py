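"""Kinetic model equations, fitting and R²-based comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from releasekit import (
    GeneratorConfig,
    ReleaseCurve,
    compare_models,
    fit_release_model,
    generate_release_curve,
    gompertz_q,
    higuchi_q,
    korsmeyer_peppas_q,
    r_squared,
    zero_order_q,
)
from releasekit.kinetics import DegenerateDataError

from conftest import PBS_GOMPERTZ


class TestEquations:
    @pytest.mark.parametrize("t, k0, expected", [
        (0.0, 0.66, 0.0),
        (10.0, 0.66, 6.6),
        (1.0, 3.21, 3.21),
    ])
    def test_zero_order(self, t, k0, expected):
        assert zero_order_q(t, k0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t, kH, expected", [
        (0.0, 9.49, 0.0),
        (4.0, 9.49, 18.98),
        (1.0, 7.93, 7.93),
    ])
    def test_higuchi(self, t, kH, expected):
        assert higuchi_q(t, kH) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("t, kR, n, expected", [
        (1.0, 48.60, 0.13, 48.60),
        (4.0, 48.60, 0.13, 48.60 * 4**0.13),  # = 58.197... (log-space check)
        (0.0, 48.60, 0.13, 0.0),
    ])
    def test_korsmeyer_peppas(self, t, kR, n, expected):
        assert korsmeyer_peppas_q(t, kR, n) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_korsmeyer_peppas_log_space_consistency(self):
        # power-law evaluation agrees with exp/log arithmetic
        got = korsmeyer_peppas_q(4.0, 48.60, 0.13)
        assert got == pytest.approx(
            np.exp(np.log(48.60) + 0.13 * np.log(4.0)), rel=1e-12)
        assert got == pytest.approx(58.1975, abs=5e-4)

    def test_gompertz_base10_values(self):
        # log10(1) = 0 so Q(1) = Qmax * exp(-alpha)
        assert gompertz_q(1.0, 83, 0.83, -2.7) == pytest.approx(
            83 * np.exp(-0.83), rel=1e-12)
        # base-10 convention puts the 50-h plateau at 82.3% (rounds to 82)
        assert gompertz_q(50.0, 83, 0.83, -2.7) == pytest.approx(82.30, abs=0.01)
        # asymptote is Qmax for beta < 0
        assert gompertz_q(1e8, 83, 0.83, -2.7) == pytest.approx(83.0, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zero_order_q(-1.0, 0.66)
        with pytest.raises(ValueError):
            higuchi_q(-0.1, 9.49)
        with pytest.raises(ValueError):
            korsmeyer_peppas_q(1.0, 48.6, 0.0)  # nonpositive exponent
        with pytest.raises(ValueError):
            gompertz_q(0.0, 83, 0.83, -2.7)  # log undefined

    @given(t=st.floats(0, 1e6), k=st.floats(1e-3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_peppas_half_exponent_equals_higuchi(self, t, k):
        assert korsmeyer_peppas_q(t, k, 0.5) == higuchi_q(t, k)

    def test_gompertz_monotone_saturating(self):
        t = np.geomspace(1e-3, 1e8, 400)
        q = gompertz_q(t, 83, 0.83, -2.7)
        assert np.all(np.diff(q) >= 0)  # flat only where exp underflows
        assert np.all(np.diff(q[(t > 0.01) & (t < 1e4)]) > 0)
        assert q[-1] <= 83.0 + 1e-9


class TestRSquared:
    def test_perfect_baseline_and_negative(self):
        obs = [1.0, 2.0, 5.0]
        assert r_squared(obs, obs) == pytest.approx(1.0)
        mean = [np.mean(obs)] * 3
        assert r_squared(obs, mean) == pytest.approx(0.0)
        # hand arithmetic: SSres = 200, SStot = 50
        assert r_squared([0, 10], [10, 0]) == pytest.approx(-3.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            r_squared([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])  # zero SStot

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_affine_invariance(self, a, b):
        obs = np.array([3.0, 8.0, 20.0, 55.0])
        pred = np.array([2.5, 9.0, 19.0, 60.0])
        assert r_squared(a * obs + b, a * pred + b) == pytest.approx(
            r_squared(obs, pred), rel=1e-9)


NOISELESS_CASES = [
    ("zero_order", {"K0": 0.66}),
    ("higuchi", {"KH": 9.49}),
    ("korsmeyer_peppas", {"KR": 48.60, "n": 0.13}),
    ("gompertz", PBS_GOMPERTZ),
]


class TestFitting:
    @pytest.mark.parametrize("model, params", NOISELESS_CASES)
    def test_noiseless_self_recovery(self, model, params):
        """All four models recover their generating parameters exactly."""
        curve = generate_release_curve(GeneratorConfig(
            model=model, params=params, sigma_pct=0.0, clip=None))
        res = fit_release_model(curve, model)
        assert res.converged
        for name, truth in params.items():
            assert res.params[name] == pytest.approx(truth, rel=1e-4)
        assert res.rsquared == pytest.approx(1.0, abs=1e-8)

    def test_predictions_regenerate_from_params(self, pbs_curve_noisy):
        res = fit_release_model(pbs_curve_noisy, "gompertz")
        again = gompertz_q(res.times_used, *res.params.values())
        np.testing.assert_array_equal(res.fittedvalues, again)

    def test_saturating_curve_breaks_linear_models(self, pbs_curve_noisy):
        """Burst-then-plateau data leaves zero-order and Higuchi with
        negative R² (worse than the flat mean line)."""
        for model in ("zero_order", "higuchi"):
            assert fit_release_model(pbs_curve_noisy, model).rsquared < 0

    def test_t0_points_excluded_for_log_models(self):
        t = np.array([0.0, 1.0, 4.0, 16.0, 64.0])
        curve = ReleaseCurve(t, gompertz_q(np.maximum(t, 1e-12), **{
            k.lower() if k == "Qmax" else k: v
            for k, v in PBS_GOMPERTZ.items()}))
        res = fit_release_model(curve, "gompertz")
        assert res.n_dropped_t0 == 1
        assert res.nobs == 4
        res0 = fit_release_model(curve, "zero_order")
        assert res0.nobs == 5

    def test_too_few_points_rejected(self):
        curve = ReleaseCurve([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        with pytest.raises(ValueError, match="at least 4"):
            fit_release_model(curve, "gompertz")

    def test_degenerate_flat_curve_rejected_for_multiparameter(self):
        curve = ReleaseCurve([1.0, 2.0, 4.0, 8.0, 16.0], [50.0] * 5)
        with pytest.raises(DegenerateDataError):
            fit_release_model(curve, "korsmeyer_peppas")

    def test_fit_is_deterministic(self, pbs_curve_noisy):
        a = fit_release_model(pbs_curve_noisy, "gompertz")
        b = fit_release_model(pbs_curve_noisy, "gompertz")
        assert a.params == b.params

    def test_fickian_flag(self, pbs_curve_noisy):
        res = fit_release_model(pbs_curve_noisy, "korsmeyer_peppas")
        assert res.is_fickian is (res.params["n"] <= 0.5)
        assert fit_release_model(pbs_curve_noisy, "gompertz").is_fickian is None


class TestComparison:
    def test_generator_identity_ranks_gompertz_first(self, pbs_curve_noisy):
        comp = compare_models(pbs_curve_noisy)
        assert comp.best.model.name == "gompertz"
        assert comp.best.rsquared > 0.9

    def test_single_model(self, pbs_curve_noisy):
        comp = compare_models(pbs_curve_noisy, ["higuchi"])
        assert len(comp.fits) == 1 and not comp.failures

    def test_ranking_follows_r2(self, pbs_curve_noisy):
        comp = compare_models(pbs_curve_noisy)
        r2s = [f.rsquared for f in comp.fits]
        assert r2s == sorted(r2s, reverse=True)

    def test_per_model_failure_isolated(self):
        # 3 points: enough for the 1-parameter laws, not for Gompertz
        curve = ReleaseCurve([1.0, 4.0, 16.0], [30.0, 60.0, 80.0])
        comp = compare_models(curve)
        assert "gompertz" in comp.failures
        fitted = {f.model.name for f in comp.fits}
        assert {"zero_order", "higuchi", "korsmeyer_peppas"} <= fitted

    def test_empty_model_list_rejected(self, pbs_curve_noisy):
        with pytest.raises(ValueError):
            compare_models(pbs_curve_noisy, [])

    def test_summary_and_frame(self, pbs_curve_noisy):
        comp = compare_models(pbs_curve_noisy)
        assert "gompertz" in comp.summary()
        df = comp.to_frame()
        assert list(df["model"][:1]) == ["gompertz"]
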