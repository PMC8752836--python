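"""Two-compartment kinetics: closed form, integrator, steady state, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from genegate import (
    NuclearExportModel,
    TranscriptKinetics,
    export_ratio,
    predict_expression_ratio,
    pulse_chase_solution,
    simulate_compartments,
    solve_compartments,
    steady_state_cytoplasmic,
)
from genegate.kinetics import normalize_expression
from genegate.simulate import gen_pulse_chase


def reference_solution(k: TranscriptKinetics, t: float) -> tuple[float, float]:
    """Independent high-accuracy integration of the compartment ODEs."""

    def rhs(_t, s):
        return [k.beta - k.gamma * s[0], k.k_e * s[0] - k.lambda_c * s[1]]

    sol = solve_ivp(rhs, (k.t0, t), [0.0, 0.0], method="DOP853",
                    rtol=1e-11, atol=1e-12)
    return sol.y[0, -1], sol.y[1, -1]


class TestClosedForm:
    def test_no_source_gives_empty_pools(self, kinetics_default):
        k = TranscriptKinetics(0.0, 1.0, 1.0, 0.5)
        x, y = solve_compartments(k, np.linspace(0, 10, 11))
        assert np.all(x == 0) and np.all(y == 0)

    def test_no_export_decouples_cytoplasm(self):
        k = TranscriptKinetics(beta=5.0, k_e=0.0, lambda_n=0.4, lambda_c=0.5)
        t = np.linspace(0, 12, 25)
        x, y = solve_compartments(k, t)
        assert np.all(y == 0)
        np.testing.assert_allclose(x, 5.0 / 0.4 * (1 - np.exp(-0.4 * t)), rtol=1e-12)

    def test_matches_independent_integrator(self, kinetics_default):
        x, y = solve_compartments(kinetics_default, 8.0)
        x_ref, y_ref = reference_solution(kinetics_default, 8.0)
        assert abs(float(x) - x_ref) / x_ref < 1e-6
        assert abs(float(y) - y_ref) / y_ref < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_integrator_random_parameters(self, seed):
        rng = np.random.default_rng(seed)
        k = TranscriptKinetics(*rng.uniform(0.05, 3.0, size=4))
        t = float(rng.uniform(0.5, 15.0))
        x, y = solve_compartments(k, t)
        x_ref, y_ref = reference_solution(k, t)
        assert abs(float(x) - x_ref) <= 1e-6 * max(abs(x_ref), 1e-12)
        assert abs(float(y) - y_ref) <= 1e-6 * max(abs(y_ref), 1e-12)

    def test_degenerate_eigenvalue_is_continuous(self):
        # lambda_c exactly equal to k_e + lambda_n hits the resonant branch;
        # it must agree with nearby non-degenerate parameters.
        k_eq = TranscriptKinetics(beta=7.0, k_e=0.8, lambda_n=0.4, lambda_c=1.2)
        t = np.linspace(0.1, 10, 40)
        x0, y0 = solve_compartments(k_eq, t)
        for eps in (1e-7, -1e-7):
            k_near = TranscriptKinetics(7.0, 0.8, 0.4, 1.2 + eps)
            _, y_near = solve_compartments(k_near, t)
            assert np.max(np.abs(y_near - y0)) < 1e-6

    def test_rejects_time_before_pulse_onset(self):
        k = TranscriptKinetics(1.0, 1.0, 0.1, 0.1, t0=5.0)
        with pytest.raises(ValueError):
            solve_compartments(k, 4.0)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            TranscriptKinetics(1.0, -0.1, 0.1, 0.1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        beta=st.floats(0.0, 20.0),
        k_e=st.floats(0.0, 3.0),
        lambda_n=st.floats(0.0, 3.0),
        lambda_c=st.floats(0.0, 3.0),
        t=st.floats(0.0, 30.0),
    )
    def test_pools_never_negative(self, beta, k_e, lambda_n, lambda_c, t):
        k = TranscriptKinetics(beta, k_e, lambda_n, lambda_c)
        x, y = solve_compartments(k, t)
        assert float(x) >= -1e-12 and float(y) >= -1e-12


class TestNumericalIntegrator:
    def test_agrees_with_closed_form(self, kinetics_default):
        series = simulate_compartments(kinetics_default, 10.0, 1e-3)
        x, y = solve_compartments(kinetics_default, series.times)
        assert np.max(np.abs(series.X - x)) < 1e-6
        assert np.max(np.abs(series.Y - y)) < 1e-6

    def test_fourth_order_convergence(self, kinetics_default):
        errors = []
        for dt in (0.1, 0.05):
            series = simulate_compartments(kinetics_default, 8.0, dt)
            _, y = solve_compartments(kinetics_default, series.times)
            errors.append(np.max(np.abs(series.Y - y)))
        assert errors[0] / errors[1] >= 8.0

    def test_zero_source_stays_zero(self):
        series = simulate_compartments(TranscriptKinetics(0.0, 1.0, 0.2, 0.3), 5.0, 0.01)
        assert np.all(series.X == 0) and np.all(series.Y == 0)

    def test_mass_balance_residual(self, kinetics_default):
        # Per-step increments of X+Y must track the closed-form balance
        # beta - lambda_n X - lambda_c Y to the integrator's order.
        dt = 1e-2
        series = simulate_compartments(kinetics_default, 5.0, dt)
        x_ref, y_ref = solve_compartments(kinetics_default, series.times)
        inc_num = np.diff(series.X + series.Y)
        inc_ref = np.diff(x_ref + y_ref)
        assert np.max(np.abs(inc_num - inc_ref)) < 10 * dt**4


class TestRatiosAndSteadyState:
    def test_zero_export_zero_ratio(self):
        k = TranscriptKinetics(5.0, 0.0, 0.4, 0.5)
        series = simulate_compartments(k, 10.0, 0.01)
        assert export_ratio(series, 10.0) == 0.0

    def test_ratio_approaches_ke_over_lambda_c(self, kinetics_default):
        k = kinetics_default
        x, y = solve_compartments(k, 200.0)
        assert abs(float(y) / float(x) - k.k_e / k.lambda_c) < 1e-9

    def test_ratio_undefined_at_zero_nuclear(self):
        series = simulate_compartments(TranscriptKinetics(0.0, 1.0, 0.2, 0.3), 5.0, 0.01)
        with pytest.raises(ZeroDivisionError):
            export_ratio(series, 5.0)

    def test_ratio_monotone_in_export_rate(self):
        t = 10.0
        ratios = []
        for k_e in (0.1, 0.3, 0.9, 2.7):
            k = TranscriptKinetics(10.0, k_e, 0.5, 0.4)
            x, y = solve_compartments(k, t)
            ratios.append(float(y) / float(x))
        assert np.all(np.diff(ratios) > 0)

    def test_threefold_export_reduction_tracks_closed_form(self):
        # A 3x lower export rate must reduce the pre-saturation export
        # ratio exactly as the closed form predicts.
        t = 15.0
        k_hi = TranscriptKinetics(10.0, 0.6, 0.2, 0.1)
        k_lo = k_hi.with_export_rate(0.2)
        ratios = {}
        for name, k in (("hi", k_hi), ("lo", k_lo)):
            x, y = solve_compartments(k, t)
            ratios[name] = float(y) / float(x)
        assert ratios["lo"] < ratios["hi"]
        x, y = solve_compartments(k_lo, t)
        assert np.isclose(ratios["lo"], float(y) / float(x), rtol=1e-12)

    def test_steady_state_formula(self):
        k = TranscriptKinetics(10.0, 1.0, 1.0, 0.5)
        assert steady_state_cytoplasmic(k) == pytest.approx(10.0)
        assert steady_state_cytoplasmic(TranscriptKinetics(0.0, 1.0, 1.0, 0.5)) == 0.0

    def test_steady_state_requires_decay(self):
        with pytest.raises(ValueError):
            steady_state_cytoplasmic(TranscriptKinetics(1.0, 1.0, 1.0, 0.0))

    def test_steady_state_increasing_in_export(self):
        values = [
            steady_state_cytoplasmic(TranscriptKinetics(10.0, k_e, 0.7, 0.5))
            for k_e in np.linspace(0.05, 5.0, 25)
        ]
        assert np.all(np.diff(values) > 0)

    def test_expression_ratio_identity_and_limits(self):
        k = TranscriptKinetics(10.0, 1.0, 0.0, 0.5)
        assert predict_expression_ratio(k, k) == pytest.approx(1.0)
        # With no nuclear decay every transcript is eventually exported, so
        # steady-state expression cannot depend on the export rate.
        assert predict_expression_ratio(k, k.with_export_rate(0.5)) == pytest.approx(1.0)
        # Export-limited regime (lambda_n >> k_e): ratio approaches k_e ratio.
        k_fast_decay = TranscriptKinetics(10.0, 1.0, 1e4, 0.5)
        ratio = predict_expression_ratio(k_fast_decay, k_fast_decay.with_export_rate(0.5))
        assert ratio == pytest.approx(0.5, rel=1e-3)

    def test_expression_ratio_reduced_formula(self):
        # Only k_e differs: ratio = k_mut (k_wt + l_n) / (k_wt (k_mut + l_n)).
        k_wt_e = 0.9
        k_mut_e = k_wt_e / 3.0
        lam_n = k_wt_e
        k_wt = TranscriptKinetics(10.0, k_wt_e, lam_n, 0.5)
        k_mut = k_wt.with_export_rate(k_mut_e)
        expected = (k_mut_e * (k_wt_e + lam_n)) / (k_wt_e * (k_mut_e + lam_n))
        assert predict_expression_ratio(k_wt, k_mut) == pytest.approx(expected, rel=1e-12)


class TestNormalization:
    def test_identity_and_spike_scaling(self):
        assert normalize_expression(3.0, 3.0, 1.0) == pytest.approx(1.0)
        assert normalize_expression(4.0, 2.0, 2.0) == pytest.approx(
            normalize_expression(4.0, 2.0, 1.0) / 2.0
        )

    def test_vectorised_replicates(self):
        out = normalize_expression([2.0, 4.0, 6.0], [1.0, 2.0, 3.0], 2.0)
        np.testing.assert_allclose(out, [1.0, 1.0, 1.0])
        assert out.mean() == pytest.approx(1.0) and out.std() == pytest.approx(0.0)

    def test_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            normalize_expression(1.0, 0.0)


class TestExportRateInversion:
    KNOWN = dict(beta=10.0, lambda_n=0.02, lambda_c=0.03)

    def test_noiseless_recovery_is_exact(self):
        k = TranscriptKinetics(k_e=0.2, **self.KNOWN)
        data = gen_pulse_chase(k, cv=0.0, seed=0)
        res = NuclearExportModel(data, pulse_min=30.0, **self.KNOWN).fit(n_boot=0)
        assert abs(res.k_e - 0.2) < 1e-6

    def test_zero_cytoplasmic_signal_fits_zero_export(self):
        k = TranscriptKinetics(k_e=0.0, **self.KNOWN)
        data = gen_pulse_chase(k, cv=0.0, seed=0)
        assert np.all(data["cytoplasmic"] == 0)
        res = NuclearExportModel(data, pulse_min=30.0, **self.KNOWN).fit(n_boot=0)
        assert res.k_e < 1e-6

    def test_all_zero_observations_unidentifiable(self):
        import pandas as pd

        data = pd.DataFrame(
            {"replicate": [0, 0], "time_min": [10.0, 20.0],
             "nuclear": [0.0, 0.0], "cytoplasmic": [0.0, 0.0]}
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            NuclearExportModel(data, pulse_min=30.0, **self.KNOWN)

    def test_noisy_recovery_within_ten_percent(self):
        k = TranscriptKinetics(k_e=0.2, **self.KNOWN)
        data = gen_pulse_chase(k, cv=0.05, n_reps=3, seed=11)
        res = NuclearExportModel(data, pulse_min=30.0, **self.KNOWN).fit(
            n_boot=200, seed=1
        )
        assert abs(res.k_e - 0.2) / 0.2 < 0.10
        lo, hi = res.conf_int()
        assert lo < res.k_e < hi
        assert "k_e" in res.summary()


class TestPulseChase:
    def test_chase_switches_off_source(self):
        k = TranscriptKinetics(10.0, 0.2, 0.05, 0.04)
        t = np.array([10.0, 30.0, 60.0, 90.0])
        x, y = pulse_chase_solution(k, t, pulse_min=30.0)
        # Nuclear pool decays after the source turns off.
        assert x[2] < x[1] and x[3] < x[2]

    def test_matches_piecewise_integrator(self):
        k = TranscriptKinetics(10.0, 0.2, 0.05, 0.04)

        def rhs(t, s):
            beta = k.beta if t < 30.0 else 0.0
            return [beta - k.gamma * s[0], k.k_e * s[0] - k.lambda_c * s[1]]

        t_eval = [15.0, 30.0, 55.0, 90.0]
        sol = solve_ivp(rhs, (0, 90.0), [0.0, 0.0], method="DOP853",
                        rtol=1e-11, atol=1e-12, t_eval=t_eval, max_step=1.0)
        x, y = pulse_chase_solution(k, np.array(t_eval), pulse_min=30.0)
        np.testing.assert_allclose(x, sol.y[0], rtol=1e-7, atol=1e-9)
        np.testing.assert_allclose(y, sol.y[1], rtol=1e-7, atol=1e-9)
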