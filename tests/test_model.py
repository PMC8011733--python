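"""Model core: flux algebra, steady state, mass balance, integrator."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from ogtt_persona import _kernel
from ogtt_persona.model import (
    MealInput,
    ModelConstants,
    ModelParameters,
    ModelState,
    SimulationError,
    basal_steady_state,
    glucose_fluxes,
    insulin_fluxes,
    pack_kernel_params,
    rhs,
    simulate,
)
from ogtt_persona.synthetic import default_priors, sample_parameters


class TestGlucoseFluxes:
    def test_basal_state_zero_dose_balances(self, ref_params, ref_constants):
        st = basal_steady_state(ref_params, ref_constants)
        gf = glucose_fluxes(st, 10.0, ref_params, ref_constants, MealInput(0.0))
        assert gf.gut_appearance == 0.0
        assert gf.net_plasma == pytest.approx(0.0, abs=1e-14)
        # hepatic production exactly offsets the two uptake fluxes
        assert gf.hepatic == pytest.approx(
            gf.insulin_independent_uptake + gf.insulin_dependent_uptake, rel=1e-14
        )

    def test_gut_to_plasma_proportional_to_gut_mass(self, ref_params, ref_constants, meal):
        c = ref_constants
        s1 = ModelState(50.0, c.Gb, c.Ib, 0.0)
        s2 = ModelState(100.0, c.Gb, c.Ib, 0.0)
        f1 = glucose_fluxes(s1, 30.0, ref_params, c, meal)
        f2 = glucose_fluxes(s2, 30.0, ref_params, c, meal)
        assert f2.gut_to_plasma == pytest.approx(2 * f1.gut_to_plasma, rel=1e-12)

    def test_gut_appearance_integral_equals_bioavailable_dose(
        self, ref_params, ref_constants, meal
    ):
        st = basal_steady_state(ref_params, ref_constants)
        val, err = quad(
            lambda t: glucose_fluxes(st, t, ref_params, ref_constants, meal).gut_appearance,
            0.0,
            1440.0,
            limit=200,
        )
        assert val == pytest.approx(ref_constants.f * meal.dose_mmol, rel=1e-6)

    def test_insulin_dependent_uptake_monotone_and_saturating(
        self, ref_params, ref_constants, meal
    ):
        c = ref_constants
        lo = glucose_fluxes(ModelState(0, 8.0, 20.0, 0), 0, ref_params, c, meal)
        hi = glucose_fluxes(ModelState(0, 8.0, 40.0, 0), 0, ref_params, c, meal)
        assert hi.insulin_dependent_uptake > lo.insulin_dependent_uptake
        # saturation: doubling glucose less than doubles the uptake
        g2 = glucose_fluxes(ModelState(0, 16.0, 20.0, 0), 0, ref_params, c, meal)
        assert g2.insulin_dependent_uptake < 2 * lo.insulin_dependent_uptake

    def test_renal_flux_zero_below_threshold(self, ref_params, ref_constants, meal):
        c = ref_constants
        below = glucose_fluxes(ModelState(0, c.Gth - 0.1, c.Ib, 0), 0, ref_params, c, meal)
        above = glucose_fluxes(ModelState(0, c.Gth + 1.0, c.Ib, 0), 0, ref_params, c, meal)
        assert below.renal == 0.0
        assert above.renal > 0.0

    def test_errors(self, ref_params, ref_constants):
        with pytest.raises(ValueError):
            glucose_fluxes(
                ModelState(0, np.nan, 8.0, 0), 0, ref_params, ref_constants, MealInput(0)
            )
        with pytest.raises(ValueError):
            MealInput(-1.0)


class TestInsulinFluxes:
    def test_basal_fluxes_net_zero(self, ref_params, ref_constants):
        st = basal_steady_state(ref_params, ref_constants)
        inf = insulin_fluxes(st, 0.0, ref_params, ref_constants)
        assert inf.pancreatic_secretion == 0.0
        assert inf.liver_clearance == 0.0
        assert inf.interstitial_transfer == 0.0

    def test_proportional_branch_doubles_with_elevation(self, ref_params, ref_constants):
        c = ref_constants
        p = ref_params.with_values(k7=1e-12, k8=1e-12)
        a = insulin_fluxes(ModelState(0, c.Gb + 1, c.Ib, 0), 0.0, p, c)
        b = insulin_fluxes(ModelState(0, c.Gb + 2, c.Ib, 0), 0.0, p, c)
        assert b.pancreatic_secretion == pytest.approx(2 * a.pancreatic_secretion, rel=1e-9)

    def test_derivative_branch_matches_finite_difference(self, ref_params, ref_constants):
        """With k6 = k7 ~ 0 the secretion must track k8*tau_d*dG/dt during a
        glucose rise, where dG/dt is checked by finite differences of the
        simulated trajectory."""
        c = ref_constants
        p = ref_params.with_values(k6=1e-12, k7=1e-12)
        r = simulate(p, c, MealInput(75.0), np.arange(0.0, 60.0, 0.5), dense=False)
        g = r.glucose
        t = r.times
        i_mid = 30  # index during the rise
        dgdt_fd = (g[i_mid + 1] - g[i_mid - 1]) / (t[i_mid + 1] - t[i_mid - 1])
        st = ModelState(0.0, g[i_mid], r.insulin[i_mid], 0.0)
        sec = insulin_fluxes(st, dgdt_fd, p, c).pancreatic_secretion
        assert sec == pytest.approx(p.k8 * c.tau_d * dgdt_fd / c.beta, rel=1e-9)
        assert sec > 0  # responds during the rise


class TestRhs:
    def test_zero_at_basal_with_zero_dose(self, ref_params, ref_constants):
        st = basal_steady_state(ref_params, ref_constants)
        d = rhs(st, 5.0, ref_params, ref_constants, MealInput(0.0))
        assert np.max(np.abs(d)) < 1e-9

    def test_pure_function(self, ref_params, ref_constants, meal):
        st = ModelState(40.0, 7.0, 30.0, 12.0)
        a = rhs(st, 17.0, ref_params, ref_constants, meal)
        b = rhs(st, 17.0, ref_params, ref_constants, meal)
        assert np.array_equal(a, b)

    def test_kernel_matches_reference_algebra(self, ref_params, ref_constants, meal):
        """The jitted packed RHS must agree exactly with the typed flux
        composition on random admissible states."""
        pk = pack_kernel_params(ref_params, ref_constants, meal)
        rng = np.random.default_rng(1)
        for _ in range(100):
            st = ModelState(
                rng.uniform(0, 300),
                rng.uniform(2, 18),
                rng.uniform(2, 300),
                rng.uniform(-100, 400),
            )
            t = rng.uniform(0, 240)
            a = rhs(st, t, ref_params, ref_constants, meal)
            b = _kernel.rhs_packed(t, st.as_array(), pk)
            np.testing.assert_allclose(a, b, rtol=1e-13, atol=1e-15)

    def test_consistent_with_trajectory_finite_difference(
        self, ref_params, ref_constants, meal
    ):
        r = simulate(ref_params, ref_constants, meal, np.arange(0, 121, 1.0), dense=True)
        h = 1e-3
        for t_probe in (20.0, 60.0, 110.0):
            a = simulate(ref_params, ref_constants, meal, (t_probe - h, t_probe + h))
            idx = int(t_probe)
            st = ModelState(
                r.dense_gut_mass[idx], r.dense_glucose[idx], r.dense_insulin[idx], 0.0
            )
            dG = rhs(st, t_probe, ref_params, ref_constants, meal)[1]
            fd = (a.glucose[1] - a.glucose[0]) / (2 * h)
            assert fd == pytest.approx(dG, rel=5e-3, abs=1e-5)


class TestSimulate:
    def test_zero_dose_flat_line(self, ref_params, ref_constants):
        r = simulate(ref_params, ref_constants, MealInput(0.0), (0, 30, 60, 90, 120))
        assert np.max(np.abs(r.glucose - ref_constants.Gb)) < 1e-6
        assert np.max(np.abs(r.insulin - ref_constants.Ib)) < 1e-6

    def test_reference_morphology(self, ref_params, ref_constants, meal):
        """Healthy reference: glucose rises above basal, has one interior
        maximum, and insulin returns toward basal late."""
        r = simulate(ref_params, ref_constants, meal, np.arange(0, 241, 1.0))
        g = r.glucose
        assert g.max() > ref_constants.Gb + 1.0
        peak = int(np.argmax(g))
        assert 0 < peak < len(g) - 1
        # single interior maximum: derivative changes sign exactly once
        sign_changes = np.sum(np.diff(np.sign(np.diff(g))) != 0)
        assert sign_changes <= 2
        assert abs(r.insulin[-1] - ref_constants.Ib) < 0.3 * (
            r.insulin.max() - ref_constants.Ib
        )

    def test_mass_balance(self, ref_params, ref_constants, meal):
        """Cumulative gut outflow never exceeds the bioavailable dose and
        converges to it."""
        r = simulate(ref_params, ref_constants, meal, (0.0, 1440.0), dense=True)
        fD = ref_constants.f * meal.dose_mmol
        appeared = np.array(
            [
                quad(
                    lambda t: glucose_fluxes(
                        basal_steady_state(ref_params, ref_constants),
                        t,
                        ref_params,
                        ref_constants,
                        meal,
                    ).gut_appearance,
                    0,
                    T,
                )[0]
                for T in (60.0, 240.0, 1440.0)
            ]
        )
        outflow = appeared - np.interp([60.0, 240.0, 1440.0], r.dense_times, r.dense_gut_mass)
        assert np.all(outflow <= fD * (1 + 1e-9))
        assert outflow[-1] == pytest.approx(fD, rel=5e-3)

    def test_gut_mass_nonnegative_and_depleted(self, ref_params, ref_constants, meal):
        r = simulate(ref_params, ref_constants, meal, (0.0, 1440.0), dense=True)
        assert np.all(r.dense_gut_mass >= -1e-12)
        assert r.dense_gut_mass[-1] < 0.01 * ref_constants.f * meal.dose_mmol

    def test_dose_monotonicity(self, ref_params, ref_constants):
        aucs = []
        for d in (25, 50, 75, 100):
            r = simulate(ref_params, ref_constants, MealInput(d), np.arange(0, 121, 1.0))
            aucs.append(np.trapezoid(r.glucose - ref_constants.Gb, r.times))
        assert np.all(np.diff(aucs) >= 0)

    def test_tolerance_robustness(self, ref_params, ref_constants, meal):
        a = simulate(ref_params, ref_constants, meal, (0, 30, 60, 90, 120))
        b = simulate(
            ref_params, ref_constants, meal, (0, 30, 60, 90, 120), rtol=0.5e-8, atol=0.5e-10
        )
        assert np.max(np.abs(a.glucose - b.glucose) / b.glucose) < 1e-3
        assert np.max(np.abs(a.insulin - b.insulin) / b.insulin) < 1e-3

    def test_agrees_with_scipy_integrator(self, ref_params, ref_constants, meal):
        """Independent route: scipy's adaptive RK45 on the same packed RHS."""
        times = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        r = simulate(ref_params, ref_constants, meal, times)
        pk = pack_kernel_params(ref_params, ref_constants, meal)
        y0 = basal_steady_state(ref_params, ref_constants).as_array()
        sol = solve_ivp(
            lambda t, y: _kernel.rhs_packed(t, y, pk),
            (0, 120),
            y0,
            t_eval=times,
            rtol=1e-10,
            atol=1e-12,
            max_step=5.0,
        )
        np.testing.assert_allclose(r.glucose, sol.y[1], rtol=1e-6)
        np.testing.assert_allclose(r.insulin, sol.y[2], rtol=1e-6)

    def test_invalid_times_rejected(self, ref_params, ref_constants, meal):
        with pytest.raises(ValueError):
            simulate(ref_params, ref_constants, meal, (0, 30, 30))
        with pytest.raises(ValueError):
            simulate(ref_params, ref_constants, meal, (0, 2000))


class TestBasalSteadyState:
    def test_rhs_zero_for_prior_sampled_parameters(self, ref_params, ref_constants):
        rng = np.random.default_rng(7)
        priors = default_priors(ref_params)
        for _ in range(20):
            prior = priors[rng.integers(len(priors))]
            p, Gb, Ib = sample_parameters(prior, rng, ref_params)
            c = ref_constants.with_fasting(Gb, Ib)
            st = basal_steady_state(p, c)
            assert st.plasma_glucose == Gb and st.plasma_insulin == Ib
            assert np.max(np.abs(rhs(st, 0.0, p, c, MealInput(0.0)))) < 1e-9

    def test_independent_of_meal(self, ref_params, ref_constants):
        # the pre-load equilibrium does not reference the meal at all
        st = basal_steady_state(ref_params, ref_constants)
        assert st == basal_steady_state(ref_params, ref_constants)

    def test_locally_stable_under_glucose_perturbation(self, ref_params, ref_constants):
        y0 = basal_steady_state(ref_params, ref_constants).as_array()
        y0[1] *= 1.01
        pk = pack_kernel_params(ref_params, ref_constants, MealInput(0.0))
        ys, status = _kernel.integrate(pk, y0, np.array([0.0, 240.0]), 1e-8, 1e-10, 5.0)
        assert status == 0
        assert abs(ys[-1, 1] - ref_constants.Gb) < 0.1 * abs(y0[1] - ref_constants.Gb)


class TestValidation:
    def test_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            ModelParameters(k1=-1, k2=1, k3=1, k4=1, k5=1, k6=1, k7=1, k8=1, k9=1)

    def test_constants_invariants(self):
        with pytest.raises(ValueError):
            ModelConstants(f=1.5)
        with pytest.raises(ValueError):
            ModelConstants(Gb=12.0, Gth=11.0)

    def test_simulation_error_carries_parameters(
        self, ref_params, ref_constants, meal, monkeypatch
    ):
        """An integrator failure surfaces as SimulationError carrying the
        offending parameter vector."""
        import ogtt_persona.model as model_mod

        def failing_integrate(pk, y0, t_out, rtol, atol, h_max):
            return np.zeros((len(t_out), 4)), 1

        monkeypatch.setattr(model_mod._kernel, "integrate", failing_integrate)
        with pytest.raises(SimulationError) as exc:
            simulate(ref_params, ref_constants, meal, (0, 30, 60, 90, 120))
        assert exc.value.parameters == ref_params

    def test_extreme_parameters_integrate_finite_or_fail_loudly(
        self, ref_constants, meal
    ):
        bad = ModelParameters(
            k1=0.025, k2=1e3, k3=1e3, k4=1e3, k5=1e3, k6=1e3, k7=1e3, k8=1e3, k9=1e-4
        )
        try:
            r = simulate(bad, ref_constants, meal, (0, 30, 60, 90, 120))
        except SimulationError:
            return
        assert np.all(np.isfinite(r.glucose)) and np.all(np.isfinite(r.insulin))
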