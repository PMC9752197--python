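"""Kinetics of one individual: closed-form propagation vs analytic and ODE oracles."""
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

import ebopk as e
from ebopk.errors import ContractError, InputError, ParameterError

from conftest import ode_oracle, random_params

TIMES = np.array([0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 14.0, 16.0, 24.0, 36.0])


def mixed_schedule():
    return [
        e.DoseEvent(0.0, 500.0, "IV", 1.0),
        e.DoseEvent(12.0, 500.0, "PO", 0.0, fed=True),
        e.DoseEvent(24.0, 250.0, "PO", 0.0, fed=False),
    ]


class TestSolveProfile:
    def test_no_doses_gives_zero(self, theta):
        prof = e.solve_profile(theta, [], [1.0, 2.0, 3.0])
        assert np.all(prof.conc == 0)

    def test_one_compartment_collapse(self):
        # Q2 = Q3 -> 0 reduces to mono-exponential C(t) = (D/V1) exp(-(CL/V1) t)
        p = e.StructuralParams(CL=np.log(2) * 10, V1=10, Q2=1e-9, V2=60, Q3=1e-9,
                               V3=120, ka_fed=0.6, ka_fasted=1.2)
        prof = e.solve_profile(p, [e.DoseEvent(0, 100, "IV")], [1.0, 2.0])
        assert prof.conc[0] == pytest.approx(5.0, rel=1e-6)
        assert prof.conc[1] == pytest.approx(2.5, rel=1e-6)

    def test_matches_ode_oracle_random_draws(self, rng):
        for _ in range(10):
            p = random_params(rng)
            prof = e.solve_profile(p, mixed_schedule(), TIMES)
            oracle = ode_oracle(p, mixed_schedule(), TIMES)
            np.testing.assert_allclose(prof.conc, oracle, rtol=1e-6)

    def test_dose_proportionality(self, theta):
        base = e.solve_profile(theta, mixed_schedule(), TIMES).conc
        scaled = [e.DoseEvent(d.time, 3 * d.amount, d.route, d.duration, d.fed)
                  for d in mixed_schedule()]
        np.testing.assert_allclose(e.solve_profile(theta, scaled, TIMES).conc, 3 * base,
                                   rtol=1e-12)

    def test_superposition(self, theta):
        d1 = e.DoseEvent(0.0, 500.0, "IV", 1.0)
        d2 = e.DoseEvent(6.0, 500.0, "PO", 0.0, fed=True)
        both = e.solve_profile(theta, [d1, d2], TIMES).conc
        single = (e.solve_profile(theta, [d1], TIMES).conc
                  + e.solve_profile(theta, [d2], TIMES).conc)
        np.testing.assert_allclose(both, single, rtol=1e-10, atol=1e-14)

    def test_mass_balance(self, theta):
        # eliminated drug (independent quadrature of CL*C) + drug still in the
        # body must equal the absorbed input F*D
        from ebopk.structural import _system_matrix

        dose = e.DoseEvent(0.0, 500.0, "PO", 0.0, fed=True)
        t_end = 96.0

        def conc(t):
            return e.solve_profile(theta, [dose], [t]).conc[0]

        eliminated, _ = quad(lambda t: theta.CL * conc(t), 0, t_end, limit=300)
        # total amount remaining in every compartment at t_end
        A, layout = _system_matrix(theta, (True,))
        from scipy.linalg import expm

        x0 = np.zeros(layout["m"])
        x0[layout["starts"][True]] = theta.F * dose.amount
        remaining = expm(A * t_end) @ x0
        total = eliminated + remaining.sum()
        assert total == pytest.approx(theta.F * dose.amount, rel=1e-6)

    def test_unsorted_times_rejected(self, theta):
        with pytest.raises(InputError):
            e.solve_profile(theta, [], [2.0, 1.0])

    def test_bad_params_rejected(self):
        with pytest.raises(ParameterError):
            e.StructuralParams(CL=-1, V1=30, Q2=8, V2=60, Q3=2, V3=120,
                               ka_fed=0.6, ka_fasted=1.2)
        with pytest.raises(ParameterError):
            e.StructuralParams(CL=12, V1=30, Q2=8, V2=60, Q3=2, V3=120,
                               ka_fed=0.6, ka_fasted=1.2, n_transit=-1)

    def test_fed_fasted_differ_iff_ka_differ(self, theta, rng):
        times = TIMES[TIMES > 0]
        fed = e.solve_profile(theta, [e.DoseEvent(0, 500, "PO", 0, True)], times).conc
        fast = e.solve_profile(theta, [e.DoseEvent(0, 500, "PO", 0, False)], times).conc
        assert not np.allclose(fed, fast)
        same = replace(theta, ka_fed=theta.ka_fasted)
        fed2 = e.solve_profile(same, [e.DoseEvent(0, 500, "PO", 0, True)], times).conc
        fast2 = e.solve_profile(same, [e.DoseEvent(0, 500, "PO", 0, False)], times).conc
        np.testing.assert_allclose(fed2, fast2, rtol=1e-12)


class TestTransitAbsorption:
    def test_zero_transit_is_first_order(self, rng):
        p = random_params(rng, n_transit=0)
        dose = e.DoseEvent(0.0, 200.0, "PO", 0.0, fed=False)
        t = np.array([0.1, 0.5, 1.0, 3.0])
        rate = e.transit_absorption_rate(p, dose, t)
        ka = p.ka_fasted
        expected = ka * p.F * 200.0 * np.exp(-ka * t)
        np.testing.assert_allclose(rate, expected, rtol=1e-9)

    def test_mass_conservation(self, theta):
        dose = e.DoseEvent(0.0, 500.0, "PO", 0.0, fed=True)
        total, err = quad(lambda t: e.transit_absorption_rate(theta, dose, t),
                          0, np.inf, limit=300)
        assert total == pytest.approx(theta.F * 500.0, rel=1e-8)

    def test_matches_explicit_chain_ode(self, rng):
        # n_transit = 3: 4-state absorption cascade integrated brute-force
        from scipy.integrate import solve_ivp

        p = random_params(rng, n_transit=3)
        dose = e.DoseEvent(0.0, 100.0, "PO", 0.0, fed=True)
        ktr, ka = p.transit_rate(True), p.ka_fed

        def rhs(t, x):
            return [-ktr * x[0],
                    ktr * x[0] - ktr * x[1],
                    ktr * x[1] - ktr * x[2],
                    ktr * x[2] - ka * x[3]]

        sol = solve_ivp(rhs, (0, 12), [p.F * 100.0, 0, 0, 0], rtol=1e-11, atol=1e-13,
                        dense_output=True)
        for t in (0.5, 1.0, 2.0, 6.0, 12.0):
            assert e.transit_absorption_rate(p, dose, t) == pytest.approx(
                ka * sol.sol(t)[3], rel=1e-7)

    def test_iv_dose_rejected(self, theta):
        with pytest.raises(ContractError):
            e.transit_absorption_rate(theta, e.DoseEvent(0, 100, "IV"), 1.0)


class TestSteadyState:
    def test_iv_auc_identity(self, rng):
        p = random_params(rng)
        m = e.steady_state_metrics(p, e.DoseEvent(0, 500, "IV", 1.0), 24.0)
        assert m["AUC_tau"] == pytest.approx(500.0 / p.CL, rel=1e-3)
        assert m["Cmax"] >= m["Cmin"] >= 0

    def test_po_auc_scales_with_f(self, theta):
        half = replace(theta, F=0.5)
        full = replace(theta, F=1.0)
        d = e.DoseEvent(0, 500, "PO", 0, True)
        m_half = e.steady_state_metrics(half, d, 24.0)
        m_full = e.steady_state_metrics(full, d, 24.0)
        assert m_half["AUC_tau"] / m_full["AUC_tau"] == pytest.approx(0.5, rel=1e-10)
        assert m_full["AUC_tau"] == pytest.approx(500.0 / theta.CL, rel=1e-3)

    def test_trough_matches_long_run_superposition(self):
        # terminal phase fast enough that 20 doses reach steady state
        p = e.StructuralParams(CL=12, V1=30, Q2=8, V2=50, Q3=4, V3=40,
                               ka_fed=0.6, ka_fasted=1.2, ktr=1.5, F=0.85)
        d = e.DoseEvent(0, 500, "PO", 0, True)
        m = e.steady_state_metrics(p, d, 24.0)
        doses = [e.DoseEvent(24.0 * k, 500, "PO", 0, True) for k in range(20)]
        trough = e.solve_profile(p, doses, [480.0 - 1e-9]).conc[0]
        assert trough == pytest.approx(m["Ctrough"], rel=1e-4)

    def test_bad_interval_rejected(self, theta):
        with pytest.raises(InputError):
            e.steady_state_metrics(theta, e.DoseEvent(0, 500, "IV", 1.0), 0.0)
        with pytest.raises(InputError):
            e.steady_state_metrics(theta, e.DoseEvent(30.0, 500, "IV", 1.0), 24.0)
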