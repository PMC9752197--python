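"""Marginal-likelihood objective, fitting contracts, EBEs and shrinkage."""
import numpy as np
import pandas as pd
import pytest

import ebopk as e
from ebopk.dataio import PKDataset
from ebopk.errors import FitError
from ebopk.estimation import PARAM_NAMES, eta_shrinkage
from ebopk.laplace import laplace_m2ll


def small_dataset(truth, seed=3, n_iv=6, n_po=6):
    roster = e.recovery_program(n_iv=n_iv, n_po_fed=n_po, n_po_fasted=0)
    return e.generate(roster, truth, seed=seed)


class TestLaplaceEngine:
    def test_exact_on_linear_mixed_model(self):
        """Log-scale one-compartment decay with an additive random slope is a
        linear mixed model; the Laplace objective must equal the closed-form
        marginal multivariate-normal -2 log L."""
        rng = np.random.default_rng(12)
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0])
        b0, k, w, s2 = 2.5, 0.15, 0.05, 0.02
        for _ in range(5):
            y = b0 - (k + rng.normal(0, np.sqrt(w))) * t + rng.normal(0, np.sqrt(s2), t.size)

            def nll2(eta):
                r = y - (b0 - (k + eta[0]) * t)
                return float(np.sum(r * r / s2 + np.log(2 * np.pi * s2)))

            ofv, eta_hat, ok = laplace_m2ll(nll2, np.array([w]))
            S = s2 * np.eye(t.size) + w * np.outer(t, t)
            r = y - (b0 - k * t)
            _, logdet = np.linalg.slogdet(2 * np.pi * S)
            closed = float(r @ np.linalg.solve(S, r) + logdet)
            assert ok
            assert ofv == pytest.approx(closed, abs=1e-4)

    def test_zero_dimensional_prior_is_exact_nll(self):
        y = np.array([1.0, 2.0])
        val, eta, ok = laplace_m2ll(lambda _: float(np.sum(y**2)), np.zeros(0))
        assert val == pytest.approx(5.0)
        assert eta.size == 0


class TestConditionalObjective:
    def test_degenerate_hierarchy_equals_weighted_least_squares(self, truth):
        """With omega -> 0 and additive-only error the objective collapses to
        the fixed-effect weighted residual sum of squares plus log-variance
        terms, computable by hand."""
        pop = truth.replace(omega_cl=0.0, omega_f=0.0, sigma_prop=0.0, sigma_add=0.4)
        data = small_dataset(truth, seed=21, n_iv=4, n_po=3)
        ofv = e.conditional_objective(pop, data)

        s2 = 0.4**2
        expected = 0.0
        for rec in data.subjects():
            subj = e.Subject(rec.id, rec.wt)
            p = e.individual_params(pop, subj, np.zeros(2))
            c = e.ProfileEvaluator(rec.doses, rec.obs_times).conc(p)
            expected += float(np.sum((rec.dv - c) ** 2 / s2 + np.log(2 * np.pi * s2)))
        assert ofv == pytest.approx(expected, rel=1e-10)

    def test_duplicating_subjects_doubles_ofv(self, truth):
        data = small_dataset(truth, seed=8, n_iv=3, n_po=3)
        ofv1 = e.conditional_objective(truth, data)
        df2 = data.df.copy()
        df2["ID"] = df2["ID"] + 10_000
        doubled = PKDataset(pd.concat([data.df, df2], ignore_index=True))
        ofv2 = e.conditional_objective(truth, doubled)
        assert ofv2 == pytest.approx(2 * ofv1, rel=1e-8)

    def test_invariant_to_subject_order_and_relabelling(self, truth):
        data = small_dataset(truth, seed=8, n_iv=3, n_po=3)
        ofv1 = e.conditional_objective(truth, data)
        df = data.df.copy()
        df["__order"] = -df["ID"]
        df = df.sort_values(["__order", "TIME", "EVID"], kind="stable").drop(columns="__order")
        df["ID"] = df["ID"].map(lambda i: f"subj-{i}")
        ofv2 = e.conditional_objective(truth, PKDataset(df.reset_index(drop=True)))
        assert ofv2 == pytest.approx(ofv1, rel=1e-9)


class TestFit:
    def test_all_fixed_returns_init_with_ofv(self, truth):
        data = small_dataset(truth, seed=5, n_iv=3, n_po=3)
        res = e.fit(data, truth, fixed="all")
        assert res.pop == truth
        assert res.converged
        assert res.ofv == pytest.approx(e.conditional_objective(truth, data), rel=1e-9)

    def test_init_at_truth_barely_improves(self, truth):
        data = small_dataset(truth, seed=19, n_iv=8, n_po=8)
        fixed = set(PARAM_NAMES) - {"CL", "omega_CL"}
        res = e.fit(data, truth, fixed=fixed)
        assert res.ofv <= res.ofv_init
        assert res.ofv_init - res.ofv < 2.0

    def test_freeing_a_parameter_never_hurts(self, truth):
        data = small_dataset(truth, seed=23, n_iv=6, n_po=6)
        init = truth.replace(theta_kw={"CL": truth.theta.CL * 1.2})
        fixed_small = set(PARAM_NAMES) - {"CL"}
        fixed_large = set(PARAM_NAMES) - {"CL", "omega_CL"}
        restricted = e.fit(data, init, fixed=fixed_small)
        freed = e.fit(data, init, fixed=fixed_large)
        assert freed.ofv <= restricted.ofv + 0.1

    def test_unknown_fixed_name_rejected(self, truth):
        data = small_dataset(truth, seed=5, n_iv=2, n_po=2)
        with pytest.raises(FitError):
            e.fit(data, truth, fixed={"CLX"})

    def test_iv_only_data_fixes_bioavailability(self, truth):
        data = small_dataset(truth, seed=5, n_iv=5, n_po=0)
        fixed = set(PARAM_NAMES) - {"CL", "F", "omega_F"}
        with pytest.warns(UserWarning, match="not identifiable"):
            res = e.fit(data, truth, fixed=fixed)
        assert "F" in res.fixed and "omega_F" in res.fixed
        assert res.pop.theta.F == truth.theta.F

    def test_no_observations_rejected(self, truth):
        df = small_dataset(truth, seed=5, n_iv=2, n_po=0).df
        df = df[df["EVID"] == 1].reset_index(drop=True)
        with pytest.raises(FitError):
            e.fit(PKDataset(df), truth, fixed="all")


class TestShrinkage:
    def test_degenerate_values(self):
        assert eta_shrinkage(np.zeros(50), 0.04) == pytest.approx(100.0)
        rng = np.random.default_rng(4)
        draws = rng.standard_normal(200_000) * 0.2
        assert eta_shrinkage(draws, 0.04) == pytest.approx(0.0, abs=1.0)

    def test_omega_zero_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(eta_shrinkage(np.zeros(10), 0.0))

    def test_sparse_design_shrinks_more_than_rich(self, truth):
        rich_times = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 16.0, 24.0, 36.0)
        sparse_times = (2.0, 24.0)

        def program(times):
            return e.ProgramRoster((e.StudyDesign(
                "S", 1, 40, doses=(e.DoseEvent(0, 500, "IV", 1.0),),
                sample_times=times,
            ),))

        rich = e.generate(program(rich_times), truth, seed=31)
        sparse = e.generate(program(sparse_times), truth, seed=31)
        shr_rich = eta_shrinkage(e.ebes(truth, rich)["eta_CL"].to_numpy(), truth.omega_cl)
        shr_sparse = eta_shrinkage(e.ebes(truth, sparse)["eta_CL"].to_numpy(), truth.omega_cl)
        assert shr_sparse > shr_rich
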