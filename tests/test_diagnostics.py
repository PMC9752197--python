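"""pcVPC correction, binning, determinism; goodness-of-fit residuals."""
import numpy as np
import pandas as pd
import pytest

import ebopk as e
from ebopk.dataio import PKDataset
from ebopk.diagnostics import make_time_bins

PO_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)


def po_program(n, dose=500.0):
    return e.ProgramRoster((e.StudyDesign(
        "VPC", 1, n, doses=(e.DoseEvent(0, dose, "PO", 0, True),),
        sample_times=PO_TIMES,
    ),))


class TestPredictionCorrect:
    def test_identity_when_pred_uniform(self):
        dv = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, 5.0)
        np.testing.assert_allclose(e.prediction_correct(dv, pred, pred), dv)

    def test_halved_when_pred_double_of_ref(self):
        out = e.prediction_correct(np.array([4.0]), np.array([10.0]), np.array([5.0]))
        assert out[0] == pytest.approx(2.0)

    def test_nonpositive_pred_flagged_nan(self):
        out = e.prediction_correct(np.array([1.0, 1.0]), np.array([0.0, 2.0]),
                                   np.array([1.0, 1.0]))
        assert np.isnan(out[0]) and np.isfinite(out[1])

    def test_dose_groups_coincide_after_correction(self, truth):
        """Linear kinetics, no IIV, no noise: 100 mg and 500 mg arms must give
        identical prediction-corrected values."""
        pop = truth.replace(omega_cl=0.0, omega_f=0.0, sigma_prop=1e-9, sigma_add=0.0)
        lo = e.generate(po_program(10, dose=100.0), pop, seed=2).df
        hi = e.generate(po_program(10, dose=500.0), pop, seed=2).df
        hi["ID"] = hi["ID"] + 1000
        hi["STUDY"] = "VPC-HI"
        data = PKDataset(pd.concat([lo, hi], ignore_index=True))
        res = e.run_pcvpc(pop, data, n_sim=100, seed=1, target_bins=5)
        # per-bin observed percentiles collapse: p5 == p95 across pooled groups
        for _, g in res.table.groupby("bin"):
            vals = g.set_index("percentile")["observed"]
            assert vals[5.0] == pytest.approx(vals[95.0], rel=1e-6)

    def test_pcvpc_invariant_to_subgroup_dose_rescaling(self, truth):
        pop = truth.replace(omega_cl=0.0, omega_f=0.0, sigma_prop=1e-9, sigma_add=0.0)
        base = e.generate(po_program(20, dose=250.0), pop, seed=3).df
        rescaled = base.copy()
        half = rescaled["ID"] <= base["ID"].median()
        dose_rows = rescaled["EVID"] == 1
        rescaled.loc[half & dose_rows, "AMT"] *= 4
        rescaled.loc[half & (~dose_rows), "DV"] *= 4
        r1 = e.run_pcvpc(pop, PKDataset(base), n_sim=100, seed=5, target_bins=4)
        r2 = e.run_pcvpc(pop, PKDataset(rescaled), n_sim=100, seed=5, target_bins=4)
        # the bin reference rescales observed and simulated sides alike, so the
        # position of the observed percentile inside its band is unchanged
        np.testing.assert_allclose(r1.table["observed"] / r1.table["band_mid"],
                                   r2.table["observed"] / r2.table["band_mid"],
                                   rtol=1e-9)


class TestRunPcvpc:
    def test_same_seed_is_bit_identical(self, truth, tmp_path):
        data = e.generate(po_program(20), truth, seed=6)
        r1 = e.run_pcvpc(truth, data, n_sim=100, seed=42)
        r2 = e.run_pcvpc(truth, data, n_sim=100, seed=42)
        p1, p2 = tmp_path / "v1.csv", tmp_path / "v2.csv"
        r1.to_csv(p1)
        r2.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bands_ordered_and_bins_partition(self, truth):
        data = e.generate(po_program(30), truth, seed=6)
        res = e.run_pcvpc(truth, data, n_sim=100, seed=0)
        t = res.table
        assert (t["band_lo"] <= t["band_mid"]).all()
        assert (t["band_mid"] <= t["band_hi"]).all()
        obs_times = data.df.loc[data.df["EVID"] == 0, "TIME"]
        assert res.bin_edges[0] <= obs_times.min()
        assert res.bin_edges[-1] >= obs_times.max()
        assert (t.groupby("bin")["n_obs"].first() >= 10).all()

    def test_min_nsim_enforced(self, truth):
        data = e.generate(po_program(10), truth, seed=6)
        with pytest.raises(e.InputError):
            e.run_pcvpc(truth, data, n_sim=50, seed=0)


class TestBinning:
    def test_quantile_bins_respect_minimum(self, rng):
        times = rng.uniform(0, 48, size=200)
        edges = make_time_bins(times, target_bins=8, min_per_bin=10)
        counts, _ = np.histogram(times, bins=edges)
        assert counts.sum() == 200
        assert (counts >= 10).all()

    def test_tiny_sample_collapses_to_one_bin(self):
        edges = make_time_bins(np.array([1.0, 2.0, 3.0]), target_bins=8, min_per_bin=10)
        assert edges.size == 2


class TestGofResiduals:
    def test_additive_only_no_iiv_is_ordinary_standardised_residuals(self, truth):
        pop = truth.replace(omega_cl=0.0, omega_f=0.0, sigma_prop=0.0, sigma_add=0.3)
        data = e.generate(po_program(8), pop, seed=9)
        tab = e.gof_residuals(pop, data)
        np.testing.assert_allclose(tab["PRED"], tab["IPRED"], rtol=1e-12)
        manual = (tab["DV"] - tab["PRED"]) / 0.3
        np.testing.assert_allclose(tab["IWRES"], manual, rtol=1e-10)
        np.testing.assert_allclose(tab["CWRES"], manual, rtol=1e-10)

    def test_zero_residual_gives_zero_iwres(self, truth):
        pop = truth.replace(omega_cl=0.0, omega_f=0.0)
        data = e.generate(po_program(3), pop, seed=9)
        pred = e.gof_residuals(pop, data)["PRED"].to_numpy()
        df = data.df.copy()
        df.loc[df["EVID"] == 0, "DV"] = pred  # observation exactly at prediction
        tab = e.gof_residuals(pop, PKDataset(df))
        np.testing.assert_allclose(tab["IWRES"], 0.0, atol=1e-12)

    def test_cwres_calibrated_on_self_simulated_data(self, truth):
        data = e.generate(e.recovery_program(n_iv=40, n_po_fed=30, n_po_fasted=30),
                          truth, seed=13)
        tab = e.gof_residuals(truth, data)
        assert abs(tab["CWRES"].mean()) < 0.1
        assert 0.85 < tab["CWRES"].std() < 1.15
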