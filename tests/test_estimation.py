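"""FOCE-I engine: conditional objective, OFV against a quadrature oracle,
EBE recovery/shrinkage, and the descent property of the fit."""

import numpy as np
import pandas as pd
import pytest

import dexpop as dp
from dexpop.dataio import COLUMNS, AnalysisDataset, flag_blq
from dexpop.estimation import CompiledDataset, LOG_2PI
from oracles import gauss_hermite_neg2ll

TIMES = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])


def tiny_study(model, n, seed, times=TIMES):
    return dp.generate_single_arm(model, n=n, dose=100.0, times=times, seed=seed)


def subject_dataset(model, dv, times=TIMES, bw=60.0):
    base = dict(ID=1, BW=bw, AGE=40.0, SEX=0, BMI=23.0, BSA=1.7, STATE=1,
                STUDY="phase3")
    rows = [dict(base, TIME=0.0, AMT=100.0, RATE=0.0, DV=np.nan, EVID=1,
                 MDV=1, CMT=1, BLQ=0)]
    for t, y in zip(times, dv):
        rows.append(dict(base, TIME=float(t), AMT=0.0, RATE=0.0, DV=float(y),
                         EVID=0, MDV=0, CMT=2, BLQ=0))
    return AnalysisDataset(flag_blq(pd.DataFrame(rows)[COLUMNS], 0.0), 0.0)


def noise_free_prediction(model, cov, eta=(0.0, 0.0), times=TIMES):
    p = dp.individual_params(model.theta, cov, eta, model.allometric)
    return dp.conc_profile(p, [dp.DoseEvent(0.0, 100.0, "intranasal")], times)


class TestConditionalObjective:
    def test_zero_residual_data_leaves_only_log_variance_terms(self, model, patient_cov):
        pred = noise_free_prediction(model, patient_cov)
        ds = subject_dataset(model, pred)
        value = dp.subject_conditional_objective(ds, model, (0.0, 0.0))
        v = dp.residual_variance(pred, model.sigma, "combined")
        om = model.omega
        expected = float(np.sum(np.log(v))) + np.log(
            om.omega_cl**2 * om.omega_ka**2
        )
        assert value == pytest.approx(expected, rel=1e-10)

    def test_optimized_eta_not_worse_than_zero(self, model, patient_cov):
        rng = np.random.default_rng(4)
        pred = noise_free_prediction(model, patient_cov, eta=(0.25, -0.4))
        dv = dp.simulate_observation(pred, model.sigma, "combined", rng)
        ds = subject_dataset(model, np.maximum(dv, 0.1))
        ebes = dp.estimate_ebes(ds, model)
        at_hat = dp.subject_conditional_objective(
            ds, model, tuple(ebes.iloc[0][["eta_cl", "eta_ka"]])
        )
        at_zero = dp.subject_conditional_objective(ds, model, (0.0, 0.0))
        assert at_hat <= at_zero + 1e-9

    def test_singular_omega_instructive_error(self, model, patient_cov):
        pred = noise_free_prediction(model, patient_cov)
        ds = subject_dataset(model, pred)
        bad = model.with_updates(omega=dp.OmegaMatrix(0.0, 0.0))
        with pytest.raises(ValueError, match="[Ss]ingular"):
            dp.subject_conditional_objective(ds, bad, (0.0, 0.0))


class TestOfvOracles:
    def test_matches_gauss_hermite_quadrature(self, model):
        # moderate IIV keeps the intrinsic Laplace error well inside the
        # window, so any formula mistake (missing log-det, wrong
        # interaction term) would show up as a gross miss
        model = model.with_updates(omega=dp.OmegaMatrix(0.1, 0.15))
        study = tiny_study(model, n=3, seed=11)
        ds = study.dataset
        value = dp.ofv(ds, model)

        c = CompiledDataset(ds)
        subjects = []
        for sid in c.ids:
            cov = ds.subject_covariates(sid)
            rows = ds.observations()
            rows = rows[rows["ID"] == sid]
            y = rows["DV"].to_numpy(dtype=float)
            t = rows["TIME"].to_numpy(dtype=float)

            def predict(eta, cov=cov, t=t):
                f = noise_free_prediction(model, cov, eta=tuple(eta), times=t)
                v = dp.residual_variance(f, model.sigma, "combined")
                return f, v

            subjects.append({"y": y, "predict": predict})
        oracle = gauss_hermite_neg2ll(
            subjects, (model.omega.omega_cl, model.omega.omega_ka), n_nodes=80
        )
        assert value == pytest.approx(oracle, abs=0.5)

    def test_omega_zero_collapses_to_weighted_least_squares(self, model):
        fixed_model = model.with_updates(omega=dp.OmegaMatrix(0.0, 0.0))
        study = tiny_study(fixed_model, n=5, seed=12)
        ds = study.dataset
        value = dp.ofv(ds, fixed_model)
        # independent ELS objective via the scalar structural API
        total = 0.0
        for sid in ds.subject_ids:
            cov = ds.subject_covariates(sid)
            rows = ds.observations()
            rows = rows[rows["ID"] == sid]
            f = noise_free_prediction(
                model, cov, times=rows["TIME"].to_numpy(dtype=float)
            )
            v = dp.residual_variance(f, model.sigma, "combined")
            r = rows["DV"].to_numpy(dtype=float) - f
            total += float(np.sum(LOG_2PI + np.log(v) + r**2 / v))
        assert value == pytest.approx(total, rel=1e-9)


class TestEbes:
    def test_recovery_on_rich_design(self, model, patient_cov):
        quiet = model.with_updates(sigma=dp.SigmaPair(0.05, 0.5))
        rich_times = np.array([0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 10, 12])
        rng = np.random.default_rng(21)
        pred = noise_free_prediction(
            quiet, patient_cov, eta=(0.3, 0.0), times=rich_times
        )
        dv = dp.simulate_observation(pred, quiet.sigma, "combined", rng)
        ds = subject_dataset(quiet, dv, times=rich_times)
        ebes = dp.estimate_ebes(ds, quiet)
        assert ebes.iloc[0]["eta_cl"] == pytest.approx(0.3, abs=0.05)

    def test_self_consistency_with_tiny_error(self, model, patient_cov):
        quiet = model.with_updates(sigma=dp.SigmaPair(0.001, 0.01))
        pred = noise_free_prediction(quiet, patient_cov)
        ds = subject_dataset(quiet, pred)
        ebes = dp.estimate_ebes(ds, quiet)
        assert abs(ebes.iloc[0]["eta_cl"]) < 0.01
        assert abs(ebes.iloc[0]["eta_ka"]) < 0.01

    def test_shrinkage_increases_as_sampling_thins(self, model):
        rich = tiny_study(model, n=100, seed=31,
                          times=np.array([0.25, 0.5, 1, 2, 3, 4, 6, 8, 10, 12]))
        sparse = tiny_study(model, n=100, seed=32, times=np.array([0.5, 4.0]))
        e_rich = dp.estimate_ebes(rich.dataset, model)
        e_sparse = dp.estimate_ebes(sparse.dataset, model)
        # EBEs are pulled toward zero relative to each study's own truth,
        # more strongly under the two-sample design
        ratio_rich = (
            np.abs(e_rich["eta_cl"]).mean() / np.abs(rich.truth["eta_cl"]).mean()
        )
        ratio_sparse = (
            np.abs(e_sparse["eta_cl"]).mean()
            / np.abs(sparse.truth["eta_cl"]).mean()
        )
        assert np.abs(e_sparse["eta_cl"]).mean() < np.abs(
            sparse.truth["eta_cl"]
        ).mean()
        assert ratio_sparse < ratio_rich


class TestFit:
    def test_descent_from_generating_values(self, model):
        study = tiny_study(model, n=16, seed=41)
        ds = study.dataset
        fixed = {"vc", "q", "vp", "state_ka", "f1", "alag",
                 "omega_ka", "sigma_add"}
        res = dp.fit(ds, model, fixed=fixed)
        assert res.ofv <= dp.ofv(ds, model) + 1e-6
        assert res.n_subjects == 16
        assert set(res.ebes.columns) >= {"eta_cl", "eta_ka"}

    def test_no_iv_arm_fixes_bioavailability(self, model):
        study = tiny_study(model, n=6, seed=42)
        with pytest.warns(UserWarning, match="no IV arm"):
            res = dp.fit(
                ds := study.dataset, model,
                fixed={"vc", "q", "vp", "ka", "state_ka", "omega_cl",
                       "omega_ka", "sigma_prop", "sigma_add"},
            )
        assert res.theta.f1_pop == model.theta.f1_pop
        assert res.theta.alag_pop == model.theta.alag_pop

    def test_deterministic_given_data_and_init(self, model):
        study = tiny_study(model, n=8, seed=43)
        fixed = {"vc", "q", "vp", "ka", "state_ka", "f1", "alag",
                 "omega_ka", "sigma_add"}
        r1 = dp.fit(study.dataset, model, fixed=fixed)
        r2 = dp.fit(study.dataset, model, fixed=fixed)
        assert r1.ofv == r2.ofv
        assert r1.theta == r2.theta
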