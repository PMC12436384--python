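"""Synthetic study designs: covariate distributions, sampling layouts,
sedation linkage and determinism."""

import numpy as np
import pytest

import dexpop as dp
from dexpop.exposure_response import prob_at
from dexpop.synthetic import (
    PHASE1_COVARIATES,
    PHASE3_COVARIATES,
    RSS_TIMES,
    SCHEDULE_NASAL,
)


class TestCovariates:
    def test_phase3_bw_distribution(self):
        rng = np.random.default_rng(10)
        covs = dp.generate_covariates(PHASE3_COVARIATES, 10_000, rng)
        bw = np.array([c.bw for c in covs])
        assert np.median(bw) == pytest.approx(60.0, abs=3.0)
        assert bw.min() >= 46.0 and bw.max() <= 97.0

    def test_body_size_latent_correlation(self):
        rng = np.random.default_rng(11)
        covs = dp.generate_covariates(PHASE3_COVARIATES, 3000, rng)
        bw = np.array([c.bw for c in covs])
        bsa = np.array([c.bsa for c in covs])
        assert np.corrcoef(bw, bsa)[0, 1] > 0.8

    def test_sex_split_matches_ratio(self):
        rng = np.random.default_rng(12)
        covs = dp.generate_covariates(PHASE3_COVARIATES, 148, rng)
        assert sum(c.sex for c in covs) == 108

    def test_single_subject(self):
        rng = np.random.default_rng(13)
        [cov] = dp.generate_covariates(PHASE1_COVARIATES, 1, rng,
                                       study="phase1_part1")
        assert 45.2 <= cov.bw <= 82.0
        assert cov.is_hv


class TestPhase1(object):
    def test_arm_sizes_and_sampling_layout(self, model):
        study = dp.generate_phase1(model, seed=14)
        rec = study.dataset.records
        counts = rec.groupby("STUDY")["ID"].nunique()
        assert counts["phase1_part1"] == 24
        assert counts["phase1_part2"] == 12
        assert counts["phase1_part3"] == 12
        part2 = rec[(rec["STUDY"] == "phase1_part2") & (rec["EVID"] == 0)]
        per_subject = part2.groupby("ID").size()
        # predose + 17 post-dose samples out to 24 h
        assert (per_subject == len(SCHEDULE_NASAL) + 1).all()
        assert (per_subject == 18).all()

    def test_part3_is_a_split_dose(self, model):
        study = dp.generate_phase1(model, seed=15)
        doses = study.dataset.doses()
        part3 = doses[doses["STUDY"] == "phase1_part3"]
        assert (part3.groupby("ID")["AMT"].sum() == 120.0).all()
        assert (part3["TIME"] == 0.0).all()

    def test_noise_free_generation_matches_closed_form(self, model):
        quiet = model.with_updates(
            omega=dp.OmegaMatrix(0.0, 0.0), sigma=dp.SigmaPair(0.0, 1e-30)
        )
        study = dp.generate_phase1(quiet, seed=16)
        ds = study.dataset
        obs = ds.observations()
        sid = obs[obs["STUDY"] == "phase1_part2"]["ID"].iloc[0]
        rows = obs[obs["ID"] == sid]
        p = dp.individual_params(
            quiet.theta, ds.subject_covariates(sid), (0.0, 0.0),
            quiet.allometric,
        )
        pred = dp.conc_profile(
            p, [dp.DoseEvent(0.0, 150.0, "intranasal")],
            rows["TIME"].to_numpy(dtype=float),
        )
        np.testing.assert_allclose(rows["DV"].to_numpy(dtype=float), pred,
                                   rtol=1e-9)


class TestPhase3:
    def test_two_observations_per_subject(self, model):
        study = dp.generate_phase3(model, dp.PUBLISHED_ER, seed=17)
        obs = study.dataset.observations()
        assert study.dataset.n_subjects == 148
        assert (obs.groupby("ID").size() == 2).all()

    def test_first_sample_tracks_sedation_onset(self, model):
        study = dp.generate_phase3(model, dp.PUBLISHED_ER, seed=18)
        obs = study.dataset.observations()
        first = obs.groupby("ID")["TIME"].min()
        onset = study.truth["t_rss3"].fillna(RSS_TIMES[-1])
        assert (first.to_numpy() >= onset.to_numpy() - 1e-12).all()
        assert (first.to_numpy() <= onset.to_numpy() + 5.0 / 60.0 + 1e-12).all()

    def test_higher_dose_sedates_more(self, model):
        study = dp.generate_phase3(model, dp.PUBLISHED_ER, n=600, seed=19)
        truth = study.truth
        p75 = truth.loc[truth["dose"] == 75.0, "success"].mean()
        p100 = truth.loc[truth["dose"] == 100.0, "success"].mean()
        assert p100 > p75

    def test_marginal_success_rate_matches_logistic_law(self, model):
        # single latent uniform per subject: P(success) must equal the
        # logistic probability at the full 45-min Cmax on average
        study = dp.generate_phase3(model, dp.PUBLISHED_ER, n=400, seed=20)
        truth = study.truth
        ds = study.dataset
        probs = []
        for sid, row in truth.iterrows():
            p = dp.individual_params(
                model.theta, ds.subject_covariates(sid),
                (row["eta_cl"], row["eta_ka"]), model.allometric,
            )
            cm = dp.cmax45(p, [dp.DoseEvent(0.0, row["dose"], "intranasal")])
            probs.append(prob_at(dp.PUBLISHED_ER, cm))
        expected = float(np.mean(probs))
        observed = float(truth["success"].mean())
        se = np.sqrt(expected * (1 - expected) / len(truth))
        assert observed == pytest.approx(expected, abs=4 * se)


class TestFullStudy:
    def test_cohort_composition(self, full_study):
        ds = full_study.dataset
        assert ds.n_subjects == 196
        cov = ds.covariates()
        assert (cov["STUDY"] == "phase3").sum() == 148

    def test_blq_fraction_near_one_percent(self, full_study):
        obs = full_study.dataset.observations()
        frac = obs["BLQ"].mean()
        assert 0.002 < frac < 0.035

    def test_same_seed_byte_identical_csv(self, model, tmp_path):
        a = dp.generate_full_study(model, dp.PUBLISHED_ER, seed=21)
        b = dp.generate_full_study(model, dp.PUBLISHED_ER, seed=21)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        dp.write_dataset(a.dataset, pa)
        dp.write_dataset(b.dataset, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_round_trips_through_dataio(self, full_study, tmp_path):
        path = tmp_path / "full.csv"
        dp.write_dataset(full_study.dataset, path)
        again = dp.read_dataset(path, lloq=full_study.dataset.lloq)
        assert again.n_subjects == 196
        assert again.n_observations == full_study.dataset.n_observations
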