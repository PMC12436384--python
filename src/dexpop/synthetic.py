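"""Virtual-study generator.

The real concentration data behind the published model are confidential,
so this module generates stand-in studies with the same designs: a rich
phase I (IV infusion and intranasal arms in healthy volunteers, fixed
sampling grids out to 10-24 h) and a sparse phase III (patients, single
intranasal dose, two samples whose first timing is linked to sedation
onset).  Covariates are drawn to match the published baseline table;
concentrations come from the final population model with lognormal IIV
on CL and KA and combined residual error; sedation outcomes are driven
by the exposure-response logistic model through a single latent uniform
per subject, so the marginal success probability at the 45-min Cmax is
exactly the logistic curve while sedation onset occurs at the first
assessment whose running Cmax crosses the subject's latent threshold.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import (
    COLUMNS,
    DEFAULT_LLOQ,
    STATE_HV,
    STATE_PATIENT,
    AnalysisDataset,
    SubjectCovariates,
    flag_blq,
)
from .exposure_response import ErFit, ErRecord, prob_at
from .population import ModelConfig, individual_params, simulate_observation
from .structural import DoseEvent, cmax_in_window, conc_profile

#: phase I sampling grid (h): predose handled separately
SCHEDULE_IV = np.array(
    [5, 10, 15, 20, 30, 45], dtype=float
) / 60.0
SCHEDULE_IV = np.concatenate([SCHEDULE_IV, [1, 1.5, 2, 3, 4, 6, 8, 10]])
SCHEDULE_NASAL = np.concatenate([SCHEDULE_IV, [12.0, 16.0, 24.0]])

#: RSS sedation assessment times (h) in the sparse study
RSS_TIMES = (0.25, 0.5, 0.75)

IV_INFUSION_DURATION = 0.25  # h


@dataclass(frozen=True)
class CovariateSpec:
    """Per-study covariate distributions (published baseline table)."""

    study_state: int
    bw_median: float          # kg
    bw_range: tuple[float, float]
    bw_log_sd: float          # SD of log BW before truncation
    age_range: tuple[float, float]
    female_fraction: float
    bmi_range: tuple[float, float]


PHASE1_COVARIATES = CovariateSpec(
    study_state=STATE_HV,
    bw_median=57.65, bw_range=(45.2, 82.0), bw_log_sd=0.12,
    age_range=(18.0, 38.0), female_fraction=0.5,
    bmi_range=(19.18, 24.80),
)
PHASE3_COVARIATES = CovariateSpec(
    study_state=STATE_PATIENT,
    bw_median=60.0, bw_range=(46.0, 97.0), bw_log_sd=0.15,
    age_range=(20.0, 65.0), female_fraction=108.0 / 148.0,
    bmi_range=(18.6, 29.9),
)


def _du_bois_bsa(bw: np.ndarray, height_m: np.ndarray) -> np.ndarray:
    return 0.007184 * (height_m * 100.0) ** 0.725 * bw**0.425


def generate_covariates(
    spec: CovariateSpec, n: int, rng: np.random.Generator, study: str = "phase3"
) -> list[SubjectCovariates]:
    """Draw n subjects' baseline covariates.

    BW is truncated lognormal around the published median; AGE uniform
    over the published range; sex split deterministically at the
    published ratio; BSA derived by Du Bois from BW and a height
    back-solved from a uniformly sampled BMI.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = spec.bw_range
    bw = np.empty(n)
    filled = 0
    while filled < n:
        draw = np.exp(rng.normal(np.log(spec.bw_median), spec.bw_log_sd, size=2 * n))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        bw[filled: filled + draw.size] = draw
        filled += draw.size
    age = rng.uniform(*spec.age_range, size=n)
    n_female = int(round(n * spec.female_fraction))
    sex = np.zeros(n, dtype=int)
    sex[:n_female] = 1
    rng.shuffle(sex)
    bmi = rng.uniform(*spec.bmi_range, size=n)
    height = np.sqrt(bw / bmi)
    bsa = _du_bois_bsa(bw, height)
    return [
        SubjectCovariates(
            bw=float(bw[i]), age=float(age[i]), sex=int(sex[i]),
            bmi=float(bmi[i]), bsa=float(bsa[i]),
            state=spec.study_state, study=study,
        )
        for i in range(n)
    ]


def _rows_for_subject(
    sid: int,
    cov: SubjectCovariates,
    dose_rows: list[dict],
    obs_times: np.ndarray,
    dv: np.ndarray,
    mdv: np.ndarray,
) -> list[dict]:
    base = {
        "ID": sid, "BW": cov.bw, "AGE": cov.age, "SEX": cov.sex,
        "BMI": cov.bmi, "BSA": cov.bsa, "STATE": cov.state, "STUDY": cov.study,
    }
    rows = []
    for t, y, m in zip(obs_times, dv, mdv):
        if t == 0.0:  # predose observation rows come before the dose
            rows.append(dict(base, TIME=float(t), AMT=0.0, RATE=0.0,
                             DV=(np.nan if m else float(y)), EVID=0,
                             MDV=int(m), CMT=2, BLQ=0))
    for d in dose_rows:
        rows.append(dict(base, **d))
    for t, y, m in zip(obs_times, dv, mdv):
        if t > 0.0:
            rows.append(dict(base, TIME=float(t), AMT=0.0, RATE=0.0,
                             DV=(np.nan if m else float(y)), EVID=0,
                             MDV=int(m), CMT=2, BLQ=0))
    return rows


@dataclass
class GeneratedStudy:
    """A simulated dataset plus the generating truth (for recovery tests)."""

    dataset: AnalysisDataset
    truth: pd.DataFrame                 # per subject: eta_cl, eta_ka, ...
    er_records: list[ErRecord] | None = None


def _simulate_subject_obs(
    model: ModelConfig,
    cov: SubjectCovariates,
    eta: tuple[float, float],
    regimen: list[DoseEvent],
    times: np.ndarray,
    rng: np.random.Generator,
):
    p = individual_params(
        model.theta, cov, eta, model.allometric, model.extra_effects
    )
    pred = conc_profile(p, regimen, times)
    dv = simulate_observation(pred, model.sigma, model.residual_model, rng)
    return p, dv


def generate_phase1(
    model: ModelConfig,
    seed: int | np.random.Generator = 0,
    lloq: float = DEFAULT_LLOQ,
    start_id: int = 1,
) -> GeneratedStudy:
    """Rich-sampling healthy-volunteer study.

    Part 1: 12 + 12 subjects, IV 20/40 ug over 15 min; part 2: 12
    subjects, intranasal 150 ug; part 3: 12 subjects, two simultaneous
    intranasal doses of 100 + 20 ug.  Fixed sampling grids with a predose
    (missing-DV) row per subject.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    arms = (
        [("phase1_part1", [DoseEvent(0.0, 20.0, "iv_infusion", IV_INFUSION_DURATION)],
          SCHEDULE_IV)] * 12
        + [("phase1_part1", [DoseEvent(0.0, 40.0, "iv_infusion", IV_INFUSION_DURATION)],
            SCHEDULE_IV)] * 12
        + [("phase1_part2", [DoseEvent(0.0, 150.0, "intranasal")], SCHEDULE_NASAL)] * 12
        + [("phase1_part3",
            [DoseEvent(0.0, 100.0, "intranasal"), DoseEvent(0.0, 20.0, "intranasal")],
            SCHEDULE_NASAL)] * 12
    )
    covs = generate_covariates(PHASE1_COVARIATES, len(arms), rng, study="phase1_part1")
    all_rows: list[dict] = []
    truth_rows = []
    for i, ((study, regimen, sched), cov) in enumerate(zip(arms, covs)):
        sid = start_id + i
        cov = SubjectCovariates(**{**vars(cov), "study": study})
        eta = (
            rng.normal(0.0, model.omega.omega_cl),
            rng.normal(0.0, model.omega.omega_ka),
        )
        times = np.concatenate([[0.0], sched])
        mdv = np.zeros(times.size, dtype=int)
        mdv[0] = 1  # predose sample: no quantifiable concentration
        _, dv = _simulate_subject_obs(model, cov, eta, regimen, times, rng)
        dose_rows = []
        for d in regimen:
            if d.route == "iv_infusion":
                dose_rows.append({"TIME": d.time, "AMT": d.amount,
                                  "RATE": d.amount / d.duration, "DV": np.nan,
                                  "EVID": 1, "MDV": 1, "CMT": 2, "BLQ": 0})
            else:
                dose_rows.append({"TIME": d.time, "AMT": d.amount, "RATE": 0.0,
                                  "DV": np.nan, "EVID": 1, "MDV": 1, "CMT": 1,
                                  "BLQ": 0})
        all_rows.extend(_rows_for_subject(sid, cov, dose_rows, times, dv, mdv))
        truth_rows.append({"ID": sid, "eta_cl": eta[0], "eta_ka": eta[1],
                           "study": study})
    df = flag_blq(pd.DataFrame(all_rows)[COLUMNS], lloq)
    return GeneratedStudy(
        dataset=AnalysisDataset(records=df, lloq=lloq),
        truth=pd.DataFrame(truth_rows).set_index("ID"),
    )


def generate_phase3(
    model: ModelConfig,
    er_fit: ErFit,
    n: int = 148,
    seed: int | np.random.Generator = 0,
    lloq: float = DEFAULT_LLOQ,
    start_id: int = 1,
) -> GeneratedStudy:
    """Sparse-sampling patient study with sedation-linked sampling times.

    n subjects split equally across 75 and 100 ug intranasal arms; each
    contributes two samples: one within 5 min of sedation onset (or of
    the 45-min assessment when sedation is not reached) and one either
    during surgery (2-4 h) or around 8 h post-dose.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    covs = generate_covariates(PHASE3_COVARIATES, n, rng, study="phase3")
    doses = np.where(np.arange(n) < n // 2, 75.0, 100.0)
    late_8h = np.zeros(n, dtype=bool)  # half per arm sampled around 8 h
    for arm in (75.0, 100.0):
        idx = np.flatnonzero(doses == arm)
        pick = rng.permutation(idx)[: idx.size // 2]
        late_8h[pick] = True
    all_rows: list[dict] = []
    truth_rows = []
    er_records: list[ErRecord] = []
    for i, cov in enumerate(covs):
        sid = start_id + i
        eta = (
            rng.normal(0.0, model.omega.omega_cl),
            rng.normal(0.0, model.omega.omega_ka),
        )
        p = individual_params(
            model.theta, cov, eta, model.allometric, model.extra_effects
        )
        regimen = [DoseEvent(0.0, float(doses[i]), "intranasal")]
        u = rng.uniform()
        t_rss3 = None
        for t_assess in RSS_TIMES:
            running_cmax, _ = cmax_in_window(p, regimen, (0.0, t_assess))
            if u <= prob_at(er_fit, running_cmax):
                t_rss3 = t_assess
                break
        success = t_rss3 is not None
        t1 = (t_rss3 if success else RSS_TIMES[-1]) + rng.uniform(0.0, 5.0 / 60.0)
        t2 = 8.0 + rng.uniform(-1.0, 1.0) if late_8h[i] else rng.uniform(2.0, 4.0)
        times = np.array(sorted([t1, t2]))
        pred = conc_profile(p, regimen, times)
        dv = simulate_observation(pred, model.sigma, model.residual_model, rng)
        dose_rows = [{"TIME": 0.0, "AMT": float(doses[i]), "RATE": 0.0,
                      "DV": np.nan, "EVID": 1, "MDV": 1, "CMT": 1, "BLQ": 0}]
        mdv = np.zeros(times.size, dtype=int)
        all_rows.extend(_rows_for_subject(sid, cov, dose_rows, times, dv, mdv))
        cmax45, _ = cmax_in_window(
            p, regimen, (0.0, min(t_rss3, RSS_TIMES[-1]) if success else RSS_TIMES[-1])
        )
        er_records.append(ErRecord(subject_id=sid, cmax45=cmax45, success=success))
        truth_rows.append({
            "ID": sid, "eta_cl": eta[0], "eta_ka": eta[1], "study": "phase3",
            "dose": float(doses[i]), "success": success,
            "t_rss3": t_rss3 if success else np.nan, "cmax45": cmax45,
        })
    df = flag_blq(pd.DataFrame(all_rows)[COLUMNS], lloq)
    return GeneratedStudy(
        dataset=AnalysisDataset(records=df, lloq=lloq),
        truth=pd.DataFrame(truth_rows).set_index("ID"),
        er_records=er_records,
    )


def generate_single_arm(
    model: ModelConfig,
    n: int = 32,
    dose: float = 100.0,
    route: str = "intranasal",
    times=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
    seed: int | np.random.Generator = 0,
    covariates: CovariateSpec = PHASE3_COVARIATES,
    study: str = "phase3",
    lloq: float = DEFAULT_LLOQ,
    start_id: int = 1,
) -> GeneratedStudy:
    """One-arm design with a common sampling grid.

    A deliberately small, flexible design used for calibration and
    property experiments (null simulations, shrinkage studies, reduced
    bootstraps); not one of the published study designs.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    covs = generate_covariates(covariates, n, rng, study=study)
    if route == "iv_infusion":
        regimen = [DoseEvent(0.0, dose, route, IV_INFUSION_DURATION)]
        dose_row = {"TIME": 0.0, "AMT": dose,
                    "RATE": dose / IV_INFUSION_DURATION, "DV": np.nan,
                    "EVID": 1, "MDV": 1, "CMT": 2, "BLQ": 0}
    else:
        regimen = [DoseEvent(0.0, dose, route)]
        dose_row = {"TIME": 0.0, "AMT": dose, "RATE": 0.0, "DV": np.nan,
                    "EVID": 1, "MDV": 1, "CMT": 1, "BLQ": 0}
    times = np.asarray(times, dtype=float)
    all_rows: list[dict] = []
    truth_rows = []
    for i, cov in enumerate(covs):
        sid = start_id + i
        eta = (
            rng.normal(0.0, model.omega.omega_cl),
            rng.normal(0.0, model.omega.omega_ka),
        )
        _, dv = _simulate_subject_obs(model, cov, eta, regimen, times, rng)
        mdv = np.zeros(times.size, dtype=int)
        all_rows.extend(_rows_for_subject(sid, cov, [dose_row], times, dv, mdv))
        truth_rows.append({"ID": sid, "eta_cl": eta[0], "eta_ka": eta[1],
                           "study": study})
    df = flag_blq(pd.DataFrame(all_rows)[COLUMNS], lloq)
    return GeneratedStudy(
        dataset=AnalysisDataset(records=df, lloq=lloq),
        truth=pd.DataFrame(truth_rows).set_index("ID"),
    )


def generate_full_study(
    model: ModelConfig,
    er_fit: ErFit,
    seed: int | np.random.Generator = 0,
    lloq: float = DEFAULT_LLOQ,
    n_phase3: int = 148,
) -> GeneratedStudy:
    """Phase I (48 HV) + phase III (148 patients) combined: 196 subjects."""
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    p1 = generate_phase1(model, rng, lloq=lloq, start_id=1)
    p3 = generate_phase3(
        model, er_fit, n=n_phase3, seed=rng, lloq=lloq, start_id=49
    )
    records = pd.concat(
        [p1.dataset.records, p3.dataset.records], ignore_index=True
    )
    truth = pd.concat([p1.truth, p3.truth])
    return GeneratedStudy(
        dataset=AnalysisDataset(records=records, lloq=lloq),
        truth=truth,
        er_records=p3.er_records,
    )
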