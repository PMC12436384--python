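"""Population-to-individual parameter mapping: fixed effects, allometric
body-weight scaling, covariate effects, lognormal inter-individual
variability (IIV) and the residual-error model.

Individual parameters follow ``P_i = P_tv * exp(eta_i)`` with ``eta_i ~
N(0, omega^2)``; clearances scale with body weight to the 0.75 power and
volumes linearly (theory-based allometry), and the absorption rate
constant carries a categorical healthy-volunteer/patient effect.  The
residual model is combined proportional + additive on the concentration
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .dataio import SubjectCovariates
from .structural import IndividualParams

RESIDUAL_MODELS = ("additive", "proportional", "combined")

#: covariate-effect functional forms
FORM_LINEAR = "linear"
FORM_POWER = "power"
FORM_PIECEWISE = "piecewise"


@dataclass(frozen=True)
class ThetaVector:
    """Population typical values (fixed effects).

    ``theta_state_ka`` is the fractional shift of KA for healthy
    volunteers relative to patients: ``KA_hv = ka_pop * (1 +
    theta_state_ka)``.  Patients are the reference category.
    """

    cl_pop: float = 35.3      # L/h
    vc_pop: float = 21.5      # L
    q_pop: float = 116.0      # L/h
    vp_pop: float = 86.5      # L
    ka_pop: float = 0.523     # 1/h (patients)
    theta_state_ka: float = 1.05
    f1_pop: float = 0.653     # intranasal bioavailability
    alag_pop: float = 0.0592  # h

    def __post_init__(self) -> None:
        for name in ("cl_pop", "vc_pop", "q_pop", "vp_pop", "ka_pop",
                     "f1_pop", "alag_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.f1_pop <= 1.0:
            raise ValueError("f1_pop must be in (0, 1]")
        if self.theta_state_ka <= -1.0:
            raise ValueError("theta_state_ka must exceed -1")


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal IIV: SDs of eta on the log scale for CL and KA."""

    omega_cl: float = 0.224
    omega_ka: float = 0.923

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_ka < 0:
            raise ValueError("omega SDs must be >= 0")

    def as_matrix(self) -> np.ndarray:
        return np.diag([self.omega_cl ** 2, self.omega_ka ** 2])


@dataclass(frozen=True)
class SigmaPair:
    """Residual error: proportional SD (fraction) and additive SD (pg/mL)."""

    sigma_prop: float = 0.277
    sigma_add: float = 5.01

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("sigma components must be >= 0")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            raise ValueError("sigma components must not both be 0")


@dataclass(frozen=True)
class CovariateEffect:
    """A single covariate effect on one PK parameter.

    forms:
      linear    : factor = 1 + theta * (cov - reference)
      power     : factor = (cov / reference) ** theta
      piecewise : factor = 1 + theta  if cov is the non-reference category
                  (cov passed as a 0/1 indicator)
    """

    parameter: str            # one of cl, vc, q, vp, ka, f1, alag
    covariate: str            # column name, e.g. AGE, SEX, STATE, BW
    form: str
    theta: float
    reference: float = 0.0    # covariate median (continuous) / 0 (categorical)

    def __post_init__(self) -> None:
        if self.form not in (FORM_LINEAR, FORM_POWER, FORM_PIECEWISE):
            raise ValueError(f"unknown covariate-effect form {self.form!r}")
        if self.parameter not in ("cl", "vc", "q", "vp", "ka", "f1", "alag"):
            raise ValueError(f"unknown target parameter {self.parameter!r}")


@dataclass(frozen=True)
class AllometricRule:
    """Theory-based allometry: fixed exponents, not estimated."""

    reference_bw: float = 60.0   # kg, total-cohort median
    exp_clearances: float = 0.75
    exp_volumes: float = 1.0

    def clearance_factor(self, bw) -> np.ndarray | float:
        return (np.asarray(bw, dtype=float) / self.reference_bw) ** self.exp_clearances

    def volume_factor(self, bw) -> np.ndarray | float:
        return (np.asarray(bw, dtype=float) / self.reference_bw) ** self.exp_volumes


def covariate_factor(effect: CovariateEffect, cov_value) -> np.ndarray | float:
    """Multiplicative factor contributed by one covariate effect."""
    x = np.asarray(cov_value, dtype=float)
    if effect.form == FORM_LINEAR:
        out = 1.0 + effect.theta * (x - effect.reference)
    elif effect.form == FORM_POWER:
        if np.any(x <= 0):
            raise ValueError("power-form covariate must be positive")
        out = (x / effect.reference) ** effect.theta
    else:  # piecewise, x is a 0/1 category indicator
        out = 1.0 + effect.theta * x
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class ModelConfig:
    """Complete population model definition (serializable)."""

    theta: ThetaVector = field(default_factory=ThetaVector)
    omega: OmegaMatrix = field(default_factory=OmegaMatrix)
    sigma: SigmaPair = field(default_factory=SigmaPair)
    allometric: AllometricRule = field(default_factory=AllometricRule)
    extra_effects: tuple[CovariateEffect, ...] = ()
    residual_model: str = "combined"

    def __post_init__(self) -> None:
        if self.residual_model not in RESIDUAL_MODELS:
            raise ValueError(f"unknown residual model {self.residual_model!r}")

    def with_updates(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "theta": vars(self.theta).copy(),
            "omega": vars(self.omega).copy(),
            "sigma": vars(self.sigma).copy(),
            "allometric": vars(self.allometric).copy(),
            "extra_effects": [vars(e).copy() for e in self.extra_effects],
            "residual_model": self.residual_model,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            theta=ThetaVector(**d.get("theta", {})),
            omega=OmegaMatrix(**d.get("omega", {})),
            sigma=SigmaPair(**d.get("sigma", {})),
            allometric=AllometricRule(**d.get("allometric", {})),
            extra_effects=tuple(
                CovariateEffect(**e) for e in d.get("extra_effects", [])
            ),
            residual_model=d.get("residual_model", "combined"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def final_model() -> ModelConfig:
    """The published final adult model (all estimates at their defaults)."""
    return ModelConfig()


def individual_params(
    theta: ThetaVector,
    cov: SubjectCovariates,
    eta: tuple[float, float] = (0.0, 0.0),
    allo: AllometricRule = AllometricRule(),
    extra_effects: tuple[CovariateEffect, ...] = (),
) -> IndividualParams:
    """Realize one subject's PK parameters.

    ``eta = (eta_cl, eta_ka)`` are the subject's lognormal random effects;
    the healthy-volunteer indicator raises KA by ``1 + theta_state_ka``.
    """
    if cov.state not in (0, 1):
        raise ValueError(f"unknown state category {cov.state!r}")
    eta_cl, eta_ka = float(eta[0]), float(eta[1])
    fc = float(allo.clearance_factor(cov.bw))
    fv = float(allo.volume_factor(cov.bw))
    is_hv = 1.0 if cov.is_hv else 0.0
    values = {
        "cl": theta.cl_pop * fc * np.exp(eta_cl),
        "vc": theta.vc_pop * fv,
        "q": theta.q_pop * fc,
        "vp": theta.vp_pop * fv,
        "ka": theta.ka_pop * (1.0 + theta.theta_state_ka * is_hv) * np.exp(eta_ka),
        "f1": theta.f1_pop,
        "alag": theta.alag_pop,
    }
    cov_row = {
        "BW": cov.bw, "AGE": cov.age, "SEX": cov.sex, "BMI": cov.bmi,
        "BSA": cov.bsa, "STATE": cov.state, "IS_HV": 1 - cov.state,
    }
    for eff in extra_effects:
        values[eff.parameter] *= covariate_factor(eff, cov_row[eff.covariate])
    return IndividualParams(**{k: float(v) for k, v in values.items()})


def residual_variance(pred, sigma: SigmaPair, model: str = "combined"):
    """Variance of the observed concentration given the prediction.

    combined: (sigma_prop*pred)^2 + sigma_add^2; the pure models are its
    nested special cases.
    """
    if model not in RESIDUAL_MODELS:
        raise ValueError(f"unknown residual model {model!r}")
    pred_arr = np.asarray(pred, dtype=float)
    if np.any(pred_arr < 0):
        raise ValueError("prediction must be non-negative")
    if model == "additive":
        out = np.full_like(pred_arr, sigma.sigma_add ** 2)
    elif model == "proportional":
        out = (sigma.sigma_prop * pred_arr) ** 2
    else:
        out = (sigma.sigma_prop * pred_arr) ** 2 + sigma.sigma_add ** 2
    return out if out.ndim else float(out)


def simulate_observation(pred, sigma: SigmaPair, model: str, rng: np.random.Generator):
    """Draw observed concentrations: Y = pred*(1 + eps1) + eps2.

    eps1 ~ N(0, sigma_prop^2), eps2 ~ N(0, sigma_add^2) independently.
    Values may be negative; clamping happens only at BLQ flagging.
    """
    if model not in RESIDUAL_MODELS:
        raise ValueError(f"unknown residual model {model!r}")
    pred_arr = np.asarray(pred, dtype=float)
    if np.any(pred_arr < 0):
        raise ValueError("prediction must be non-negative")
    shape = pred_arr.shape
    eps1 = rng.normal(0.0, sigma.sigma_prop, size=shape) if model != "additive" else 0.0
    eps2 = rng.normal(0.0, sigma.sigma_add, size=shape) if model != "proportional" else 0.0
    out = pred_arr * (1.0 + eps1) + eps2
    return out if out.ndim else float(out)


def subject_base_params(config: ModelConfig, cov_frame) -> dict[str, np.ndarray]:
    """Vectorized covariate model: typical parameters per subject, eta = 0.

    ``cov_frame`` is a per-subject frame with columns BW/AGE/SEX/BMI/BSA/
    STATE (as produced by ``AnalysisDataset.covariates``).  Returns arrays
    aligned with the frame's rows.
    """
    th, allo = config.theta, config.allometric
    bw = cov_frame["BW"].to_numpy(dtype=float)
    is_hv = (cov_frame["STATE"].to_numpy(dtype=float) == 0).astype(float)
    fc = allo.clearance_factor(bw)
    fv = allo.volume_factor(bw)
    out = {
        "cl": th.cl_pop * fc,
        "vc": th.vc_pop * fv,
        "q": th.q_pop * fc,
        "vp": th.vp_pop * fv,
        "ka": th.ka_pop * (1.0 + th.theta_state_ka * is_hv),
        "f1": np.full(bw.shape, th.f1_pop),
        "alag": np.full(bw.shape, th.alag_pop),
    }
    for eff in config.extra_effects:
        if eff.covariate == "IS_HV":
            x = is_hv
        else:
            x = cov_frame[eff.covariate].to_numpy(dtype=float)
        out[eff.parameter] = out[eff.parameter] * covariate_factor(eff, x)
    return out
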