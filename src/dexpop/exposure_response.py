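"""Exposure-response analysis: logistic regression of sedation success
(Ramsay Sedation Scale >= 3 within 45 min) on the individual predicted
Cmax over the same window.

Success probability is modelled as ``logit(p) = intercept + slope *
Cmax`` with Cmax in pg/mL; the published adult fit has intercept 0.27
and slope 0.01 per pg/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit, logit as _logit
from scipy.stats import chi2

from .structural import IndividualParams, cmax_in_window

#: ER evaluation window: 45 min after dosing, in hours
ER_WINDOW_H = 0.75


class SeparationError(RuntimeError):
    """The outcome is (quasi-)separable in Cmax: the MLE does not exist."""


@dataclass(frozen=True)
class ErRecord:
    """One subject's exposure-response observation."""

    subject_id: object
    cmax45: float          # pg/mL, predicted Cmax up to sedation onset or 45 min
    success: bool          # RSS >= 3 within 45 min

    def __post_init__(self) -> None:
        if self.cmax45 < 0:
            raise ValueError("cmax45 must be >= 0")


@dataclass(frozen=True)
class ErFit:
    """Fitted (or published) logistic exposure-response model."""

    intercept: float       # logit units
    slope: float           # logit per pg/mL
    lrt_pvalue: float = float("nan")
    loglik: float = float("nan")
    n: int = 0


#: the published adult exposure-response coefficients
PUBLISHED_ER = ErFit(intercept=0.27, slope=0.01)


def cmax45(
    ebe_params: IndividualParams,
    regimen,
    t_rss3: float | None = None,
) -> float:
    """Individual predicted Cmax from dosing to sedation onset.

    The window runs from 0 to ``min(t_rss3, 45 min)``; when sedation was
    not reached within 45 min the full 45-min window is used.
    """
    if t_rss3 is not None:
        if t_rss3 < 0:
            raise ValueError("t_rss3 must be >= 0")
        end = min(float(t_rss3), ER_WINDOW_H)
    else:
        end = ER_WINDOW_H
    if end <= 0.0:
        return 0.0
    value, _ = cmax_in_window(ebe_params, regimen, (0.0, end))
    return value


def fit_logistic(records: list[ErRecord]) -> ErFit:
    """Maximum-likelihood logistic fit of success on Cmax.

    Also reports the likelihood-ratio p-value against the intercept-only
    model.  Complete or quasi-complete separation raises
    :class:`SeparationError` with a diagnostic.
    """
    y = np.array([r.success for r in records], dtype=float)
    x = np.array([r.cmax45 for r in records], dtype=float)
    if y.size < 2 or len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes to fit the ER model")
    exog = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises/warns on separation
        raise SeparationError(
            "logistic MLE failed, likely due to separation: the success "
            f"indicator may be a deterministic function of Cmax ({exc})"
        ) from exc
    if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 1e3:
        raise SeparationError(
            "logistic fit did not converge to finite coefficients "
            f"(params={res.params}); check for separation in Cmax"
        )
    null = sm.Logit(y, np.ones_like(y)).fit(disp=0)
    lrt = 2.0 * (res.llf - null.llf)
    pvalue = float(chi2.sf(max(lrt, 0.0), df=1))
    return ErFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        lrt_pvalue=pvalue,
        loglik=float(res.llf),
        n=int(y.size),
    )


def prob_at(fit: ErFit, conc) -> np.ndarray | float:
    """Success probability at a concentration (inverse-logit)."""
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentration must be >= 0")
    out = expit(fit.intercept + fit.slope * conc_arr)
    return out if out.ndim else float(out)


def conc_for_prob(fit: ErFit, p: float) -> float:
    """Concentration achieving a target success probability.

    Inverse of :func:`prob_at`.  A target already exceeded at zero
    exposure maps to 0 (with a warning).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if fit.slope <= 0:
        raise ValueError("conc_for_prob requires a positive slope")
    conc = (float(_logit(p)) - fit.intercept) / fit.slope
    if conc < 0.0:
        if conc < -1e-9:
            warnings.warn(
                f"target probability {p} is already attained at zero exposure"
            )
        return 0.0
    return conc
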