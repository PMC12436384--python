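"""Closed-form two-compartment disposition with IV-infusion and first-order
absorption inputs.

The central compartment (volume ``vc``) exchanges with a peripheral
compartment (volume ``vp``) at inter-compartmental clearance ``q`` and is
cleared linearly at clearance ``cl``.  Intranasal doses enter a depot
compartment and transfer to the central compartment at first-order rate
``ka`` after an absorption lag ``alag``, with absolute bioavailability
``f1``; IV infusions enter the central compartment directly at a constant
rate.  All solutions are sums of exponentials in the two disposition
macro-rates, so multi-dose profiles follow by superposition.

Units: time h, amounts ug, volumes L, clearances L/h, concentrations pg/mL
(1 ug/L = 1000 pg/mL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

#: concentration unit factor: amount[ug] / volume[L] -> pg/mL
UNIT_PG_PER_ML = 1000.0

#: |ka - lambda| below which the degenerate (limit-form) absorption
#: solution is used instead of the generic tri-exponential one
DEGENERATE_EPS = 1e-8

ROUTE_IV = "iv_infusion"
ROUTE_NASAL = "intranasal"


@dataclass(frozen=True)
class IndividualParams:
    """Realized PK parameters of one subject.

    cl : L/h, elimination clearance
    vc : L, central volume
    q : L/h, inter-compartmental clearance
    vp : L, peripheral volume
    ka : 1/h, first-order absorption rate constant
    f1 : absolute bioavailability of the depot dose, in (0, 1]
    alag : h, absorption lag time
    """

    cl: float
    vc: float
    q: float
    vp: float
    ka: float = 1.0
    f1: float = 1.0
    alag: float = 0.0

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp", "ka", "f1"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.f1 > 1.0:
            raise ValueError(f"f1 must be <= 1, got {self.f1!r}")
        if self.alag < 0.0 or not np.isfinite(self.alag):
            raise ValueError(f"alag must be >= 0, got {self.alag!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration.

    time : h, start of administration
    amount : ug
    route : ``"iv_infusion"`` or ``"intranasal"``
    duration : h, infusion duration (IV only; ignored for intranasal)
    """

    time: float
    amount: float
    route: str
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.route not in (ROUTE_IV, ROUTE_NASAL):
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount < 0.0:
            raise ValueError(f"amount must be >= 0, got {self.amount!r}")
        if self.route == ROUTE_IV and self.duration <= 0.0:
            raise ValueError("iv_infusion requires duration > 0")


def disposition_macro(p: IndividualParams) -> tuple[float, float, float, float]:
    """Macro-rate constants and unit-bolus coefficients.

    Returns ``(lambda1, lambda2, a1, a2)`` such that a unit bolus into the
    central compartment gives ``C(t) = a1*exp(-lambda1*t) + a2*exp(-lambda2*t)``
    in ug/L, with ``lambda1 > lambda2 > 0``.
    """
    k10 = p.cl / p.vc
    k12 = p.q / p.vc
    k21 = p.q / p.vp
    s = k10 + k12 + k21
    disc = np.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    lam1 = 0.5 * (s + disc)
    lam2 = 0.5 * (s - disc)
    denom = p.vc * (lam1 - lam2)
    a1 = (lam1 - k21) / denom
    a2 = (k21 - lam2) / denom
    return lam1, lam2, a1, a2


def conc_iv_infusion(p: IndividualParams, d: DoseEvent, t) -> np.ndarray | float:
    """Central concentration (pg/mL) after a zero-order IV infusion.

    Standard bi-exponential constant-rate-input solution; zero before the
    dose and continuous at the end of the infusion.
    """
    if d.route != ROUTE_IV:
        raise ValueError("conc_iv_infusion requires an iv_infusion dose")
    t_arr = np.asarray(t, dtype=float)
    if d.amount == 0.0:
        out = np.zeros_like(t_arr)
        return out if out.ndim else float(out)
    lam1, lam2, a1, a2 = disposition_macro(p)
    rate = d.amount / d.duration
    dt = t_arr - d.time
    tau = np.clip(dt, 0.0, d.duration)
    conc = np.zeros_like(dt)
    for lam, coef in ((lam1, a1), (lam2, a2)):
        with np.errstate(over="ignore"):
            conc += (coef / lam) * (1.0 - np.exp(-lam * tau)) * np.exp(
                -lam * np.maximum(dt - tau, 0.0)
            )
    conc *= UNIT_PG_PER_ML * rate
    conc = np.where(dt > 0.0, conc, 0.0)
    return conc if conc.ndim else float(conc)


def conc_firstorder(p: IndividualParams, d: DoseEvent, t) -> np.ndarray | float:
    """Central concentration (pg/mL) after a first-order-absorbed dose.

    Tri-exponential solution for a depot dose ``f1 * amount`` entering at
    rate ``ka`` after lag ``alag``.  When ``ka`` coincides with a
    disposition macro-rate the removable singularity is evaluated by its
    limit form ``t * exp(-lam * t)``.
    """
    if d.route != ROUTE_NASAL:
        raise ValueError("conc_firstorder requires an intranasal dose")
    t_arr = np.asarray(t, dtype=float)
    if d.amount == 0.0:
        out = np.zeros_like(t_arr)
        return out if out.ndim else float(out)
    lam1, lam2, a1, a2 = disposition_macro(p)
    dt = t_arr - d.time - p.alag
    dt_pos = np.maximum(dt, 0.0)
    conc = np.zeros_like(dt)
    with np.errstate(over="ignore"):
        e_ka = np.exp(-p.ka * dt_pos)
        for lam, coef in ((lam1, a1), (lam2, a2)):
            e_lam = np.exp(-lam * dt_pos)
            if abs(p.ka - lam) < DEGENERATE_EPS:
                conc += coef * dt_pos * e_lam
            else:
                conc += coef * (e_lam - e_ka) / (p.ka - lam)
    conc *= UNIT_PG_PER_ML * p.ka * p.f1 * d.amount
    conc = np.where(dt > 0.0, conc, 0.0)
    return conc if conc.ndim else float(conc)


def conc_single_dose(p: IndividualParams, d: DoseEvent, t) -> np.ndarray | float:
    """Dispatch on dose route."""
    if d.route == ROUTE_IV:
        return conc_iv_infusion(p, d, t)
    return conc_firstorder(p, d, t)


def conc_profile(p: IndividualParams, regimen, times) -> np.ndarray:
    """Concentration-time profile under a multi-dose regimen.

    Linear kinetics: the profile is the superposition of single-dose
    solutions.  ``times`` must be sorted; an empty regimen yields zeros.
    """
    t_arr = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(np.diff(t_arr) < 0.0):
        raise ValueError("times must be sorted non-decreasing")
    total = np.zeros_like(t_arr)
    for d in regimen:
        total += np.asarray(conc_single_dose(p, d, t_arr))
    return total


def cmax_in_window(
    p: IndividualParams,
    regimen,
    window: tuple[float, float],
    grid_step: float = 1.0 / 60.0,
) -> tuple[float, float]:
    """Maximum residual-free concentration over a time window.

    The profile is scanned on a dense grid (default 1 min) and the best
    point refined by bounded scalar maximization.  Returns ``(cmax, tmax)``
    in pg/mL and h.  A window that ends before any drug can appear returns
    ``(0.0, t0)``.
    """
    t0, t1 = float(window[0]), float(window[1])
    if not (t1 > t0 >= 0.0):
        raise ValueError(f"require t1 > t0 >= 0, got window ({t0}, {t1})")
    regimen = list(regimen)
    if not regimen:
        return 0.0, t0

    def onset(d: DoseEvent) -> float:
        return d.time + (p.alag if d.route == ROUTE_NASAL else 0.0)

    if t1 <= min(onset(d) for d in regimen):
        return 0.0, t0

    grid = np.arange(t0, t1, grid_step)
    grid = np.append(grid, t1)
    values = conc_profile(p, regimen, grid)
    i = int(np.argmax(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi > lo:
        res = minimize_scalar(
            lambda t: -float(conc_profile(p, regimen, [t])[0]),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun >= values[i]:
            return float(-res.fun), float(res.x)
    return float(values[i]), float(grid[i])
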