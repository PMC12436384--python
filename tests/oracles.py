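"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's closed-form/Laplace code paths:
concentrations come from direct ODE integration of the compartmental
mass-balance equations, and marginal likelihoods from tensor-product
Gauss-Hermite quadrature over the random effects.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from numpy.polynomial.hermite_e import hermegauss

from dexpop.structural import DoseEvent, IndividualParams


def ode_conc(
    p: IndividualParams,
    regimen: list[DoseEvent],
    times,
    rtol: float = 1e-11,
    atol: float = 1e-12,
) -> np.ndarray:
    """Central concentration (pg/mL) by direct ODE integration.

    States are amounts (ug) in depot, central and peripheral
    compartments; depot doses arrive as impulses at dose time + alag,
    infusions as piecewise-constant input rates.
    """
    times = np.asarray(times, dtype=float)
    k10, k12, k21 = p.cl / p.vc, p.q / p.vc, p.q / p.vp

    impulses: list[tuple[float, float]] = []   # (time, depot amount)
    infusions: list[tuple[float, float, float]] = []  # (t0, t1, rate)
    for d in regimen:
        if d.route == "intranasal":
            impulses.append((d.time + p.alag, p.f1 * d.amount))
        else:
            infusions.append((d.time, d.time + d.duration, d.amount / d.duration))

    def rate_in(t: float) -> float:
        return sum(r for (t0, t1, r) in infusions if t0 <= t < t1)

    def rhs(t, y):
        a_d, a_c, a_p = y
        return [
            -p.ka * a_d,
            p.ka * a_d + rate_in(t) - (k10 + k12) * a_c + k21 * a_p,
            k12 * a_c - k21 * a_p,
        ]

    breaks = sorted(
        {0.0}
        | {t for (t, _) in impulses}
        | {t for (t0, t1, _) in infusions for t in (t0, t1)}
        | {float(times.max())}
    )
    breaks = [b for b in breaks if b <= float(times.max())]
    if breaks[-1] < float(times.max()):
        breaks.append(float(times.max()))

    y = np.zeros(3)
    out = np.zeros(times.size)
    out[times <= breaks[0]] = 0.0
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        for t_imp, amt in impulses:
            if np.isclose(t_imp, t0):
                y[0] += amt
        if t1 <= t0:
            continue
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA", rtol=rtol, atol=atol,
            dense_output=True, max_step=(t1 - t0) / 4.0,
        )
        mask = (times > t0) & (times <= t1)
        if mask.any():
            out[mask] = 1000.0 * sol.sol(times[mask])[1] / p.vc
        y = sol.y[:, -1]
    return out


def gauss_hermite_neg2ll(
    subjects: list[dict],
    omega_sds: tuple[float, float],
    n_nodes: int = 64,
) -> float:
    """-2 log marginal likelihood by 2-d Gauss-Hermite quadrature.

    Each subject dict carries ``y`` (observations), and ``predict(eta)``
    returning (f, v) at a 2-vector eta.  Independent N(0, sd^2) random
    effects; a zero SD collapses that dimension.
    """
    x, w = hermegauss(n_nodes)     # weight exp(-x^2/2), integrates to sqrt(2*pi)
    w = w / np.sqrt(2.0 * np.pi)   # now sums to 1: expectation weights
    total = 0.0
    for s in subjects:
        y = np.asarray(s["y"], dtype=float)
        like = 0.0
        nodes1 = x * omega_sds[0] if omega_sds[0] > 0 else np.array([0.0])
        wts1 = w if omega_sds[0] > 0 else np.array([1.0])
        nodes2 = x * omega_sds[1] if omega_sds[1] > 0 else np.array([0.0])
        wts2 = w if omega_sds[1] > 0 else np.array([1.0])
        for e1, w1 in zip(nodes1, wts1):
            for e2, w2 in zip(nodes2, wts2):
                f, v = s["predict"](np.array([e1, e2]))
                ll = -0.5 * np.sum(
                    np.log(2.0 * np.pi * v) + (y - f) ** 2 / v
                )
                like += w1 * w2 * np.exp(ll)
        total += -2.0 * np.log(max(like, 1e-300))
    return total
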