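"""Model qualification: bootstrap parameter uncertainty, prediction-
corrected visual predictive check (pcVPC), and conditional weighted
residuals (CWRES).

All routines are pure functions of (data, model, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import AnalysisDataset
from .estimation import (
    CompiledDataset,
    STANDARD_PARAMS,
    _get_param,
    _SubjectObjective,
    fit,
)
from .population import ModelConfig

#: default pcVPC bin edges (h): absorption, distribution, elimination phases
DEFAULT_BIN_EDGES = (0.0, 0.25, 0.75, 2.0, 4.0, 8.0, 24.0)


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    n_iter: int
    success_rate: float
    summary: pd.DataFrame        # index parameter, columns median/ci_lo/ci_hi
    samples: pd.DataFrame        # one row per converged iteration
    unreliable: bool = False


def _resample_subjects(
    ds: AnalysisDataset, rng: np.random.Generator, stratify: bool
) -> AnalysisDataset:
    cov = ds.covariates()
    strata = cov["STUDY"] if stratify else pd.Series("all", index=cov.index)
    blocks = []
    new_id = 0
    rec = ds.records
    by_id = {sid: g for sid, g in rec.groupby("ID", sort=False)}
    for _, ids in strata.groupby(strata, sort=False):
        pool = ids.index.to_numpy()
        picks = pool[rng.integers(0, pool.size, size=pool.size)]
        for sid in picks:
            new_id += 1
            g = by_id[sid].copy()
            g["ID"] = new_id
            blocks.append(g)
    return AnalysisDataset(
        records=pd.concat(blocks, ignore_index=True), lloq=ds.lloq
    )


def bootstrap(
    ds: AnalysisDataset,
    model: ModelConfig,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    stratify: bool = True,
    fixed: set[str] = frozenset(),
    maxiter: int = 200,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population parameters.

    Subjects are resampled with replacement (stratified by study, so the
    rich/sparse information balance is preserved) to the original
    per-stratum sizes; the model is refitted to each replicate starting
    from the supplied estimates.  Percentile 95% CIs are computed over
    converged iterations only; a success rate below 50% flags the result
    unreliable.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    names = [p for p in STANDARD_PARAMS] + [
        f"effect_{i}" for i in range(len(model.extra_effects))
    ]
    rows = []
    n_ok = 0
    for _ in range(n_iter):
        ds_b = _resample_subjects(ds, rng, stratify)
        try:
            res = fit(ds_b, model, fixed=fixed, maxiter=maxiter)
        except Exception:
            rows.append(dict({n: np.nan for n in names}, converged=False))
            continue
        row = {n: _get_param(res.model, n) for n in names}
        row["converged"] = bool(res.converged)
        n_ok += int(res.converged)
        rows.append(row)
    samples = pd.DataFrame(rows)
    ok = samples[samples["converged"].astype(bool)]
    success_rate = n_ok / n_iter if n_iter else 0.0
    unreliable = success_rate < 0.5
    if unreliable:
        warnings.warn(
            f"bootstrap success rate {success_rate:.1%} is below 50%; "
            "percentile CIs are unreliable"
        )
    summary = pd.DataFrame(
        {
            "median": ok[names].median(),
            "ci_lo": ok[names].quantile(0.025),
            "ci_hi": ok[names].quantile(0.975),
        }
    )
    return BootstrapResult(
        n_iter=n_iter, success_rate=success_rate,
        summary=summary, samples=samples, unreliable=unreliable,
    )


# --------------------------------------------------------------------------
# pcVPC
# --------------------------------------------------------------------------


@dataclass
class VpcBin:
    t_lo: float
    t_hi: float
    n_obs: int
    observed: dict[int, float]                       # percentile -> value
    simulated: dict[int, tuple[float, float, float]]  # pct -> (lo, mid, hi)


def _merge_small_bins(
    assignment: np.ndarray, edges: list[float], min_obs: int
) -> tuple[np.ndarray, list[float]]:
    """Merge bins holding fewer than min_obs observations into a neighbor."""
    edges = list(edges)
    while True:
        counts = np.bincount(assignment, minlength=len(edges) - 1)
        small = [b for b in range(len(counts)) if 0 < counts[b] < min_obs or
                 (counts[b] == 0 and len(counts) > 1)]
        if not small or len(edges) <= 2:
            return assignment, edges
        b = small[0]
        drop = b if b > 0 else 1  # merge with the left neighbor when possible
        edges.pop(drop)
        assignment = np.where(assignment >= drop, assignment - 1, assignment)


def pcvpc(
    ds: AnalysisDataset,
    model: ModelConfig,
    n_sim: int = 1000,
    bin_edges=DEFAULT_BIN_EDGES,
    seed: int | np.random.Generator = 0,
    percentiles=(5, 50, 95),
    min_bin_obs: int = 5,
) -> list[VpcBin]:
    """Prediction-corrected visual predictive check.

    Every observed and simulated concentration is rescaled by the ratio
    of the bin-median population prediction to that record's own
    population prediction, removing dose and covariate heterogeneity
    before percentiles are compared.  Simulated 95% CIs of each
    percentile come from ``n_sim`` full-study replicates (IIV plus
    residual error).  Simulated concentrations below the dataset's LLOQ
    are discarded before percentiles are taken, mirroring the M1
    handling of the observed data.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    c = CompiledDataset(ds)
    obj = _SubjectObjective(c, model)
    pred = obj.predict(np.zeros((c.n_sub, obj.d)))
    if np.any(pred <= 0):
        raise ValueError("population prediction non-positive at an observation")

    edges = sorted(set(float(e) for e in bin_edges))
    t_max = float(c.obs_time.max())
    if edges[-1] < t_max:
        edges.append(t_max)
    assignment = np.clip(
        np.searchsorted(edges, c.obs_time, side="right") - 1, 0, len(edges) - 2
    )
    assignment, edges = _merge_small_bins(assignment, edges, min_bin_obs)
    n_bins = len(edges) - 1

    bin_median_pred = np.array([
        np.median(pred[assignment == b]) for b in range(n_bins)
    ])
    correction = bin_median_pred[assignment] / pred
    pc_obs = c.obs_dv * correction

    def bin_percentiles(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
        out = np.empty((n_bins, len(percentiles)))
        for b in range(n_bins):
            m = (assignment == b) & keep
            if not m.any():          # fully censored bin: fall back to all
                m = assignment == b
            out[b] = np.percentile(values[m], percentiles)
        return out

    all_rows = np.ones(c.n_obs, dtype=bool)
    obs_pct = bin_percentiles(pc_obs, all_rows)

    sim_pct = np.empty((n_sim, n_bins, len(percentiles)))
    om = np.array([model.omega.omega_cl, model.omega.omega_ka])
    for r in range(n_sim):
        eta = rng.normal(0.0, 1.0, size=(c.n_sub, 2)) * om
        pars = dict(obj.base)
        pars["cl"] = obj.base["cl"] * np.exp(eta[:, 0])
        pars["ka"] = obj.base["ka"] * np.exp(eta[:, 1])
        sim = c.predict(pars)
        eps1 = rng.normal(0.0, model.sigma.sigma_prop, size=sim.size)
        eps2 = rng.normal(0.0, model.sigma.sigma_add, size=sim.size)
        sim_dv = sim * (1.0 + eps1) + eps2
        sim_pct[r] = bin_percentiles(sim_dv * correction, sim_dv >= ds.lloq)

    out = []
    for b in range(n_bins):
        observed = {p: float(obs_pct[b, k]) for k, p in enumerate(percentiles)}
        simulated = {}
        for k, p in enumerate(percentiles):
            lo, mid, hi = np.percentile(sim_pct[:, b, k], [2.5, 50.0, 97.5])
            simulated[p] = (float(lo), float(mid), float(hi))
        out.append(VpcBin(
            t_lo=float(edges[b]), t_hi=float(edges[b + 1]),
            n_obs=int((assignment == b).sum()),
            observed=observed, simulated=simulated,
        ))
    return out


def vpc_table(bins: list[VpcBin]) -> pd.DataFrame:
    """Plot-ready long table: one row per (bin, percentile)."""
    rows = []
    for b in bins:
        for p, obs in b.observed.items():
            lo, mid, hi = b.simulated[p]
            rows.append({
                "t_lo": b.t_lo, "t_hi": b.t_hi, "n_obs": b.n_obs,
                "percentile": p, "observed": obs,
                "sim_lo": lo, "sim_mid": mid, "sim_hi": hi,
            })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CWRES
# --------------------------------------------------------------------------


def cwres(
    ds: AnalysisDataset,
    model: ModelConfig,
    ebes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Conditional weighted residuals (FOCE linearization about the EBEs).

    Per subject the model is linearized at the conditional mode
    eta-hat: mean ``f(eta-hat) - F eta-hat``, covariance ``F Omega F' +
    V``; CWRES is the Cholesky-whitened residual and is approximately
    standard normal under a correct model.  Returns a frame aligned with
    the quantifiable observations (ID, TIME, DV, PRED, CWRES).
    """
    c = CompiledDataset(ds)
    obj = _SubjectObjective(c, model)
    if ebes is not None:
        eta_full = ebes.loc[c.ids, ["eta_cl", "eta_ka"]].to_numpy(dtype=float)
        eta = eta_full[:, obj.active]
    else:
        eta, _ = obj.optimize_eta()
    f_hat = obj.predict(eta)
    v = obj.variance(f_hat)
    d = obj.d
    h = 1e-4
    F = np.zeros((c.n_obs, d))
    for k in range(d):
        e = np.zeros(d)
        e[k] = h
        F[:, k] = (obj.predict(eta + e) - obj.predict(eta - e)) / (2.0 * h)
    omega_active = np.diag(obj.om2) if d else np.zeros((0, 0))
    values = np.empty(c.n_obs)
    for s in range(c.n_sub):
        rows = np.flatnonzero(c.obs_sub == s)
        Fs = F[rows]
        cov = np.diag(v[rows]) + Fs @ omega_active @ Fs.T
        r = c.obs_dv[rows] - f_hat[rows] + Fs @ eta[s]
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular conditional covariance for subject {c.ids[s]!r}"
            ) from exc
        values[rows] = np.linalg.solve(L, r)
    return pd.DataFrame({
        "ID": c.ids[c.obs_sub], "TIME": c.obs_time, "DV": c.obs_dv,
        "PRED": obj.predict(np.zeros_like(eta)), "CWRES": values,
    })
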