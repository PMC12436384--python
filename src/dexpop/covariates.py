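"""Covariate selection: collinearity screening and stepwise covariate
modeling (SCM).

Forward inclusion accepts, one candidate at a time, the covariate effect
with the largest objective-function drop exceeding 3.84 (chi-square,
p < 0.05, 1 df); backward elimination then removes every retained effect
whose deletion raises the objective by 10.83 or less (p < 0.001).
Body-size measures (BW/BSA/BMI) are strongly collinear, so only one of
each collinear group - body weight by preference - enters the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .dataio import AnalysisDataset
from .estimation import CompiledDataset, FitResult, fit
from .population import CovariateEffect, ModelConfig

FORWARD_DOFV = 3.84     # chi-square(1) at p = 0.05
BACKWARD_DOFV = 10.83   # chi-square(1) at p = 0.001


@dataclass
class ScreenResult:
    groups: list[list[str]]          # collinear groups (|r| > threshold)
    retained: list[str]              # one representative per group + singletons
    dropped_constant: list[str] = field(default_factory=list)
    correlation: pd.DataFrame | None = None


def correlation_screen(
    cov_table: pd.DataFrame, threshold: float = 0.8,
    prefer: tuple[str, ...] = ("BW",),
) -> ScreenResult:
    """Group covariates whose pairwise |Pearson r| exceeds the threshold.

    Within each collinear group a single representative is retained
    (preferred names first, then column order); constant columns are
    excluded with a warning.
    """
    if cov_table.shape[1] < 2:
        raise ValueError("need at least two covariates to screen")
    cols = list(cov_table.columns)
    constant = [c for c in cols if cov_table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant covariates excluded from screening: {constant}")
    cols = [c for c in cols if c not in constant]
    corr = cov_table[cols].corr()
    # union-find over the collinearity graph
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)
    members: dict[str, list[str]] = {}
    for c in cols:
        members.setdefault(find(c), []).append(c)
    groups = [g for g in members.values() if len(g) > 1]
    retained = []
    for g in members.values():
        rep = next((p for p in prefer if p in g), g[0])
        retained.append(rep)
    retained = [c for c in cols if c in retained]  # keep column order
    return ScreenResult(
        groups=groups, retained=retained,
        dropped_constant=constant, correlation=corr,
    )


@dataclass
class ScmStep:
    candidate: CovariateEffect
    delta_ofv: float
    accepted: bool
    direction: str                   # "forward" | "backward"
    converged: bool = True
    note: str = ""


@dataclass
class ScmResult:
    final_model: ModelConfig
    final_fit: FitResult
    steps: list[ScmStep]
    base_ofv: float

    def included(self) -> list[CovariateEffect]:
        return list(self.final_model.extra_effects)


def scm(
    ds: AnalysisDataset,
    base: ModelConfig,
    candidates: list[CovariateEffect],
    fixed: set[str] = frozenset(),
    forward_dofv: float = FORWARD_DOFV,
    backward_dofv: float = BACKWARD_DOFV,
    maxiter: int = 200,
) -> ScmResult:
    """Stepwise covariate modeling with the standard ΔOFV thresholds.

    The base model (including its allometric body-weight scaling, which
    is never searched) is fitted first; candidates are then added
    greedily by largest significant ΔOFV and pruned by backward
    elimination.  Ties are broken by candidate order.  Non-convergent
    candidate fits are logged and skipped.
    """
    compiled = CompiledDataset(ds)
    steps: list[ScmStep] = []

    def _fit(cfg: ModelConfig) -> FitResult:
        return fit(ds, cfg, fixed=fixed, maxiter=maxiter, compiled=compiled)

    current_fit = _fit(base)
    base_ofv = current_fit.ofv
    current = current_fit.model
    remaining = list(candidates)

    while remaining:
        trials: list[tuple[float, int, FitResult]] = []
        for j, cand in enumerate(remaining):
            cfg = current.with_updates(
                extra_effects=current.extra_effects + (cand,)
            )
            try:
                res = _fit(cfg)
            except Exception as exc:  # candidate fit failed outright
                steps.append(ScmStep(cand, float("nan"), False, "forward",
                                     converged=False, note=str(exc)))
                continue
            dofv = current_fit.ofv - res.ofv
            if not res.converged and dofv <= forward_dofv:
                steps.append(ScmStep(cand, dofv, False, "forward",
                                     converged=False, note="non-convergent"))
                continue
            steps.append(ScmStep(cand, dofv, False, "forward",
                                 converged=res.converged))
            trials.append((dofv, j, res))
        significant = [t for t in trials if t[0] > forward_dofv]
        if not significant:
            break
        significant.sort(key=lambda t: (-t[0], t[1]))
        dofv, j, res = significant[0]
        # mark the accepted step (last matching forward record)
        for s in reversed(steps):
            if s.direction == "forward" and s.candidate is remaining[j]:
                s.accepted = True
                break
        current_fit = res
        current = res.model
        remaining.pop(j)

    # backward elimination over the searched effects only
    n_base_effects = len(base.extra_effects)
    while len(current.extra_effects) > n_base_effects:
        increases: list[tuple[float, int, FitResult]] = []
        for j in range(n_base_effects, len(current.extra_effects)):
            effects = tuple(
                e for k, e in enumerate(current.extra_effects) if k != j
            )
            cfg = current.with_updates(extra_effects=effects)
            try:
                res = _fit(cfg)
            except Exception as exc:
                steps.append(ScmStep(current.extra_effects[j], float("nan"),
                                     True, "backward", converged=False,
                                     note=str(exc)))
                continue
            increases.append((res.ofv - current_fit.ofv, j, res))
        if not increases:
            break
        increases.sort(key=lambda t: (t[0], t[1]))
        inc, j, res = increases[0]
        eff = current.extra_effects[j]
        if inc <= backward_dofv:
            steps.append(ScmStep(eff, inc, False, "backward"))
            current_fit = res
            current = res.model
        else:
            for inc_k, k, _ in increases:
                steps.append(ScmStep(current.extra_effects[k], inc_k, True,
                                     "backward"))
            break

    return ScmResult(
        final_model=current, final_fit=current_fit,
        steps=steps, base_ofv=base_ofv,
    )
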