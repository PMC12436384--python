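# Methods

This note documents the models, algorithms and design choices in
`dexpop`, in the order a pharmacometrician would meet them: structural
model, population layer, estimation, covariate search, qualification,
exposure–response, trial simulation, and the synthetic-data generator
that stands in for the confidential clinical datasets.

## Structural model

Two compartments with linear elimination; intranasal doses enter a
depot and transfer first-order (rate `ka`, lag `alag`, bioavailability
`f1`); IV doses are zero-order infusions into the central compartment
(reference bioavailability 1).  All solutions are closed-form sums of
exponentials in the two disposition macro-rates `lambda_1 > lambda_2`,
the roots of `lambda^2 - (k10+k12+k21) lambda + k10 k21` with
`k10 = cl/vc`, `k12 = q/vc`, `k21 = q/vp`.  Units: h, ug, L;
concentrations in pg/mL via the factor 1000 x ug/L.

Numerical choices:

- When `ka` coincides with a macro-rate the generic term
  `(e^{-lambda t} - e^{-ka t})/(ka - lambda)` is replaced by its limit
  `t e^{-lambda t}` below `|ka - lambda| < 1e-8`.
- Multi-dose profiles are superpositions of single-dose solutions
  (linear kinetics); the split "100/20 ug" phase-I arm is modelled as
  two simultaneous depot doses at t = 0 totalling 120 ug.  Whether the
  split was simultaneous or staggered is not documented for the
  original study; simultaneous dosing is the default and a staggered
  regimen is expressible through the same `DoseEvent` list.
- Window-restricted Cmax is located on a 1-minute grid and refined by
  bounded scalar maximization; at the ~1-2 h time-to-peak of this drug
  the grid already resolves the maximum to well below 0.1%.  The
  vectorized simulation path refines the grid maximum with one
  parabolic step, and only at strict interior maxima with genuine
  concavity — a profile still rising at the window edge keeps its grid
  value (the parabola is numerically unstable on near-linear
  segments).

Closed forms are validated against direct ODE integration (LSODA,
rtol 1e-11) at 1e-6 relative tolerance, and against the mass-balance
identity `AUC x CL = F x Dose`.

## Population layer

`P_i = P_tv x allometry x covariate factors x exp(eta_i)`.

- Allometry: exponents fixed at 0.75 (clearances) and 1.0 (volumes),
  reference body weight 60 kg — the total-cohort median; the reference
  is a modelling convention, not an estimated quantity.
- The state effect on absorption is piecewise: patients are the
  reference category, healthy volunteers get `ka x (1 + 1.05)`.  This
  orientation is the only one consistent with both the printed typical
  KA (0.523 1/h) and the statement that patient absorption runs at
  ~49% of the healthy-volunteer rate (~1.07 1/h).
- IIV is diagonal and limited to CL and KA.  The printed percentages
  (22.4%, 92.3%) are treated as approximate CVs and implemented as SDs
  of eta on the log scale (0.224, 0.923), the standard reporting
  convention.
- Residual error is combined: `Var(Y|f) = (0.277 f)^2 + 5.01^2`
  (pg/mL)^2; pure additive and proportional models are nested special
  cases.
- Generic covariate effects (linear, power, piecewise) multiply any
  structural parameter and are what the stepwise search manipulates;
  the derived indicator `IS_HV = 1 - STATE` lets piecewise effects use
  patients as the reference category.

## Estimation (FOCE-I)

The per-subject marginal likelihood is approximated by a Laplace
expansion about the conditional mode of `eta = (eta_CL, eta_KA)`, with
the residual variance evaluated at the conditional predictions (the
interaction term).  Writing `g(eta)` for the conditional -2 log joint
density, the objective is

```
OFV = sum_i [ n_i log 2pi + g_i(eta_hat_i)
              + log det( F_i' V_i^-1 F_i + Omega^-1 ) ]
```

with `F_i = df/d eta` at the mode (central finite differences) and
`V_i` the residual variances — the standard FOCE linearization of the
curvature.  The log-determinant term uses the linearized rather than
the exact Hessian; on small test problems the two differ by less than
0.05 OFV units while both carry the intrinsic Laplace error, which
grows with omega (about 0.4 OFV units per subject at 30% IIV on a
6-observation design, and more at the 92% KA IIV of the final model).
Absolute OFV values are therefore never interpreted; only differences
between nested models on the same data are.

- Inner problem: damped Newton on each subject's 2-d eta, vectorized
  across all subjects (finite-difference gradient/Hessian, Armijo
  backtracking, gradient tolerance 1e-8, start at eta = 0 so the
  objective is a deterministic function of data and parameters).
- Outer problem: L-BFGS-B on transformed parameters — log for positive
  parameters, logit for F1, log1p for the state effect — with
  finite-difference gradients.  An abnormal line-search exit near a
  flat optimum (a known artifact of FD gradients) triggers one
  restart; the fit is reported converged when the restart finds no
  further descent.
- Omega components fixed at zero drop their eta dimension, collapsing
  to extended least squares; this is also the escape hatch for
  singular-Omega errors.
- F1 and ALAG are estimated only when an IV arm is present; without
  one they are fixed with a warning (absolute bioavailability is not
  identifiable from extravascular data alone).
- BLQ rows are excluded at compilation; the estimator never sees them
  (M1 handling is upstream of fitting).
- No covariance-step standard errors: uncertainty comes from the
  bootstrap.

Empirical Bayes estimates (EBEs) are the inner-problem modes; their
shrinkage toward zero grows as per-subject sampling thins, which the
test suite checks explicitly.

Known behaviour at the published IIV magnitudes: on single-arm
intranasal designs the 92% KA IIV induces a ~5% upward finite-sample
bias in CL; the joint IV + intranasal design removes it.  The same
skewness means the published factor-2.05 state effect on KA is less
than one IIV standard deviation, so reduced two-arm designs (20–30
subjects per state) often cannot hold it through the 10.83 backward
threshold — detecting and retaining it reliably needs either the full
196-subject design or a moderated KA IIV, and the reduced covariate-
search tests use the latter.

## Covariate search

Correlation screening groups covariates with pairwise |Pearson r|
above 0.8 (union-find over the collinearity graph) and keeps one
representative per group, body weight by preference — in generated
cohorts BW, BSA and BMI form one such group.  The stepwise search then
adds, one at a time, the candidate with the largest ΔOFV above 3.84
(ties: fewest parameters, then candidate order) and afterwards deletes
every retained effect whose removal costs 10.83 or less, weakest
first.  Allometric body-weight scaling belongs to the base model and
is never searched.  Every fit in the search is logged in an audit
trail (candidate, ΔOFV, direction, accepted, convergence) sufficient
to replay the search.

## Qualification

- Bootstrap: subjects resampled with replacement within study strata
  to the original per-stratum sizes (preserving the rich/sparse
  information balance; unstratified available), refit from the final
  estimates, medians and 2.5/97.5 percentile CIs over converged
  replicates; success below 50% flags the result unreliable.
- pcVPC: observations and simulated replicates are rescaled by
  bin-median population prediction / record-level population
  prediction before 5/50/95th percentiles are compared; default bins
  0–0.25–0.75–2–4–8–24 h resolve absorption, distribution and
  elimination, and bins under 5 observations merge leftward.
  Simulated values below the dataset LLOQ are discarded before
  percentiles, mirroring the M1 treatment of the observed data —
  without this the terminal bin is biased high.  On self-simulated
  full studies the observed bin median falls inside its simulated 95%
  band at the nominal ~95% rate; the calibration test pools indicators
  over ten replicate studies because a single six-bin study passes an
  all-bins check only ~75% of the time even for a perfect model.
- CWRES: FOCE linearization about the EBEs — residual
  `y - f(eta_hat) + F eta_hat`, covariance `F Omega F' + V`, whitened
  by Cholesky; approximately N(0,1) under a correct model
  (variance within [0.8, 1.2] and |CWRES| < 4 checked on 1000+
  observations).

## Exposure–response

Success is RSS >= 3 within 45 min; exposure is the individual
predicted Cmax from dosing to sedation onset (or to 45 min when
sedation is not reached).  Concentration enters the logit linearly in
pg/mL — the published intercept 0.27 and slope 0.01 imply 78.1%
success probability at 100 pg/mL and 192.7 pg/mL for a 90% target,
which the source rounds to "about 80%" and "about 180".  The MLE is
fitted by statsmodels; separation fails loudly with a diagnostic
rather than being penalized away, a deliberate choice at this cohort
size.  The single-cohort intercept estimate at n = 2000 carries a
sampling SD of ~0.15 (the intercept extrapolates to zero exposure,
below ~99% of simulated Cmax values), so recovery experiments report
means over replicate cohorts.

## Trial simulation

Virtual subjects draw eta from Omega; exposure metrics are
residual-free predicted Cmax over 0–24 h (matching the typical
EBE-based usage; a flag adds residual error).  Adults: 1000 subjects
at exactly 40/60/80/100 kg, patient state, 100 ug.  Pediatrics: body
weight uniform within each stratum (10–20, 20–30, 30–50 kg at
30/50/75 ug) — the stratified-sampling distribution is not documented,
uniform is the default and truncated-lognormal is one code path away —
with patient-state absorption and pure allometric extrapolation (no
maturation function; above ~10 kg maturation of clearance is largely
complete, but this remains an extrapolation assumption, not a
validated pediatric model).  The CI of the mean is a 1000-draw
percentile bootstrap; PTA is the empirical fraction of draws at or
above 100 or 180 pg/mL.

## Synthetic data

The generator emulates the two study designs:

- Phase I (48 healthy volunteers): 12+12 IV 20/40 ug over 15 min with
  a 14-point grid to 10 h; 12 intranasal 150 ug and 12 split-dose
  100/20 ug with 17-point grids to 24 h; every subject also carries a
  predose missing-DV row.
- Phase III (148 patients, 74 per 75/100-ug arm): two samples each.
  Sedation is assessed at 15/30/45 min.  Each subject draws a single
  latent uniform u; sedation onset is the first assessment where the
  running Cmax makes the logistic probability exceed u.  Because the
  running Cmax is non-decreasing, the marginal success probability is
  exactly the logistic curve at the 45-min Cmax, while onset times
  remain well-defined — the property the law-of-total-probability test
  checks.  Sample 1 falls within 5 min of onset (or of the 45-min
  assessment); sample 2 is drawn at 2–4 h (surgery end, an assumption
  — the duration is not documented) for half the arm and 8 ± 1 h for
  the rest.

Covariates match the published baseline table: body weight truncated
lognormal around the per-study median (log-SD 0.12 phase I, 0.15 phase
III, truncated to the printed ranges), age uniform over the printed
range, sex at the printed counts, BMI uniform over the printed range
with height back-solved (`h = sqrt(BW/BMI)`) and BSA by Du Bois — so
BW, BSA and BMI reproduce the multicollinearity the screening step
expects (r(BW, BSA) > 0.9 in generated cohorts).

The default LLOQ is 2 pg/mL: at the final-model parameters and these
designs it leaves ~1.4% of observations below quantification,
concentrated in the 16–24 h samples — the "close to 1%" regime the M1
method is appropriate for.  (At 5 pg/mL the same designs would censor
~2.7%.)  A deliberately small `generate_single_arm` design exists for
calibration and property experiments; it is not one of the study
designs.

What the generator does not emulate: dropout and missing covariates,
assay failures, inter-occasion variability (single-dose studies),
deviations from nominal sampling times in phase I, and any real-data
idiosyncrasies beyond the published design and summary statistics.
Passing recovery tests on this generator therefore demonstrates
internal consistency of the estimator and pipeline under the stated
model, not fidelity to the confidential data.

## Problem sizes in the test suite

The suite favours designs that make each property sharp at small
scale: the full two-study design (196 subjects, ~1040 quantifiable
observations) for the refit and CWRES checks; 100 replicates of a
32-subject single-arm design (IIV on CL only) for the null ΔOFV
calibration; 20 such replicates for the false-inclusion rate; ten
replicate full studies for pcVPC coverage; and 20-iteration bootstraps
with nuisance parameters held for the bootstrap behaviour.  The
acceptance script averages three full-design refits and 200
exposure-response cohorts, sizes at which the Monte-Carlo error of the
reported means is small relative to the quantities themselves.
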