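# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `flunipk`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Study design emulated

The generator reproduces a two-phase crossover design in dairy goats:
flunixin meglumine at 1.1 mg/kg given IV and SC to each animal (washout
between arms), as a single dose or every 12 h for six treatments. Blood is
sampled at 0, 5, 10, 15, 30 and 45 min and 1–48 h after the (last) dose;
milk at 1, 2, 4, 6, 8 and 18 h by hand and at 12-h machine milkings out to
96–120 h. Three cohorts are modelled — pregnant non-lactating, nulliparous
non-lactating and lactating does — with body-weight ranges of 64–96,
32.5–61 and 75–95 kg and clearance magnitudes of 114, 182 and 265 ml/kg/h
respectively; milk is generated only for the lactating cohort.

## Plasma model (simulator ground truth)

The parent drug follows a one-compartment model with first-order
elimination k = CL/V. This is the simplest model whose NCA truth is closed
form, and with the cohort CL/V magnitudes above it reproduces terminal
half-lives in the observed 2–5 h range. An IV bolus contributes
(D/V)·e^(−k·τ); an SC dose contributes first-order absorption,
(F·D·ka)/(V·(ka−k))·(e^(−k·τ) − e^(−ka·τ)), τ the time since that dose.
Multiple doses combine by superposition (verified exactly in the tests).
The metabolite amount follows dAm/dt = fm·k·Ap − km·Am (Bateman form) with
its own volume Vm. Defaults ka = 2 /h, F = 0.9, fm = 0.95, km = 1 /h,
Vm = 5000 ml/kg were chosen once so that metabolite exposure sits near 5%
of parent exposure with an apparent metabolite clearance near 5000 ml/kg/h,
matching the observed magnitudes; they are free parameters of the
simulator, not estimates.

Rate-constant degeneracy (ka ≈ k, or km equal to any parent rate) is
resolved analytically: when two rates differ by less than 1e−8 /h the
kernels switch to their limits (τ·e^(−kτ), and τ²/2·e^(−kτ) for the double
coincidence) rather than dividing by a near-zero difference.

Units are hours, ng/ml, ml/kg and ml/kg/h throughout the simulator; doses
convert mg/kg → ng/kg (×10⁶) so that amount/volume is ng/ml.

## Milk model

Two generators are provided. *Partition* mode sets milk concentration to
P_milk × plasma metabolite concentration at each milking time
(complete-evacuation, instantaneous-equilibrium assumption). *Empirical*
mode — the workhorse for the withdrawal machinery — places the post-dose
peak at the first milking ≥ 1 h after the last dose and decays
log-linearly, C(t) = C0·e^(−λ_milk·(t − t_last_dose)) from the peak onward,
with a linear rise before it; only post-peak points feed the withdrawal
regression. C0 defaults to the partition value at the peak milking so the
two modes agree there. No milk:plasma partition measurement exists for this
drug in goats, so P_milk (default 2) and λ_milk (default 0.1155 /h, a 6-h
depletion half-life consistent with the estimated 36–60 h intervals) are
simulator conditions, not data-derived claims.

## Assay error and censoring

Measured values are the true values multiplied by N(1, CV²) deviates with
CV = √(cv_intra² + cv_inter²), truncated at zero. A multiplicative normal
(rather than log-normal) model was chosen because the assay CVs are small
(≤ 6%), where the two are indistinguishable; this keeps the
moment-recovery tests exactly interpretable. Method limits are, by
(analyte, matrix): LOD/LOQ 0.1/0.5 (parent, plasma), 0.3/0.9 (parent,
milk), 0.3/0.8 (metabolite, plasma) and 0.4/0.9 ng/ml (metabolite, milk),
with intra/inter-assay CVs of 3.2–5.7%. Values below the LOD are flagged
BLD, values in [LOD, LOQ) BLQ; censored points carry no numeric value.
Between-animal variability is log-normal (median = cohort mean, CV default
0.2) on rates and volumes; the bounded fractions F and fm are drawn the
same way and clipped to their valid range.

## Noncompartmental analysis

* **Trapezoid convention.** "Log-linear trapezoidal" is implemented as
  linear-up/log-down: declining intervals use
  ΔAUC = (C1−C2)·Δt/ln(C1/C2) and the matching first-moment rule
  (t1·C1 − t2·C2)/k + (C1−C2)/k² with k = ln(C1/C2)/Δt; level or rising
  intervals use the linear trapezoid (a pure-log rule is undefined there).
* **Terminal slope.** All contiguous terminal windows of ≥ 3 quantified
  positive points are scanned — starting strictly after Tmax for
  extravascular routes, strictly after the first sample for IV — and the
  window with the highest adjusted R² wins, requiring a negative slope;
  ties prefer more points. Failure raises a typed error carrying
  diagnostics; the profile-level routine then reports the observed
  parameters (Cmax, Tmax, AUClast) with the λz-dependent block as NaN.
* **Extrapolation** uses the observed Clast (the common software default);
  an extrapolated fraction ≥ 20% is recorded as a warning, not an error.
* **Censoring.** A censored pre-dose t = 0 sample is integrated as zero;
  censored interior points are dropped and the trapezoid spans the gap.
* **Units.** Inputs in ng/ml are reported as μg/ml (and h·μg/ml) for the
  concentration/area block; CL and volumes are computed in consistent
  internal units (ml/kg/h, ml/kg).
* **Extraction ratio.** Cardiac output is allometric, 180·BW⁻⁰·¹⁹
  ml/kg/min, converted to ml/kg/h so E = CL/CO is dimensionless. Computed
  this way E is of order 0.02–0.06 for these clearances; published values
  above 1 for this quantity imply a different unit convention that cannot
  be reconstructed, so the package documents the dimensionless definition
  and makes no attempt to reproduce values above 1. An apparent (CL/F)
  clearance is rejected — the ratio is defined for systemic clearance only.

Bioavailability is the within-animal ratio AUC∞(SC)/AUC∞(IV). Note that
the mean of per-animal ratios differs from the ratio of group-mean AUCs;
per-animal computation is authoritative throughout, since summary rows do
not commute through nonlinear functions.

## ELISA calibration

The descending four-parameter logistic y = D + (A−D)/(1 + (x/C)^B) is fit
by nonlinear least squares with starting values from the data range
(A = max y, D = min y, C = median positive x, B = 1), requiring ≥ 5
distinct concentrations including zero (which pins A). Inversion is closed
form, x = C·((A−y)/(y−D))^(1/B), defined only for absorbances strictly
inside (D, A) — readings outside require re-dilution. IC_q is the
concentration reducing the zero-analyte absorbance by fraction q; the LOD
is the plate-averaged IC10 and the working range IC15–IC85, all scaled by
the dilution factor (the limits are homogeneous of degree 1 in dilution).

The per-time-point method-agreement test pre-tests variance equality with
a two-sided F test at α = 0.05 (a deliberate, switchable choice among
equal-variance tests), then applies the pooled t test, or Welch's test if
equality is rejected. A summary-statistic mode exists so published
(mean, SD, n) rows can be replayed without raw data; published per-time
P values are not recoverable from summaries alone (they were evidently
computed on raw, possibly paired, data), so equal printed means simply
force t = 0, p = 1.

## Monte Carlo augmentation

Each measured value spawns k additional replicates (default 2, giving
triplicates) drawn from N(value, cv·value) with the milk intra-assay CV of
3.2%. Virtual animals are drawn per time point from the real animals' mean
and SD at that time, independently across times, exactly as a
per-time-point procedure implies; correlated-profile generation is out of
scope. Negative draws are truncated at zero (the procedure's source is
silent on this; truncation bias is negligible at CV ≤ 6%), and sub-LOQ
handling is surfaced as configuration (excluded by default). Real
measurements always pass through byte-identical. Sampling times are
matched to a common grid within 0.01 h; by default the standalone
virtual-animal operation demands a complete common grid (error listing
missing times), while the FDA pipeline relaxes this so that
censoring-driven dropout at late times does not abort augmentation — grid
times observed in fewer than two animals are simply not generated for
virtual animals.

## Withdrawal estimation

The depletion dataset keeps post-last-dose, post-peak records whose
concentration is strictly greater than the LOQ (a value exactly at the
limit is excluded), on the natural-log scale; exclusion counts by reason
are retained. Fewer than 3 points or 2 animals is a typed
insufficient-data failure, mirroring datasets that are "not calculable".

The pooled OLS treats all points as independent — no per-animal random
effect — matching the regression the regulatory tools fit. Pre-checks are
computed and stored: a pure-error lack-of-fit F test (replicated times), a
Bartlett test of variance homogeneity across time groups, and the
one-sided significance of the slope. A slope that is not significantly
negative at α = 0.05 is a hard not-calculable failure; the other two
pre-checks warn by default and can be promoted to hard failures, since
which check invalidates a given dataset is tool-dependent.

The tolerance bound uses the noncentral-t formulation with
leverage-dependent noncentrality (see README for the formula). This is the
standard one-sided regression tolerance bound underlying both regulatory
tools; its claimed coverage is verified by Monte Carlo in the test suite
rather than assumed. The crossing search evaluates the bound on a 512-point
grid over the horizon (default 10× the observed time span) and refines the
last down-crossing by Brent's method; if the bound never falls below
ln(limit) within the horizon the result is a typed not-calculable failure.
Residual SDs below 1e−10 collapse the bound onto the mean line exactly,
so noise-free data reproduce the analytic crossing ln(C0/MRL)/λ.

**Outlier screen.** Animals are screened by leave-one-animal-out
studentization: each animal's residuals are measured against the regression
fitted to the other animals and scaled by that fit's prediction SE, and the
animal is excluded (one round at most, default threshold 3) if its mean
absolute studentized residual exceeds the threshold. Point-level external
studentization was rejected deliberately: an animal whose whole curve is
shifted inflates the pooled residual SD through its own remaining points,
capping point-level studentized residuals near ~2.8 regardless of the shift
magnitude in an 8-animal × 6-time design — the screen would never fire.
The leave-one-animal-out form flags gross animal-level outliers while
leaving homogeneous data untouched.

**Rounding.** The continuous estimate is rounded to the smallest
nonnegative integer multiple of the milking interval that is ≥ the
estimate; exact multiples are kept (36.0 h stays 36 h) — "next milking"
is interpreted as a ceiling, not a strict successor.

**Regression base.** The machinery works on natural logs; rescaling the
data to log10 with a correspondingly rescaled limit gives identical
withdrawal times (base-invariance, tested to 1e−9 h), and regressing on
observed versus nominal times is inert when the generator emits nominal
times. The EMA path runs at p = 0.95, γ = 0.95; the FDA path at p = 0.99,
γ = 0.95 after enforcing (or establishing by augmentation) the
10-animal/triplicate contract, with virtual/replicate provenance kept in
the diagnostics.

## Pipeline, configuration and determinism

`run_study_pipeline` binds the stages: simulate the lactating crossover
cohort (plasma parent + metabolite, milk) and a second plasma-only cohort,
run per-animal NCA on both routes with crossover F, compare IV clearance
between cohorts (Shapiro–Wilk per group at α = 0.05, then the unpaired t
test if both pass and the two-sided Mann–Whitney test otherwise), build
the milk depletion dataset and run the requested withdrawal methods. Every
stochastic stage draws from a child generator spawned from the single root
seed, so identical configurations give byte-identical JSON reports; stage
failures are captured as `not_calculable` report sections with diagnostics
rather than aborting the run. The CLI (`flunipk simulate|nca|withdraw|run`)
is a thin wrapper over these functions; YAML configuration overrides the
defaults and flags override the file.

The injection-site utility scores daily observations on the five-point
scale used for SC sites: 0/1/2 points for no swelling, swelling < 2 cm, or
swelling > 2 cm, plus one point each for heat, redness and pain.

## Problem sizes

The simulation-backed checks use sizes chosen to give stable Monte Carlo
estimates at interactive runtimes: 1,000 replicate depletion studies
(8 animals × 7 times, ln-scale residual SD 0.15) for tolerance-limit
coverage, 5,000 null replicates for each two-stage type-I-error estimate,
5,000 draws for moment-recovery checks, and dense 0.01-h grids for the
integration oracles. At these sizes the binomial SE of a 95% coverage
estimate is ~0.7 percentage points and of a 5% rejection rate ~0.3 points.

## What the synthetic data do and do not show

The generator shares the real study's design (schedules, doses, cohort
sizes, assay limits and CVs) but idealizes the biology: one-compartment
parent kinetics, exactly log-linear milk depletion, independent
multiplicative assay error, and no milk-yield dynamics, enterohepatic
recycling, or disease-state (e.g. mastitis) kinetics. Passing tests
therefore demonstrate that the estimators recover known truth under the
stated error model and sample sizes — not that any particular field
dataset satisfies that model. Real depletion data must still pass the
lack-of-fit, variance-homogeneity and slope pre-checks before the
tolerance-limit numbers mean what they claim.

## Known limitations

* No two-compartment or nonlinear mixed-effects plasma models; no
  physiologically based PK. No sparse-sampling (pooled) NCA.
* The EMA time-to-safe-concentration and safe-concentration-per-milking
  methods are not implemented (not applicable under a zero tolerance,
  where the operational limit sits below all quantifiable values).
* Virtual animals are uncorrelated across time points by construction.
  The regression offers only a per-animal-means sensitivity mode
  (collapsing replicates) rather than a full random-effects model.
* The published per-time-point agreement P values and the printed
  extraction-ratio magnitudes cannot be reproduced from summary data and
  are documented as such rather than fitted.
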