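"""Synthetic crossover-study data generator.

Produces plasma parent/metabolite and milk marker-residue concentration–time
data with known ground truth, emulating a two-phase crossover design in dairy
goats: single 1.1 mg/kg doses of flunixin meglumine given IV or SC, and a
multiple-dose regimen of 1.1 mg/kg every 12 h for six treatments.  The parent
drug (flunixin, FLU) follows one-compartment first-order kinetics; the
metabolite (5-hydroxy flunixin, 5-OH) follows the Bateman form driven by the
fraction of parent converted.  Milk 5-OH can be generated either by an
instantaneous-partition assumption against plasma or by an empirical
log-linear depletion curve, the latter being the workhorse for the
withdrawal-interval machinery.

Units: time in hours, concentrations in ng/ml, doses in mg/kg (converted to
ng/kg internally), volumes in ml/kg, clearances in ml/kg/h.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Route",
    "Censor",
    "Cohort",
    "DoseEvent",
    "Regimen",
    "TruePKParameters",
    "AssayNoiseModel",
    "ConcentrationSeries",
    "AnimalProfile",
    "ANALYTE_PARENT",
    "ANALYTE_METABOLITE",
    "MATRIX_PLASMA",
    "MATRIX_MILK",
    "RATE_TOL",
    "MG_PER_KG_TO_NG_PER_KG",
    "single_dose_regimen",
    "q12h_regimen",
    "simulate_plasma_profile",
    "simulate_milk_profile",
    "milk_depletion_curve",
    "apply_assay_noise",
    "generate_cohort",
    "analytic_auc_inf_parent",
    "COHORT_PARAMS",
    "COHORT_BW_RANGES",
    "ASSAY_LIMITS_NG_ML",
    "PLASMA_SCHEDULE_H",
    "MILK_SCHEDULE_SINGLE_H",
    "MILK_SCHEDULE_MULTI_H",
    "DEFAULT_DOSE_MG_KG",
]

# ---------------------------------------------------------------------------
# Constants and enumerations
# ---------------------------------------------------------------------------

#: Conversion of a mg/kg dose to ng/kg so that amount/volume yields ng/ml.
MG_PER_KG_TO_NG_PER_KG = 1.0e6

#: Rate-constant difference (1/h) below which the Bateman expression is
#: replaced by its analytic limit (t * exp kernel) to avoid ~0 division.
RATE_TOL = 1e-8

DEFAULT_DOSE_MG_KG = 1.1

ANALYTE_PARENT = "FLU"
ANALYTE_METABOLITE = "5-OH"
MATRIX_PLASMA = "plasma"
MATRIX_MILK = "milk"


class Route(str, enum.Enum):
    IV = "IV"
    SC = "SC"


class Censor(str, enum.Enum):
    QUANTIFIED = "Q"
    BELOW_LOQ = "BLQ"
    BELOW_LOD = "BLD"


class Cohort(str, enum.Enum):
    PREGNANT_NL = "pregnant_NL"
    NULLIPAROUS_NL = "nulliparous_NL"
    LACTATING = "lactating"


#: Blood sampling schedule (h) shared by both study phases: 0, 5, 10, 15, 30,
#: 45 min then 1–48 h.
PLASMA_SCHEDULE_H = (
    0.0, 5 / 60, 10 / 60, 15 / 60, 0.5, 0.75,
    1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 30.0, 32.0, 36.0, 48.0,
)

#: Milking schedule (h after the single dose): hand milkings at 1–18 h plus
#: machine milkings to 120 h.
MILK_SCHEDULE_SINGLE_H = (
    1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 36.0, 48.0,
    60.0, 72.0, 84.0, 96.0, 108.0, 120.0,
)

#: Milking schedule (h after the last of six q12h doses).
MILK_SCHEDULE_MULTI_H = (
    1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 36.0, 48.0,
    60.0, 72.0, 84.0, 96.0,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEvent:
    """One dose administration: time (h since study start), mg/kg, route."""

    time: float
    dose: float
    route: Route

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.dose <= 0:
            raise ValueError(f"dose must be > 0, got {self.dose}")
        object.__setattr__(self, "route", Route(self.route))


@dataclass(frozen=True)
class Regimen:
    """Ordered dose events; all routes identical within one regimen arm."""

    events: tuple[DoseEvent, ...]

    def __post_init__(self) -> None:
        events = tuple(self.events)
        if not events:
            raise ValueError("regimen must contain at least one dose event")
        times = [e.time for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        routes = {e.route for e in events}
        if len(routes) > 1:
            raise ValueError("all routes must be identical within one regimen arm")
        object.__setattr__(self, "events", events)

    @property
    def route(self) -> Route:
        return self.events[0].route

    @property
    def last_dose_time(self) -> float:
        return self.events[-1].time


def single_dose_regimen(dose: float = DEFAULT_DOSE_MG_KG,
                        route: Route | str = Route.IV) -> Regimen:
    return Regimen((DoseEvent(0.0, dose, Route(route)),))


def q12h_regimen(dose: float = DEFAULT_DOSE_MG_KG,
                 route: Route | str = Route.IV,
                 n_doses: int = 6,
                 interval: float = 12.0) -> Regimen:
    """Every-12-hours multiple dosing, six treatments by default."""
    return Regimen(tuple(
        DoseEvent(i * interval, dose, Route(route)) for i in range(n_doses)
    ))


@dataclass(frozen=True)
class TruePKParameters:
    """Simulator ground truth for one animal.

    CL, V refer to the parent drug; ka and F govern SC absorption; fm is the
    fraction of eliminated parent converted to the metabolite, which is
    cleared with first-order rate km from volume Vm.  P_milk is the
    milk:plasma partition coefficient and lambda_milk the empirical milk
    depletion rate used by the empirical milk generator.
    """

    CL: float          # ml/kg/h
    V: float           # ml/kg
    ka: float = 2.0    # 1/h
    F: float = 0.9     # fraction of SC dose absorbed
    fm: float = 0.95   # fraction of parent converted to metabolite
    km: float = 1.0    # 1/h metabolite elimination
    Vm: float = 5000.0  # ml/kg metabolite volume
    P_milk: float = 2.0       # milk:plasma partition (free parameter)
    lambda_milk: float = 0.1155  # 1/h empirical milk depletion rate

    def __post_init__(self) -> None:
        for name in ("CL", "V", "ka", "km", "Vm", "P_milk", "lambda_milk"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.F <= 1:
            raise ValueError("F must be in (0, 1]")
        if not 0 <= self.fm <= 1:
            raise ValueError("fm must be in [0, 1]")

    @property
    def k(self) -> float:
        """Parent elimination rate constant CL/V (1/h)."""
        return self.CL / self.V


#: Per-cohort parameter means with magnitudes matching the study groups:
#: pregnant non-lactating (CL ~114 ml/kg/h), nulliparous non-lactating
#: (CL ~182) and lactating does (CL ~265); volumes chosen to put terminal
#: half-lives in the observed 2–5 h range.
COHORT_PARAMS: dict[Cohort, TruePKParameters] = {
    Cohort.PREGNANT_NL: TruePKParameters(CL=114.0, V=444.0),
    Cohort.NULLIPAROUS_NL: TruePKParameters(CL=182.0, V=903.0),
    Cohort.LACTATING: TruePKParameters(CL=265.0, V=1400.0),
}

#: Body-weight ranges (kg) per cohort.
COHORT_BW_RANGES: dict[Cohort, tuple[float, float]] = {
    Cohort.PREGNANT_NL: (64.0, 96.0),
    Cohort.NULLIPAROUS_NL: (32.5, 61.0),
    Cohort.LACTATING: (75.0, 95.0),
}


@dataclass(frozen=True)
class AssayNoiseModel:
    """Multiplicative assay error plus detection/quantification limits."""

    cv_intra: float
    cv_inter: float
    lod: float  # ng/ml
    loq: float  # ng/ml

    def __post_init__(self) -> None:
        if not (0 <= self.cv_intra < 1 and 0 <= self.cv_inter < 1):
            raise ValueError("CVs must lie in [0, 1)")
        if not 0 < self.lod <= self.loq:
            raise ValueError("require 0 < lod <= loq")

    @property
    def cv_combined(self) -> float:
        return float(np.hypot(self.cv_intra, self.cv_inter))


#: UPLC-MS/MS method limits and CVs by (analyte, matrix): LOD/LOQ of 0.1/0.5
#: (plasma FLU), 0.3/0.9 (milk FLU), 0.3/0.8 (plasma 5-OH), 0.4/0.9 (milk
#: 5-OH) ng/ml, with intra/inter-assay CVs between 3.2 and 5.7%.
ASSAY_LIMITS_NG_ML: dict[tuple[str, str], AssayNoiseModel] = {
    (ANALYTE_PARENT, MATRIX_PLASMA): AssayNoiseModel(0.043, 0.052, 0.1, 0.5),
    (ANALYTE_PARENT, MATRIX_MILK): AssayNoiseModel(0.034, 0.047, 0.3, 0.9),
    (ANALYTE_METABOLITE, MATRIX_PLASMA): AssayNoiseModel(0.043, 0.057, 0.3, 0.8),
    (ANALYTE_METABOLITE, MATRIX_MILK): AssayNoiseModel(0.032, 0.057, 0.4, 0.9),
}


@dataclass
class ConcentrationSeries:
    """One animal x analyte x matrix concentration-time trace.

    ``concs`` holds NaN wherever the point is censored (below LOD/LOQ the
    numeric value carries no information); ``censor`` holds the matching
    flag per point.  ``route`` records the treatment arm the sample belongs
    to (crossover animals have one series per arm).
    """

    animal_id: str
    analyte: str
    matrix: str
    times: np.ndarray
    concs: np.ndarray
    censor: list[Censor] = field(default_factory=list)
    route: Route | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.shape != self.concs.shape:
            raise ValueError("times and concs must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.censor:
            self.censor = [Censor.QUANTIFIED] * len(self.times)
        if len(self.censor) != len(self.times):
            raise ValueError("censor flags must match number of points")
        self.censor = [Censor(c) for c in self.censor]
        if self.route is not None:
            self.route = Route(self.route)

    def __len__(self) -> int:
        return len(self.times)

    def quantified(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of the quantified points only."""
        mask = np.array([c is Censor.QUANTIFIED for c in self.censor])
        return self.times[mask], self.concs[mask]


@dataclass
class AnimalProfile:
    """One study animal with its ground-truth parameters and series."""

    id: str
    body_weight: float
    cohort: Cohort
    true_params: TruePKParameters
    series: list[ConcentrationSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        self.cohort = Cohort(self.cohort)

    @property
    def lactating(self) -> bool:
        return self.cohort is Cohort.LACTATING


# ---------------------------------------------------------------------------
# Kinetic kernels
# ---------------------------------------------------------------------------


def _bateman(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    """(exp(-a*tau) - exp(-b*tau)) / (b - a), with the a==b analytic limit."""
    if abs(b - a) < RATE_TOL:
        return tau * np.exp(-a * tau)
    return (np.exp(-a * tau) - np.exp(-b * tau)) / (b - a)


def _conv_t_exp(a: float, b: float, tau: np.ndarray) -> np.ndarray:
    """Convolution of u*exp(-a*u) with exp(-b*u):

    int_0^tau exp(-b*(tau-u)) * u * exp(-a*u) du,
    with the a==b limit tau^2/2 * exp(-a*tau).
    """
    d = a - b
    if abs(d) < RATE_TOL:
        return 0.5 * tau ** 2 * np.exp(-a * tau)
    return np.exp(-b * tau) * (1.0 - np.exp(-d * tau) * (1.0 + d * tau)) / d ** 2


def _parent_terms(params: TruePKParameters,
                  event: DoseEvent) -> tuple[list[tuple[float, float]],
                                             list[tuple[float, float]]]:
    """Exponential representation of the parent *amount* (ng/kg) after one dose.

    Returns (exp_terms, texp_terms) where exp_terms are (coef, rate) pairs for
    coef*exp(-rate*tau) and texp_terms are (coef, rate) pairs for
    coef*tau*exp(-rate*tau) (used only when ka collapses onto k).
    """
    D = event.dose * MG_PER_KG_TO_NG_PER_KG
    k = params.k
    if event.route is Route.IV:
        return [(D, k)], []
    ka = params.ka
    if abs(ka - k) < RATE_TOL:
        return [], [(params.F * D * ka, k)]
    c = params.F * D * ka / (ka - k)
    return [(c, k), (-c, ka)], []


def simulate_plasma_profile(
    params: TruePKParameters,
    regimen: Regimen,
    sample_times: Sequence[float],
    animal_id: str = "sim",
) -> tuple[ConcentrationSeries, ConcentrationSeries]:
    """Noise-free plasma parent and metabolite profiles under ``regimen``.

    The parent follows one-compartment kinetics with k = CL/V; an IV bolus
    contributes (D/V)*exp(-k*(t-td)) and an SC dose the first-order absorption
    form (F*D*ka)/(V*(ka-k)) * (exp(-k*(t-td)) - exp(-ka*(t-td))).  Multiple
    doses combine by superposition.  The metabolite amount obeys
    dAm/dt = fm*k*Ap - km*Am with volume Vm (Bateman form).  When two rate
    constants coincide within ``RATE_TOL`` the analytic t*exp limit kernels
    are used instead of dividing by ~0.
    """
    t = np.asarray(sample_times, dtype=float)
    if np.any(t < 0):
        raise ValueError("sample times must be >= 0")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")

    k, km, fm = params.k, params.km, params.fm
    parent_amt = np.zeros_like(t)
    metab_amt = np.zeros_like(t)
    for event in regimen.events:
        tau = t - event.time
        live = tau >= 0
        if not live.any():
            continue
        tau = tau[live]
        exp_terms, texp_terms = _parent_terms(params, event)
        p = np.zeros_like(tau)
        m = np.zeros_like(tau)
        for coef, rate in exp_terms:
            p += coef * np.exp(-rate * tau)
            m += fm * k * coef * _bateman(rate, km, tau)
        for coef, rate in texp_terms:
            p += coef * tau * np.exp(-rate * tau)
            m += fm * k * coef * _conv_t_exp(rate, km, tau)
        parent_amt[live] += p
        metab_amt[live] += m

    parent = ConcentrationSeries(
        animal_id, ANALYTE_PARENT, MATRIX_PLASMA, t, parent_amt / params.V,
        route=regimen.route,
    )
    metab = ConcentrationSeries(
        animal_id, ANALYTE_METABOLITE, MATRIX_PLASMA, t, metab_amt / params.Vm,
        route=regimen.route,
    )
    return parent, metab


def analytic_auc_inf_parent(params: TruePKParameters, regimen: Regimen) -> float:
    """Closed-form parent AUC(0-inf) in h*ng/ml: absorbed dose / CL."""
    f = 1.0 if regimen.route is Route.IV else params.F
    total = sum(e.dose for e in regimen.events) * MG_PER_KG_TO_NG_PER_KG
    return f * total / params.CL


# ---------------------------------------------------------------------------
# Milk generation
# ---------------------------------------------------------------------------


def milk_depletion_curve(t_since_last_dose: np.ndarray | float,
                         c0: float, lambda_milk: float) -> np.ndarray | float:
    """Empirical marker-residue depletion C(t) = C0 * exp(-lambda * t).

    ``t_since_last_dose`` is hours after the final dose; the curve is the
    log-linear depletion the withdrawal regression estimates.
    """
    return c0 * np.exp(-lambda_milk * np.asarray(t_since_last_dose, dtype=float))


def simulate_milk_profile(
    params: TruePKParameters,
    regimen: Regimen,
    milking_times: Sequence[float],
    mode: str = "empirical",
    c0: float | None = None,
    cohort: Cohort | str = Cohort.LACTATING,
    animal_id: str = "sim",
) -> ConcentrationSeries:
    """Noise-free milk 5-OH profile at the given milking times.

    ``partition`` mode multiplies the plasma metabolite concentration by
    P_milk at each milking time (complete-evacuation, instantaneous
    equilibrium).  ``empirical`` mode places the post-last-dose peak at the
    first milking at least 1 h after the final dose and decays log-linearly,
    C(t) = C0*exp(-lambda_milk*(t - t_last_dose)) for t at/after the peak,
    preceded by a linear rise; C0 defaults to P_milk times the plasma
    metabolite concentration at the peak milking.
    """
    if Cohort(cohort) is not Cohort.LACTATING:
        raise ValueError("milk profiles are only defined for the lactating cohort")
    times = np.asarray(milking_times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("milking times must be strictly increasing")

    if mode == "partition":
        _, metab = simulate_plasma_profile(params, regimen, times, animal_id)
        conc = params.P_milk * metab.concs
    elif mode == "empirical":
        t_last = regimen.last_dose_time
        post = times[times >= t_last + 1.0]
        if post.size == 0:
            raise ValueError("no milking time >= 1 h after the last dose")
        t_peak = float(post[0])
        if c0 is None:
            _, metab = simulate_plasma_profile(params, regimen, [t_peak], animal_id)
            c0 = params.P_milk * float(metab.concs[0])
        lam = params.lambda_milk
        conc = np.zeros_like(times)
        rising = (times >= t_last) & (times < t_peak)
        decaying = times >= t_peak
        peak_value = float(milk_depletion_curve(t_peak - t_last, c0, lam))
        if t_peak > t_last:
            conc[rising] = peak_value * (times[rising] - t_last) / (t_peak - t_last)
        conc[decaying] = milk_depletion_curve(times[decaying] - t_last, c0, lam)
    else:
        raise ValueError(f"unknown milk mode {mode!r}")

    return ConcentrationSeries(
        animal_id, ANALYTE_METABOLITE, MATRIX_MILK, times, conc,
        route=regimen.route,
    )


# ---------------------------------------------------------------------------
# Assay noise and censoring
# ---------------------------------------------------------------------------


def _censor_flag(value: float, noise: AssayNoiseModel) -> Censor:
    if value < noise.lod:
        return Censor.BELOW_LOD
    if value < noise.loq:
        return Censor.BELOW_LOQ
    return Censor.QUANTIFIED


def apply_assay_noise(series: ConcentrationSeries,
                      noise: AssayNoiseModel,
                      seed: int | np.random.Generator) -> ConcentrationSeries:
    """Multiply each value by N(1, combined CV) and apply LOD/LOQ censoring.

    The combined CV is sqrt(cv_intra^2 + cv_inter^2); negative draws are
    truncated to 0.  Values below the LOD are flagged BELOW_LOD, values in
    [LOD, LOQ) BELOW_LOQ; censored points have their numeric value suppressed
    (NaN).  Identical seed gives identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cv = noise.cv_combined
    if cv > 0:
        factors = rng.normal(1.0, cv, size=len(series))
    else:
        factors = np.ones(len(series))
    values = np.maximum(series.concs * factors, 0.0)
    flags = [_censor_flag(v, noise) for v in values]
    out = np.where([f is Censor.QUANTIFIED for f in flags], values, np.nan)
    return ConcentrationSeries(
        series.animal_id, series.analyte, series.matrix,
        series.times.copy(), out, flags, route=series.route,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_LOGNORMAL_FIELDS = ("CL", "V", "ka", "km", "Vm", "P_milk", "lambda_milk")


def generate_cohort(
    n_animals: int,
    cohort: Cohort | str,
    param_means: TruePKParameters | None = None,
    between_animal_cv: float = 0.2,
    bw_range: tuple[float, float] | None = None,
    seed: int | np.random.Generator = 0,
    id_prefix: str | None = None,
) -> list[AnimalProfile]:
    """Draw ``n_animals`` animals with log-normal between-animal variability.

    Rates/volumes are drawn log-normally with the given CV around (median =
    geometric mean =) the cohort means; the bounded fractions F and fm are
    drawn the same way and clipped to their valid range.  Body weights are
    uniform on ``bw_range``.  Reproducible under ``seed``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    cohort = Cohort(cohort)
    if param_means is None:
        param_means = COHORT_PARAMS[cohort]
    if bw_range is None:
        bw_range = COHORT_BW_RANGES[cohort]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prefix = id_prefix if id_prefix is not None else cohort.value

    sigma = float(np.sqrt(np.log1p(between_animal_cv ** 2)))
    animals: list[AnimalProfile] = []
    for i in range(n_animals):
        if sigma > 0:
            kw = {name: getattr(param_means, name) * np.exp(rng.normal(0.0, sigma))
                  for name in _LOGNORMAL_FIELDS}
            kw["F"] = min(param_means.F * np.exp(rng.normal(0.0, sigma)), 1.0)
            kw["fm"] = min(param_means.fm * np.exp(rng.normal(0.0, sigma)), 1.0)
        else:
            kw = {name: getattr(param_means, name)
                  for name in _LOGNORMAL_FIELDS + ("F", "fm")}
        bw = float(rng.uniform(*bw_range))
        animals.append(AnimalProfile(
            id=f"{prefix}-{i + 1:02d}",
            body_weight=bw,
            cohort=cohort,
            true_params=TruePKParameters(**kw),
        ))
    return animals
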