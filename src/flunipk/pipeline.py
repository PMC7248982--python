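"""Study orchestration: file I/O, configuration, cohort statistics,
injection-site scoring, and the end-to-end simulate -> NCA -> augment ->
withdrawal pipeline.

The long-format concentration CSV schema is
``animal_id,cohort,body_weight_kg,route,analyte,matrix,time_h,conc_ng_ml,censor``
with censor in {Q, BLQ, BLD}; censored rows carry an empty concentration.
All randomness derives from one root seed via spawned child generators, so
two runs with identical configuration produce byte-identical reports.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import nca as _nca
from .augment import AugmentationSpec
from .simulate import (
    ASSAY_LIMITS_NG_ML,
    ANALYTE_METABOLITE,
    ANALYTE_PARENT,
    MATRIX_MILK,
    MATRIX_PLASMA,
    MILK_SCHEDULE_MULTI_H,
    MILK_SCHEDULE_SINGLE_H,
    PLASMA_SCHEDULE_H,
    AnimalProfile,
    AssayNoiseModel,
    Censor,
    Cohort,
    ConcentrationSeries,
    Regimen,
    Route,
    apply_assay_noise,
    generate_cohort,
    q12h_regimen,
    simulate_milk_profile,
    simulate_plasma_profile,
    single_dose_regimen,
)
from .withdrawal import (
    NotCalculableError,
    build_depletion_dataset,
    ema_sclr,
    fda_milk_discard,
)

__all__ = [
    "CSV_COLUMNS",
    "StudyConfig",
    "GroupComparison",
    "GroupTestKind",
    "Swelling",
    "InjectionSiteObservation",
    "write_concentration_csv",
    "read_concentration_csv",
    "write_regimen_csv",
    "read_regimen_csv",
    "compare_parameter_groups",
    "injection_site_score",
    "run_study_pipeline",
]

CSV_COLUMNS = ["animal_id", "cohort", "body_weight_kg", "route", "analyte",
               "matrix", "time_h", "conc_ng_ml", "censor"]

REGIMEN_COLUMNS = ["time_h", "dose_mg_kg", "route"]

_VALID_ANALYTES = {ANALYTE_PARENT, ANALYTE_METABOLITE}
_VALID_MATRICES = {MATRIX_PLASMA, MATRIX_MILK}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Everything a reproducible end-to-end run needs.

    The defaults replay the crossover design: a lactating cohort of eight
    does dosed 1.1 mg/kg IV and SC (single dose, or q12h x 6 when
    ``regimen`` is "multiple"), the study's plasma and milking schedules,
    per-analyte/matrix assay noise, and the zero-tolerance operational MRL
    (milk marker-residue LOD, 0.4 ng/ml) with a 12-h milking interval.  A
    second, non-lactating cohort supports the age/status group comparison.
    """

    seed: int = 0
    n_lactating: int = 8
    n_comparison: int = 20
    comparison_cohort: str = Cohort.NULLIPAROUS_NL.value
    between_animal_cv: float = 0.2
    dose_mg_kg: float = 1.1
    regimen: str = "single"            # "single" | "multiple"
    plasma_times: tuple = PLASMA_SCHEDULE_H
    milking_times: tuple | None = None  # defaults by regimen
    milk_mode: str = "empirical"
    assay_noise: bool = True
    mrl: float = 0.4
    milking_interval: float = 12.0
    withdrawal_method: str = "both"    # "ema" | "fda" | "both"
    augmentation: AugmentationSpec | None = None
    strict_prechecks: bool = False

    def __post_init__(self) -> None:
        if self.regimen not in ("single", "multiple"):
            raise ValueError("regimen must be 'single' or 'multiple'")
        if self.withdrawal_method not in ("ema", "fda", "both"):
            raise ValueError("withdrawal_method must be ema, fda or both")
        if self.milking_times is None:
            self.milking_times = (MILK_SCHEDULE_SINGLE_H if self.regimen == "single"
                                  else MILK_SCHEDULE_MULTI_H)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        aug = raw.pop("augmentation", None)
        cfg = cls(**raw)
        if aug is not None:
            cfg.augmentation = AugmentationSpec(**aug)
        return cfg


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_concentration_csv(profiles, path: str | Path) -> None:
    """Write animal profiles to the long-format concentration CSV."""
    rows = []
    for p in profiles:
        for s in p.series:
            for t, c, flag in zip(s.times, s.concs, s.censor):
                rows.append({
                    "animal_id": p.id,
                    "cohort": p.cohort.value,
                    "body_weight_kg": p.body_weight,
                    "route": s.route.value if s.route else "",
                    "analyte": s.analyte,
                    "matrix": s.matrix,
                    "time_h": t,
                    "conc_ng_ml": "" if not math.isfinite(c) else c,
                    "censor": flag.value,
                })
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_concentration_csv(path: str | Path) -> list[AnimalProfile]:
    """Read and validate a long-format concentration CSV.

    Malformed rows raise errors naming the offending (1-based, header
    included) line number.
    """
    df = pd.read_csv(path, dtype={"animal_id": str, "censor": str})
    if list(df.columns) != CSV_COLUMNS:
        raise ValueError(
            f"unexpected header {list(df.columns)}; expected {CSV_COLUMNS}")

    for idx, row in df.iterrows():
        line = idx + 2
        if row["analyte"] not in _VALID_ANALYTES:
            raise ValueError(f"line {line}: unknown analyte {row['analyte']!r}")
        if row["matrix"] not in _VALID_MATRICES:
            raise ValueError(f"line {line}: unknown matrix {row['matrix']!r}")
        try:
            Censor(row["censor"])
        except ValueError:
            raise ValueError(f"line {line}: unknown censor flag {row['censor']!r}")
        conc = row["conc_ng_ml"]
        if pd.notna(conc) and float(conc) < 0:
            raise ValueError(f"line {line}: negative concentration {conc}")

    profiles: list[AnimalProfile] = []
    for (animal, cohort, bw), adf in df.groupby(
            ["animal_id", "cohort", "body_weight_kg"], sort=False):
        series = []
        for (route, analyte, matrix), g in adf.groupby(
                ["route", "analyte", "matrix"], sort=False):
            g = g.sort_values("time_h")
            concs = g["conc_ng_ml"].to_numpy(dtype=float)
            series.append(ConcentrationSeries(
                animal_id=animal, analyte=analyte, matrix=matrix,
                times=g["time_h"].to_numpy(dtype=float),
                concs=concs,
                censor=[Censor(c) for c in g["censor"]],
                route=Route(route) if isinstance(route, str) and route else None,
            ))
        from .simulate import COHORT_PARAMS  # placeholder truth for loaded data
        profiles.append(AnimalProfile(
            id=animal, body_weight=float(bw), cohort=Cohort(cohort),
            true_params=COHORT_PARAMS[Cohort(cohort)], series=series))
    return profiles


def write_regimen_csv(regimen: Regimen, path: str | Path) -> None:
    pd.DataFrame(
        [{"time_h": e.time, "dose_mg_kg": e.dose, "route": e.route.value}
         for e in regimen.events],
        columns=REGIMEN_COLUMNS,
    ).to_csv(path, index=False)


def read_regimen_csv(path: str | Path) -> Regimen:
    from .simulate import DoseEvent
    df = pd.read_csv(path)
    if list(df.columns) != REGIMEN_COLUMNS:
        raise ValueError(f"unexpected regimen header {list(df.columns)}")
    return Regimen(tuple(
        DoseEvent(float(r.time_h), float(r.dose_mg_kg), Route(r.route))
        for r in df.itertuples(index=False)))


# ---------------------------------------------------------------------------
# Cohort comparison statistics
# ---------------------------------------------------------------------------


class GroupTestKind(str, enum.Enum):
    UNPAIRED_T = "unpaired_t"
    MANN_WHITNEY = "mann_whitney"


@dataclass(frozen=True)
class GroupComparison:
    """Two-cohort comparison of one PK parameter."""

    parameter: str
    group_a: str
    group_b: str
    normality_p_a: float
    normality_p_b: float
    test_used: GroupTestKind
    p_value: float
    degenerate: bool = False


def compare_parameter_groups(values_a, values_b, parameter_name: str = "",
                             group_a: str = "A", group_b: str = "B",
                             alpha: float = 0.05) -> GroupComparison:
    """Shapiro-Wilk normality per group, then unpaired t or Mann-Whitney.

    Both groups passing normality at ``alpha`` selects the unpaired
    two-sided t test; otherwise the two-sided Mann-Whitney test.  A
    ties-only degenerate comparison (all values identical) returns p = 1
    flagged as degenerate.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 values")

    def _shapiro_p(x: np.ndarray) -> float:
        if np.ptp(x) == 0:
            return 0.0  # constant sample: treat as non-normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    if pa >= alpha and pb >= alpha:
        res = stats.ttest_ind(a, b, equal_var=True)
        return GroupComparison(parameter_name, group_a, group_b, pa, pb,
                               GroupTestKind.UNPAIRED_T, float(res.pvalue))
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupComparison(parameter_name, group_a, group_b, pa, pb,
                               GroupTestKind.MANN_WHITNEY, 1.0, degenerate=True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(parameter_name, group_a, group_b, pa, pb,
                           GroupTestKind.MANN_WHITNEY, float(res.pvalue))


# ---------------------------------------------------------------------------
# Injection-site scoring
# ---------------------------------------------------------------------------


class Swelling(str, enum.Enum):
    NONE = "none"
    UNDER_2CM = "under_2cm"
    OVER_2CM = "over_2cm"


@dataclass(frozen=True)
class InjectionSiteObservation:
    """Daily injection-site assessment: swelling category plus three signs."""

    swelling: Swelling = Swelling.NONE
    heat: bool = False
    redness: bool = False
    pain: bool = False


_SWELLING_POINTS = {Swelling.NONE: 0, Swelling.UNDER_2CM: 1, Swelling.OVER_2CM: 2}


def injection_site_score(obs: InjectionSiteObservation) -> int:
    """Five-point score: 0/1/2 for swelling (none, <2 cm, >2 cm) plus one
    point each for heat, redness and pain."""
    return (_SWELLING_POINTS[Swelling(obs.swelling)]
            + int(obs.heat) + int(obs.redness) + int(obs.pain))


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def _simulate_crossover_cohort(cfg: StudyConfig, rng_cohort, rng_noise,
                               cohort: Cohort, n: int,
                               with_milk: bool) -> list[AnimalProfile]:
    animals = generate_cohort(n, cohort, between_animal_cv=cfg.between_animal_cv,
                              seed=rng_cohort)
    make = single_dose_regimen if cfg.regimen == "single" else q12h_regimen
    for animal in animals:
        for route in (Route.IV, Route.SC):
            regimen = make(cfg.dose_mg_kg, route)
            t0 = regimen.last_dose_time
            plasma_times = tuple(t0 + t for t in cfg.plasma_times)
            parent, metab = simulate_plasma_profile(
                animal.true_params, regimen, plasma_times, animal.id)
            new_series = [parent, metab]
            if with_milk:
                milking = tuple(t0 + t for t in cfg.milking_times)
                new_series.append(simulate_milk_profile(
                    animal.true_params, regimen, milking, mode=cfg.milk_mode,
                    animal_id=animal.id))
            for s in new_series:
                if cfg.assay_noise:
                    s = apply_assay_noise(
                        s, ASSAY_LIMITS_NG_ML[(s.analyte, s.matrix)], rng_noise)
                animal.series.append(s)
    return animals


_SUMMARY_FIELDS = ("cmax_obs", "tmax_obs", "t_half_z", "auc_inf", "auc_pct_ext",
                   "vz_or_vzf", "cl_or_clf", "aumc_inf", "mrt_inf", "vss",
                   "e_body")


def _summarize(results: list[_nca.NCAResult]) -> dict:
    out = {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            out[name] = {"mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "n": int(vals.size)}
        else:
            out[name] = {"mean": None, "sd": None, "n": 0}
    return out


def _withdrawal_section(result) -> dict:
    return {
        "status": "ok",
        "method": result.method,
        "percentile": result.percentile,
        "confidence": result.confidence,
        "continuous_wdt_h": result.continuous_wdt,
        "rounded_wdt_h": result.rounded_wdt,
        "milking_interval_h": result.milking_interval,
        "mrl_ng_ml": result.mrl_used,
        "excluded_animals": result.excluded_animals,
        "diagnostics": result.diagnostics,
    }


def run_study_pipeline(config: StudyConfig,
                       out_dir: str | Path | None = None) -> dict:
    """Simulate, analyze and report one full synthetic study.

    Stages: cohort simulation (lactating crossover with milk; a second
    plasma-only cohort for the group comparison) -> per-animal NCA on both
    routes with crossover bioavailability -> cohort comparison of IV
    clearance -> milk depletion dataset -> EMA and/or FDA withdrawal
    estimates.  Stage failures are captured in the report as
    ``not_calculable`` sections with the stage's diagnostics; the rest of
    the report is still produced.  Fully reproducible under ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ("lact_cohort", "lact_noise", "cmp_cohort", "cmp_noise", "augment")
    rngs = dict(zip(keys, (np.random.default_rng(s) for s in ss.spawn(len(keys)))))

    lactating = _simulate_crossover_cohort(
        config, rngs["lact_cohort"], rngs["lact_noise"],
        Cohort.LACTATING, config.n_lactating, with_milk=True)
    comparison = _simulate_crossover_cohort(
        config, rngs["cmp_cohort"], rngs["cmp_noise"],
        Cohort(config.comparison_cohort), config.n_comparison, with_milk=False)

    report: dict = {
        "config": {
            "seed": config.seed, "regimen": config.regimen,
            "dose_mg_kg": config.dose_mg_kg,
            "n_lactating": config.n_lactating,
            "n_comparison": config.n_comparison,
            "mrl_ng_ml": config.mrl,
            "milking_interval_h": config.milking_interval,
            "assay_noise": config.assay_noise,
        },
        "log": [],
    }

    def log(stage, **info):
        report["log"].append({"stage": stage, **info})

    log("simulate", n_lactating=len(lactating), n_comparison=len(comparison),
        regimen=config.regimen)

    # --- NCA per cohort/route, crossover F --------------------------------
    nca_results: dict[str, dict[str, list[_nca.NCAResult]]] = {}
    f_values: dict[str, list[float]] = {}
    # NCA is run on the post-(last-)dose profile with the per-dose amount,
    # the convention for steady-state profiles.
    dose_total = config.dose_mg_kg
    for label, animals in (("lactating", lactating), ("comparison", comparison)):
        by_route: dict[str, list[_nca.NCAResult]] = {"IV": [], "SC": []}
        fs: list[float] = []
        for animal in animals:
            per_route = {}
            for s in animal.series:
                if s.matrix != MATRIX_PLASMA or s.analyte != ANALYTE_PARENT:
                    continue
                res = _nca.nca_single_profile(
                    s, dose_total, s.route, body_weight=animal.body_weight)
                by_route[s.route.value].append(res)
                per_route[s.route.value] = res
            if {"IV", "SC"} <= per_route.keys():
                try:
                    fs.append(_nca.bioavailability(
                        per_route["SC"], per_route["IV"]).f)
                except ValueError:
                    pass
        nca_results[label] = by_route
        f_values[label] = fs
    log("nca", profiles=sum(len(v) for by in nca_results.values()
                            for v in by.values()))

    report["pk_parameters"] = {
        label: {route: _summarize(results) for route, results in by.items()}
        for label, by in nca_results.items()
    }
    report["bioavailability"] = {
        label: {"per_animal_f": fs,
                "mean_f": float(np.mean(fs)) if fs else None,
                "n": len(fs)}
        for label, fs in f_values.items()
    }

    # --- group comparison on IV clearance ---------------------------------
    cl_a = [r.cl_or_clf for r in nca_results["lactating"]["IV"]
            if math.isfinite(r.cl_or_clf)]
    cl_b = [r.cl_or_clf for r in nca_results["comparison"]["IV"]
            if math.isfinite(r.cl_or_clf)]
    if len(cl_a) >= 3 and len(cl_b) >= 3:
        cmp_res = compare_parameter_groups(
            cl_a, cl_b, "CL_iv", "lactating", config.comparison_cohort)
        report["group_comparisons"] = [{
            "parameter": cmp_res.parameter,
            "groups": [cmp_res.group_a, cmp_res.group_b],
            "normality_p": [cmp_res.normality_p_a, cmp_res.normality_p_b],
            "test_used": cmp_res.test_used.value,
            "p_value": cmp_res.p_value,
        }]
    else:
        report["group_comparisons"] = []
    log("compare", n_comparisons=len(report["group_comparisons"]))

    # --- milk withdrawal ---------------------------------------------------
    make = single_dose_regimen if config.regimen == "single" else q12h_regimen
    last_dose = make(config.dose_mg_kg, Route.IV).last_dose_time
    milk_rows = []
    for animal in lactating:
        for s in animal.series:
            if s.matrix != MATRIX_MILK or s.route is not Route.IV:
                continue
            for t, c, flag in zip(s.times, s.concs, s.censor):
                milk_rows.append({"animal_id": animal.id, "time_h": t,
                                  "conc_ng_ml": c, "censor": flag.value})
    milk_df = pd.DataFrame(milk_rows)

    report["withdrawal"] = {}
    try:
        dataset = build_depletion_dataset(
            milk_df, last_dose_time=last_dose, mrl=config.mrl)
    except NotCalculableError as err:
        for m in ("EMA_SCLR", "FDA"):
            report["withdrawal"][m] = {"status": "not_calculable",
                                       "reason": str(err),
                                       "diagnostics": err.diagnostics}
        dataset = None

    if dataset is not None:
        if config.withdrawal_method in ("ema", "both"):
            try:
                report["withdrawal"]["EMA_SCLR"] = _withdrawal_section(
                    ema_sclr(dataset, config.milking_interval,
                             strict_prechecks=config.strict_prechecks))
            except NotCalculableError as err:
                report["withdrawal"]["EMA_SCLR"] = {
                    "status": "not_calculable", "reason": str(err),
                    "diagnostics": err.diagnostics}
        if config.withdrawal_method in ("fda", "both"):
            aug = config.augmentation or AugmentationSpec(
                seed=int(rngs["augment"].integers(2 ** 31)))
            try:
                report["withdrawal"]["FDA"] = _withdrawal_section(
                    fda_milk_discard(dataset, aug, config.milking_interval,
                                     strict_prechecks=config.strict_prechecks))
            except NotCalculableError as err:
                report["withdrawal"]["FDA"] = {
                    "status": "not_calculable", "reason": str(err),
                    "diagnostics": err.diagnostics}
    log("withdraw", methods=sorted(report["withdrawal"]))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_concentration_csv(lactating, out_dir / "lactating_cohort.csv")
        write_concentration_csv(comparison, out_dir / "comparison_cohort.csv")
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, enum.Enum):
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")
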