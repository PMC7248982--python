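"""Regression-based tolerance-limit milk-withdrawal estimation.

Implements the two regulatory calculations for a marker residue depleting
log-linearly in milk after the last dose:

* the EMA safe-concentration-from-linear-regression (SCLR) method — pooled
  OLS of ln(concentration) on time with a one-sided 95th-percentile / 95%
  confidence upper tolerance limit crossed against ln(MRL);
* the FDA milk-discard calculation — the same machinery at the 99th
  percentile / 95% confidence, applied to data meeting (or Monte Carlo
  augmented to meet) the >= 10 animals / triplicate-measurements contract.

The tolerance limit at time x is

    TL(x) = a + b*x + s * sqrt(d(x)) * q,
    d(x)  = 1/n + (x - t_mean)^2 / Sxx,
    q     = gamma-quantile of the noncentral t with n-2 df and
            noncentrality z_p / sqrt(d(x)),

which with confidence gamma bounds the p-th percentile of the population
regression line — the standard one-sided regression tolerance bound used by
both regulatory tools.  With a tolerance of zero the assay LOD serves as
the operational MRL.  Continuous estimates are rounded up to the next
milking interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .augment import AugmentationSpec, augment_dataset

__all__ = [
    "DepletionDataset",
    "ToleranceLimitFit",
    "WithdrawalResult",
    "NotCalculableError",
    "InsufficientDataError",
    "DataFormatError",
    "build_depletion_dataset",
    "fit_depletion_regression",
    "tolerance_limit",
    "withdrawal_time",
    "detect_outlier_animals",
    "round_to_milking",
    "ema_sclr",
    "fda_milk_discard",
]

DEFAULT_MILKING_INTERVAL_H = 12.0
#: Marker-residue LOD in milk (ng/ml), the operational zero-tolerance MRL.
DEFAULT_MRL_NG_ML = 0.4
DEFAULT_MILK_LOQ_NG_ML = 0.9
OUTLIER_THRESHOLD_DEFAULT = 3.0

#: Residual SDs below this are treated as an exact fit (s = 0 collapse).
_S_TINY = 1e-10


class NotCalculableError(RuntimeError):
    """The withdrawal interval cannot be computed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(NotCalculableError):
    """Too few quantifiable points or animals."""


class DataFormatError(NotCalculableError):
    """Dataset does not meet a method's data contract."""


@dataclass
class DepletionDataset:
    """Post-peak, quantifiable marker-residue data on the natural-log scale.

    ``records`` columns: animal_id, time_h (since last dose), ln_conc,
    replicate, virtual.  ``exclusions`` counts dropped points by reason.
    """

    records: pd.DataFrame
    marker: str
    loq: float
    mrl: float
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("animal_id", "time_h", "ln_conc"):
            if col not in self.records.columns:
                raise ValueError(f"records missing column {col!r}")
        if "replicate" not in self.records.columns:
            self.records["replicate"] = 0
        if "virtual" not in self.records.columns:
            self.records["virtual"] = False
        if self.mrl <= 0:
            raise ValueError("mrl must be > 0")

    @property
    def n_animals(self) -> int:
        return int(self.records["animal_id"].nunique())

    @property
    def n_records(self) -> int:
        return int(len(self.records))


@dataclass(frozen=True)
class ToleranceLimitFit:
    """Pooled log-depletion OLS state from which tolerance bounds follow."""

    intercept: float       # a, ln(ng/ml)
    slope: float           # b, 1/h, expected < 0
    residual_sd: float     # s
    n: int
    t_mean: float          # mean of times, h
    sxx: float             # centered sum of squares of times
    t_min: float
    t_max: float
    slope_p_one_sided: float      # P(observing this slope | b >= 0)
    lack_of_fit_p: float = math.nan
    variance_homogeneity_p: float = math.nan

    @property
    def df(self) -> int:
        return self.n - 2

    def mean_line(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class WithdrawalResult:
    """Withdrawal-interval estimate with its provenance and diagnostics."""

    method: str                 # "EMA_SCLR" | "FDA"
    percentile: float
    confidence: float
    continuous_wdt: float       # h
    rounded_wdt: float          # h, integer multiple of milking_interval
    milking_interval: float
    mrl_used: float
    fit: ToleranceLimitFit
    excluded_animals: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Dataset construction
# ---------------------------------------------------------------------------


def build_depletion_dataset(
    milk_records: pd.DataFrame,
    last_dose_time: float = 0.0,
    loq: float = DEFAULT_MILK_LOQ_NG_ML,
    mrl: float = DEFAULT_MRL_NG_ML,
    marker: str = "5-OH",
    drop_pre_peak: bool = True,
) -> DepletionDataset:
    """Assemble the regression dataset from per-animal milk series.

    ``milk_records`` needs columns animal_id, time_h, conc_ng_ml (and
    optionally censor, replicate, virtual).  Retained are post-last-dose
    points from each animal's observed peak onward whose concentration is
    strictly greater than the LOQ (values exactly at the LOQ are excluded);
    concentrations are stored as natural logs.  Raises
    ``InsufficientDataError`` if fewer than 3 points or 2 animals survive.
    """
    df = milk_records.copy()
    if "censor" in df.columns:
        n0 = len(df)
        df = df[df["censor"].astype(str) == "Q"]
        censored = n0 - len(df)
    else:
        censored = 0
    df = df.dropna(subset=["conc_ng_ml"])
    df["time_h"] = df["time_h"].astype(float) - last_dose_time
    pre_dose = int((df["time_h"] <= 0).sum())
    df = df[df["time_h"] > 0]

    pre_peak = 0
    if drop_pre_peak and len(df):
        kept = []
        for _, g in df.groupby("animal_id", sort=False):
            g = g.sort_values(["time_h", *([c for c in ("replicate",) if c in g])])
            t_peak = g.loc[g["conc_ng_ml"].idxmax(), "time_h"]
            pre_peak += int((g["time_h"] < t_peak).sum())
            kept.append(g[g["time_h"] >= t_peak])
        df = pd.concat(kept, ignore_index=True)

    below = int((df["conc_ng_ml"] <= loq).sum())
    df = df[df["conc_ng_ml"] > loq]

    exclusions = {"censored": censored, "pre_dose": pre_dose,
                  "pre_peak": pre_peak, "at_or_below_loq": below}
    if len(df) < 3 or df["animal_id"].nunique() < 2:
        raise InsufficientDataError(
            "fewer than 3 quantifiable points or fewer than 2 animals "
            "remain after filtering",
            {"n_records": int(len(df)),
             "n_animals": int(df["animal_id"].nunique()),
             "exclusions": exclusions},
        )
    out = pd.DataFrame({
        "animal_id": df["animal_id"].to_numpy(),
        "time_h": df["time_h"].to_numpy(dtype=float),
        "ln_conc": np.log(df["conc_ng_ml"].to_numpy(dtype=float)),
    })
    for col in ("replicate", "virtual"):
        if col in df.columns:
            out[col] = df[col].to_numpy()
    return DepletionDataset(out.reset_index(drop=True), marker=marker,
                            loq=loq, mrl=mrl, exclusions=exclusions)


# ---------------------------------------------------------------------------
# Regression and pre-checks
# ---------------------------------------------------------------------------


def _lack_of_fit_p(t: np.ndarray, y: np.ndarray, sse: float) -> float:
    """Pure-error lack-of-fit F test; NaN when degenerate."""
    groups = pd.Series(y).groupby(pd.Series(t))
    g_counts = groups.count()
    n, n_groups = len(t), len(g_counts)
    df_pe = n - n_groups
    df_lof = n_groups - 2
    if df_pe < 1 or df_lof < 1:
        return math.nan
    ss_pe = float(((pd.Series(y) - groups.transform("mean")) ** 2).sum())
    if ss_pe <= 0:
        return math.nan
    ss_lof = max(sse - ss_pe, 0.0)
    fstat = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(fstat, df_lof, df_pe))


def _variance_homogeneity_p(t: np.ndarray, y: np.ndarray) -> float:
    """Bartlett test across time groups with >= 2 observations."""
    groups = [g.to_numpy() for _, g in pd.Series(y).groupby(pd.Series(t))
              if len(g) >= 2]
    if len(groups) < 2 or any(np.var(g, ddof=1) <= 0 for g in groups):
        return math.nan
    return float(stats.bartlett(*groups).pvalue)


def fit_depletion_regression(dataset: DepletionDataset,
                             per_animal_means: bool = False) -> ToleranceLimitFit:
    """Pooled OLS of ln(concentration) on time, with pre-check diagnostics.

    All points are treated as independent (no per-animal random effect),
    matching the pooled-regression description of the SCLR method.  Stores
    the lack-of-fit F test (pure error from replicated times), the Bartlett
    variance-homogeneity test across time groups and the one-sided
    significance of the (negative) slope.

    ``per_animal_means`` is a sensitivity mode that first averages ln
    concentrations within (animal, time) so that assay replicates do not
    inflate the effective sample size.
    """
    records = dataset.records
    if per_animal_means:
        records = (records.groupby(["animal_id", "time_h"], as_index=False)
                   ["ln_conc"].mean())
    t = records["time_h"].to_numpy(dtype=float)
    y = records["ln_conc"].to_numpy(dtype=float)
    n = len(t)
    if n < 3:
        raise InsufficientDataError("need >= 3 records", {"n_records": n})
    t_mean = float(t.mean())
    sxx = float(((t - t_mean) ** 2).sum())
    if sxx <= 0:
        raise InsufficientDataError("all times identical; slope undefined",
                                    {"n_records": n})
    b = float(((t - t_mean) * (y - y.mean())).sum() / sxx)
    a = float(y.mean() - b * t_mean)
    resid = y - (a + b * t)
    sse = float((resid ** 2).sum())
    df = n - 2
    s = math.sqrt(sse / df)

    if s < _S_TINY:
        slope_p = 0.0 if b < 0 else 1.0
    else:
        se_b = s / math.sqrt(sxx)
        slope_p = float(stats.t.cdf(b / se_b, df))

    return ToleranceLimitFit(
        intercept=a, slope=b, residual_sd=s, n=n, t_mean=t_mean, sxx=sxx,
        t_min=float(t.min()), t_max=float(t.max()),
        slope_p_one_sided=slope_p,
        lack_of_fit_p=_lack_of_fit_p(t, y, sse),
        variance_homogeneity_p=_variance_homogeneity_p(t, y),
    )


# ---------------------------------------------------------------------------
# Tolerance limit and crossing
# ---------------------------------------------------------------------------


def tolerance_limit(fit: ToleranceLimitFit, x, percentile: float = 0.95,
                    confidence: float = 0.95):
    """One-sided upper tolerance bound on ln-concentration at time(s) x.

    TL(x) = a + b*x + s*sqrt(d(x))*q with d(x) = 1/n + (x-t_mean)^2/sxx and
    q the ``confidence``-quantile of the noncentral t distribution with n-2
    df and noncentrality z_percentile/sqrt(d(x)).
    """
    if not (0 < percentile < 1 and 0 < confidence < 1):
        raise ValueError("percentile and confidence must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    mean = fit.mean_line(x)
    if fit.residual_sd < _S_TINY:
        return mean if mean.shape else float(mean)
    d = 1.0 / fit.n + (x - fit.t_mean) ** 2 / fit.sxx
    zp = stats.norm.ppf(percentile)
    q = stats.nct.ppf(confidence, fit.df, zp / np.sqrt(d))
    out = mean + fit.residual_sd * np.sqrt(d) * q
    return out if out.shape else float(out)


def withdrawal_time(fit: ToleranceLimitFit, mrl: float,
                    percentile: float = 0.95, confidence: float = 0.95,
                    search_horizon: float | None = None) -> float:
    """Smallest x >= 0 with TL(x') <= ln(mrl) for all x' >= x in the horizon.

    The tolerance-limit curve is eventually decreasing for a negative slope,
    so the crossing is located on a grid and refined by root bracketing.
    Returns 0 if TL(0) is already below ln(mrl); raises
    ``NotCalculableError`` if the curve never crosses within the horizon.
    """
    if mrl <= 0:
        raise ValueError("mrl must be > 0")
    if search_horizon is None:
        span = max(fit.t_max - fit.t_min, fit.t_max, 1.0)
        search_horizon = 10.0 * span
    target = math.log(mrl)

    def excess(x):
        return tolerance_limit(fit, x, percentile, confidence) - target

    xs = np.linspace(0.0, search_horizon, 512)
    vals = np.asarray(excess(xs))
    above = vals > 0
    if not above.any():
        return 0.0
    i = int(np.nonzero(above)[0][-1])
    if i == len(xs) - 1:
        raise NotCalculableError(
            f"tolerance limit does not fall below ln(MRL) within "
            f"{search_horizon:.1f} h",
            {"horizon_h": search_horizon, "tl_at_horizon": float(vals[-1] + target)},
        )
    return float(optimize.brentq(excess, xs[i], xs[i + 1], xtol=1e-10))


# ---------------------------------------------------------------------------
# Outlier screen and rounding
# ---------------------------------------------------------------------------


def detect_outlier_animals(
    dataset: DepletionDataset,
    threshold: float = OUTLIER_THRESHOLD_DEFAULT,
) -> tuple[list[str], DepletionDataset, ToleranceLimitFit]:
    """Flag animals whose mean externally-studentized residual magnitude
    exceeds ``threshold``; refit without them (single exclusion round).

    Studentization is leave-one-animal-out: each animal's residuals are
    measured against the regression fitted to the *other* animals and scaled
    by that fit's prediction SE, so a wholly shifted animal cannot mask
    itself by inflating the pooled residual SD.  Returns (excluded ids,
    possibly reduced dataset, refitted regression).  An exact fit (zero
    residual SD) has no outliers by construction.
    """
    fit = fit_depletion_regression(dataset)
    if not math.isfinite(threshold) or fit.residual_sd < _S_TINY:
        return [], dataset, fit
    scores: dict[str, float] = {}
    for animal in dataset.records["animal_id"].unique():
        mask = dataset.records["animal_id"] != animal
        rest = dataset.records[mask]
        if rest["animal_id"].nunique() < 2 or len(rest) < 3:
            continue
        t0 = rest["time_h"].to_numpy(dtype=float)
        y0 = rest["ln_conc"].to_numpy(dtype=float)
        ols = sm.OLS(y0, sm.add_constant(t0)).fit()
        s0 = math.sqrt(ols.scale)
        if s0 < _S_TINY:
            s0 = _S_TINY
        ti = dataset.records.loc[~mask, "time_h"].to_numpy(dtype=float)
        yi = dataset.records.loc[~mask, "ln_conc"].to_numpy(dtype=float)
        pred = ols.predict(sm.add_constant(ti, has_constant="add"))
        tbar = t0.mean()
        sxx0 = float(((t0 - tbar) ** 2).sum())
        se = s0 * np.sqrt(1.0 + 1.0 / len(t0) + (ti - tbar) ** 2 / sxx0)
        scores[animal] = float(np.mean(np.abs(yi - pred) / se))
    excluded = sorted(a for a, r in scores.items() if r > threshold)
    if not excluded:
        return [], dataset, fit
    keep = ~dataset.records["animal_id"].isin(excluded)
    remaining = dataset.records[keep]
    if remaining["animal_id"].nunique() < 2:
        raise InsufficientDataError(
            "outlier exclusion would leave < 2 animals",
            {"excluded": excluded})
    reduced = DepletionDataset(remaining.reset_index(drop=True),
                               marker=dataset.marker, loq=dataset.loq,
                               mrl=dataset.mrl, exclusions=dataset.exclusions)
    return excluded, reduced, fit_depletion_regression(reduced)


def round_to_milking(continuous_wdt: float,
                     milking_interval: float = DEFAULT_MILKING_INTERVAL_H) -> float:
    """Smallest nonnegative integer multiple of the milking interval that is
    >= the continuous estimate; exact multiples are kept as-is."""
    if milking_interval <= 0:
        raise ValueError("milking_interval must be > 0")
    if continuous_wdt < 0:
        raise ValueError("continuous withdrawal time must be >= 0")
    n = math.ceil(continuous_wdt / milking_interval - 1e-9)
    return max(n, 0) * milking_interval


# ---------------------------------------------------------------------------
# Regulatory pipelines
# ---------------------------------------------------------------------------


def _run_tolerance_pipeline(dataset: DepletionDataset,
                            method: str,
                            percentile: float,
                            confidence: float,
                            milking_interval: float,
                            outlier_threshold: float,
                            strict_prechecks: bool,
                            extra_diag: dict | None = None) -> WithdrawalResult:
    excluded, dataset, fit = detect_outlier_animals(dataset, outlier_threshold)

    diag: dict = dict(extra_diag or {})
    diag.update({
        "n_animals": dataset.n_animals,
        "n_records": dataset.n_records,
        "exclusions": dataset.exclusions,
        "slope_p_one_sided": fit.slope_p_one_sided,
        "lack_of_fit_p": fit.lack_of_fit_p,
        "variance_homogeneity_p": fit.variance_homogeneity_p,
    })
    if fit.slope >= 0 or fit.slope_p_one_sided > 0.05:
        raise NotCalculableError(
            "depletion slope is not significantly negative at alpha = 0.05",
            diag | {"slope": fit.slope})
    warnings = []
    for name, p in (("lack_of_fit", fit.lack_of_fit_p),
                    ("variance_homogeneity", fit.variance_homogeneity_p)):
        if math.isfinite(p) and p < 0.05:
            warnings.append(f"{name} pre-check failed (p = {p:.4f})")
    if warnings and strict_prechecks:
        raise NotCalculableError("; ".join(warnings), diag)
    diag["precheck_warnings"] = warnings

    wdt = withdrawal_time(fit, dataset.mrl, percentile, confidence)
    return WithdrawalResult(
        method=method, percentile=percentile, confidence=confidence,
        continuous_wdt=wdt,
        rounded_wdt=round_to_milking(wdt, milking_interval),
        milking_interval=milking_interval, mrl_used=dataset.mrl, fit=fit,
        excluded_animals=excluded, diagnostics=diag,
    )


def ema_sclr(dataset: DepletionDataset,
             milking_interval: float = DEFAULT_MILKING_INTERVAL_H,
             percentile: float = 0.95, confidence: float = 0.95,
             outlier_threshold: float = OUTLIER_THRESHOLD_DEFAULT,
             strict_prechecks: bool = False) -> WithdrawalResult:
    """EMA safe-concentration-from-linear-regression withdrawal interval.

    Outlier screen, pooled log-linear regression with pre-checks, 95/95
    upper tolerance limit crossed against ln(MRL), and rounding up to the
    next milking interval.  Not-calculable states raise
    ``NotCalculableError`` with diagnostics rather than returning numbers.
    """
    return _run_tolerance_pipeline(dataset, "EMA_SCLR", percentile, confidence,
                                   milking_interval, outlier_threshold,
                                   strict_prechecks)


def _meets_fda_contract(dataset: DepletionDataset) -> bool:
    if dataset.n_animals < 10:
        return False
    reps = dataset.records.groupby(["animal_id", "time_h"])["replicate"].count()
    return bool((reps >= 3).all())


def fda_milk_discard(dataset: DepletionDataset,
                     augmentation: AugmentationSpec | None = None,
                     milking_interval: float = DEFAULT_MILKING_INTERVAL_H,
                     percentile: float = 0.99, confidence: float = 0.95,
                     outlier_threshold: float = OUTLIER_THRESHOLD_DEFAULT,
                     strict_prechecks: bool = False) -> WithdrawalResult:
    """FDA 99th-percentile/95%-confidence milk-discard interval.

    The input must satisfy the >= 10 animals / triplicate-measurements data
    contract; otherwise an ``AugmentationSpec`` must be supplied and the
    dataset is expanded by Monte Carlo replicates and virtual animals before
    the tolerance-limit machinery runs at p = 0.99.
    """
    extra: dict = {"n_real_animals": dataset.n_animals}
    if not _meets_fda_contract(dataset):
        if augmentation is None:
            raise DataFormatError(
                "FDA method requires >= 10 animals and triplicate "
                "measurements per sample; augment the dataset "
                "(pass an AugmentationSpec)",
                {"n_animals": dataset.n_animals})
        milk = dataset.records.assign(
            conc_ng_ml=np.exp(dataset.records["ln_conc"]))
        milk = milk[milk["replicate"] == 0][["animal_id", "time_h", "conc_ng_ml"]]
        aug = augment_dataset(milk, augmentation)
        records = aug.records
        n_aug_animals = int(records["animal_id"].nunique())
        reps_ok = bool(
            (records.groupby(["animal_id", "time_h"])["replicate"].count() >= 3).all())
        if n_aug_animals < 10 or not reps_ok:
            raise DataFormatError(
                "augmented dataset still fails the 10-animal/triplicate "
                "contract", {"n_animals": n_aug_animals})
        if not augmentation.include_subloq:
            records = records[records["conc_ng_ml"] > dataset.loq]
        dataset = DepletionDataset(
            pd.DataFrame({
                "animal_id": records["animal_id"].to_numpy(),
                "time_h": records["time_h"].to_numpy(dtype=float),
                "ln_conc": np.log(records["conc_ng_ml"].to_numpy(dtype=float)),
                "replicate": records["replicate"].to_numpy(),
                "virtual": records["virtual"].to_numpy(),
            }).reset_index(drop=True),
            marker=dataset.marker, loq=dataset.loq, mrl=dataset.mrl,
            exclusions=dataset.exclusions,
        )
        extra.update({
            "augmented": True,
            "n_virtual_animals": aug.n_virtual_animals,
            "n_replicates_per_sample": aug.n_replicates_per_sample,
        })
    else:
        extra["augmented"] = False
    return _run_tolerance_pipeline(dataset, "FDA", percentile, confidence,
                                   milking_interval, outlier_threshold,
                                   strict_prechecks, extra_diag=extra)
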