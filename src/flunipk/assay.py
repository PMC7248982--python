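"""ELISA calibration and method-agreement statistics.

Four-parameter logistic (4PL) calibration of competitive-inhibition plates,
derivation of assay limits from inhibition concentrations (LOD at IC10,
working range IC15-IC85, dilution-adjusted), and the per-time-point
method-agreement test: a two-sided F pre-test of variance equality followed
by the pooled or Welch two-sample t test.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Calibration4PL",
    "AssayLimits",
    "TimepointComparison",
    "TTestKind",
    "Fit4PLError",
    "fit_4pl",
    "invert_4pl",
    "assay_limits",
    "compare_methods_at_timepoint",
]


class Fit4PLError(RuntimeError):
    """4PL fit did not converge; carries the best iterate if any."""

    def __init__(self, message: str, best_iterate=None):
        super().__init__(message)
        self.best_iterate = best_iterate


@dataclass(frozen=True)
class Calibration4PL:
    """Descending 4PL inhibition curve y = D + (A-D)/(1 + (x/C)^B).

    A is the zero-analyte (upper) absorbance asymptote, D the
    infinite-analyte (lower) asymptote, C the IC50 concentration (ng/ml)
    and B the slope factor (> 0 for a descending curve).
    """

    A: float
    B: float
    C: float
    D: float
    fit_rss: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= self.D:
            raise ValueError("require A > D for an inhibition curve")
        if self.C <= 0 or self.B <= 0:
            raise ValueError("require C > 0 and B > 0")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return _four_pl(np.asarray(x, dtype=float), self.A, self.B, self.C, self.D)

    def ic(self, q: float) -> float:
        """Concentration reducing the zero-analyte absorbance by fraction q."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        return self.C * (q / (1.0 - q)) ** (1.0 / self.B)


@dataclass(frozen=True)
class AssayLimits:
    """LOD (averaged IC10) and IC15-IC85 working range, ng/ml."""

    lod: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not self.lod < self.range_low < self.range_high:
            raise ValueError("require lod < range_low < range_high")


class TTestKind(str, enum.Enum):
    POOLED = "pooled_t"
    WELCH = "welch_t"


@dataclass(frozen=True)
class TimepointComparison:
    """Two-method comparison at one sampling time."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    variance_test_p: float
    t_statistic: float
    p_value: float
    test_used: TTestKind
    degenerate: bool = False
    time: float | None = None


def _four_pl(x, A, B, C, D):
    # x == 0 maps exactly to A for B > 0 since 0**B == 0
    return D + (A - D) / (1.0 + (np.asarray(x, dtype=float) / C) ** B)


def fit_4pl(points) -> Calibration4PL:
    """Least-squares 4PL fit of (concentration ng/ml, absorbance) pairs.

    Requires at least 5 distinct concentrations including a zero-analyte
    point, which pins the upper asymptote A.  Starting values come from the
    data range (A = max y, D = min y, C = median positive x, B = 1).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, absorbance) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct concentrations")
    if 0.0 not in x:
        raise ValueError("calibration must include a zero-concentration point")

    span = y.max() - y.min()
    if span <= 1e-12 * max(1.0, abs(y).max()):
        raise Fit4PLError("flat absorbances: upper and lower asymptotes coincide")
    p0 = (y.max(), 1.0, float(np.median(x[x > 0])), y.min())
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, x, y, p0=p0,
            bounds=([-np.inf, 1e-9, 1e-12, -np.inf], [np.inf, 50.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise Fit4PLError(f"4PL fit did not converge: {err}", best_iterate=p0) from err
    A, B, C, D = (float(v) for v in popt)
    if A - D <= 1e-9 * max(1.0, abs(A)):
        raise Fit4PLError("degenerate fit: A ~= D", best_iterate=popt)
    rss = float(np.sum((_four_pl(x, *popt) - y) ** 2))
    return Calibration4PL(A=A, B=B, C=C, D=D, fit_rss=rss)


def invert_4pl(curve: Calibration4PL, absorbance: float,
               dilution_factor: float = 1.0) -> float:
    """Concentration from absorbance: x = C*((A-D)/(y-D) - 1)^(1/B) * dilution.

    The absorbance must lie strictly inside (D, A); readings outside the
    calibrated response range need re-dilution and re-reading.
    """
    y = float(absorbance)
    if not curve.D < y < curve.A:
        raise ValueError(
            f"absorbance {y} outside calibrated range "
            f"({curve.D:.4g}, {curve.A:.4g}); re-dilute the sample")
    x = curve.C * ((curve.A - curve.D) / (y - curve.D) - 1.0) ** (1.0 / curve.B)
    return x * dilution_factor


def assay_limits(curves, dilution_factor: float = 1.0) -> AssayLimits:
    """Average IC10/IC15/IC85 over plates, adjusted for the dilution factor."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one calibration curve")
    ic10 = float(np.mean([c.ic(0.10) for c in curves]))
    ic15 = float(np.mean([c.ic(0.15) for c in curves]))
    ic85 = float(np.mean([c.ic(0.85) for c in curves]))
    return AssayLimits(
        lod=ic10 * dilution_factor,
        range_low=ic15 * dilution_factor,
        range_high=ic85 * dilution_factor,
    )


def _summary(sample) -> tuple[float, float, int]:
    arr = np.asarray(sample, dtype=float)
    if arr.size < 2:
        raise ValueError("each sample needs n >= 2")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def compare_methods_at_timepoint(
    sample_a=None,
    sample_b=None,
    *,
    summary_a: tuple[float, float, int] | None = None,
    summary_b: tuple[float, float, int] | None = None,
    alpha_var: float = 0.05,
    time: float | None = None,
) -> TimepointComparison:
    """Equal-variance pre-test then Student's t at one time point.

    A two-sided F test of variance equality at ``alpha_var`` decides between
    the pooled two-sample t test (variances not rejected as unequal) and the
    Welch test.  Accepts raw samples or (mean, sd, n) summaries so published
    summary rows can be replayed without raw data.  Both samples having zero
    variance and equal means returns t = 0, p = 1 flagged as degenerate.
    """
    if summary_a is None:
        summary_a = _summary(sample_a)
    if summary_b is None:
        summary_b = _summary(sample_b)
    ma, sa, na = summary_a
    mb, sb, nb = summary_b
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")

    if sa == 0.0 and sb == 0.0:
        if ma == mb:
            return TimepointComparison(ma, sa, na, mb, sb, nb,
                                       variance_test_p=1.0, t_statistic=0.0,
                                       p_value=1.0, test_used=TTestKind.POOLED,
                                       degenerate=True, time=time)
        var_p = 1.0  # no variance evidence either way; fall through to pooled t
    elif sb == 0.0 or sa == 0.0:
        var_p = 0.0
    else:
        fstat = (sa / sb) ** 2
        cdf = stats.f.cdf(fstat, na - 1, nb - 1)
        var_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))

    kind = TTestKind.POOLED if var_p >= alpha_var else TTestKind.WELCH
    res = stats.ttest_ind_from_stats(
        ma, sa, na, mb, sb, nb, equal_var=(kind is TTestKind.POOLED))
    return TimepointComparison(
        ma, sa, na, mb, sb, nb,
        variance_test_p=var_p,
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_used=kind,
        time=time,
    )
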