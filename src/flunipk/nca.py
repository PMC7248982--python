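"""Noncompartmental analysis of plasma concentration-time profiles.

Implements the standard NCA parameter block per animal profile: observed
Cmax/Tmax/Clast/Tlast, AUC and AUMC by the linear-up/log-down trapezoidal
rule with Clast/lambda_z tail extrapolation, terminal slope (lambda_z)
selection by best adjusted R^2 over contiguous terminal windows, mean
residence time, clearance, volumes, the whole-body extraction ratio against
allometric cardiac output (180 * BW^-0.19 ml/kg/min), and crossover
bioavailability as the ratio of extravascular to IV AUC(0-inf).

Inputs are in ng/ml and hours; reported concentration/area parameters are
converted to ug/ml (and h*ug/ml) to match conventional reporting, while
clearance and volumes stay in ml/kg/h and ml/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .simulate import Censor, ConcentrationSeries, Route

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "CrossoverPair",
    "LambdaZError",
    "select_lambda_z",
    "auc_aumc",
    "nca_single_profile",
    "extraction_ratio",
    "cardiac_output",
    "bioavailability",
]

NG_TO_UG = 1e-3
MG_PER_KG_TO_NG_PER_KG = 1.0e6

#: Extrapolated-area fraction (%) above which a diagnostic warning is recorded.
AUC_EXTRAPOLATION_WARN_PCT = 20.0


class LambdaZError(ValueError):
    """Terminal-slope estimation failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class LambdaZFit:
    """Accepted terminal log-linear regression window."""

    lambda_z: float      # 1/h, positive
    n_points: int
    t_first: float       # h, first time in the window
    t_last: float        # h, last time in the window
    adj_r2: float
    intercept: float     # ln(ng/ml)

    def __post_init__(self) -> None:
        if self.lambda_z <= 0:
            raise ValueError("lambda_z must be > 0 for an accepted fit")
        if self.n_points < 3:
            raise ValueError("lambda_z window needs >= 3 points")

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.lambda_z


@dataclass
class NCAResult:
    """Full NCA parameter block for one profile.

    Concentrations in ug/ml, areas in h*ug/ml (AUMC h^2*ug/ml), clearance in
    ml/kg/h, volumes in ml/kg.  lambda_z-dependent entries are NaN when the
    terminal fit failed (``lambda_fit`` is then None).  ``vss`` and
    ``e_body`` are defined for the IV route only.
    """

    animal_id: str
    route: Route
    dose_mg_kg: float
    cmax_obs: float
    tmax_obs: float
    clast_obs: float
    tlast_obs: float
    auc_last: float
    auc_inf: float = math.nan
    auc_pct_ext: float = math.nan
    aumc_inf: float = math.nan
    mrt_inf: float = math.nan
    t_half_z: float = math.nan
    lambda_fit: LambdaZFit | None = None
    cl_or_clf: float = math.nan
    vz_or_vzf: float = math.nan
    vss: float = math.nan
    e_body: float = math.nan
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CrossoverPair:
    """IV and SC results from the same animal with bioavailability f."""

    animal_id: str
    nca_iv: NCAResult
    nca_sc: NCAResult
    f: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("bioavailability must be > 0")


# ---------------------------------------------------------------------------
# Terminal slope
# ---------------------------------------------------------------------------


def select_lambda_z(series: ConcentrationSeries,
                    route: Route | str) -> LambdaZFit:
    """Best-adjusted-R^2 terminal log-linear window.

    Candidate windows are all contiguous terminal windows of >= 3 quantified
    positive points starting strictly after Tmax for extravascular routes and
    strictly after the first sample for IV; the window maximizing the
    adjusted R^2 of the ln(C)-vs-t regression wins, requiring a negative
    slope.  Ties in adjusted R^2 prefer the window with more points.
    """
    route = Route(route)
    t, c = series.quantified()
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) < 3:
        raise LambdaZError(
            "need >= 3 quantified positive points for lambda_z",
            {"n_points": int(len(t))},
        )
    imax = int(np.argmax(c))
    start = imax + 1 if route is Route.SC else 1
    logc = np.log(c)

    best: LambdaZFit | None = None
    n_total = len(t)
    for i in range(start, n_total - 2):
        tw, yw = t[i:], logc[i:]
        res = stats.linregress(tw, yw)
        if not np.isfinite(res.slope) or res.slope >= 0:
            continue
        n = len(tw)
        r2 = res.rvalue ** 2 if np.isfinite(res.rvalue) else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        # iterate from the largest window down: strict improvement required,
        # so equal adjusted R^2 keeps the earlier (larger) window
        if best is None or adj > best.adj_r2 + 1e-9:
            best = LambdaZFit(
                lambda_z=-res.slope, n_points=n,
                t_first=float(tw[0]), t_last=float(tw[-1]),
                adj_r2=float(adj), intercept=float(res.intercept),
            )
    if best is None:
        raise LambdaZError(
            "no terminal window with a negative slope",
            {"n_points": n_total, "start_index": start, "route": route.value},
        )
    return best


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------


def auc_aumc(times: np.ndarray, concs: np.ndarray,
             t_start: float | None = None,
             t_end: float | None = None) -> tuple[float, float]:
    """AUC and AUMC by the linear-up/log-down trapezoidal rule.

    Declining intervals (C2 < C1, both positive) use the logarithmic
    trapezoid dAUC = (C1-C2)*dt/ln(C1/C2) and its first-moment analogue
    (t1*C1 - t2*C2)/k + (C1-C2)/k^2 with k = ln(C1/C2)/dt; level or rising
    intervals use the linear trapezoid.  A zero concentration is permitted
    only as the leading baseline sample (pre-dose); any negative value, or a
    zero elsewhere, raises an error naming the offending point.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t_start is not None or t_end is not None:
        lo = -np.inf if t_start is None else t_start
        hi = np.inf if t_end is None else t_end
        keep = (t >= lo) & (t <= hi)
        t, c = t[keep], c[keep]
    if len(t) < 2:
        raise ValueError("need >= 2 points inside the integration window")
    for j, cj in enumerate(c):
        if cj < 0 or (cj == 0 and j > 0):
            raise ValueError(
                f"nonpositive concentration {cj} at t={t[j]} h inside window")

    auc = aumc = 0.0
    for (t1, t2, c1, c2) in zip(t[:-1], t[1:], c[:-1], c[1:]):
        dt = t2 - t1
        if 0 < c2 < c1:
            k = math.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


# ---------------------------------------------------------------------------
# Full profile
# ---------------------------------------------------------------------------


def _integration_points(series: ConcentrationSeries) -> tuple[np.ndarray, np.ndarray]:
    """Quantified points; a censored pre-dose t=0 sample becomes a zero.

    Censored interior points are dropped, so integration spans the gap with
    a single trapezoid.
    """
    ts, cs = [], []
    for j, (tj, cj, flag) in enumerate(zip(series.times, series.concs, series.censor)):
        if flag is Censor.QUANTIFIED:
            ts.append(tj)
            cs.append(cj)
        elif j == 0 and tj == 0.0:
            ts.append(0.0)
            cs.append(0.0)
    return np.asarray(ts), np.asarray(cs)


def nca_single_profile(series: ConcentrationSeries,
                       dose_mg_kg: float,
                       route: Route | str,
                       body_weight: float | None = None,
                       allow_partial: bool = True) -> NCAResult:
    """NCA of one plasma profile; dose in mg/kg, series in ng/ml and h.

    On terminal-fit failure the observed parameters (Cmax, Tmax, AUClast)
    are still reported, with every lambda_z-dependent quantity NaN, unless
    ``allow_partial`` is False in which case the failure propagates.
    """
    route = Route(route)
    t, c = _integration_points(series)
    if len(t) < 2:
        raise ValueError("fewer than 2 usable points in profile")

    imax = int(np.argmax(c))
    cmax_ng, tmax = float(c[imax]), float(t[imax])
    pos = c > 0
    clast_ng, tlast = float(c[pos][-1]), float(t[pos][-1])
    auc_last_ng, aumc_last_ng = auc_aumc(t, c)

    result = NCAResult(
        animal_id=series.animal_id, route=route, dose_mg_kg=dose_mg_kg,
        cmax_obs=cmax_ng * NG_TO_UG, tmax_obs=tmax,
        clast_obs=clast_ng * NG_TO_UG, tlast_obs=tlast,
        auc_last=auc_last_ng * NG_TO_UG,
    )

    try:
        fit = select_lambda_z(series, route)
    except LambdaZError as err:
        if not allow_partial:
            raise
        result.warnings.append(f"lambda_z fit failed: {err}")
        return result

    lz = fit.lambda_z
    auc_inf_ng = auc_last_ng + clast_ng / lz
    aumc_inf_ng = aumc_last_ng + clast_ng * tlast / lz + clast_ng / lz ** 2
    pct_ext = 100.0 * (auc_inf_ng - auc_last_ng) / auc_inf_ng
    dose_ng = dose_mg_kg * MG_PER_KG_TO_NG_PER_KG
    cl = dose_ng / auc_inf_ng                      # ml/kg/h (CL/F for SC)
    mrt = aumc_inf_ng / auc_inf_ng

    result.lambda_fit = fit
    result.auc_inf = auc_inf_ng * NG_TO_UG
    result.aumc_inf = aumc_inf_ng * NG_TO_UG
    result.auc_pct_ext = pct_ext
    result.mrt_inf = mrt
    result.t_half_z = fit.t_half
    result.cl_or_clf = cl
    result.vz_or_vzf = cl / lz
    if route is Route.IV:
        result.vss = cl * mrt
        if body_weight is not None:
            result.e_body = extraction_ratio(cl, body_weight)
    if pct_ext >= AUC_EXTRAPOLATION_WARN_PCT:
        result.warnings.append(
            f"extrapolated AUC fraction {pct_ext:.1f}% >= "
            f"{AUC_EXTRAPOLATION_WARN_PCT:.0f}%")
    return result


# ---------------------------------------------------------------------------
# Extraction ratio and bioavailability
# ---------------------------------------------------------------------------


def cardiac_output(body_weight: float) -> float:
    """Allometric cardiac output 180 * BW^-0.19, in ml/kg/min."""
    if body_weight <= 0:
        raise ValueError("body weight must be > 0")
    return 180.0 * body_weight ** -0.19


def extraction_ratio(cl: float, body_weight: float,
                     route: Route | str = Route.IV) -> float:
    """Whole-body extraction ratio: systemic clearance / cardiac output.

    ``cl`` must be a systemic (IV) clearance in ml/kg/h; cardiac output is
    converted to ml/kg/h so the ratio is dimensionless.
    """
    if Route(route) is not Route.IV:
        raise ValueError(
            "extraction ratio is defined for systemic (IV) clearance only; "
            "got an apparent CL/F")
    return cl / (60.0 * cardiac_output(body_weight))


def bioavailability(nca_sc: NCAResult, nca_iv: NCAResult) -> CrossoverPair:
    """Within-animal crossover bioavailability f = AUCinf(SC)/AUCinf(IV)."""
    if nca_sc.animal_id != nca_iv.animal_id:
        raise ValueError(
            f"mismatched animals: {nca_sc.animal_id!r} vs {nca_iv.animal_id!r}")
    if nca_iv.route is not Route.IV or nca_sc.route is Route.IV:
        raise ValueError("expected one IV and one extravascular result")
    if not (np.isfinite(nca_sc.auc_inf) and np.isfinite(nca_iv.auc_inf)):
        raise ValueError("both AUC(0-inf) values must be available")
    return CrossoverPair(
        animal_id=nca_iv.animal_id, nca_iv=nca_iv, nca_sc=nca_sc,
        f=nca_sc.auc_inf / nca_iv.auc_inf,
    )
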