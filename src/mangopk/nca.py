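"""Non-compartmental analysis of concentration-time profiles.

Implements the standard NCA chain: trapezoidal AUC/AUMC (linear or
linear-up/log-down), terminal-slope estimation by best adjusted-R^2
window search, extrapolation to infinity, and the derived parameters

    t1/2 = ln2 / lambda_z        MRT = AUMC_inf / AUC_inf   (IV bolus)
    CL   = Dose / AUC_inf        Vss = CL x MRT             (IV bolus)
    CL_R = Ae / AUC_inf          CL_NR = CL - CL_R
    F%   = 100 (AUC_po/Dose_po) / (AUC_iv/Dose_iv)

Below-LLOQ handling: leading censored points (pre-absorption) count as
zero; embedded and trailing censored points are excluded from both the
AUC and the terminal fit. Cmax/Tmax are read from observed quantifiable
points without interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import LambdaZNotEstimable, ProfileError
from .records import UG_PER_MG, ConcProfile, DoseEvent, ExcretionRecord, NCAResult

__all__ = [
    "LambdaZFit",
    "auc_trapezoid",
    "fit_lambda_z",
    "nca_single",
    "bioavailability",
    "dose_normalize",
    "run_nca",
    "results_to_frame",
]

LN2 = float(np.log(2.0))


def _working_points(profile: ConcProfile) -> tuple[np.ndarray, np.ndarray]:
    """Times/concs used for integration.

    Leading censored points become zeros (nothing absorbed yet);
    embedded and trailing censored points are dropped. The series ends
    at the last quantifiable observation.
    """
    quant = profile.quantifiable_mask
    if not quant.any():
        raise ProfileError("profile has no quantifiable points")
    first_q = int(np.argmax(quant))
    last_q = len(quant) - 1 - int(np.argmax(quant[::-1]))
    t_parts, c_parts = [], []
    for i in range(last_q + 1):
        if quant[i]:
            t_parts.append(profile.times[i])
            c_parts.append(profile.concs[i])
        elif i < first_q:  # leading BLQ, pre-absorption
            t_parts.append(profile.times[i])
            c_parts.append(0.0)
        # embedded BLQ: skipped
    return np.asarray(t_parts), np.asarray(c_parts)


def _segment_areas(
    t: np.ndarray, c: np.ndarray, method: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment (AUC, AUMC) contributions."""
    t1, t2 = t[:-1], t[1:]
    c1, c2 = c[:-1], c[1:]
    dt = t2 - t1
    auc_lin = 0.5 * (c1 + c2) * dt
    aumc_lin = 0.5 * (t1 * c1 + t2 * c2) * dt
    if method == "linear":
        return auc_lin, aumc_lin
    if method != "linear_up_log_down":
        raise ValueError(f"unknown AUC method {method!r}")
    down = (c1 > c2) & (c2 > 0)
    lam = np.ones_like(dt)
    np.divide(np.log(np.where(down, c1 / np.where(down, c2, 1.0), 1.0)), dt,
              out=lam, where=down)
    auc_log = np.where(down, (c1 - c2) / np.where(down, lam, 1.0), auc_lin)
    aumc_log = np.where(
        down,
        (t1 * c1 - t2 * c2) / np.where(down, lam, 1.0)
        + (c1 - c2) / np.where(down, lam, 1.0) ** 2,
        aumc_lin,
    )
    return auc_log, aumc_log


def auc_trapezoid(
    profile: ConcProfile,
    method: str = "linear_up_log_down",
    t_end: Optional[float] = None,
) -> float:
    """Partial AUC from the first working point to t_end (ug*min/mL).

    Log-down segments use (C1-C2) dt / ln(C1/C2) only when both
    concentrations are positive and decreasing; all other segments are
    linear. t_end defaults to the last quantifiable time; an earlier
    t_end truncates with linear interpolation at the cut.
    """
    t, c = _working_points(profile)
    if len(t) < 2:
        raise ProfileError("need at least 2 quantifiable points for AUC")
    if t_end is None:
        t_end = t[-1]
    if t_end < t[1]:
        raise ValueError("t_end is before the second sample")
    if t_end < t[-1]:
        c_end = float(np.interp(t_end, t, c))
        keep = t < t_end
        t = np.append(t[keep], t_end)
        c = np.append(c[keep], c_end)
    auc_seg, _ = _segment_areas(t, c, method)
    return float(auc_seg.sum())


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float  # 1/min
    n_points: int
    r2_adj: float
    intercept: float  # ln-concentration at t = 0
    t_last: float  # last quantifiable time (min)
    clast_pred: float  # model-predicted conc at t_last (ug/mL)


def fit_lambda_z(
    profile: ConcProfile, route: str = "iv_bolus", min_points: int = 3
) -> LambdaZFit:
    """Best-adjusted-R^2 terminal slope over suffix windows.

    Candidate windows are all suffixes of the post-Cmax quantifiable
    points (Cmax itself is excluded for the oral route) with at least
    ``min_points`` points. Among windows whose slope is negative the one
    maximizing adjusted R^2 wins; ties go to the window with more
    points. Raises LambdaZNotEstimable when no valid window exists.
    """
    t, c = profile.quantifiable()
    if len(t) < min_points:
        raise LambdaZNotEstimable("fewer quantifiable points than min_points")
    imax = int(np.argmax(c))
    start = imax + 1 if route == "oral" else imax
    t_tail = t[start:]
    y_tail = np.log(c[start:])
    n = len(t_tail)
    if n < min_points:
        raise LambdaZNotEstimable("not enough post-Cmax points")

    # suffix regression statistics via reversed cumulative sums
    def rev_cumsum(a: np.ndarray) -> np.ndarray:
        return np.cumsum(a[::-1])[::-1]

    m = np.arange(n, 0, -1).astype(float)  # points in suffix starting at i
    sx = rev_cumsum(t_tail)
    sy = rev_cumsum(y_tail)
    sxx = rev_cumsum(t_tail * t_tail)
    sxy = rev_cumsum(t_tail * y_tail)
    syy = rev_cumsum(y_tail * y_tail)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = m * sxy - sx * sy
        var_x = m * sxx - sx * sx
        var_y = m * syy - sy * sy
        slope = cov / var_x
        r2 = np.where(var_y > 0, cov * cov / (var_x * var_y), 0.0)
        r2_adj = 1.0 - (1.0 - r2) * (m - 1.0) / (m - 2.0)
    valid = (m >= min_points) & (slope < 0) & np.isfinite(r2_adj)
    if not valid.any():
        raise LambdaZNotEstimable("no decreasing terminal window found")
    best_val = np.max(r2_adj[valid])
    # tie-break toward more points: earliest start index within tolerance
    tied = valid & (r2_adj >= best_val - 1e-9)
    i_best = int(np.argmax(tied))  # smallest start index -> largest window
    lam = -float(slope[i_best])
    npts = int(m[i_best])
    intercept = float((sy[i_best] - slope[i_best] * sx[i_best]) / m[i_best])
    t_last = float(t[-1])
    clast_pred = float(np.exp(intercept + slope[i_best] * t_last))
    return LambdaZFit(
        lambda_z=lam,
        n_points=npts,
        r2_adj=float(r2_adj[i_best]),
        intercept=intercept,
        t_last=t_last,
        clast_pred=clast_pred,
    )


def _back_extrapolate_c0(t: np.ndarray, c: np.ndarray) -> float:
    """C0 for an IV profile missing t=0: log-linear through the first two points."""
    if len(t) < 2 or c[0] <= 0 or c[1] <= 0 or c[1] >= c[0]:
        return float(c[0])
    slope = (np.log(c[1]) - np.log(c[0])) / (t[1] - t[0])
    return float(np.exp(np.log(c[0]) - slope * t[0]))


def nca_single(
    profile: ConcProfile,
    dose_event: DoseEvent,
    excretion: Optional[ExcretionRecord] = None,
    auc_method: str = "linear_up_log_down",
    min_lambda_points: int = 3,
) -> NCAResult:
    """Full NCA for one subject.

    When the terminal slope is not estimable the extrapolated
    quantities (AUC_inf, MRT, CL, Vss, ...) are left as None and
    auc_last is still reported.
    """
    route = dose_event.route
    dose = dose_event.dose
    t_obs, c_obs = profile.quantifiable()
    if len(t_obs) < 3:
        raise ProfileError("NCA needs at least 3 quantifiable points")
    imax = int(np.argmax(c_obs))
    cmax = float(c_obs[imax])
    tmax = float(t_obs[imax])

    t, c = _working_points(profile)
    if route == "iv_bolus" and t[0] > 0:
        # t=0 sample missing: back-extrapolate C0 from the first two points
        c0 = _back_extrapolate_c0(t, c)
        t = np.insert(t, 0, 0.0)
        c = np.insert(c, 0, c0)
    auc_seg, aumc_seg = _segment_areas(t, c, auc_method)
    auc_last = float(auc_seg.sum())
    aumc_last = float(aumc_seg.sum())

    result = NCAResult(
        subject_id=profile.subject_id,
        route=route,
        dose=dose,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
        dose_normalized_cmax=dose_normalize(cmax, dose),
    )

    try:
        fit = fit_lambda_z(profile, route=route, min_points=min_lambda_points)
    except LambdaZNotEstimable:
        result.dose_normalized_auc = dose_normalize(auc_last, dose)
        return result

    lam = fit.lambda_z
    auc_inf = auc_last + fit.clast_pred / lam
    aumc_inf = aumc_last + fit.t_last * fit.clast_pred / lam + fit.clast_pred / lam**2
    result.lambda_z = lam
    result.lambda_z_npoints = fit.n_points
    result.lambda_z_r2adj = fit.r2_adj
    result.t_half = LN2 / lam
    result.auc_inf = auc_inf
    result.auc_extrap_pct = 100.0 * (auc_inf - auc_last) / auc_inf
    result.aumc_inf = aumc_inf
    result.dose_normalized_auc = dose_normalize(auc_inf, dose)

    if route == "iv_bolus":
        result.mrt = aumc_inf / auc_inf
        result.cl = dose * UG_PER_MG / auc_inf
        result.vss = result.cl * result.mrt

    if excretion is not None:
        amount_per_kg = excretion.ae_0_24_pct / 100.0 * dose * UG_PER_MG  # ug/kg
        result.cl_r = amount_per_kg / auc_inf
        if result.cl is not None:
            result.cl_nr = result.cl - result.cl_r
    return result


def bioavailability(
    auc_oral: float, dose_oral: float, auc_iv: float, dose_iv: float
) -> float:
    """Absolute oral bioavailability, percent.

    F% = 100 (AUC_oral/Dose_oral) / (AUC_iv/Dose_iv); at equal doses
    this reduces to 100 AUC_oral/AUC_iv.
    """
    for name, v in (
        ("auc_oral", auc_oral),
        ("dose_oral", dose_oral),
        ("auc_iv", auc_iv),
        ("dose_iv", dose_iv),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return 100.0 * (auc_oral / dose_oral) / (auc_iv / dose_iv)


def dose_normalize(value: float, dose: float, ref_dose: float = 1.0) -> float:
    """Scale a dose-proportional parameter to the reference dose (1 mg/kg)."""
    if not dose > 0:
        raise ValueError("dose must be positive")
    return value * ref_dose / dose


def run_nca(
    profiles: Iterable[ConcProfile],
    dose_events: Iterable[DoseEvent],
    excretions: Optional[Iterable[ExcretionRecord]] = None,
    **kwargs,
) -> list[NCAResult]:
    """NCA over a study: profiles matched to dose events by subject_id."""
    doses = {d.subject_id: d for d in dose_events}
    excr = {e.subject_id: e for e in excretions} if excretions else {}
    results = []
    for profile in profiles:
        if profile.subject_id not in doses:
            raise ValueError(f"no dose event for subject {profile.subject_id!r}")
        results.append(
            nca_single(profile, doses[profile.subject_id],
                       excr.get(profile.subject_id), **kwargs)
        )
    return results


def results_to_frame(results: Sequence[NCAResult]) -> pd.DataFrame:
    """Tidy long-format table: subject, parameter, value, units."""
    rows: list[dict] = []
    for r in results:
        rows.extend(r.to_tidy_rows())
    return pd.DataFrame(
        rows, columns=["subject_id", "route", "dose_mg_kg", "parameter", "value", "units"]
    )
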