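"""Per-animal non-compartmental analysis (NCA) of plasma profiles.

The estimation follows the standard non-compartmental workflow for a
single bolus dose:

* ``Cmax``/``Tmax`` and the last quantifiable point are read directly off
  the observed data;
* AUC and AUMC to the last quantifiable point use the linear-up/log-down
  trapezoid: linear for non-decreasing segments, logarithmic for
  decreasing ones;
* the terminal rate constant λz comes from an ordinary least-squares fit
  of ln(concentration) on time over a terminal window chosen to maximise
  adjusted R² (never including Tmax or earlier points), with
  T½ = ln 2 / λz;
* extrapolation to infinity uses AUCinf = AUClast + Clast/λz and the
  matching first-moment form;
* for intravenous profiles, CL = dose/AUCinf, MRT = AUMCinf/AUCinf and
  Vss = CL·MRT.

Concentrations are ng/ml, times hours, doses mg/kg; derived units are
noted per function. Only quantifiable records (see
:mod:`gampk.pk_data`) ever enter a computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from ._format import sigfig_round, sigfig_str
from .pk_data import PKProfile, Route, quantifiable_records

LN2 = math.log(2.0)

#: adjusted-R² differences below this are treated as ties (resolved toward
#: the window with more points), matching common NCA software behaviour
_R2_TIE_TOL = 1e-4


class EstimationError(RuntimeError):
    """An NCA quantity could not be estimated from the available data."""


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression: λz (1/hr) and its diagnostics."""

    lambda_z: float
    t_half: float
    n_points: int
    window_start: float
    r_squared_adj: float
    intercept_log: float


@dataclass(frozen=True)
class NCAResult:
    """Complete per-animal NCA parameter set.

    AUC quantities are ng·hr/ml and AUMC ng·hr²/ml (internal scale);
    ``cl_obs`` is ml/hr/kg, ``vss`` L/kg — populated for IV animals only.
    ``f_pct`` is filled in at the study level once an IV reference exists.
    """

    animal_id: str
    route: Route
    dose: float
    cmax: float
    tmax: float
    c_last: float
    t_last: float
    auc_last: float
    auc_inf: float
    aumc_last: float
    aumc_inf: float
    lambda_fit: LambdaZFit
    extrap_frac: float
    cl_obs: Optional[float] = None
    mrt: Optional[float] = None
    vss: Optional[float] = None
    f_pct: Optional[float] = None


@dataclass(frozen=True)
class GroupSummary:
    group: str
    parameter: str
    mean: float
    sd: Optional[float]
    n: int
    formatted: str


# ---------------------------------------------------------------------------
# terminal slope


def _ols_loglinear(times: np.ndarray, log_conc: np.ndarray):
    """Slope/intercept/adjusted-R² of ln C on t (n >= 3 guaranteed)."""
    n = len(times)
    slope, intercept = np.polyfit(times, log_conc, 1)
    fitted = slope * times + intercept
    ss_res = float(np.sum((log_conc - fitted) ** 2))
    ss_tot = float(np.sum((log_conc - log_conc.mean()) ** 2))
    if ss_tot == 0.0:
        return slope, intercept, -math.inf
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, r2_adj


def fit_lambda_z(
    profile: PKProfile,
    selection: str = "best_fit",
    manual_window: Optional[tuple[float, float]] = None,
) -> LambdaZFit:
    """Estimate λz from the terminal log-linear portion of a profile.

    ``best_fit`` examines every contiguous terminal window of >= 3
    quantifiable points strictly after Tmax and keeps the one with the
    highest adjusted R² (ties go to the window with more points);
    ``manual`` restricts the candidate points to ``manual_window``
    (inclusive time range) instead. A window with a non-negative slope is
    never accepted.
    """
    recs = quantifiable_records(profile)
    times = np.array([r.time for r in recs])
    concs = np.array([r.concentration for r in recs])
    if len(recs) == 0:
        raise EstimationError(f"{profile.animal_id}: no quantifiable records")

    tmax_idx = int(np.argmax(concs))  # argmax returns the earliest maximum
    cand_t = times[tmax_idx + 1 :]
    cand_c = concs[tmax_idx + 1 :]

    if selection == "manual":
        if manual_window is None:
            raise ValueError("manual selection requires manual_window")
        lo, hi = manual_window
        keep = (cand_t >= lo) & (cand_t <= hi)
        cand_t, cand_c = cand_t[keep], cand_c[keep]
        windows = [len(cand_t)] if len(cand_t) >= 3 else []
    elif selection == "best_fit":
        windows = list(range(3, len(cand_t) + 1))
    else:
        raise ValueError(f"unknown selection {selection!r}")

    if not windows:
        raise EstimationError(
            f"{profile.animal_id}: fewer than 3 usable points after Tmax"
        )
    if np.any(cand_c <= 0):
        # quantifiable records are > 0 by the LLOQ policy; belt and braces
        raise EstimationError(f"{profile.animal_id}: non-positive concentration")

    log_c = np.log(cand_c)
    best: Optional[tuple[float, int, float, float]] = None  # r2, m, slope, icept
    for m in windows:
        t_w, y_w = cand_t[-m:], log_c[-m:]
        slope, intercept, r2_adj = _ols_loglinear(t_w, y_w)
        if slope >= 0:
            continue
        if (
            best is None
            or r2_adj > best[0] + _R2_TIE_TOL
            or (abs(r2_adj - best[0]) <= _R2_TIE_TOL and m > best[1])
        ):
            best = (r2_adj, m, slope, intercept)
    if best is None:
        raise EstimationError(f"{profile.animal_id}: no terminal decline")

    r2_adj, m, slope, intercept = best
    lam = -slope
    return LambdaZFit(
        lambda_z=lam,
        t_half=LN2 / lam,
        n_points=m,
        window_start=float(cand_t[-m]),
        r_squared_adj=min(r2_adj, 1.0) if math.isfinite(r2_adj) else 1.0,
        intercept_log=float(intercept),
    )


# ---------------------------------------------------------------------------
# areas


def _segment(t1: float, t2: float, c1: float, c2: float) -> tuple[float, float]:
    """(AUC, AUMC) of one segment: linear up, logarithmic down.

    The log branch assumes mono-exponential decline within the segment; a
    zero concentration in a decreasing segment falls back to linear (the
    logarithm is undefined there).
    """
    dt = t2 - t1
    if c2 >= c1 or c1 <= 0.0 or c2 <= 0.0:
        return (c1 + c2) / 2.0 * dt, (t1 * c1 + t2 * c2) / 2.0 * dt
    k = math.log(c1 / c2) / dt
    auc = (c1 - c2) / k
    aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    return auc, aumc


def _areas(profile: PKProfile) -> tuple[float, float]:
    recs = quantifiable_records(profile)
    if len(recs) < 2:
        raise EstimationError(
            f"{profile.animal_id}: need >= 2 quantifiable points for AUC"
        )
    auc = aumc = 0.0
    for a, b in zip(recs[:-1], recs[1:]):
        s_auc, s_aumc = _segment(a.time, b.time, a.concentration, b.concentration)
        auc += s_auc
        aumc += s_aumc
    return auc, aumc


def auc_last(profile: PKProfile) -> float:
    """Linear-up/log-down AUC from the first to last quantifiable record."""
    return _areas(profile)[0]


def aumc_last(profile: PKProfile) -> float:
    """First-moment area (∫ t·C dt) with the same up/down segment rule."""
    return _areas(profile)[1]


def auc_inf(
    auc_last_value: float, c_last: float, lambda_fit: LambdaZFit
) -> tuple[float, float]:
    """AUCinf = AUClast + Clast/λz; returns (AUCinf, extrapolated fraction)."""
    if lambda_fit.lambda_z <= 0:
        raise EstimationError("lambda_z must be positive")
    total = auc_last_value + c_last / lambda_fit.lambda_z
    frac = (total - auc_last_value) / total if total > 0 else 0.0
    return total, frac


def aumc_inf(
    aumc_last_value: float, c_last: float, t_last: float, lambda_fit: LambdaZFit
) -> float:
    """AUMCinf via the standard tail: Clast·tlast/λz + Clast/λz²."""
    if lambda_fit.lambda_z <= 0:
        raise EstimationError("lambda_z must be positive")
    lam = lambda_fit.lambda_z
    return aumc_last_value + c_last * t_last / lam + c_last / lam**2


def observed_extrema(profile: PKProfile) -> tuple[float, float, float, float]:
    """(Cmax, Tmax, Clast, Tlast) read directly from quantifiable data.

    Ties in the maximum go to the earliest time.
    """
    recs = quantifiable_records(profile)
    if not recs:
        raise EstimationError(f"{profile.animal_id}: no quantifiable records")
    cmax_rec = max(recs, key=lambda r: (r.concentration, -r.time))
    last = recs[-1]
    return cmax_rec.concentration, cmax_rec.time, last.concentration, last.time


def iv_parameters(result: NCAResult) -> tuple[float, float, float]:
    """(CL ml/hr/kg, MRT hr, Vss L/kg) for an intravenous bolus profile.

    CL = dose/AUCinf, MRT = AUMCinf/AUCinf, Vss = CL·MRT. The dose is
    mg/kg and AUC ng·hr/ml, so the mg→ng factor 1e6 yields CL in ml/hr/kg.
    """
    if result.route is not Route.IV:
        raise EstimationError(
            f"{result.animal_id}: IV parameters requested for {result.route.value} route"
        )
    if result.aumc_inf <= 0:
        raise EstimationError(f"{result.animal_id}: non-positive AUMCinf")
    cl = result.dose * 1e6 / result.auc_inf  # ml/hr/kg
    mrt = result.aumc_inf / result.auc_inf  # hr
    vss = cl * mrt / 1000.0  # L/kg
    return cl, mrt, vss


def bioavailability(
    auc_im: float, dose_im: float, auc_iv: float, dose_iv: float
) -> float:
    """Absolute bioavailability F (%) = dose-corrected AUC ratio vs IV."""
    for name, v in (
        ("auc_im", auc_im),
        ("dose_im", dose_im),
        ("auc_iv", auc_iv),
        ("dose_iv", dose_iv),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return (auc_im / auc_iv) * (dose_iv / dose_im) * 100.0


def dose_normalize(value: float, dose: float) -> float:
    """Exposure or concentration divided by the dose (per mg/kg)."""
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    return value / dose


def summarize_group(values: Sequence[float], label: str, parameter: str = "") -> GroupSummary:
    """Arithmetic mean ± sample SD, formatted at 3 significant figures."""
    if len(values) == 0:
        raise ValueError("summarize_group: empty value list")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) >= 2:
        sd = float(arr.std(ddof=1))
        formatted = f"{sigfig_str(mean)} ± {sigfig_str(sd)}"
    else:
        sd = None
        formatted = sigfig_str(mean)
    return GroupSummary(label, parameter, mean, sd, len(arr), formatted)


# ---------------------------------------------------------------------------
# per-animal driver


def analyze_profile(
    profile: PKProfile,
    selection: str = "best_fit",
    manual_window: Optional[tuple[float, float]] = None,
) -> NCAResult:
    """Run the full NCA on one profile and assemble an :class:`NCAResult`."""
    cmax, tmax, c_last, t_last = observed_extrema(profile)
    auc_l, aumc_l = _areas(profile)
    lam = fit_lambda_z(profile, selection=selection, manual_window=manual_window)
    auc_i, extrap = auc_inf(auc_l, c_last, lam)
    aumc_i = aumc_inf(aumc_l, c_last, t_last, lam)
    result = NCAResult(
        animal_id=profile.animal_id,
        route=profile.dose_event.route,
        dose=profile.dose_event.dose,
        cmax=cmax,
        tmax=tmax,
        c_last=c_last,
        t_last=t_last,
        auc_last=auc_l,
        auc_inf=auc_i,
        aumc_last=aumc_l,
        aumc_inf=aumc_i,
        lambda_fit=lam,
        extrap_frac=extrap,
    )
    if profile.dose_event.route is Route.IV:
        cl, mrt, vss = iv_parameters(result)
        result = replace(result, cl_obs=cl, mrt=mrt, vss=vss)
    return result


def analyze_study(
    profiles: Sequence[PKProfile],
    selection: str = "best_fit",
) -> list[NCAResult]:
    """NCA for every profile, then per-animal F against the IV group mean.

    Per-animal bioavailability uses the IV group's mean dose-corrected
    AUCinf as the reference; the group-level F of the report layer uses
    group-mean AUCs directly.
    """
    results = [analyze_profile(p, selection=selection) for p in profiles]
    iv = [r for r in results if r.route is Route.IV]
    if iv:
        iv_ref = float(np.mean([r.auc_inf / r.dose for r in iv]))
        results = [
            replace(r, f_pct=(r.auc_inf / r.dose) / iv_ref * 100.0)
            if r.route is Route.IM
            else r
            for r in results
        ]
    return results
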