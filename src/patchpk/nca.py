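"""Model-independent moment analysis (non-compartmental analysis, NCA).

Estimates AUC, AUMC, MRT, the terminal slope lambda_z and the derived
disposition parameters (CL_tot, Vd_ss for IV boluses; C_max, T_max and
CL_tot/F for transdermal profiles) directly from sampled concentration-time
data without assuming a compartmental model.

Conventions (all configurable where noted):

* trapezoidal integration is linear-up / log-down by default;
* lambda_z is an ordinary least-squares fit of ln(C) on t over the last
  ``n_terminal`` positive samples (default 3);
* IV profiles are back-extrapolated to t=0 by a log-linear extension of the
  first two samples; transdermal profiles start at C(0) = 0;
* zeros inside a profile force the spanning segment to the linear rule;
  trailing zeros are dropped before the terminal fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pk_models import DoseEvent, Route

__all__ = [
    "ConcentrationTimeProfile",
    "TerminalSlope",
    "IVMomentResult",
    "TDMomentResult",
    "terminal_slope",
    "auc_aumc",
    "moment_analysis_iv",
    "moment_analysis_td",
    "read_profiles_csv",
    "write_profiles_csv",
]

TrapezoidRule = Literal["linear_log", "linear"]


class TerminalSlopeError(ValueError):
    """Raised when the terminal window is unusable (non-positive samples)."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject's sampled concentration curve with dose metadata.

    times are in hours (strictly increasing, >= 3 samples), concentrations
    in ng/mL (finite, non-negative), body_weight in kg.
    """

    subject_id: str
    route: Route
    times: np.ndarray
    concentrations: np.ndarray
    dose: DoseEvent
    body_weight: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if t.ndim != 1 or c.shape != t.shape:
            raise ValueError("times and concentrations must be 1-D and equal length")
        if t.size < 3:
            raise ValueError("need at least 3 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentrations must be finite and non-negative")
        if self.route != self.dose.route:
            raise ValueError("profile route and dose route disagree")
        if not self.body_weight > 0:
            raise ValueError("body_weight must be positive")


@dataclass(frozen=True)
class TerminalSlope:
    """OLS terminal slope of ln(C) vs t, reported as lambda_z = -slope."""

    lambda_z: float
    r_squared: float
    n_points: int
    flagged: bool = False  # lambda_z <= 0: rising tail, unusable for tails


@dataclass(frozen=True)
class IVMomentResult:
    AUC_0_inf: float
    AUMC_0_inf: float
    MRT: float
    k_e: float  # lambda_z of the terminal fit
    CL_tot: float  # L/hr/kg (IV dose is per kg)
    Vd_ss: float  # L/kg
    n_terminal_points: int
    r_squared_terminal: float
    subject_id: str = ""


@dataclass(frozen=True)
class TDMomentResult:
    C_max: float
    T_max: float
    AUC_0_inf: float
    CL_tot_over_F: float  # L/hr/kg
    lambda_z: float = math.nan
    subject_id: str = ""


def terminal_slope(profile: ConcentrationTimeProfile, n_points: int = 3) -> TerminalSlope:
    """Fit lambda_z over the last ``n_points`` samples.

    Trailing zero concentrations are dropped first.  Any zero or negative
    concentration inside the fit window raises :class:`TerminalSlopeError`;
    a non-negative slope (rising tail) returns a flagged result rather than
    silently extrapolating.
    """
    if n_points < 3:
        raise ValueError("terminal fit needs at least 3 points")
    t = profile.times
    c = profile.concentrations
    keep = np.nonzero(c > 0)[0]
    if keep.size == 0:
        raise TerminalSlopeError("profile has no positive concentrations")
    last = keep[-1] + 1
    t, c = t[:last], c[:last]
    if t.size < n_points:
        raise TerminalSlopeError(
            f"only {t.size} samples before trailing zeros; need {n_points}"
        )
    tw = t[-n_points:]
    cw = c[-n_points:]
    if np.any(cw <= 0):
        raise TerminalSlopeError("zero concentration inside the terminal window")
    slope, intercept = np.polyfit(tw, np.log(cw), 1)
    fitted = slope * tw + intercept
    ss_res = float(np.sum((np.log(cw) - fitted) ** 2))
    ss_tot = float(np.sum((np.log(cw) - np.log(cw).mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    lam = -float(slope)
    return TerminalSlope(lambda_z=lam, r_squared=r2, n_points=n_points, flagged=lam <= 0)


def _segment_areas(
    t1: float, t2: float, c1: float, c2: float, rule: TrapezoidRule
) -> tuple[float, float]:
    """(AUC, AUMC) of one segment; log rule only on a strict decline."""
    dt = t2 - t1
    if rule == "linear_log" and c1 > c2 > 0:
        lam = math.log(c1 / c2) / dt
        auc = (c1 - c2) / lam
        aumc = (t1 * c1 - t2 * c2) / lam + (c1 - c2) / lam**2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def _extrapolated_c0(profile: ConcentrationTimeProfile) -> float:
    """Back-extrapolate C(0) for IV boluses from the first two samples."""
    t, c = profile.times[:2], profile.concentrations[:2]
    if np.any(c <= 0):
        return float(c[0])  # cannot log-extrapolate; hold first value
    if c[1] >= c[0]:
        return float(c[0])
    slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
    return float(math.exp(math.log(c[0]) - slope * t[0]))


def auc_aumc(
    profile: ConcentrationTimeProfile,
    lambda_z: float,
    rule: TrapezoidRule = "linear_log",
) -> tuple[float, float]:
    """AUC and AUMC from 0 to infinity.

    The observed part is integrated by trapezoids (``rule``); the tail
    beyond the last positive sample ``(t_z, C_z)`` is the analytic
    exponential-tail area ``C_z / lambda_z`` and first moment
    ``C_z t_z / lambda_z + C_z / lambda_z**2``.
    """
    if not lambda_z > 0:
        raise ValueError("lambda_z must be positive to extrapolate the tail")
    t = profile.times
    c = profile.concentrations
    keep = np.nonzero(c > 0)[0]
    if keep.size == 0:
        raise ValueError("profile has no positive concentrations")
    last = keep[-1] + 1
    t, c = list(t[:last]), list(c[:last])

    if t[0] > 0:
        if profile.route == "iv_bolus":
            c0 = _extrapolated_c0(profile)
        else:
            c0 = 0.0
        t.insert(0, 0.0)
        c.insert(0, c0)

    auc = aumc = 0.0
    for i in range(len(t) - 1):
        a, m = _segment_areas(t[i], t[i + 1], c[i], c[i + 1], rule)
        auc += a
        aumc += m
    c_last, t_last = c[-1], t[-1]
    auc += c_last / lambda_z
    aumc += c_last * t_last / lambda_z + c_last / lambda_z**2
    return auc, aumc


def moment_analysis_iv(
    profile: ConcentrationTimeProfile,
    n_terminal: int = 3,
    rule: TrapezoidRule = "linear_log",
) -> IVMomentResult:
    """Moment analysis of an IV-bolus profile.

    CL_tot = dose / AUC (per kg: the IV dose is in µg/kg), MRT = AUMC/AUC,
    Vd_ss = CL_tot * MRT, and k_e is reported as the terminal lambda_z.
    """
    if profile.route != "iv_bolus":
        raise ValueError("moment_analysis_iv requires an iv_bolus profile")
    ts = terminal_slope(profile, n_terminal)
    if ts.flagged:
        raise TerminalSlopeError(
            f"terminal phase not declining (lambda_z={ts.lambda_z:.3g}); "
            "cannot extrapolate"
        )
    auc, aumc = auc_aumc(profile, ts.lambda_z, rule)
    mrt = aumc / auc
    cl = profile.dose.amount / auc  # (µg/kg)/(ng·hr/mL) = L/hr/kg
    return IVMomentResult(
        AUC_0_inf=auc,
        AUMC_0_inf=aumc,
        MRT=mrt,
        k_e=ts.lambda_z,
        CL_tot=cl,
        Vd_ss=cl * mrt,
        n_terminal_points=ts.n_points,
        r_squared_terminal=ts.r_squared,
        subject_id=profile.subject_id,
    )


def moment_analysis_td(
    profile: ConcentrationTimeProfile,
    n_terminal: int = 3,
    rule: TrapezoidRule = "linear_log",
) -> TDMomentResult:
    """Moment analysis of a transdermal profile.

    C_max/T_max are taken from the sampled grid (earliest time on ties);
    CL_tot/F = (dose / body_weight) / AUC, per kg because the transdermal
    dose is a total amount.
    """
    if profile.route != "transdermal":
        raise ValueError("moment_analysis_td requires a transdermal profile")
    ts = terminal_slope(profile, n_terminal)
    if ts.flagged:
        raise TerminalSlopeError(
            f"terminal phase not declining (lambda_z={ts.lambda_z:.3g}); "
            "cannot extrapolate"
        )
    auc, _ = auc_aumc(profile, ts.lambda_z, rule)
    i_max = int(np.argmax(profile.concentrations))  # argmax takes the first tie
    dose_per_kg = profile.dose.amount / profile.body_weight
    return TDMomentResult(
        C_max=float(profile.concentrations[i_max]),
        T_max=float(profile.times[i_max]),
        AUC_0_inf=auc,
        CL_tot_over_F=dose_per_kg / auc,
        lambda_z=ts.lambda_z,
        subject_id=profile.subject_id,
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "subject_id",
    "route",
    "time_hr",
    "conc_ng_ml",
    "dose",
    "dose_units",
    "body_weight_kg",
    "removal_time_hr",
]


def read_profiles_csv(path: str | Path) -> list[ConcentrationTimeProfile]:
    """Read profiles from tabular text.

    Expected columns: subject_id, route, time_hr (or time_min, converted on
    ingest), conc_ng_ml, dose, dose_units, body_weight_kg and optionally
    removal_time_hr.  One profile per (subject_id, route) pair.
    """
    df = pd.read_csv(path)
    if "time_hr" not in df.columns:
        if "time_min" in df.columns:
            df = df.assign(time_hr=df["time_min"] / 60.0)
        else:
            raise ValueError("profile CSV needs a time_hr or time_min column")
    missing = {"subject_id", "route", "conc_ng_ml", "dose", "body_weight_kg"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    profiles = []
    for (sid, route), grp in df.groupby(["subject_id", "route"], sort=False):
        grp = grp.sort_values("time_hr")
        removal = None
        if "removal_time_hr" in grp.columns:
            r = grp["removal_time_hr"].dropna()
            if len(r):
                removal = float(r.iloc[0])
        dose = DoseEvent(route=route, amount=float(grp["dose"].iloc[0]), removal_time=removal)
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(sid),
                route=route,
                times=grp["time_hr"].to_numpy(float),
                concentrations=grp["conc_ng_ml"].to_numpy(float),
                dose=dose,
                body_weight=float(grp["body_weight_kg"].iloc[0]),
            )
        )
    return profiles


def write_profiles_csv(profiles: Sequence[ConcentrationTimeProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        units = "ug_per_kg" if p.route == "iv_bolus" else "ug"
        for t, c in zip(p.times, p.concentrations):
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "route": p.route,
                    "time_hr": t,
                    "conc_ng_ml": c,
                    "dose": p.dose.amount,
                    "dose_units": units,
                    "body_weight_kg": p.body_weight,
                    "removal_time_hr": p.dose.removal_time,
                }
            )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)
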