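"""Titration-period extraction and logistic-regression screening.

The clinical question is how long it takes to stabilise a patient newly
started on a 24-h transdermal fentanyl formulation.  The titration period
is defined operationally from the medication record alone: the first day
ending a run of ``stability_days`` consecutive days (default 5) in which
the patch dose never changed and rescue opioids were used at most
``rescue_max`` times per day (default 3).  Patients are then dichotomised
at "within 5 days" versus "6 days or more", candidate factors (demographics
and ICD-10 coded comorbidities) are screened by univariate logistic
regression at p < 0.1, and the surviving factors enter one joint
multivariate logistic model whose exponentiated coefficients are the
adjusted odds ratios (AOR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PatientRecord",
    "TitrationOutcome",
    "LogisticResult",
    "titration_period",
    "dichotomize",
    "univariate_screen",
    "multivariate_aor",
    "read_cohort_csv",
    "read_daily_records_csv",
]

RescueConvention = Literal["window", "final_day"]

#: covariates screened alongside the comorbidity indicators
BASE_FACTORS = ("female", "age", "bmi", "albumin", "initial_dose")

#: non-factor columns of a cohort table
_META_COLUMNS = {
    "patient_id",
    "male",
    "height",
    "weight",
    "outcome",
    "titration_period",
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient's longitudinal medication record plus covariates.

    daily_dose[i] is the formulation strength (mg) on study day i+1 (day 1
    is initiation); daily_rescue_count[i] the number of rescue opioid doses
    that day.  Comorbidities are ICD-10 three-character categories (with
    C78.x/C79.x four-character subcategories) mapped to presence flags.
    """

    patient_id: str
    daily_dose: tuple[float, ...]
    daily_rescue_count: tuple[int, ...]
    covariates: Mapping[str, float] = field(default_factory=dict)
    comorbidity_flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "daily_dose", tuple(float(d) for d in self.daily_dose))
        object.__setattr__(
            self, "daily_rescue_count", tuple(int(r) for r in self.daily_rescue_count)
        )
        if len(self.daily_dose) != len(self.daily_rescue_count):
            raise ValueError("dose and rescue sequences must be the same length")
        if len(self.daily_dose) < 5:
            raise ValueError("record must cover at least 5 days")
        if any(d <= 0 for d in self.daily_dose):
            raise ValueError("daily doses must be positive")
        if any(r < 0 for r in self.daily_rescue_count):
            raise ValueError("rescue counts must be non-negative")


@dataclass(frozen=True)
class TitrationOutcome:
    """Extracted titration period; ``censored`` when the criteria were
    never met within the record."""

    titration_period: int | None
    group: Literal["within_5", "six_or_more"] | None
    censored: bool = False


@dataclass(frozen=True)
class LogisticResult:
    factor: str
    odds_ratio: float  # OR (univariate) or AOR (multivariate)
    ci_low: float
    ci_high: float
    p_value: float
    analysis: Literal["univariate", "multivariate"]
    n: int
    coef: float = math.nan
    se: float = math.nan
    flagged: bool = False  # separation / non-convergence
    note: str = ""


def titration_period(
    record: PatientRecord,
    stability_days: int = 5,
    rescue_max: int = 3,
    rescue_convention: RescueConvention = "window",
) -> TitrationOutcome:
    """First day ending a fully stable window.

    Returns the smallest day T >= ``stability_days`` such that over the
    ``stability_days`` consecutive days ending at T the dose is constant
    and (under the default ``"window"`` convention) every day's rescue
    count is <= ``rescue_max``.  The ``"final_day"`` convention applies the
    rescue criterion to day T only.  Records in which no such window exists
    are censored.
    """
    if stability_days < 1:
        raise ValueError("stability_days must be >= 1")
    n = len(record.daily_dose)
    if n < stability_days:
        raise ValueError(
            f"record of {n} days is shorter than the {stability_days}-day window"
        )
    doses = record.daily_dose
    rescues = record.daily_rescue_count
    for end in range(stability_days - 1, n):  # end index of the window (0-based)
        start = end - stability_days + 1
        window_doses = doses[start : end + 1]
        if len(set(window_doses)) != 1:
            continue
        if rescue_convention == "window":
            ok = all(r <= rescue_max for r in rescues[start : end + 1])
        else:
            ok = rescues[end] <= rescue_max
        if ok:
            t = end + 1  # days are 1-based
            return TitrationOutcome(
                titration_period=t,
                group="within_5" if t <= stability_days else "six_or_more",
            )
    return TitrationOutcome(titration_period=None, group=None, censored=True)


def dichotomize(
    outcomes: Sequence[TitrationOutcome], cutoff: int = 5
) -> tuple[np.ndarray, int]:
    """Binary outcome vector: 1 iff titration period >= cutoff + 1.

    Censored records are dropped; the second return value counts them.
    """
    values = []
    n_censored = 0
    for o in outcomes:
        if o.censored or o.titration_period is None:
            n_censored += 1
            continue
        values.append(1 if o.titration_period >= cutoff + 1 else 0)
    return np.asarray(values, dtype=int), n_censored


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------

_SEPARATION_SE = 50.0  # Wald SEs explode under (quasi-)separation


def _fit_logit(X: np.ndarray, y: np.ndarray):
    # non-convergence under separation is expected and surfaced via the
    # ``flagged`` field, so the optimizer's own warning is silenced here
    import warnings as _warnings

    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        try:
            return model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except Exception:
            try:
                return model.fit(disp=0, method="bfgs", maxiter=500)
            except Exception:
                return None


def _result_from_fit(fit, j: int, factor: str, analysis: str, n: int) -> LogisticResult:
    """Build a LogisticResult for coefficient j (0 is the intercept)."""
    beta = float(fit.params[j])
    se = float(fit.bse[j])
    converged = True
    if hasattr(fit, "mle_retvals") and isinstance(fit.mle_retvals, dict):
        converged = bool(fit.mle_retvals.get("converged", True))
    flagged = (
        not (math.isfinite(beta) and math.isfinite(se) and se < _SEPARATION_SE)
        or not converged
    )
    z = 1.959963984540054  # Phi^{-1}(0.975)

    def _exp(x: float) -> float:
        if not math.isfinite(x):
            return math.nan
        try:
            return math.exp(x)
        except OverflowError:
            return math.inf

    return LogisticResult(
        factor=factor,
        odds_ratio=_exp(beta),
        ci_low=_exp(beta - z * se),
        ci_high=_exp(beta + z * se),
        p_value=float(fit.pvalues[j]),
        analysis=analysis,  # type: ignore[arg-type]
        n=n,
        coef=beta,
        se=se,
        flagged=flagged,
        note="possible separation or non-convergence" if flagged else "",
    )


def _factor_columns(cohort: pd.DataFrame, factors: Sequence[str] | None) -> list[str]:
    if factors is not None:
        return list(factors)
    comorbidities = [
        c for c in cohort.columns if c not in _META_COLUMNS and c not in BASE_FACTORS
    ]
    return [f for f in BASE_FACTORS if f in cohort.columns] + comorbidities


def univariate_screen(
    cohort: pd.DataFrame,
    outcome: Sequence[int] | np.ndarray,
    factors: Sequence[str] | None = None,
    alpha_screen: float = 0.1,
) -> tuple[list[LogisticResult], list[str]]:
    """One single-predictor logistic fit per candidate factor.

    Each factor is fitted on its complete cases (e.g. missing albumin rows
    are dropped for the albumin fit only).  Zero-variance factors are
    skipped with a note.  Returns all per-factor results and the names of
    factors with Wald p < ``alpha_screen``.
    """
    y_all = np.asarray(outcome, dtype=float)
    if len(y_all) != len(cohort):
        raise ValueError("outcome length must match the cohort")
    results: list[LogisticResult] = []
    selected: list[str] = []
    for factor in _factor_columns(cohort, factors):
        x = cohort[factor].to_numpy(dtype=float)
        keep = np.isfinite(x)
        x, y = x[keep], y_all[keep]
        n = int(keep.sum())
        if n < 10:
            raise ValueError(f"fewer than 10 complete cases for factor {factor!r}")
        if np.ptp(x) == 0:
            results.append(
                LogisticResult(
                    factor=factor,
                    odds_ratio=math.nan,
                    ci_low=math.nan,
                    ci_high=math.nan,
                    p_value=math.nan,
                    analysis="univariate",
                    n=n,
                    flagged=True,
                    note="zero variance; skipped",
                )
            )
            continue
        fit = _fit_logit(x[:, None], y)
        if fit is None:
            results.append(
                LogisticResult(
                    factor=factor,
                    odds_ratio=math.nan,
                    ci_low=math.nan,
                    ci_high=math.nan,
                    p_value=math.nan,
                    analysis="univariate",
                    n=n,
                    flagged=True,
                    note="fit failed",
                )
            )
            continue
        res = _result_from_fit(fit, 1, factor, "univariate", n)
        results.append(res)
        if not res.flagged and res.p_value < alpha_screen:
            selected.append(factor)
    return results, selected


def multivariate_aor(
    cohort: pd.DataFrame,
    outcome: Sequence[int] | np.ndarray,
    selected_factors: Sequence[str],
) -> list[LogisticResult]:
    """Joint logistic fit of the screened factors; AOR = exp(coefficient).

    Rows with a missing value in any included factor are dropped
    (complete-case analysis).  Separation or non-convergence is flagged on
    the affected factors, never silently reported as an estimate.  No
    multiple-testing correction is applied.
    """
    if not selected_factors:
        raise ValueError("selected_factors must be non-empty")
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(cohort):
        raise ValueError("outcome length must match the cohort")
    X = cohort[list(selected_factors)].to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]
    n = int(keep.sum())
    if n < 10:
        raise ValueError("fewer than 10 complete cases for the multivariate model")
    fit = _fit_logit(X, y)
    if fit is None:
        return [
            LogisticResult(
                factor=f,
                odds_ratio=math.nan,
                ci_low=math.nan,
                ci_high=math.nan,
                p_value=math.nan,
                analysis="multivariate",
                n=n,
                flagged=True,
                note="fit failed",
            )
            for f in selected_factors
        ]
    return [
        _result_from_fit(fit, j + 1, factor, "multivariate", n)
        for j, factor in enumerate(selected_factors)
    ]


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read the one-row-per-patient cohort table.

    Comorbidity flags are 0/1 columns named by ICD-10 code; missing
    continuous covariates (albumin) are blank cells read as NaN.
    """
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("cohort CSV needs a patient_id column")
    return df


def read_daily_records_csv(path: str | Path) -> dict[str, PatientRecord]:
    """Read long-format daily records (patient_id, day, dose_mg, rescue_count)."""
    df = pd.read_csv(path)
    missing = {"patient_id", "day", "dose_mg", "rescue_count"} - set(df.columns)
    if missing:
        raise ValueError(f"daily record CSV missing columns: {sorted(missing)}")
    records: dict[str, PatientRecord] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy(int)
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise ValueError(f"patient {pid}: days must run 1..n without gaps")
        records[str(pid)] = PatientRecord(
            patient_id=str(pid),
            daily_dose=tuple(grp["dose_mg"].astype(float)),
            daily_rescue_count=tuple(grp["rescue_count"].astype(int)),
        )
    return records
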