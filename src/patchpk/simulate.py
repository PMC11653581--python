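"""Synthetic-data generators for both study arms.

No raw animal or patient data are deposited for this kind of study, so the
pipeline is exercised end to end on virtual data with the statistical
structure the analysis assumes:

* ``simulate_rat`` builds virtual rats of two strains — normoglycemic
  Wistar controls and Goto-Kakizaki (GK) rats, a non-obese type-2 diabetes
  model — from strain presets holding the group-mean one-compartment
  parameters, the published IV (10 µg/kg, 9 samples over 5 h) and
  transdermal (160 µg patch quarter, 8 samples over 48 h, removal at 24 h)
  designs, lognormal between-animal variability with CVs taken from the
  reported group S.D./mean ratios, and lognormal proportional measurement
  error.  Matching patch-residual assays are emitted for the
  bioavailability decomposition.

* ``simulate_cohort`` builds a retrospective cohort of cancer patients
  initiated on transdermal fentanyl: covariates drawn from lognormals
  matched to the reported median/IQR, independent ICD-10 comorbidity
  indicators at preset prevalences, a binary long-titration outcome driven
  by a logistic model whose coefficients default to the log adjusted odds
  ratios of the reference analysis, and a daily dose/rescue record
  constructed so that the rule-based titration-period extractor recovers
  the drawn period exactly (round-trip guarantee).

Every generator takes a mandatory seed and is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .bioavailability import PatchResidual
from .nca import ConcentrationTimeProfile, write_profiles_csv
from .pk_models import Dialect, DoseEvent, bateman_concentration, iv_bolus_concentration
from .titration import PatientRecord

__all__ = [
    "RatPreset",
    "CohortPreset",
    "VirtualRat",
    "RatSimulation",
    "Cohort",
    "WISTAR",
    "GK",
    "REFERENCE_COHORT",
    "simulate_rat",
    "simulate_cohort",
]

_Z25 = 0.6744897501960817  # 75th-percentile standard normal quantile


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal deviates with mean 1 and the given CV."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s = _lognormal_sigma(cv)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def _lognormal_from_median_iqr(
    rng: np.random.Generator, median: float, iqr: tuple[float, float], size: int
) -> np.ndarray:
    """Lognormal draws matched to a target median and interquartile range."""
    q1, q3 = iqr
    sigma = math.log(q3 / q1) / (2.0 * _Z25)
    return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# Rat arm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatPreset:
    """Strain-level study conditions for the animal arm.

    Rates in 1/hr, Vd_ss in L/kg, doses in µg/kg (IV) and total µg
    (transdermal), schedules in minutes (IV) and hours (transdermal).
    ``cv_*`` are between-animal coefficients of variation derived from the
    reported group S.D./mean ratios.
    """

    label: str
    k_a: float
    k_e: float
    Vd_ss: float
    F: float
    F_a: float
    body_weight_mean: float  # kg
    iv_dose: float = 10.0  # µg/kg
    td_dose: float = 160.0  # µg
    iv_schedule_min: tuple[float, ...] = (1, 5, 10, 20, 30, 60, 120, 180, 300)
    td_schedule_hr: tuple[float, ...] = (1, 2, 4, 8, 12, 24, 30, 48)
    removal_time_hr: float = 24.0
    cv_k_a: float = 0.0
    cv_CL: float = 0.0
    cv_F: float = 0.0
    cv_F_a: float = 0.0
    cv_weight: float = 0.0

    @property
    def CL_tot(self) -> float:
        """Clearance implied by the preset rates: k_e * Vd_ss (L/hr/kg)."""
        return self.k_e * self.Vd_ss

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RatPreset":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("iv_schedule_min", "td_schedule_hr"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


WISTAR = RatPreset(
    label="wistar",
    k_a=2.28e-2,
    k_e=2.79e-1,
    Vd_ss=6.49,
    F=0.530,
    F_a=0.690,
    body_weight_mean=0.305,
    cv_k_a=0.67 / 2.28,
    cv_CL=0.17 / 3.21,
    cv_F=16.3 / 53.0,
    cv_F_a=6.3 / 69.0,
    cv_weight=0.010 / 0.305,
)

GK = RatPreset(
    label="gk",
    k_a=3.17e-2,
    k_e=2.55e-1,
    Vd_ss=6.94,
    F=0.555,
    F_a=0.780,
    body_weight_mean=0.339,
    cv_k_a=0.30 / 3.17,
    cv_CL=0.42 / 3.15,
    cv_F=7.1 / 55.5,
    cv_F_a=5.8 / 78.0,
    cv_weight=0.017 / 0.339,
)

PRESETS: dict[str, RatPreset] = {"wistar": WISTAR, "gk": GK}


@dataclass(frozen=True)
class VirtualRat:
    """One simulated animal: its true parameters and its sampled data."""

    subject_id: str
    k_a: float
    k_e: float
    Vd_ss: float  # L/kg
    F: float
    F_a: float
    body_weight: float  # kg
    iv_profile: ConcentrationTimeProfile
    td_profile: ConcentrationTimeProfile
    residual: PatchResidual


@dataclass(frozen=True)
class RatSimulation:
    preset: RatPreset
    seed: int
    subjects: tuple[VirtualRat, ...]

    @property
    def iv_profiles(self) -> list[ConcentrationTimeProfile]:
        return [s.iv_profile for s in self.subjects]

    @property
    def td_profiles(self) -> list[ConcentrationTimeProfile]:
        return [s.td_profile for s in self.subjects]

    @property
    def residuals(self) -> list[PatchResidual]:
        return [s.residual for s in self.subjects]

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "profiles": out / f"{self.preset.label}_profiles.csv",
            "residuals": out / f"{self.preset.label}_residuals.csv",
            "true_params": out / f"{self.preset.label}_true_params.csv",
        }
        write_profiles_csv(self.iv_profiles + self.td_profiles, paths["profiles"])
        pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "x_unused_ug": [s.residual.X_unused for s in self.subjects],
                "x_used_ug": [s.residual.X_used for s in self.subjects],
            }
        ).to_csv(paths["residuals"], index=False)
        pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "k_a": s.k_a,
                    "k_e": s.k_e,
                    "Vd_ss": s.Vd_ss,
                    "F": s.F,
                    "F_a": s.F_a,
                    "body_weight_kg": s.body_weight,
                }
                for s in self.subjects
            ]
        ).to_csv(paths["true_params"], index=False)
        return paths


def simulate_rat(
    preset: RatPreset,
    n_subjects: int,
    error_cv: float = 0.10,
    iiv_cv: float | None = None,
    seed: int | None = None,
    assay_cv: float = 0.02,
    dialect: Dialect = "full_depot",
) -> RatSimulation:
    """Simulate a strain group: IV and transdermal profiles plus residuals.

    Between-animal variability is lognormal on k_a, clearance (applied to
    k_e with Vd_ss held at the preset) and F, with per-parameter CVs taken
    from the preset unless a single ``iiv_cv`` overrides them all.
    Measurement error is proportional lognormal with CV ``error_cv`` on
    every sampled concentration.  The patch residual is
    ``X_used = X_unused * (1 - F_a * (1 + assay noise))`` with normal
    assay noise of CV ``assay_cv``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if error_cv < 0 or assay_cv < 0 or (iiv_cv is not None and iiv_cv < 0):
        raise ValueError("CVs must be non-negative")
    rng = np.random.default_rng(seed)

    cvs = {
        "k_a": preset.cv_k_a if iiv_cv is None else iiv_cv,
        "CL": preset.cv_CL if iiv_cv is None else iiv_cv,
        "F": preset.cv_F if iiv_cv is None else iiv_cv,
        "F_a": preset.cv_F_a if iiv_cv is None else iiv_cv,
        "weight": preset.cv_weight if iiv_cv is None else iiv_cv,
    }

    iv_times = np.asarray(preset.iv_schedule_min, dtype=float) / 60.0
    td_times = np.asarray(preset.td_schedule_hr, dtype=float)

    subjects = []
    for i in range(n_subjects):
        sid = f"{preset.label}_{i + 1:02d}"
        k_a = preset.k_a * _mean_one_lognormal(rng, cvs["k_a"])
        k_e = preset.k_e * _mean_one_lognormal(rng, cvs["CL"])  # CL varies, Vd fixed
        F = min(preset.F * _mean_one_lognormal(rng, cvs["F"]), 0.999)
        F_a = min(preset.F_a * _mean_one_lognormal(rng, cvs["F_a"]), 0.999)
        bw = preset.body_weight_mean * _mean_one_lognormal(rng, cvs["weight"])

        c_iv = iv_bolus_concentration(iv_times, preset.iv_dose, k_e, preset.Vd_ss)
        c_iv = c_iv * _mean_one_lognormal(rng, error_cv, size=c_iv.shape)
        iv_profile = ConcentrationTimeProfile(
            subject_id=sid,
            route="iv_bolus",
            times=iv_times,
            concentrations=c_iv,
            dose=DoseEvent(route="iv_bolus", amount=preset.iv_dose),
            body_weight=bw,
        )

        c_td = bateman_concentration(
            td_times,
            preset.td_dose,
            F,
            k_a,
            k_e,
            preset.Vd_ss * bw,
            removal_time=preset.removal_time_hr,
            dialect=dialect,
        )
        c_td = c_td * _mean_one_lognormal(rng, error_cv, size=c_td.shape)
        td_profile = ConcentrationTimeProfile(
            subject_id=sid,
            route="transdermal",
            times=td_times,
            concentrations=c_td,
            dose=DoseEvent(
                route="transdermal",
                amount=preset.td_dose,
                removal_time=preset.removal_time_hr,
            ),
            body_weight=bw,
        )

        release = F_a * (1.0 + assay_cv * rng.standard_normal())
        release = min(max(release, 0.0), 1.0)
        residual = PatchResidual(
            X_unused=preset.td_dose,
            X_used=preset.td_dose * (1.0 - release),
            subject_id=sid,
        )
        subjects.append(
            VirtualRat(
                subject_id=sid,
                k_a=float(k_a),
                k_e=float(k_e),
                Vd_ss=preset.Vd_ss,
                F=float(F),
                F_a=float(F_a),
                body_weight=float(bw),
                iv_profile=iv_profile,
                td_profile=td_profile,
                residual=residual,
            )
        )
    return RatSimulation(preset=preset, seed=seed, subjects=tuple(subjects))


# ---------------------------------------------------------------------------
# Clinical arm
# ---------------------------------------------------------------------------

#: comorbidity prevalences (carriers / 387) consistent with the reference
#: cohort's reported univariate odds ratios and outcome margins (261 short /
#: 126 long titration); two null codes with zero coefficient are included so
#: that screening has true negatives to reject
_COMORBIDITY_PREVALENCE = {
    "C67": 10 / 387,    # malignant neoplasm of bladder
    "C78.8": 8 / 387,   # secondary neoplasm, digestive organs
    "C79.5": 63 / 387,  # secondary neoplasm, bone and bone marrow
    "C79.7": 14 / 387,  # secondary neoplasm, adrenal gland
    "C92": 5 / 387,     # myeloid leukaemia
    "E03": 14 / 387,    # other hypothyroidism
    "E14": 66 / 387,    # unspecified diabetes mellitus
    "F03": 5 / 387,     # unspecified dementia
    "I71": 9 / 387,     # aortic aneurysm and dissection
    "K92": 6 / 387,     # other diseases of digestive system
    "M48": 9 / 387,     # other spondylopathies
    "N40": 6 / 387,     # hyperplasia of prostate
    "I10": 120 / 387,   # essential hypertension (null factor)
    "K21": 40 / 387,    # gastro-oesophageal reflux (null factor)
}

#: outcome-model log-odds per comorbidity: log of the reference multivariate
#: adjusted odds ratios for a titration period of 6 days or more
_COMORBIDITY_COEF = {
    "C67": math.log(3.831),
    "C78.8": math.log(2.009),
    "C79.5": math.log(1.563),
    "C79.7": math.log(2.475),
    "C92": math.log(6.771),
    "E03": math.log(2.635),
    "E14": math.log(0.438),
    "F03": math.log(8.415),
    "I71": math.log(4.590),
    "K92": math.log(4.040),
    "M48": math.log(3.055),
    "N40": math.log(4.241),
}


@dataclass(frozen=True)
class CohortPreset:
    """Study conditions for the clinical arm.

    Covariates are drawn from lognormals matched to the reported
    median/IQR; the binary outcome (titration period of 6 days or more)
    follows a logistic model over the comorbidity indicators with the
    intercept calibrated so the expected outcome fraction equals
    ``outcome_fraction``.
    """

    n: int = 387
    male_fraction: float = 239 / 387
    age_median: float = 66.0
    age_iqr: tuple[float, float] = (58.0, 73.0)
    height_median: float = 162.3  # cm
    height_iqr: tuple[float, float] = (155.4, 168.2)
    bmi_median: float = 20.3
    bmi_iqr: tuple[float, float] = (18.3, 22.5)
    albumin_median: float = 2.9  # g/dL
    albumin_iqr: tuple[float, float] = (2.4, 3.4)
    albumin_missing_rate: float = 34 / 387
    initial_dose_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)  # mg strengths
    initial_dose_probs: tuple[float, ...] = (0.05, 0.75, 0.15, 0.05)
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_COMORBIDITY_PREVALENCE)
    )
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_COMORBIDITY_COEF)
    )
    outcome_fraction: float = 126 / 387
    #: per-day continuation probability of the long-titration tail; the
    #: drawn period is 6 + (geometric - 1), capped at 39 days
    long_tail_continue: float = 0.735

    def __post_init__(self) -> None:
        for code, p in self.comorbidity_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {code} outside [0, 1]")
        if abs(sum(self.initial_dose_probs) - 1.0) > 1e-9:
            raise ValueError("initial_dose_probs must sum to 1")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.comorbidity_prevalence)

    def intercept(self) -> float:
        """Logistic intercept solving E[p] = outcome_fraction exactly.

        The expectation runs over all 2^k combinations of the k indicators
        with non-zero coefficient (independent Bernoulli flags), so the
        calibration is deterministic and exact to solver tolerance.
        """
        active = [
            (self.comorbidity_prevalence[c], self.coefficients[c])
            for c in self.codes
            if self.coefficients.get(c, 0.0) != 0.0
        ]
        if len(active) > 16:
            raise ValueError("too many active factors for exact calibration")
        combos = []
        for bits in product((0, 1), repeat=len(active)):
            prob = 1.0
            lp = 0.0
            for bit, (prev, coef) in zip(bits, active):
                prob *= prev if bit else (1.0 - prev)
                lp += coef * bit
            combos.append((prob, lp))
        probs = np.array([p for p, _ in combos])
        lps = np.array([l for _, l in combos])

        def mean_p(c: float) -> float:
            return float(np.sum(probs * expit(c + lps))) - self.outcome_fraction

        return brentq(mean_p, -20.0, 20.0, xtol=1e-12)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["comorbidity_prevalence"] = dict(self.comorbidity_prevalence)
        data["coefficients"] = dict(self.coefficients)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortPreset":
        data = yaml.safe_load(Path(path).read_text())
        for key in (
            "age_iqr",
            "height_iqr",
            "bmi_iqr",
            "albumin_iqr",
            "initial_dose_levels",
            "initial_dose_probs",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


REFERENCE_COHORT = CohortPreset()


@dataclass(frozen=True)
class Cohort:
    """A simulated cohort: per-patient table plus daily records."""

    preset: CohortPreset
    seed: int
    table: pd.DataFrame  # one row per patient, flags as 0/1 columns
    records: dict[str, PatientRecord]

    def records_long(self) -> pd.DataFrame:
        rows = []
        for pid, rec in self.records.items():
            for day, (dose, rescue) in enumerate(
                zip(rec.daily_dose, rec.daily_rescue_count), start=1
            ):
                rows.append(
                    {"patient_id": pid, "day": day, "dose_mg": dose, "rescue_count": rescue}
                )
        return pd.DataFrame(rows)

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"cohort": out / "cohort.csv", "records": out / "daily_records.csv"}
        self.table.to_csv(paths["cohort"], index=False)
        self.records_long().to_csv(paths["records"], index=False)
        return paths


def _next_strength(dose: float, levels: Sequence[float]) -> float:
    """Next formulation strength up (doubling past the top of the list)."""
    higher = [d for d in levels if d > dose]
    return min(higher) if higher else dose * 2.0


def _build_record(
    rng: np.random.Generator,
    period: int,
    initial_dose: float,
    dose_levels: Sequence[float],
) -> tuple[list[float], list[int]]:
    """Daily dose/rescue sequences whose extracted titration period is
    exactly ``period`` under the 5-day window rule with rescue_max 3.

    Two mechanisms delay stabilisation: a dose change entering the final
    window (only possible for periods up to 9 days, since earlier windows
    must not exist) or rescue overuse placed every 5 days counting back
    from the last pre-window day, which blocks every earlier window.
    """
    n_days = period + int(rng.integers(3, 8))
    doses = [initial_dose] * n_days
    rescues = list(np.minimum(rng.poisson(1.2, size=n_days), 3).astype(int))

    if period > 5:
        use_dose_change = period <= 9 and rng.random() < 0.5
        if use_dose_change:
            new_dose = _next_strength(initial_dose, dose_levels)
            for i in range(period - 5, n_days):  # day period-4 onwards (0-based)
                doses[i] = new_dose
        else:
            day = period - 5  # 1-based day of the last rescue violation
            while day >= 1:
                rescues[day - 1] = 4 + int(rng.poisson(1.0))
                day -= 5
    return doses, rescues


def simulate_cohort(preset: CohortPreset, seed: int | None = None) -> Cohort:
    """Draw a full virtual cohort with consistent daily records.

    Covariates and comorbidity flags are drawn independently; the binary
    outcome comes from the preset's logistic model; the titration period is
    5 days for the short group and 6 + geometric (capped at 39) for the
    long group, echoing the right-skewed period distribution of the
    reference cohort; daily records are constructed so the window rule
    recovers the drawn period exactly.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    rng = np.random.default_rng(seed)
    n = preset.n

    male = (rng.random(n) < preset.male_fraction).astype(int)
    age = _lognormal_from_median_iqr(rng, preset.age_median, preset.age_iqr, n)
    height = _lognormal_from_median_iqr(rng, preset.height_median, preset.height_iqr, n)
    bmi = _lognormal_from_median_iqr(rng, preset.bmi_median, preset.bmi_iqr, n)
    weight = bmi * (height / 100.0) ** 2
    albumin = _lognormal_from_median_iqr(rng, preset.albumin_median, preset.albumin_iqr, n)
    albumin[rng.random(n) < preset.albumin_missing_rate] = np.nan
    initial_dose = rng.choice(
        preset.initial_dose_levels, size=n, p=preset.initial_dose_probs
    )

    flags = {
        code: (rng.random(n) < prev).astype(int)
        for code, prev in preset.comorbidity_prevalence.items()
    }

    lp = np.full(n, preset.intercept())
    for code, coef in preset.coefficients.items():
        if code in flags:
            lp = lp + coef * flags[code]
    outcome = (rng.random(n) < expit(lp)).astype(int)

    geom = rng.geometric(1.0 - preset.long_tail_continue, size=n)
    periods = np.where(outcome == 1, np.minimum(6 + geom - 1, 39), 5)

    records: dict[str, PatientRecord] = {}
    rows = []
    for i in range(n):
        pid = f"p{i + 1:04d}"
        doses, rescues = _build_record(
            rng, int(periods[i]), float(initial_dose[i]), preset.initial_dose_levels
        )
        covs = {
            "female": float(1 - male[i]),
            "age": float(age[i]),
            "height": float(height[i]),
            "weight": float(weight[i]),
            "bmi": float(bmi[i]),
            "albumin": float(albumin[i]),
            "initial_dose": float(initial_dose[i]),
        }
        records[pid] = PatientRecord(
            patient_id=pid,
            daily_dose=tuple(doses),
            daily_rescue_count=tuple(rescues),
            covariates=covs,
            comorbidity_flags={c: bool(flags[c][i]) for c in flags},
        )
        row = {"patient_id": pid, "male": int(male[i]), **covs}
        row.update({c: int(flags[c][i]) for c in flags})
        row["outcome"] = int(outcome[i])
        row["titration_period"] = int(periods[i])
        rows.append(row)

    return Cohort(preset=preset, seed=seed, table=pd.DataFrame(rows), records=records)
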