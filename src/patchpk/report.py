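"""Stage orchestration and report assembly.

``analyze_rat_group`` chains the PK stages for one strain group — moment
analysis of every IV profile, the group-mean IV AUC, per-animal
bioavailability, the patch-residual decomposition and the flip-flop k_a
fit — into one per-subject table.  ``pk_group_comparison`` summarises two
groups as mean +/- S.D. with an unpaired (Welch by default) t-test per
parameter.  ``run_titration_analysis`` chains the clinical stages: period
extraction, dichotomisation, the univariate screen and the multivariate
adjusted-odds-ratio model.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .bioavailability import PatchResidual, decompose
from .ka_fit import fit_ka
from .nca import ConcentrationTimeProfile, moment_analysis_iv, moment_analysis_td
from .pk_models import Dialect
from .titration import (
    PatientRecord,
    dichotomize,
    multivariate_aor,
    titration_period,
    univariate_screen,
)

__all__ = [
    "analyze_rat_group",
    "pk_group_comparison",
    "run_titration_analysis",
    "replicate_aor_recovery",
    "provenance",
]

#: parameter rows of the PK group summary, in display order
PK_PARAMETERS = [
    "AUC_iv",
    "CL_tot",
    "k_e",
    "Vd_ss",
    "C_max",
    "T_max",
    "AUC_td",
    "CL_tot_over_F",
    "k_a",
    "F_pct",
    "F_a_pct",
    "F_skin_pct",
]


def provenance(seed: int | None, config: Mapping) -> dict:
    """Version, seed and a stable hash of the run configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "tool": "patchpk",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }


def analyze_rat_group(
    iv_profiles: Sequence[ConcentrationTimeProfile],
    td_profiles: Sequence[ConcentrationTimeProfile],
    residuals: Sequence[PatchResidual],
    dialect: Dialect = "full_depot",
    n_terminal: int = 3,
) -> pd.DataFrame:
    """Full PK pipeline for one group; one row per animal.

    IV moment analysis supplies each animal's k_e and Vd_ss and the group
    mean AUC; each animal's transdermal AUC then gives its F against that
    mean; the patch residual gives F_a and F_skin = F / F_a; finally k_a
    is fitted to the transdermal profile with the animal's own IV
    parameters and F held fixed.  Animals are matched across the three
    inputs by subject_id.
    """
    iv_by_id = {p.subject_id: moment_analysis_iv(p, n_terminal=n_terminal) for p in iv_profiles}
    res_by_id = {r.subject_id: r for r in residuals}
    mean_auc_iv = float(np.mean([r.AUC_0_inf for r in iv_by_id.values()]))
    iv_dose = iv_profiles[0].dose.amount

    rows = []
    for td in td_profiles:
        sid = td.subject_id
        if sid not in iv_by_id:
            raise KeyError(f"no IV profile for subject {sid!r}")
        if sid not in res_by_id:
            raise KeyError(f"no patch residual for subject {sid!r}")
        iv = iv_by_id[sid]
        td_res = moment_analysis_td(td, n_terminal=n_terminal)
        bio = decompose(
            auc_td=td_res.AUC_0_inf,
            dose_td=td.dose.amount,
            body_weight=td.body_weight,
            mean_auc_iv=mean_auc_iv,
            dose_iv=iv_dose,
            residual=res_by_id[sid],
            subject_id=sid,
        )
        ka = fit_ka(
            td,
            F=min(bio.F, 1.0),
            k_e=iv.k_e,
            Vd=iv.Vd_ss * td.body_weight,
            dialect=dialect,
        )
        rows.append(
            {
                "subject_id": sid,
                "AUC_iv": iv.AUC_0_inf,
                "CL_tot": iv.CL_tot,
                "k_e": iv.k_e,
                "Vd_ss": iv.Vd_ss,
                "C_max": td_res.C_max,
                "T_max": td_res.T_max,
                "AUC_td": td_res.AUC_0_inf,
                "CL_tot_over_F": td_res.CL_tot_over_F,
                "k_a": ka.k_a,
                "ka_converged": ka.converged,
                "flip_flop": ka.flip_flop,
                "F_pct": 100.0 * bio.F,
                "F_a_pct": 100.0 * bio.F_a,
                "F_skin_pct": 100.0 * bio.F_skin,
            }
        )
    return pd.DataFrame(rows)


def pk_group_comparison(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    label_a: str = "group_a",
    label_b: str = "group_b",
    welch: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean +/- S.D. per parameter and an unpaired t-test between groups.

    Welch's unequal-variance t-test is the default; set ``welch=False``
    for Student's.  ``significant`` flags p < ``alpha``.
    """
    rows = []
    for param in PK_PARAMETERS:
        a = group_a[param].to_numpy(float)
        b = group_b[param].to_numpy(float)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "parameter": param,
                f"{label_a}_mean": a.mean(),
                f"{label_a}_sd": a.std(ddof=1),
                f"{label_b}_mean": b.mean(),
                f"{label_b}_sd": b.std(ddof=1),
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)


def run_titration_analysis(
    cohort: pd.DataFrame,
    records: Mapping[str, PatientRecord],
    stability_days: int = 5,
    rescue_max: int = 3,
    alpha_screen: float = 0.1,
    seed: int | None = None,
) -> dict:
    """Clinical arm end to end; returns a JSON-serialisable report.

    The titration period is extracted from each patient's daily record,
    dichotomised at 6 days or more, screened factor by factor with
    univariate logistic regression at p < ``alpha_screen``, and the
    surviving factors are refitted jointly for adjusted odds ratios.
    """
    outcomes = []
    order = cohort["patient_id"].astype(str).tolist()
    for pid in order:
        if pid not in records:
            raise KeyError(f"no daily record for patient {pid!r}")
        outcomes.append(
            titration_period(records[pid], stability_days=stability_days, rescue_max=rescue_max)
        )
    censored_ids = [pid for pid, o in zip(order, outcomes) if o.censored]
    y, n_censored = dichotomize(outcomes, cutoff=stability_days)
    analysed = cohort[~cohort["patient_id"].astype(str).isin(censored_ids)].reset_index(
        drop=True
    )

    uni_results, selected = univariate_screen(analysed, y, alpha_screen=alpha_screen)
    multi_results = multivariate_aor(analysed, y, selected) if selected else []

    periods = [o.titration_period for o in outcomes if not o.censored]
    report = {
        "provenance": provenance(
            seed,
            {
                "stability_days": stability_days,
                "rescue_max": rescue_max,
                "alpha_screen": alpha_screen,
                "n_patients": len(order),
            },
        ),
        "n_patients": len(order),
        "n_censored": n_censored,
        "n_within_5": int(np.sum(y == 0)),
        "n_six_or_more": int(np.sum(y == 1)),
        "titration_period_range": [int(min(periods)), int(max(periods))] if periods else None,
        "selected_factors": selected,
        "univariate": [asdict(r) for r in uni_results],
        "multivariate": [asdict(r) for r in multi_results],
    }
    return _sanitize(report)


def replicate_aor_recovery(
    preset,
    factor: str = "E14",
    n_replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Parameter-recovery experiment for one adjusted odds ratio.

    Generates ``n_replicates`` cohorts under ``preset`` (a
    :class:`~patchpk.simulate.CohortPreset`), fits the multivariate
    logistic model over all factors with a non-zero preset coefficient —
    ``factor`` always included — and collects the recovered AOR, its Wald
    coefficient and standard error per replicate.  Replicates in which a
    rare indicator separates are refitted without the offending factors
    (``factor`` is never dropped); the refit is recorded in ``refitted``.

    Returns a DataFrame with one row per replicate, suitable for checking
    estimator bias (geometric-mean AOR vs the generating value) and Wald
    confidence-interval coverage.
    """
    from .simulate import simulate_cohort

    active = [c for c in preset.codes if preset.coefficients.get(c, 0.0) != 0.0]
    if factor not in active:
        raise ValueError(f"{factor!r} has no non-zero coefficient in the preset")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(preset, seed=rep_seed)
        y = cohort.table["outcome"].to_numpy()
        results = multivariate_aor(cohort.table, y, active)
        by_factor = {r.factor: r for r in results}
        refitted = any(r.flagged and r.factor != factor for r in results)
        if refitted:
            keep = [f for f in active if f == factor or not by_factor[f].flagged]
            results = multivariate_aor(cohort.table, y, keep)
            by_factor = {r.factor: r for r in results}
        r = by_factor[factor]
        rows.append(
            {
                "replicate": rep,
                "seed": rep_seed,
                "aor": r.odds_ratio,
                "coef": r.coef,
                "se": r.se,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "flagged": r.flagged,
                "refitted": refitted,
            }
        )
    return pd.DataFrame(rows)


def _sanitize(obj):
    """Replace NaN/inf with None so the report round-trips as strict JSON."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return float(obj) if math.isfinite(obj) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
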