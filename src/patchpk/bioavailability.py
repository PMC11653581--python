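"""Transdermal bioavailability and its decomposition.

Overall bioavailability F (dose-corrected AUC ratio against the mean IV
AUC) factors into the fraction released from the patch into the stratum
corneum, F_a = (X_unused - X_used) / X_unused measured from residual patch
content, and the fraction of released drug absorbed through the skin,
F_skin = F / F_a.  The two factors localise where transdermal absorption
is altered: patch-to-skin partitioning versus permeation through skin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "PatchResidual",
    "BioavailabilityResult",
    "transdermal_F",
    "release_ratio",
    "skin_availability",
    "decompose",
    "read_patch_residuals_csv",
]


@dataclass(frozen=True)
class PatchResidual:
    """Fentanyl content (µg) of the unused patch and the removed patch."""

    X_unused: float
    X_used: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.X_unused > 0:
            raise ValueError("X_unused must be positive")
        if self.X_used < 0:
            raise ValueError("X_used cannot be negative")
        if self.X_used > self.X_unused:
            raise ValueError(
                f"assay inconsistency: X_used ({self.X_used}) exceeds "
                f"X_unused ({self.X_unused})"
            )


@dataclass(frozen=True)
class BioavailabilityResult:
    F: float
    F_a: float
    F_skin: float
    subject_id: str = ""


def transdermal_F(
    auc_td: float,
    dose_td: float,
    body_weight: float,
    mean_auc_iv: float,
    dose_iv: float,
) -> float:
    """Bioavailability from the dose-corrected AUC ratio.

    F = (AUC_td / (dose_td / body_weight)) / (mean_AUC_iv / dose_iv),
    with AUCs in ng·hr/mL, the transdermal dose in total µg (converted to
    per-kg with the subject's body weight) and the IV dose in µg/kg.  Each
    subject's own transdermal AUC is divided by the *group-mean* IV AUC.

    A value above 1 is physically impossible and is returned as-is with a
    warning, never clamped.
    """
    for name, v in (
        ("auc_td", auc_td),
        ("dose_td", dose_td),
        ("body_weight", body_weight),
        ("mean_auc_iv", mean_auc_iv),
        ("dose_iv", dose_iv),
    ):
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    f = (auc_td / (dose_td / body_weight)) / (mean_auc_iv / dose_iv)
    if f > 1:
        warnings.warn(
            f"computed F = {f:.3f} > 1 is physically impossible; "
            "check AUCs and doses",
            stacklevel=2,
        )
    return f


def release_ratio(residual: PatchResidual) -> float:
    """Fraction released from the formulation: (X_unused - X_used)/X_unused."""
    return (residual.X_unused - residual.X_used) / residual.X_unused


def skin_availability(F: float, F_a: float) -> float:
    """Fraction of released drug absorbed through the skin: F / F_a."""
    if F < 0:
        raise ValueError("F cannot be negative")
    if not F_a > 0:
        raise ValueError("F_skin is undefined when nothing was released (F_a = 0)")
    return F / F_a


def decompose(
    auc_td: float,
    dose_td: float,
    body_weight: float,
    mean_auc_iv: float,
    dose_iv: float,
    residual: PatchResidual,
    subject_id: str = "",
) -> BioavailabilityResult:
    """Full per-subject decomposition F = F_a x F_skin."""
    f = transdermal_F(auc_td, dose_td, body_weight, mean_auc_iv, dose_iv)
    fa = release_ratio(residual)
    return BioavailabilityResult(
        F=f, F_a=fa, F_skin=skin_availability(f, fa), subject_id=subject_id
    )


def read_patch_residuals_csv(path: str | Path) -> list[PatchResidual]:
    """Read a patch-assay table: subject_id, x_unused_ug, x_used_ug."""
    df = pd.read_csv(path)
    missing = {"subject_id", "x_unused_ug", "x_used_ug"} - set(df.columns)
    if missing:
        raise ValueError(f"patch residual CSV missing columns: {sorted(missing)}")
    return [
        PatchResidual(
            X_unused=float(r.x_unused_ug),
            X_used=float(r.x_used_ug),
            subject_id=str(r.subject_id),
        )
        for r in df.itertuples()
    ]
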