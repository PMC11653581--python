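"""Closed-form one-compartment pharmacokinetic models.

Two model curves are provided:

* an IV-bolus mono-exponential, used for the intravenous arm, and
* the Bateman function for first-order absorption from a depot (here a
  transdermal patch), used for the transdermal arm.

Transdermal fentanyl exhibits *flip-flop* kinetics: absorption through the
stratum corneum is much slower than systemic elimination (``k_a < k_e``),
so the apparent terminal half-life of the plasma curve reflects absorption,
not elimination.

Units are fixed throughout the package: time in hours, concentration in
ng/mL, rate constants in 1/hr, volumes in L (or L/kg where noted).  Because
µg/L is numerically identical to ng/mL, dose in µg divided by volume in L
yields ng/mL without any conversion factor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "PKParameters",
    "DoseEvent",
    "iv_bolus_concentration",
    "bateman_concentration",
    "bateman_tmax",
]

Route = Literal["iv_bolus", "transdermal"]
Dialect = Literal["full_depot", "truncated_input"]

#: relative threshold below which k_a and k_e are treated as equal and the
#: analytic limit of the Bateman function is used instead of the generic form
KA_KE_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class PKParameters:
    """One-compartment parameter set for a single subject.

    ``CL_tot``, ``k_e`` and ``Vd_ss`` are redundant (``CL = k_e * Vd``) but
    in practice come from different estimators — the terminal slope for
    ``k_e``, moment analysis for ``Vd_ss`` — so exact equality cannot be
    demanded.  When all three are present they are checked for mutual
    consistency within ``consistency_tol`` (relative, default 20%).

    Parameters
    ----------
    k_a : float or None
        First-order absorption rate constant, 1/hr.
    k_e : float or None
        First-order elimination rate constant, 1/hr.
    Vd_ss : float or None
        Volume of distribution at steady state, L/kg.
    CL_tot : float or None
        Systemic clearance, L/hr/kg.
    F : float or None
        Transdermal bioavailability as a fraction in (0, 1].
    body_weight : float or None
        Body weight, kg.
    """

    k_a: float | None = None
    k_e: float | None = None
    Vd_ss: float | None = None
    CL_tot: float | None = None
    F: float | None = None
    body_weight: float | None = None
    consistency_tol: float = 0.20

    def __post_init__(self) -> None:
        for name in ("k_a", "k_e", "Vd_ss", "CL_tot", "body_weight"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.F is not None and not (0 < self.F <= 1):
            raise ValueError(f"F must lie in (0, 1], got {self.F!r}")
        if self.k_e is not None and self.Vd_ss is not None and self.CL_tot is not None:
            implied = self.CL_tot / self.Vd_ss
            if abs(implied - self.k_e) > self.consistency_tol * self.k_e:
                raise ValueError(
                    "inconsistent parameter set: CL_tot/Vd_ss = "
                    f"{implied:.4g} /hr vs k_e = {self.k_e:.4g} /hr "
                    f"(tolerance {self.consistency_tol:.0%})"
                )


@dataclass(frozen=True)
class DoseEvent:
    """A single administration event.

    ``amount`` is in µg/kg for IV boluses (the rat protocol doses per body
    weight) and in total µg for transdermal application.  ``removal_time``
    applies to transdermal patches only.
    """

    route: Route
    amount: float
    application_time: float = 0.0
    removal_time: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ("iv_bolus", "transdermal"):
            raise ValueError(f"unknown route {self.route!r}")
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")
        if self.removal_time is not None:
            if self.route != "transdermal":
                raise ValueError("removal_time only applies to transdermal doses")
            if not self.removal_time > self.application_time:
                raise ValueError("removal_time must exceed application_time")


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def iv_bolus_concentration(t, dose: float, k_e: float, Vd: float):
    """Concentration after an IV bolus: ``C(t) = (dose / Vd) * exp(-k_e t)``.

    Parameters
    ----------
    t : array_like
        Time since the bolus, hr.  Must be >= 0.
    dose : float
        Dose in µg/kg.
    k_e : float
        Elimination rate constant, 1/hr.
    Vd : float
        Volume of distribution, L/kg.

    Returns
    -------
    ndarray or float
        Concentration in ng/mL (µg/kg over L/kg is µg/L = ng/mL).
    """
    _check_positive(dose=dose, k_e=k_e, Vd=Vd)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return (dose / Vd) * np.exp(-k_e * t)


def bateman_concentration(
    t,
    dose: float,
    F: float,
    k_a: float,
    k_e: float,
    Vd: float,
    removal_time: float | None = None,
    dialect: Dialect = "full_depot",
):
    """Concentration after first-order absorption from a depot.

    The default ``full_depot`` dialect treats the whole absorbable amount
    ``F * dose`` as a first-order depot for all time and ignores
    ``removal_time`` — the bioavailability ``F`` already accounts for drug
    left in the removed patch.  The ``truncated_input`` dialect stops the
    absorption input at ``removal_time`` and propagates a pure elimination
    solution from the state at removal.

    Parameters
    ----------
    t : array_like
        Time since application, hr.
    dose : float
        Applied amount, µg.
    F : float
        Bioavailable fraction (0, 1].
    k_a, k_e : float
        Absorption and elimination rate constants, 1/hr.
    Vd : float
        Volume of distribution in L (absolute, not per kg — the dose here
        is a total amount).
    removal_time : float, optional
        Patch removal time, hr.  Only used by ``truncated_input``.
    dialect : {"full_depot", "truncated_input"}

    Returns
    -------
    ndarray or float
        Concentration in ng/mL.

    Notes
    -----
    When ``|k_a - k_e|`` is below ``KA_KE_DEGENERACY_RTOL * max(k_a, k_e)``
    the removable singularity is handled with the analytic limit
    ``C(t) = F D k t exp(-k t) / Vd``.
    """
    _check_positive(dose=dose, k_a=k_a, k_e=k_e, Vd=Vd)
    if not (0 < F <= 1):
        raise ValueError(f"F must lie in (0, 1], got {F!r}")
    if dialect not in ("full_depot", "truncated_input"):
        raise ValueError(f"unknown dialect {dialect!r}")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")

    c = _bateman_raw(t, dose * F, k_a, k_e, Vd)

    if dialect == "truncated_input" and removal_time is not None:
        t_r = float(removal_time)
        c_r = float(_bateman_raw(np.array([t_r]), dose * F, k_a, k_e, Vd)[0])
        after = t > t_r
        c[after] = c_r * np.exp(-k_e * (t[after] - t_r))

    return float(c[0]) if scalar else c


def _bateman_raw(t: np.ndarray, amount: float, k_a: float, k_e: float, Vd: float) -> np.ndarray:
    if abs(k_a - k_e) < KA_KE_DEGENERACY_RTOL * max(k_a, k_e):
        k = 0.5 * (k_a + k_e)
        return amount * k * t * np.exp(-k * t) / Vd
    return (
        amount
        * k_a
        / (Vd * (k_a - k_e))
        * (np.exp(-k_e * t) - np.exp(-k_a * t))
    )


def bateman_tmax(k_a: float, k_e: float) -> float:
    """Time of the Bateman-curve maximum: ``ln(k_a/k_e) / (k_a - k_e)``.

    Symmetric in its arguments (the flip-flop ambiguity); returns ``1/k``
    in the degenerate limit ``k_a == k_e == k``.
    """
    _check_positive(k_a=k_a, k_e=k_e)
    if abs(k_a - k_e) < KA_KE_DEGENERACY_RTOL * max(k_a, k_e):
        return 2.0 / (k_a + k_e)
    return math.log(k_a / k_e) / (k_a - k_e)
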