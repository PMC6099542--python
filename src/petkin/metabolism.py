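"""Parent-fraction (radiometabolite) modelling and TAC metabolite correction.

The tracer is metabolized quickly in plasma and slowly in brain; only the
intact (parent) compound follows the compartmental kinetics, so both the
plasma input function and the brain time-activity curves must be rescaled
by the fraction of activity that is still parent compound at each time.

The parent fraction is modelled with an integrated Hill curve

    PF(t) = 1 - a * t^n / (t^n + t50^n)

which is monotone non-increasing, satisfies PF(0) = 1 exactly, and decays
towards the asymptotic metabolized fraction ``a``.  The functional form is
a package design choice (standard in PET metabolite modelling); its three
parameters are calibrated to measured (time, fraction) points.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    CompartmentMismatchError,
    DomainError,
    FitError,
    InsufficientDataError,
)
from .schedule import TimeActivityCurve

__all__ = [
    "ParentFractionModel",
    "pf_evaluate",
    "pf_calibrate",
    "parent_fraction_from_counts",
    "correct_tac_for_metabolites",
    "default_plasma_pf_model",
    "default_brain_pf_model",
    "PLASMA_CALIBRATION_POINTS",
    "BRAIN_CALIBRATION_POINTS",
]

#: Measured plasma parent fractions: 85% at 15 min, 60% at 30 min, 35% at 120 min.
PLASMA_CALIBRATION_POINTS = ((15.0, 0.85), (30.0, 0.60), (120.0, 0.35))
#: Measured brain parent fractions: 96% at 15 min, 77% at 120 min.
BRAIN_CALIBRATION_POINTS = ((15.0, 0.96), (120.0, 0.77))

_COMPARTMENTS = ("plasma", "brain")


@dataclass(frozen=True)
class ParentFractionModel:
    """Hill-form unmetabolized fraction PF(t) for one compartment."""

    compartment: str           # "plasma" or "brain"
    a: float                   # asymptotic metabolized fraction, in [0, 1]
    t50: float                 # half-metabolism time of the Hill term, minutes
    n: float                   # Hill exponent
    calibration_residuals: tuple = ()

    def __post_init__(self):
        if self.compartment not in _COMPARTMENTS:
            raise DomainError(f"compartment must be one of {_COMPARTMENTS}")
        if not 0.0 <= self.a <= 1.0:
            raise DomainError("asymptotic metabolized fraction a must be in [0, 1]")
        if self.t50 <= 0 or self.n <= 0:
            raise DomainError("t50 and Hill exponent n must be positive")

    def __call__(self, t):
        return pf_evaluate(self, t)


def pf_evaluate(model: ParentFractionModel, t):
    """Evaluate PF(t) = 1 - a*t^n/(t^n + t50^n) at times ``t`` (minutes)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("parent fraction is undefined for negative times")
    tn = np.power(t, model.n)
    pf = 1.0 - model.a * tn / (tn + model.t50**model.n)
    return float(pf) if pf.ndim == 0 else pf


def pf_calibrate(points, compartment: str) -> ParentFractionModel:
    """Least-squares calibration of (a, t50, n) to measured fraction points.

    With exactly two points the Hill exponent is fixed at n = 2 so the
    two remaining parameters are determined.
    """
    pts = sorted((float(t), float(f)) for t, f in points)
    if len(pts) < 2:
        raise InsufficientDataError("parent-fraction calibration needs at least 2 points")
    t = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    if np.any(t <= 0):
        raise DomainError("calibration times must be positive")
    if np.any((f <= 0) | (f > 1)):
        raise DomainError("calibration fractions must be in (0, 1]")

    fix_n = len(pts) == 2

    def resid(x):
        if fix_n:
            a, log_t50 = x
            n = 2.0
        else:
            a, log_t50, log_n = x
            n = np.exp(log_n)
        t50 = np.exp(log_t50)
        tn = np.power(t, n)
        return (1.0 - a * tn / (tn + t50**n)) - f

    x0 = [min(max(1.0 - f[-1], 0.05), 0.95), np.log(np.median(t))]
    bounds_lo = [0.0, np.log(1e-3)]
    bounds_hi = [1.0, np.log(1e4)]
    if not fix_n:
        x0.append(np.log(1.5))
        bounds_lo.append(np.log(0.1))
        bounds_hi.append(np.log(10.0))
    res = least_squares(resid, x0, bounds=(bounds_lo, bounds_hi), xtol=1e-14, ftol=1e-14)
    if not res.success:
        raise FitError(f"parent-fraction calibration did not converge: {res.message}")
    a = float(res.x[0])
    t50 = float(np.exp(res.x[1]))
    n = 2.0 if fix_n else float(np.exp(res.x[2]))
    return ParentFractionModel(
        compartment=compartment,
        a=a,
        t50=t50,
        n=n,
        calibration_residuals=tuple(float(r) for r in res.fun),
    )


def parent_fraction_from_counts(parent_peak: float, metabolite_peak: float) -> float:
    """Parent fraction from chromatogram peak activities."""
    if parent_peak < 0 or metabolite_peak < 0:
        raise DomainError("peak activities must be non-negative")
    total = parent_peak + metabolite_peak
    if total == 0:
        raise DomainError("parent fraction undefined: both peak activities are zero")
    return parent_peak / total


def correct_tac_for_metabolites(
    tac: TimeActivityCurve, brain_pf: ParentFractionModel
) -> TimeActivityCurve:
    """Rescale a measured brain TAC to the unmetabolized-tracer TAC.

    Each frame is multiplied by the brain parent fraction at the frame
    mid-time; the result is tagged metabolite-corrected.
    """
    if brain_pf.compartment != "brain":
        raise CompartmentMismatchError(
            f"brain TAC correction requires a brain parent-fraction model, "
            f"got {brain_pf.compartment!r}"
        )
    pf = pf_evaluate(brain_pf, tac.schedule.mid)
    return tac.with_values(tac.value * pf, metabolite_corrected=True)


@lru_cache(maxsize=None)
def default_plasma_pf_model() -> ParentFractionModel:
    """Plasma parent-fraction model calibrated to the measured plasma points."""
    return pf_calibrate(PLASMA_CALIBRATION_POINTS, "plasma")


@lru_cache(maxsize=None)
def default_brain_pf_model() -> ParentFractionModel:
    """Brain parent-fraction model calibrated to the measured brain points."""
    return pf_calibrate(BRAIN_CALIBRATION_POINTS, "brain")
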