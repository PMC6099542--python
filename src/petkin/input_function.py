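"""Metabolite-corrected arterial input function construction.

The continuous-time parent-plasma concentration Ca(t) driving the kinetic
model is built from discrete plasma samples: each total-plasma sample is
multiplied by the plasma parent fraction at its time, the curve is
interpolated piecewise-linearly between knots, and extrapolated beyond the
last knot by a mono-exponential tail fitted to the last three knots.
The whole-blood curve Cwb(t) (vascular term input) uses the same knots;
whole blood is taken equal to total plasma unless a blood-to-plasma ratio
is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    CompartmentMismatchError,
    DomainError,
    InsufficientDataError,
    ValidationError,
)
from .metabolism import ParentFractionModel, pf_evaluate
from .schedule import PlasmaSampleSeries

logger = logging.getLogger(__name__)

__all__ = ["InputFunction", "build_aif", "aif_value"]

#: Fallback tail rate (min^-1) when the tail cannot be estimated (flat or
#: all-zero late samples); effectively a constant tail, logged as a warning.
_FALLBACK_TAIL_LAMBDA = 1e-6


@dataclass(frozen=True)
class InputFunction:
    """Continuous-time input curves defined by knots + exponential tail."""

    knot_time: np.ndarray      # minutes, strictly increasing, starts at 0
    parent_plasma: np.ndarray  # metabolite-corrected parent concentration Ca
    total_blood: np.ndarray    # whole-blood concentration Cwb
    tail_lambda: float         # min^-1, mono-exponential extrapolation rate

    def __post_init__(self):
        t = np.asarray(self.knot_time, dtype=float)
        ca = np.asarray(self.parent_plasma, dtype=float)
        cwb = np.asarray(self.total_blood, dtype=float)
        for name, arr in (("knot_time", t), ("parent_plasma", ca), ("total_blood", cwb)):
            object.__setattr__(self, name, arr)
        if t.ndim != 1 or t.shape != ca.shape or t.shape != cwb.shape:
            raise ValidationError("knot arrays must be equal-length 1-D arrays")
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("knots must start at 0 and be strictly increasing")
        if np.any(ca < 0) or np.any(cwb < 0):
            raise ValidationError("input-function concentrations must be non-negative")
        if np.any(ca > cwb * (1 + 1e-12) + 1e-15):
            raise ValidationError("parent plasma cannot exceed total blood at any knot")
        if not self.tail_lambda > 0:
            raise ValidationError("tail_lambda must be positive")

    def _interp(self, t, values):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise DomainError("input function is undefined for negative times")
        out = np.interp(t, self.knot_time, values)
        t_last = self.knot_time[-1]
        beyond = t > t_last
        if np.any(beyond):
            out = np.where(
                beyond, values[-1] * np.exp(-self.tail_lambda * (t - t_last)), out
            )
        return float(out) if out.ndim == 0 else out

    def parent(self, t):
        """Metabolite-corrected parent-plasma concentration Ca(t)."""
        return self._interp(t, self.parent_plasma)

    def whole_blood(self, t):
        """Whole-blood concentration Cwb(t)."""
        return self._interp(t, self.total_blood)


def build_aif(
    samples: PlasmaSampleSeries,
    pf: ParentFractionModel,
    blood_to_plasma: float = 1.0,
) -> InputFunction:
    """Construct the input function from plasma samples and a plasma PF model.

    A (0, 0) knot is inserted when the first sample is later than t = 0;
    the tail rate is a log-linear regression on the last three parent knots.
    """
    if pf.compartment != "plasma":
        raise CompartmentMismatchError(
            f"input-function correction requires a plasma parent-fraction model, "
            f"got {pf.compartment!r}"
        )
    if samples.n_samples < 3:
        raise InsufficientDataError(
            "at least 3 plasma samples are needed to estimate the input-function tail"
        )
    t = samples.sample_time
    total = samples.total_plasma
    parent = total * pf_evaluate(pf, t)
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        parent = np.concatenate([[0.0], parent])
        total = np.concatenate([[0.0], total])

    tail_t, tail_c = t[-3:], parent[-3:]
    if np.all(tail_c > 0):
        slope = np.polyfit(tail_t, np.log(tail_c), 1)[0]
        if slope < 0:
            tail_lambda = -float(slope)
        else:
            logger.warning("non-decaying input-function tail; using flat extrapolation")
            tail_lambda = _FALLBACK_TAIL_LAMBDA
    else:
        logger.warning(
            "zero parent activity in the last samples; input-function tail not estimable"
        )
        tail_lambda = _FALLBACK_TAIL_LAMBDA

    return InputFunction(
        knot_time=t,
        parent_plasma=parent,
        total_blood=total * blood_to_plasma,
        tail_lambda=tail_lambda,
    )


def aif_value(aif: InputFunction, t):
    """Parent-plasma concentration Ca(t) (vectorized over ``t``)."""
    return aif.parent(t)
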