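"""Two-tissue-compartment + vascular-trapping forward model.

Tissue kinetics follow the reversible two-tissue compartment model

    dC_ND/dt = K1*Ca - (k2 + k3)*C_ND + k4*C_S
    dC_S/dt  = k3*C_ND - k4*C_S

whose impulse response is a sum of two exponentials with eigenrates

    alpha_{1,2} = [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4*k2*k4)] / 2.

On top of the tissue signal, a vascular-trapping term represents slow
irreversible binding of the tracer to TSPO on the vascular endothelium:
an irreversible compartment fed from whole blood at rate Kb, weighted by
the blood volume fraction vB alongside the whole-blood signal itself:

    C_model(t) = (1 - vB) * (h (*) Ca)(t) + vB * (Cwb(t) + Kb * int_0^t Cwb ds)

The model is evaluated on a fine uniform grid (default step 0.5 s) and
averaged over each acquisition frame, since the earliest frames are 5 s
and the input peak is sharp.  The exponential convolutions are computed
with an analytic piecewise-linear recursion (exact for piecewise-linear
inputs), implemented as a first-order IIR filter.

Macroparameters: total distribution volume VT = (K1/k2)*(1 + k3/k4)
(the irreversible Kb pathway is excluded) and BPND = k3/k4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .errors import DegenerateModelError, DomainError, UndefinedMacroparameterError
from .input_function import InputFunction
from .schedule import FrameSchedule, TimeActivityCurve

logger = logging.getLogger(__name__)

__all__ = [
    "KineticParameters",
    "Macroparameters",
    "impulse_response",
    "macroparameters",
    "model_tac",
    "TacModel",
]

#: Default convolution grid step: 0.5 s (1/120 min).  Divides every frame
#: duration and sampling knot, so frame boundaries and input-curve kinks lie
#: exactly on the grid, and gives 10 points per 5-s frame.
DEFAULT_DT = 1.0 / 120.0

#: Default cerebral blood volume fraction (not estimated by default).
DEFAULT_VB = 0.05

# relative eigenrate separation below which the confluent form is used
_CONFLUENT_RTOL = 1e-9


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants of the 2-tissue + vascular-trapping model.

    K1 in mL·cm^-3·min^-1; k2, k3, k4, Kb in min^-1; vB unitless in [0, 0.2].
    """

    K1: float
    k2: float
    k3: float
    k4: float
    Kb: float
    vB: float = DEFAULT_VB

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4", "Kb"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise DomainError(f"{name} must be finite and non-negative, got {v}")
        if not 0.0 <= self.vB <= 0.2:
            raise DomainError(f"vB must be in [0, 0.2], got {self.vB}")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.Kb])


@dataclass(frozen=True)
class Macroparameters:
    """VT (mL·cm^-3) and BPND (= k3/k4, unitless)."""

    VT: float
    BPND: float


def impulse_response(p: KineticParameters):
    """Eigenrates and amplitudes of the reversible-tissue impulse response.

    Returns (alpha1, alpha2, A1, A2) such that h(t) = A1*exp(-alpha1*t)
    + A2*exp(-alpha2*t); in the confluent case alpha1 == alpha2 the
    response is h(t) = A1*exp(-alpha*t) + A2*t*exp(-alpha*t).
    """
    s = p.k2 + p.k3 + p.k4
    if s == 0:
        raise DegenerateModelError("k2 + k3 + k4 must be positive")
    disc = s * s - 4.0 * p.k2 * p.k4  # = (k2-k4)^2 + k3^2 + 2 k3 (k2+k4) >= 0
    root = math.sqrt(max(disc, 0.0))
    alpha1 = (s - root) / 2.0
    alpha2 = (s + root) / 2.0
    if root > _CONFLUENT_RTOL * max(alpha2, 1e-300):
        A1 = p.K1 * (p.k3 + p.k4 - alpha1) / (alpha2 - alpha1)
        A2 = p.K1 * (alpha2 - p.k3 - p.k4) / (alpha2 - alpha1)
    else:
        alpha = s / 2.0
        alpha1 = alpha2 = alpha
        A1 = p.K1
        A2 = p.K1 * (p.k3 + p.k4 - alpha)
    return alpha1, alpha2, A1, A2


def macroparameters(p: KineticParameters) -> Macroparameters:
    """VT = (K1/k2)(1 + k3/k4) and BPND = k3/k4 (Kb pathway excluded)."""
    if p.k2 == 0 or p.k4 == 0:
        raise UndefinedMacroparameterError("VT and BPND require k2 > 0 and k4 > 0")
    bpnd = p.k3 / p.k4
    return Macroparameters(VT=(p.K1 / p.k2) * (1.0 + bpnd), BPND=bpnd)


def exp_conv(alpha: float, f: np.ndarray, dt: float) -> np.ndarray:
    """y(t_i) = int_0^{t_i} exp(-alpha (t_i - s)) f(s) ds on a uniform grid.

    Exact for piecewise-linear f; evaluated by a first-order recursion
    y[i+1] = E*y[i] + b0*f[i+1] + b1*f[i] with analytically derived taps.
    """
    f = np.asarray(f, dtype=float)
    x = alpha * dt
    if x < 1e-4:
        # series expansions, stable for small alpha*dt (exact at alpha = 0)
        h0 = dt * (1.0 - x / 2.0 + x * x / 6.0)
        G = dt * dt * (0.5 - x / 6.0 + x * x / 24.0)
    else:
        E = math.exp(-x)
        h0 = (1.0 - E) / alpha
        G = dt * h0 - (1.0 - E * (1.0 + x)) / (alpha * alpha)
    E = math.exp(-x)
    b0 = G / dt
    b1 = h0 - b0
    y = lfilter([b0, b1], [1.0, -E], f)
    # lfilter assumes y[0] = b0*f[0]; the true initial condition is y[0] = 0
    if f[0] != 0.0:
        y = y - (b0 * f[0]) * np.exp(-alpha * dt * np.arange(f.size))
    else:
        y[0] = 0.0
    return y


def _double_integral(f: np.ndarray, F: np.ndarray, dt: float) -> np.ndarray:
    """Exact second cumulative integral of a piecewise-linear f on a uniform grid."""
    step = F[:-1] * dt + f[:-1] * dt * dt / 2.0 + np.diff(f) * dt * dt / 6.0
    out = np.empty_like(f)
    out[0] = 0.0
    np.cumsum(step, out=out[1:])
    return out


class TacModel:
    """Forward model bound to one input function + frame schedule.

    Precomputes the fine-grid input samples so repeated evaluation (as in
    iterative fitting) only pays for the convolutions.  Frame averages are
    computed from analytic cumulative integrals of the exponential
    convolutions (each conv y obeys y' = f - alpha*y, so its running
    integral is (F - y)/alpha with F the exact integral of the
    piecewise-linear input), not by quadrature of the model curve.
    """

    def __init__(self, aif: InputFunction, schedule: FrameSchedule, dt: float = DEFAULT_DT):
        if schedule.end > 10.0 * aif.knot_time[-1]:
            logger.warning(
                "frame schedule extends far beyond the last input-function knot "
                "(%.1f min vs %.1f min); model relies on tail extrapolation",
                schedule.end,
                aif.knot_time[-1],
            )
        self.schedule = schedule
        self.dt = float(dt)
        n = int(round(schedule.end / self.dt))
        self.t = np.linspace(0.0, n * self.dt, n + 1)
        if self.t[-1] < schedule.end - 1e-12:
            self.t = np.append(self.t, schedule.end)
        self.ca = aif.parent(self.t)
        self.cwb = aif.whole_blood(self.t)
        # exact single/double cumulative integrals of the (piecewise-linear) inputs
        self.ca_int = cumulative_trapezoid(self.ca, self.t, initial=0.0)
        self.ca_int2 = _double_integral(self.ca, self.ca_int, self.dt)
        self.cwb_int = cumulative_trapezoid(self.cwb, self.t, initial=0.0)
        self.cwb_int2 = _double_integral(self.cwb, self.cwb_int, self.dt)

    def _tissue(self, p: KineticParameters):
        """Reversible-tissue curve and its exact running integral."""
        s = p.k2 + p.k3 + p.k4
        if s == 0:
            # both tissue compartments only fill: h(t) = K1 (pure integrator)
            return p.K1 * self.ca_int, p.K1 * self.ca_int2
        a1, a2, A1, A2 = impulse_response(p)
        if a1 != a2:
            tissue = np.zeros_like(self.t)
            integral = np.zeros_like(self.t)
            for A, alpha in ((A1, a1), (A2, a2)):
                if A == 0.0:
                    continue
                if alpha == 0.0:  # k4 = 0: one eigenrate collapses to an integrator
                    tissue += A * self.ca_int
                    integral += A * self.ca_int2
                else:
                    y = exp_conv(alpha, self.ca, self.dt)
                    tissue += A * y
                    integral += A * (self.ca_int - y) / alpha
            return tissue, integral
        # confluent (alpha1 == alpha2 == alpha > 0; alpha = 0 implies s = 0)
        alpha = a1
        y1 = exp_conv(alpha, self.ca, self.dt)
        Y1 = (self.ca_int - y1) / alpha
        y2 = self.t * y1 - exp_conv(alpha, self.t * self.ca, self.dt)
        Y2 = (Y1 - y2) / alpha
        return A1 * y1 + A2 * y2, A1 * Y1 + A2 * Y2

    def continuous(self, p: KineticParameters) -> np.ndarray:
        """Model concentration on the fine grid."""
        tissue, _ = self._tissue(p)
        return (1.0 - p.vB) * tissue + p.vB * (self.cwb + p.Kb * self.cwb_int)

    def frame_values(self, p: KineticParameters) -> np.ndarray:
        """Frame-averaged model values (one per frame)."""
        tissue, tissue_int = self._tissue(p)
        running = (1.0 - p.vB) * tissue_int + p.vB * (
            self.cwb_int + p.Kb * self.cwb_int2
        )
        lo = np.interp(self.schedule.start, self.t, running)
        hi = np.interp(self.schedule.start + self.schedule.duration, self.t, running)
        return (hi - lo) / self.schedule.duration


def model_tac(
    p: KineticParameters,
    aif: InputFunction,
    schedule: FrameSchedule,
    dt: float = DEFAULT_DT,
    region: str = "whole brain",
    subject_id: str = "",
    unit: str = "%ID/g",
) -> TimeActivityCurve:
    """Predict the frame-averaged tissue TAC for parameters ``p``."""
    model = TacModel(aif, schedule, dt=dt)
    return TimeActivityCurve(
        schedule=schedule,
        value=model.frame_values(p),
        region=region,
        subject_id=subject_id,
        unit=unit,
        metabolite_corrected=True,
    )
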