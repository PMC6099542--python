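"""Weighted nonlinear least-squares estimation of kinetic parameters.

Each subject's metabolite-corrected TAC is fitted with the 2-tissue +
vascular-trapping model by minimizing

    sum_i w_i * (y_i - C_model(t_i))^2

over (K1, k2, k3, k4, Kb), each bounded to [0, 10]; the blood volume
fraction vB is held fixed (it is poorly identifiable jointly with Kb).
Frame weights default to normalized frame durations, a proxy for the
count-statistics precision of each frame.

Per-parameter standard errors come from the scaled inverse Gauss-Newton
Hessian, se^2 = diag[(J^T W J)^-1] * wrss / (N - p); the %SE (100*se/|est|)
feeds the quality-filtering rule: a subject is excluded when any parameter
has %SE above the threshold (default 50%) or the fit did not converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .errors import DomainError, InsufficientDataError
from .input_function import InputFunction
from .kinetics import (
    DEFAULT_DT,
    DEFAULT_VB,
    KineticParameters,
    Macroparameters,
    TacModel,
    macroparameters,
)
from .schedule import TimeActivityCurve

__all__ = ["KineticFit", "fit_tac", "apply_exclusion", "ExclusionResult", "PARAM_NAMES"]

PARAM_NAMES = ("K1", "k2", "k3", "k4", "Kb")

#: Deterministic multi-start values (applied to all five rates), log-spaced.
DEFAULT_STARTS = (0.01, 0.1, 1.0)

DEFAULT_BOUNDS = (0.0, 10.0)

_WRSS_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class KineticFit:
    """Result of one subject/region fit."""

    params: KineticParameters
    se: dict
    percent_se: dict
    wrss: float
    converged: bool
    n_starts_used: int
    macro: Macroparameters | None
    subject_id: str = ""
    region: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def max_percent_se(self) -> float:
        return max(self.percent_se.values())


def _weights(scheme, tac: TimeActivityCurve) -> np.ndarray:
    if isinstance(scheme, np.ndarray):
        w = np.asarray(scheme, dtype=float)
        if w.shape != tac.value.shape or np.any(w < 0) or not np.any(w > 0):
            raise DomainError("explicit weights must be non-negative, same length as the TAC")
    elif scheme == "duration":
        w = tac.schedule.duration.copy()
    elif scheme == "uniform":
        w = np.ones(tac.schedule.n_frames)
    else:
        raise DomainError(f"unknown weighting scheme {scheme!r}")
    return w / w.sum()


def _runs_test(residuals: np.ndarray) -> dict:
    """Wald-Wolfowitz runs test on residual signs (fit-adequacy diagnostic)."""
    signs = np.sign(residuals)
    signs = signs[signs != 0]
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    if n_pos == 0 or n_neg == 0:
        return {"runs": 1 if signs.size else 0, "runs_z": np.nan, "runs_p": np.nan}
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n * n * (n - 1.0))
    z = (runs - mean) / np.sqrt(var) if var > 0 else np.nan
    p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return {"runs": runs, "runs_z": float(z), "runs_p": float(p)}


def _standard_errors(jac: np.ndarray, wrss: float, n_obs: int) -> np.ndarray:
    """se from the scaled inverse Gauss-Newton Hessian of weighted residuals."""
    n_par = jac.shape[1]
    dof = max(n_obs - n_par, 1)
    s2 = wrss / dof
    jtj = jac.T @ jac
    se = np.full(n_par, np.inf)
    try:
        cov = np.linalg.pinv(jtj, rcond=1e-12)
    except np.linalg.LinAlgError:
        return se
    diag = np.diag(cov)
    # a parameter in the numerical null space of J has no finite SE
    rank = np.linalg.matrix_rank(jtj, tol=1e-12 * max(np.abs(np.diag(jtj)).max(), 1e-300))
    if rank < n_par:
        col_norm = np.linalg.norm(jac, axis=0)
        dead = col_norm <= 1e-12 * max(col_norm.max(), 1e-300)
    else:
        dead = np.zeros(n_par, bool)
    with np.errstate(invalid="ignore"):
        se = np.where(dead, np.inf, np.sqrt(np.maximum(diag, 0.0) * s2))
    return se


def fit_tac(
    tac: TimeActivityCurve,
    aif: InputFunction,
    init: KineticParameters | None = None,
    weights="duration",
    vB: float = DEFAULT_VB,
    bounds=DEFAULT_BOUNDS,
    dt: float = DEFAULT_DT,
    starts=DEFAULT_STARTS,
) -> KineticFit:
    """Fit (K1, k2, k3, k4, Kb) to one TAC.

    Multi-start (deterministic log-spaced starts) unless ``init`` is given;
    the start with the lowest WRSS wins, ties broken by lowest K1.  Never
    raises on optimizer failure: a non-converged KineticFit is returned.
    """
    model = TacModel(aif, tac.schedule, dt=dt)
    y = tac.value
    w = _weights(weights, tac)
    sqrt_w = np.sqrt(w)
    lo, hi = bounds

    def resid(x):
        p = KineticParameters(*x, vB=vB)
        return sqrt_w * (model.frame_values(p) - y)

    if init is not None:
        start_list = [np.clip(init.as_array(), lo + 1e-12, hi)]
    else:
        start_list = [np.full(5, s) for s in starts]

    candidates = []
    for x0 in start_list:
        try:
            res = least_squares(
                resid, x0, bounds=([lo] * 5, [hi] * 5), method="trf", xtol=1e-12, ftol=1e-12
            )
        except Exception:  # optimizer blow-up on one start is not fatal
            continue
        if np.all(np.isfinite(res.x)):
            candidates.append(res)

    if not candidates:
        p = KineticParameters(*start_list[0], vB=vB)
        nan = {k: np.inf for k in PARAM_NAMES}
        return KineticFit(
            params=p,
            se=nan,
            percent_se=dict(nan),
            wrss=np.inf,
            converged=False,
            n_starts_used=len(start_list),
            macro=None,
            subject_id=tac.subject_id,
            region=tac.region,
        )

    best_wrss = min(2.0 * r.cost for r in candidates)
    tied = [
        r
        for r in candidates
        if 2.0 * r.cost <= best_wrss * (1.0 + _WRSS_TIE_RTOL) + 1e-300
    ]
    res = min(tied, key=lambda r: r.x[0])  # lowest K1 among WRSS ties

    x = res.x
    wrss = float(2.0 * res.cost)
    se_arr = _standard_errors(res.jac, wrss, y.size)
    se = dict(zip(PARAM_NAMES, (float(s) for s in se_arr)))
    pct = {}
    for name, est, s in zip(PARAM_NAMES, x, se_arr):
        if est == 0.0:
            pct[name] = 0.0 if s == 0.0 else np.inf
        else:
            pct[name] = float(100.0 * s / abs(est))
    params = KineticParameters(*x, vB=vB)
    macro = None
    if params.k2 > 0 and params.k4 > 0:
        macro = macroparameters(params)
    raw_resid = model.frame_values(params) - y
    diagnostics = _runs_test(raw_resid)
    diagnostics["residuals"] = raw_resid
    return KineticFit(
        params=params,
        se=se,
        percent_se=pct,
        wrss=wrss,
        converged=bool(res.success),
        n_starts_used=len(start_list),
        macro=macro,
        subject_id=tac.subject_id,
        region=tac.region,
        diagnostics=diagnostics,
    )


@dataclass(frozen=True)
class ExclusionResult:
    retained: tuple
    excluded: tuple
    reasons: dict  # subject_id -> reason string for excluded fits


def apply_exclusion(fits, threshold_percent: float = 50.0) -> ExclusionResult:
    """Partition fits by the %SE quality rule.

    A fit is excluded iff any of the five estimated parameters has
    %SE > threshold, or the fit did not converge.
    """
    if not fits:
        raise InsufficientDataError("apply_exclusion needs at least one fit")
    retained, excluded, reasons = [], [], {}
    for fit in fits:
        if not fit.converged:
            excluded.append(fit)
            reasons[fit.subject_id] = "fit did not converge"
            continue
        bad = [n for n in PARAM_NAMES if fit.percent_se[n] > threshold_percent]
        if bad:
            excluded.append(fit)
            reasons[fit.subject_id] = (
                f"%SE > {threshold_percent:g}% for: " + ", ".join(bad)
            )
        else:
            retained.append(fit)
    return ExclusionResult(tuple(retained), tuple(excluded), reasons)
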