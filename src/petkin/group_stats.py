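"""Normalizations, AUC, fold change and group comparisons.

Group comparisons use Welch's unequal-variance t-test.  Kinetic parameters
are compared one-sided with the alternative "LPS > control" (the study's
directional hypothesis); regional AUC comparisons default to two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, UnitError
from .schedule import TimeActivityCurve

__all__ = [
    "percent_id_per_g",
    "suv",
    "auc_trapezoid",
    "welch_t_test",
    "fold_change",
    "summarize_groups",
    "GroupComparisonResult",
]


def percent_id_per_g(conc: float, injected_dose: float) -> float:
    """%ID/g = 100 * concentration (activity/g) / injected dose (activity)."""
    if injected_dose <= 0:
        raise DomainError("injected dose must be positive")
    return 100.0 * conc / injected_dose


def suv(conc: float, injected_dose: float, body_weight: float) -> float:
    """Standardized uptake value = conc / (injected dose / body weight)."""
    if injected_dose <= 0:
        raise DomainError("injected dose must be positive")
    if body_weight <= 0:
        raise DomainError("body weight must be positive")
    return conc / (injected_dose / body_weight)


def auc_trapezoid(tac: TimeActivityCurve) -> float:
    """Area under the TAC in %ID/g·s, 0 to end of acquisition.

    Trapezoid rule over frame mid-times (in seconds) anchored at (0, 0);
    the last frame value is held to the end of the acquisition so the
    full scanned interval is covered.
    """
    if tac.unit != "%ID/g":
        raise UnitError(f"AUC is defined for %ID/g curves, got unit {tac.unit!r}")
    mid_s = tac.schedule.mid * 60.0
    end_s = tac.schedule.end * 60.0
    t = np.concatenate([[0.0], mid_s, [end_s]])
    v = np.concatenate([[0.0], tac.value, [tac.value[-1]]])
    return float(np.trapezoid(v, t))


def fold_change(mean_numerator: float, mean_denominator: float) -> float:
    """Ratio of group means, reported to 2 decimals."""
    if mean_denominator <= 0:
        raise DomainError("fold-change denominator must be positive")
    return round(mean_numerator / mean_denominator, 2)


@dataclass(frozen=True)
class GroupComparisonResult:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_stat: float
    df: float
    p_value: float
    sides: str            # "one" or "two"
    direction: str        # "b_greater" (one-sided alternative) or "two_sided"
    welch: bool = True


def welch_t_test(a, b, sides: str = "one", direction: str = "b_greater",
                 parameter: str = "") -> GroupComparisonResult:
    """Welch's t-test of sample ``b`` against sample ``a``.

    t = (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.  One-sided tests use the
    alternative mean_b > mean_a (b is the treated/LPS group).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Welch's t-test needs n >= 2 per group")
    if sides not in ("one", "two"):
        raise DomainError("sides must be 'one' or 'two'")
    alternative = "greater" if sides == "one" else "two-sided"
    res = stats.ttest_ind(b, a, equal_var=False, alternative=alternative)
    return GroupComparisonResult(
        parameter=parameter,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        sides=sides,
        direction="b_greater" if sides == "one" else "two_sided",
    )


def _param_values(fits, name):
    if name == "k3/k4":
        return np.array([f.macro.BPND for f in fits])
    if name == "VT":
        return np.array([f.macro.VT for f in fits])
    return np.array([getattr(f.params, name) for f in fits])


def summarize_groups(fits_control, fits_lps, auc_control=None, auc_lps=None) -> pd.DataFrame:
    """Per-parameter group summary mirroring the kinetic-parameter table.

    Rows: K1, k2, k3/k4, Kb, VT (Welch one-sided, LPS > control) and,
    when per-subject AUC values are supplied, AUC (Welch two-sided).
    Fits must already be exclusion-filtered and carry macroparameters.
    """
    if not fits_control or not fits_lps:
        raise InsufficientDataError("both groups must be non-empty after exclusion")
    rows = []
    for name in ("K1", "k2", "k3/k4", "Kb", "VT"):
        r = welch_t_test(
            _param_values(fits_control, name),
            _param_values(fits_lps, name),
            sides="one",
            parameter=name,
        )
        rows.append(r)
    if auc_control is not None and auc_lps is not None:
        rows.append(welch_t_test(auc_control, auc_lps, sides="two", parameter="AUC"))
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "control_mean": [r.mean_a for r in rows],
            "control_sd": [r.sd_a for r in rows],
            "control_n": [r.n_a for r in rows],
            "lps_mean": [r.mean_b for r in rows],
            "lps_sd": [r.sd_b for r in rows],
            "lps_n": [r.n_b for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "sides": [r.sides for r in rows],
        }
    )
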