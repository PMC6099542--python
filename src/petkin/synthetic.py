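"""Synthetic mouse cohorts with the statistical structure the pipeline assumes.

The generator emulates the study conditions end to end:

* per-subject kinetic parameters drawn from the published group
  distributions (truncated-at-zero normals on K1, k2, k3/k4 and Kb; k4 is
  pinned because only the k3/k4 ratio is reported),
* a peaked tri-exponential plasma curve sampled at the arterial sampling
  times (5..120 min) plus early knots (0.25, 0.5, 1, 2 min) to resolve the
  input peak, with observed parent fractions from the plasma Hill model,
* noiseless tissue TACs from the 2-tissue + vascular-trapping forward model
  on the 25-frame dynamic schedule,
* brain metabolism applied in reverse (the measured TAC includes the
  metabolite signal, measured = parent / PF_brain(t)), so the pipeline's
  correction stage is exercised non-trivially,
* unbiased Gaussian frame noise with sd_i = noise_scale * sqrt(C_i / dt_i),
  approximating count statistics (late 900-s frames have ~5% CV at the
  default noise_scale).

Everything is deterministic given (base_seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .input_function import build_aif
from .kinetics import KineticParameters, TacModel
from .metabolism import (
    ParentFractionModel,
    default_brain_pf_model,
    default_plasma_pf_model,
    pf_evaluate,
)
from .schedule import (
    FrameSchedule,
    PlasmaSampleSeries,
    TimeActivityCurve,
    default_frame_schedule,
)

__all__ = [
    "AifParams",
    "GroupKinetics",
    "GeneratorConfig",
    "SyntheticSubject",
    "generate_aif",
    "draw_subject_params",
    "generate_cohort",
    "cohort_to_tables",
    "CONTROL_GROUP",
    "LPS_GROUP",
    "DEFAULT_SAMPLE_TIMES",
]

#: Arterial sampling times (min): early knots resolving the input peak plus
#: the terminal-sampling schedule 5..120 min.
DEFAULT_SAMPLE_TIMES = (0.25, 0.5, 1.0, 2.0, 5.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 120.0)


@dataclass(frozen=True)
class AifParams:
    """Tri-exponential plasma curve: rise at rate lam0 to a peak near 0.5 min,
    then bi-exponential decay.

    C(t) = amplitude * [p_slow e^(-lam_slow t) + (1-p_slow) e^(-lam_fast t)
                        - e^(-lam0 t) * (p_slow + (1-p_slow))]

    The amplitude is scaled so the noiseless control whole-brain TAC peaks
    in the 0.5-4 %ID/g range reported for this tracer.
    """

    amplitude: float = 7.0      # %ID/g-equivalent concentration scale
    p_slow: float = 0.25        # weight of the slow decay component
    lam_slow: float = 0.08      # min^-1
    lam_fast: float = 1.0       # min^-1
    lam_rise: float = 6.0       # min^-1

    def __post_init__(self):
        if self.amplitude <= 0:
            raise DomainError("AIF amplitude must be positive")
        if not 0 < self.p_slow < 1:
            raise DomainError("p_slow must be in (0, 1)")
        if min(self.lam_slow, self.lam_fast, self.lam_rise) <= 0:
            raise DomainError("AIF rate constants must be positive")

    def total_plasma(self, t):
        t = np.asarray(t, dtype=float)
        decay = self.p_slow * np.exp(-self.lam_slow * t) + (1.0 - self.p_slow) * np.exp(
            -self.lam_fast * t
        )
        return self.amplitude * (decay - np.exp(-self.lam_rise * t))


@dataclass(frozen=True)
class GroupKinetics:
    """(mean, sd) of each published group parameter."""

    K1: tuple
    k2: tuple
    ratio: tuple  # k3/k4
    Kb: tuple


#: Published whole-brain group parameters (mean, SD).
CONTROL_GROUP = GroupKinetics(K1=(0.58, 0.15), k2=(0.35, 0.06), ratio=(0.34, 0.13), Kb=(0.53, 0.05))
LPS_GROUP = GroupKinetics(K1=(0.86, 0.18), k2=(0.36, 0.13), ratio=(0.61, 0.58), Kb=(0.68, 0.23))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort."""

    n_control: int = 8          # scanned cohort sizes (before quality filtering)
    n_lps: int = 7
    control: GroupKinetics = CONTROL_GROUP
    lps: GroupKinetics = LPS_GROUP
    k4_fixed: float = 0.05      # min^-1; only the k3/k4 ratio is published
    vB: float = 0.05            # cerebral blood volume fraction
    aif: AifParams = field(default_factory=AifParams)
    sample_times: tuple = DEFAULT_SAMPLE_TIMES
    noise_scale: float = 0.19   # late 900-s frames ~5% CV on the control mean TAC
    base_seed: int = 0
    region: str = "whole brain"

    def __post_init__(self):
        if self.n_control <= 0 or self.n_lps <= 0:
            raise ValidationError("group sizes must be positive")
        if self.k4_fixed <= 0:
            raise ValidationError("k4_fixed must be positive")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be non-negative")
        for grp in (self.control, self.lps):
            for name in ("K1", "k2", "ratio", "Kb"):
                mean, sd = getattr(grp, name)
                if mean <= 0 or sd < 0:
                    raise ValidationError(f"group parameter {name}: mean > 0 and sd >= 0 required")


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str                       # "control" or "lps"
    true_params: KineticParameters
    plasma: PlasmaSampleSeries
    tac_measured: TimeActivityCurve  # noisy, includes metabolite signal
    tac_noiseless: TimeActivityCurve # parent-only forward-model output
    seed: tuple


def generate_aif(
    aif_params: AifParams,
    times=DEFAULT_SAMPLE_TIMES,
    pf: ParentFractionModel | None = None,
    subject_id: str = "",
) -> PlasmaSampleSeries:
    """Sample the tri-exponential plasma curve at ``times`` (minutes).

    ``parent_fraction_obs`` is filled from the plasma parent-fraction model
    (the default §-calibrated Hill model when none is given).
    """
    if pf is None:
        pf = default_plasma_pf_model()
    t = np.asarray(times, dtype=float)
    total = aif_params.total_plasma(t)
    return PlasmaSampleSeries(
        sample_time=t,
        total_plasma=total,
        parent_fraction_obs=pf_evaluate(pf, t),
        subject_id=subject_id,
    )


def _trunc_normal(rng, mean, sd):
    """Normal(mean, sd) truncated at zero by redraw (positive-parameter prior)."""
    if sd == 0:
        return mean
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("truncated-normal rejection sampling failed")  # pragma: no cover


def draw_subject_params(group: str, config: GeneratorConfig, rng) -> KineticParameters:
    """Draw one subject's kinetic parameters from the group distribution."""
    gp = config.control if group == "control" else config.lps
    k1 = _trunc_normal(rng, *gp.K1)
    k2 = _trunc_normal(rng, *gp.k2)
    ratio = _trunc_normal(rng, *gp.ratio)
    kb = _trunc_normal(rng, *gp.Kb)
    return KineticParameters(
        K1=k1, k2=k2, k3=ratio * config.k4_fixed, k4=config.k4_fixed, Kb=kb, vB=config.vB
    )


def generate_cohort(config: GeneratorConfig | None = None) -> list[SyntheticSubject]:
    """Generate the full control + LPS cohort (deterministic in base_seed)."""
    if config is None:
        config = GeneratorConfig()
    pf_plasma = default_plasma_pf_model()
    pf_brain = default_brain_pf_model()
    schedule = default_frame_schedule()
    samples = generate_aif(config.aif, config.sample_times, pf_plasma)
    aif = build_aif(samples, pf_plasma)
    model = TacModel(aif, schedule)
    pf_mid = pf_evaluate(pf_brain, schedule.mid)

    subjects = []
    index = 0
    for group, n, prefix in (("control", config.n_control, "C"), ("lps", config.n_lps, "L")):
        for i in range(n):
            seed = (config.base_seed, index)
            rng = np.random.default_rng(seed)
            params = draw_subject_params(group, config, rng)
            subject_id = f"{prefix}{i + 1:02d}"
            parent_vals = model.frame_values(params)
            noiseless = TimeActivityCurve(
                schedule=schedule,
                value=parent_vals,
                region=config.region,
                subject_id=subject_id,
                metabolite_corrected=True,
            )
            measured_vals = parent_vals / pf_mid  # metabolite signal re-included
            if config.noise_scale > 0:
                sd = config.noise_scale * np.sqrt(
                    np.maximum(measured_vals, 0.0) / schedule.duration
                )
                measured_vals = measured_vals + rng.normal(0.0, 1.0, sd.size) * sd
            measured = TimeActivityCurve(
                schedule=schedule,
                value=measured_vals,
                region=config.region,
                subject_id=subject_id,
                is_noisy=True,
            )
            subjects.append(
                SyntheticSubject(
                    subject_id=subject_id,
                    group=group,
                    true_params=params,
                    plasma=replace(samples, subject_id=subject_id),
                    tac_measured=measured,
                    tac_noiseless=noiseless,
                    seed=seed,
                )
            )
            index += 1
    return subjects


def cohort_to_tables(subjects) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (tac, plasma, truth) tables for CSV export."""
    tac_rows, plasma_rows, truth_rows = [], [], []
    for s in subjects:
        sched = s.tac_measured.schedule
        tac_rows.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "region": s.tac_measured.region,
                    "frame_start_s": np.round(sched.start * 60.0, 9),
                    "frame_duration_s": np.round(sched.duration * 60.0, 9),
                    "value": s.tac_measured.value,
                    "unit": s.tac_measured.unit,
                }
            )
        )
        plasma_rows.append(
            pd.DataFrame(
                {
                    "subject_id": s.subject_id,
                    "sample_time_min": s.plasma.sample_time,
                    "total_plasma": s.plasma.total_plasma,
                    "parent_fraction_obs": s.plasma.parent_fraction_obs,
                }
            )
        )
        p = s.true_params
        truth_rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "K1": p.K1,
                "k2": p.k2,
                "k3": p.k3,
                "k4": p.k4,
                "Kb": p.Kb,
                "vB": p.vB,
            }
        )
    return (
        pd.concat(tac_rows, ignore_index=True),
        pd.concat(plasma_rows, ignore_index=True),
        pd.DataFrame(truth_rows),
    )
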