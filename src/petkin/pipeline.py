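"""End-to-end orchestration: generate/load -> correct -> AIF -> fit -> exclude
-> summarize, with reproducible artifacts.

Outputs written to the run directory:

* ``tac.csv``, ``plasma.csv``, ``truth.csv`` (generated cohorts only)
* ``fits.csv`` — per-subject parameters, %SE, VT/BPND, AUC, exclusion status
* ``summary.csv`` — group means ± SD and Welch p per parameter
* ``pf_models.json`` — calibrated parent-fraction model parameters
* ``manifest.json`` — seed, defaults in effect, stage completion flags
* ``run.log`` — plain-text log
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import PetkinError, PipelineError
from .fitting import PARAM_NAMES, apply_exclusion, fit_tac
from .group_stats import auc_trapezoid, summarize_groups
from .input_function import build_aif
from .io import read_plasma_table, read_tac_table
from .metabolism import correct_tac_for_metabolites, pf_calibrate
from .synthetic import cohort_to_tables, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _fit_row(fit, auc, excluded, reason):
    row = {
        "subject_id": fit.subject_id,
        "region": fit.region,
        **{n: getattr(fit.params, n) for n in PARAM_NAMES},
        "VT": fit.macro.VT if fit.macro else np.nan,
        "BPND": fit.macro.BPND if fit.macro else np.nan,
        "AUC": auc,
    }
    row.update({f"percent_se_{n}": fit.percent_se[n] for n in PARAM_NAMES})
    row.update(
        {
            "wrss": fit.wrss,
            "converged": fit.converged,
            "excluded": excluded,
            "exclusion_reason": reason,
        }
    )
    return row


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Run the full analysis; returns the artifact directory.

    Any stage failure raises :class:`PipelineError` naming the stage;
    whatever was already written stays on disk and the manifest marks the
    run incomplete.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("petkin")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest = {
        "petkin_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "stages_completed": [],
        "complete": False,
    }

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def _stage(name):
        manifest["stages_completed"].append(name)
        _write_manifest()
        logger.info("stage complete: %s", name)

    try:
        # --- metabolism: calibrate parent-fraction models ------------------
        try:
            pf_plasma = pf_calibrate(config.pf_plasma_points, "plasma")
            pf_brain = pf_calibrate(config.pf_brain_points, "brain")
            (outdir / "pf_models.json").write_text(
                json.dumps(
                    {
                        c: {"a": m.a, "t50": m.t50, "n": m.n,
                            "calibration_residuals": list(m.calibration_residuals)}
                        for c, m in (("plasma", pf_plasma), ("brain", pf_brain))
                    },
                    indent=2,
                )
            )
        except PetkinError as e:
            raise PipelineError("metabolism", str(e)) from e
        _stage("metabolism")

        # --- inputs: generate or load --------------------------------------
        try:
            if config.generator is not None:
                gen = dataclasses.replace(config.generator, base_seed=config.seed)
                cohort = generate_cohort(gen)
                tac_df, plasma_df, truth_df = cohort_to_tables(cohort)
                tac_df.to_csv(outdir / "tac.csv", index=False)
                plasma_df.to_csv(outdir / "plasma.csv", index=False)
                truth_df.to_csv(outdir / "truth.csv", index=False)
                tacs = [s.tac_measured for s in cohort]
                plasma_by_subject = {s.subject_id: s.plasma for s in cohort}
                group_by_subject = {s.subject_id: s.group for s in cohort}
            else:
                tacs = read_tac_table(config.tac_path)
                plasma_list = read_plasma_table(config.plasma_path)
                plasma_by_subject = {p.subject_id: p for p in plasma_list}
                if len(plasma_list) == 1:  # population input function
                    plasma_by_subject = {t.subject_id: plasma_list[0] for t in tacs}
                group_by_subject = {}
                if config.truth_path:
                    truth = pd.read_csv(config.truth_path)
                    group_by_subject = dict(zip(truth["subject_id"].astype(str), truth["group"]))
        except (PetkinError, OSError) as e:
            raise PipelineError("input_function" if config.generator is None else "synthetic_data",
                                str(e)) from e
        _stage("inputs")

        # --- correct, build AIF, fit ---------------------------------------
        fits, aucs = [], {}
        try:
            for tac in tacs:
                corrected = correct_tac_for_metabolites(tac, pf_brain)
                aif = build_aif(plasma_by_subject[tac.subject_id], pf_plasma)
                fit = fit_tac(corrected, aif, weights=config.weights, vB=config.vB)
                fits.append(fit)
                aucs[tac.subject_id] = auc_trapezoid(corrected)
        except (PetkinError, KeyError) as e:
            raise PipelineError("fitting", str(e)) from e
        _stage("fitting")

        # --- exclusion + per-subject table ---------------------------------
        result = apply_exclusion(fits, config.exclusion_threshold)
        excluded_ids = {f.subject_id for f in result.excluded}
        rows = [
            _fit_row(
                f,
                aucs[f.subject_id],
                f.subject_id in excluded_ids,
                result.reasons.get(f.subject_id, ""),
            )
            for f in fits
        ]
        fits_df = pd.DataFrame(rows)
        if group_by_subject:
            fits_df.insert(1, "group", fits_df["subject_id"].map(group_by_subject))
        fits_df.to_csv(outdir / "fits.csv", index=False, float_format="%.10g")
        _stage("exclusion")

        # --- group summary --------------------------------------------------
        if group_by_subject:
            retained = [f for f in result.retained if f.macro is not None]
            ctrl = [f for f in retained if group_by_subject[f.subject_id] == "control"]
            lps = [f for f in retained if group_by_subject[f.subject_id] == "lps"]
            try:
                summary = summarize_groups(
                    ctrl,
                    lps,
                    auc_control=[aucs[f.subject_id] for f in ctrl],
                    auc_lps=[aucs[f.subject_id] for f in lps],
                )
            except PetkinError as e:
                raise PipelineError("group_stats", str(e)) from e
            summary.to_csv(outdir / "summary.csv", index=False, float_format="%.10g")
            with open(outdir / "summary.txt", "w") as fh:
                fh.write(summary.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
            _stage("group_stats")
        else:
            logger.info("no group labels available; skipping group summary")

        manifest["complete"] = True
        manifest["n_fits"] = len(fits)
        manifest["n_retained"] = len(result.retained)
        manifest["n_excluded"] = len(result.excluded)
        _write_manifest()
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()
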