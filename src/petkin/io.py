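"""CSV readers/writers for TAC and plasma tables.

TAC tables: columns ``subject_id, region, frame_start_s, frame_duration_s,
value, unit`` (frame times in seconds).  Plasma tables: ``sample_time_min,
total_plasma`` with optional ``subject_id`` and ``parent_fraction_obs``.
Comma-separated, dot decimal, UTF-8, header row mandatory.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .schedule import FrameSchedule, PlasmaSampleSeries, TimeActivityCurve

logger = logging.getLogger(__name__)

TAC_COLUMNS = ["subject_id", "region", "frame_start_s", "frame_duration_s", "value", "unit"]
PLASMA_COLUMNS = ["sample_time_min", "total_plasma"]


def _read_csv(path, required, label):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s table %s is empty", label, path)
        return None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{label} table {path} is missing column(s): {', '.join(missing)}")
    return df


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read a TAC CSV into one curve per (subject_id, region).

    Curves read from disk are treated as measurements (``is_noisy=True``),
    so stored negative noise excursions survive the round trip.
    """
    df = _read_csv(path, TAC_COLUMNS, "TAC")
    if df is None or df.empty:
        return []
    curves = []
    for (subject_id, region), grp in df.groupby(["subject_id", "region"], sort=False):
        grp = grp.sort_values("frame_start_s")
        schedule = FrameSchedule(
            start=grp["frame_start_s"].to_numpy(float) / 60.0,
            duration=grp["frame_duration_s"].to_numpy(float) / 60.0,
        )
        units = grp["unit"].unique()
        if len(units) != 1:
            raise FormatError(f"mixed units for subject {subject_id!r} region {region!r}")
        curves.append(
            TimeActivityCurve(
                schedule=schedule,
                value=grp["value"].to_numpy(float),
                region=str(region),
                subject_id=str(subject_id),
                unit=str(units[0]),
                is_noisy=True,
            )
        )
    return curves


def write_tac_table(curves, path) -> None:
    rows = []
    for tac in curves:
        sched = tac.schedule
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": tac.subject_id,
                    "region": tac.region,
                    "frame_start_s": np.round(sched.start * 60.0, 9),
                    "frame_duration_s": np.round(sched.duration * 60.0, 9),
                    "value": tac.value,
                    "unit": tac.unit,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TAC_COLUMNS)
    out.to_csv(path, index=False)


def read_plasma_table(path) -> list[PlasmaSampleSeries]:
    df = _read_csv(path, PLASMA_COLUMNS, "plasma")
    if df is None or df.empty:
        return []
    if "subject_id" not in df.columns:
        df = df.assign(subject_id="")
    series = []
    for subject_id, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("sample_time_min")
        pf = None
        if "parent_fraction_obs" in grp.columns and grp["parent_fraction_obs"].notna().all():
            pf = grp["parent_fraction_obs"].to_numpy(float)
        series.append(
            PlasmaSampleSeries(
                sample_time=grp["sample_time_min"].to_numpy(float),
                total_plasma=grp["total_plasma"].to_numpy(float),
                parent_fraction_obs=pf,
                subject_id=str(subject_id),
            )
        )
    return series


def write_plasma_table(series_list, path) -> None:
    rows = []
    for s in series_list:
        row = {
            "subject_id": s.subject_id,
            "sample_time_min": s.sample_time,
            "total_plasma": s.total_plasma,
        }
        if s.parent_fraction_obs is not None:
            row["parent_fraction_obs"] = s.parent_fraction_obs
        rows.append(pd.DataFrame(row))
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["subject_id"] + PLASMA_COLUMNS)
    )
    out.to_csv(path, index=False)
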