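"""Time grids and curve containers shared by every pipeline stage.

All kinetic computations run in minutes (rate constants are min^-1);
tabular I/O expresses frame times in seconds, and the conversion happens
only at the I/O boundary (:mod:`petkin.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "PlasmaSampleSeries",
    "default_frame_schedule",
]

#: Frame durations of the 120-min dynamic acquisition, in seconds:
#: 12 x 5 s, 4 x 60 s, 2 x 300 s, 7 x 900 s (25 frames, 7200 s total).
DEFAULT_FRAME_DURATIONS_S = (5,) * 12 + (60,) * 4 + (300,) * 2 + (900,) * 7

_CONTIGUITY_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-acquisition time grid, in minutes."""

    start: np.ndarray     # frame start times, minutes
    duration: np.ndarray  # frame durations, minutes

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape or start.size == 0:
            raise ValidationError("start and duration must be equal-length 1-D arrays")
        if not np.all(np.isfinite(start)) or not np.all(np.isfinite(duration)):
            raise ValidationError("frame times must be finite")
        if np.any(duration <= 0):
            raise ValidationError("frame durations must be positive")
        if abs(start[0]) > _CONTIGUITY_TOL:
            raise ValidationError("first frame must start at t = 0")
        gaps = start[1:] - (start[:-1] + duration[:-1])
        if np.any(np.abs(gaps) > _CONTIGUITY_TOL):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations_s(cls, durations_s) -> "FrameSchedule":
        """Build a contiguous schedule from frame durations given in seconds."""
        dur = np.asarray(durations_s, dtype=float) / 60.0
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start=start, duration=dur)

    @property
    def n_frames(self) -> int:
        return self.start.size

    @property
    def mid(self) -> np.ndarray:
        """Frame mid-times, minutes."""
        return self.start + 0.5 * self.duration

    @property
    def end(self) -> float:
        """End of the last frame, minutes."""
        return float(self.start[-1] + self.duration[-1])

    @property
    def total_span_s(self) -> float:
        return self.end * 60.0

    def __eq__(self, other):
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.start, other.start) and np.array_equal(
            self.duration, other.duration
        )


def default_frame_schedule() -> FrameSchedule:
    """The study's 25-frame, 120-min dynamic schedule."""
    return FrameSchedule.from_durations_s(DEFAULT_FRAME_DURATIONS_S)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame regional activity concentration for one subject.

    ``value`` is one concentration per frame in the tagged ``unit``
    (``%ID/g`` unless stated otherwise).  Negative entries are legal only
    on curves flagged as noisy measurements, so that measurement noise is
    stored unclipped and stays unbiased.
    """

    schedule: FrameSchedule
    value: np.ndarray
    region: str = "whole brain"
    subject_id: str = ""
    unit: str = "%ID/g"
    is_noisy: bool = False
    metabolite_corrected: bool = False

    def __post_init__(self):
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "value", value)
        if value.shape != (self.schedule.n_frames,):
            raise ValidationError(
                f"value length {value.size} != number of frames {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(value)):
            raise ValidationError("TAC values must be finite")
        if not self.is_noisy and np.any(value < 0):
            raise ValidationError("negative values are only allowed on noisy measured curves")

    def with_values(self, value, **changes) -> "TimeActivityCurve":
        return replace(self, value=np.asarray(value, dtype=float), **changes)


@dataclass(frozen=True)
class PlasmaSampleSeries:
    """Discrete arterial plasma samples for one subject (or a population curve).

    Times are minutes post-injection; ``total_plasma`` is total (parent +
    metabolite) activity concentration; ``parent_fraction_obs`` optionally
    carries measured parent fractions at the same times.
    """

    sample_time: np.ndarray
    total_plasma: np.ndarray
    parent_fraction_obs: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.sample_time, dtype=float)
        c = np.asarray(self.total_plasma, dtype=float)
        object.__setattr__(self, "sample_time", t)
        object.__setattr__(self, "total_plasma", c)
        if t.ndim != 1 or t.shape != c.shape or t.size == 0:
            raise ValidationError("sample_time and total_plasma must be equal-length 1-D arrays")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValidationError("sample times must be non-negative and strictly increasing")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValidationError("plasma concentrations must be finite and non-negative")
        if self.parent_fraction_obs is not None:
            pf = np.asarray(self.parent_fraction_obs, dtype=float)
            object.__setattr__(self, "parent_fraction_obs", pf)
            if pf.shape != t.shape:
                raise ValidationError("parent_fraction_obs must match sample_time length")
            if np.any((pf < 0) | (pf > 1)):
                raise ValidationError("parent fractions must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.sample_time.size
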