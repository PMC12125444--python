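"""Frame schedules and time-activity curves.

Dynamic PET data are acquired as a sequence of contiguous time frames of
varying duration; every downstream stage (input-function correction,
compartment fitting, graphical analysis, SUVR) consumes the frame grid and
per-frame activity concentrations defined here.

Conventions
-----------
* Schedules are stored in **seconds** since injection; kinetic math elsewhere
  uses minutes (rate constants are min^-1) and converts at the boundary.
* A curve is interpolated piecewise-linearly on its frame mid-points, with a
  virtual anchor at (t=0, value=0): tracer activity is zero at injection, and
  the anchor prevents extrapolation artifacts in the 2-s early frames. Beyond
  the last mid-point the value is held constant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "parse_frame_schedule",
    "interpolate_curve",
    "integrate_curve",
    "truncate_to_duration",
]


class ScheduleError(ValueError):
    """Malformed or inconsistent frame schedule."""


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic framing grid.

    Parameters
    ----------
    starts :
        Frame start times, seconds since injection. ``starts[0]`` must be 0.
    durations :
        Frame durations in seconds, all positive.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or durations.shape != starts.shape or starts.size == 0:
            raise ScheduleError("starts and durations must be equal-length 1-D arrays")
        if not np.all(np.isfinite(starts)) or not np.all(np.isfinite(durations)):
            raise ScheduleError("non-finite frame times")
        if np.any(durations <= 0):
            raise ScheduleError("all frame durations must be > 0")
        if starts[0] != 0:
            raise ScheduleError("first frame must start at t=0")
        if starts.size > 1 and not np.allclose(
            starts[1:], starts[:-1] + durations[:-1], rtol=0, atol=1e-9
        ):
            raise ScheduleError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.starts.size)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def mids(self) -> np.ndarray:
        """Frame mid-points, seconds; strictly increasing by construction."""
        return self.starts + self.durations / 2.0

    @property
    def total_seconds(self) -> float:
        return float(self.ends[-1])

    def to_spec(self) -> str:
        """Serialize back to the ``"count x seconds"`` protocol grammar."""
        groups: list[str] = []
        count = 1
        for i in range(1, self.n_frames + 1):
            if i < self.n_frames and self.durations[i] == self.durations[i - 1]:
                count += 1
            else:
                d = self.durations[i - 1]
                d_str = f"{d:g}"
                groups.append(f"{count}x{d_str}")
                count = 1
        return ",".join(groups)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return np.array_equal(self.starts, other.starts) and np.array_equal(
            self.durations, other.durations
        )


@dataclass(frozen=True, eq=False)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) per frame for one region or blood pool.

    A mean below zero over any 5 consecutive frames is flagged (``suspect``)
    rather than rejected: individual negative excursions are legitimate
    reconstruction noise, a sustained negative run is not.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"expected {self.schedule.n_frames} values, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    @property
    def suspect(self) -> bool:
        """True if the mean of any 5 consecutive frames is negative."""
        v = self.values
        if v.size < 5:
            return bool(v.size and v.mean() < 0)
        kernel = np.ones(5) / 5.0
        return bool(np.any(np.convolve(v, kernel, mode="valid") < 0))

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, values, self.label if label is None else label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeActivityCurve):
            return NotImplemented
        return (
            self.schedule == other.schedule
            and np.array_equal(self.values, other.values)
            and self.label == other.label
        )


_GROUP_RE = re.compile(r"^\s*(\d+)\s*[x×]\s*(\d+(?:\.\d+)?)\s*$")

#: The study's dynamic framing protocol: 90 min in 65 frames with 2-s
#: early frames resolving the blood-pool bolus peak.
DEFAULT_PROTOCOL = "30x2,12x10,7x60,16x300"


def parse_frame_schedule(spec: str) -> FrameSchedule:
    """Expand a ``"count x seconds"`` protocol string into a frame grid.

    Examples
    --------
    >>> parse_frame_schedule("30x2,12x10,7x60,16x300").total_seconds
    5400.0
    """
    if not spec or not spec.strip():
        raise ScheduleError("empty protocol string")
    durations: list[float] = []
    for token in spec.split(","):
        m = _GROUP_RE.match(token)
        if m is None:
            raise ScheduleError(f"malformed protocol group {token!r}")
        count, dur = int(m.group(1)), float(m.group(2))
        if count <= 0 or dur <= 0:
            raise ScheduleError(f"non-positive count or duration in group {token!r}")
        durations.extend([dur] * count)
    durations_arr = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations_arr)[:-1]])
    return FrameSchedule(starts=starts, durations=durations_arr)


def _nodes(tac: TimeActivityCurve) -> tuple[np.ndarray, np.ndarray]:
    """Interpolation nodes: the (0, 0) anchor followed by frame mid-points."""
    t = np.concatenate([[0.0], tac.schedule.mids])
    v = np.concatenate([[0.0], tac.values])
    return t, v


def interpolate_curve(
    tac: TimeActivityCurve, query_times: np.ndarray, method: str = "linear-on-mids"
) -> np.ndarray:
    """Evaluate the piecewise-linear mid-point interpolant at ``query_times`` (s).

    Before the first mid-point the curve ramps linearly from (0, 0); after the
    last mid-point the value is held constant.
    """
    if method != "linear-on-mids":
        raise ValueError(f"unknown interpolation method {method!r}")
    q = np.asarray(query_times, dtype=float)
    end = tac.schedule.total_seconds
    if np.any(q < 0) or np.any(q > end + 1e-9):
        raise ValueError(f"query times must lie within [0, {end}] s")
    t, v = _nodes(tac)
    return np.interp(q, t, v)


def integrate_curve(tac: TimeActivityCurve, upto: float) -> float:
    """Exact integral of the interpolant from 0 to ``upto`` s, in kBq*min/mL."""
    if upto <= 0:
        raise ValueError("integration endpoint must be > 0")
    if upto > tac.schedule.total_seconds + 1e-9:
        raise ValueError("integration endpoint beyond scan end")
    t, v = _nodes(tac)
    mask = t < upto
    tt = np.concatenate([t[mask], [upto]])
    vv = np.concatenate([v[mask], [float(np.interp(upto, t, v))]])
    area_s = np.trapezoid(vv, tt)
    return float(area_s) / 60.0


def truncate_to_duration(tac: TimeActivityCurve, T: float) -> TimeActivityCurve:
    """Keep only frames fully contained in the first ``T`` minutes of the scan.

    Frame boundaries in the study protocol align with every 10-min cut point,
    so whole-frame truncation is exact for the scan-duration analysis.
    """
    if T <= 0:
        raise ValueError("truncation duration must be > 0 min")
    if T * 60.0 > tac.schedule.total_seconds + 1e-9:
        raise ValueError(
            f"truncation at {T} min exceeds scan length "
            f"{tac.schedule.total_seconds / 60.0:g} min"
        )
    keep = tac.schedule.ends <= T * 60.0 + 1e-9
    n = int(np.count_nonzero(keep))
    if n == 0:
        raise ValueError(f"no complete frame within the first {T} min")
    sched = FrameSchedule(tac.schedule.starts[:n].copy(), tac.schedule.durations[:n].copy())
    return TimeActivityCurve(sched, tac.values[:n].copy(), tac.label)
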