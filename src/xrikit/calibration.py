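"""Time calibration: mapping the clock axis to experiment time.

The fraction-of-constitutive-line-integral axis is a monotone but a priori
nonlinear function of time (the constitutive expression rate accelerates).
The calibration experiment inducibly expresses the tagged species at known
times in separate cohorts, decodes the onset fraction per filament, and
interpolates linearly between the per-cohort mean onset fractions.  The
map is anchored at fraction 1 at the fixation time (growth stops there)
and, optionally, at fraction 0 at the recording start.  The resulting
strictly monotone piecewise-linear map converts decoded traces from the
clock axis to recovered time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .decoder import DecodedSignal

__all__ = [
    "TimeCalibration",
    "build_calibration",
    "fraction_to_time",
    "time_to_fraction",
    "apply_calibration",
    "TimeTrace",
]


@dataclass
class TimeCalibration:
    """Monotone piecewise-linear map between time (days) and clock fraction."""

    times: np.ndarray
    fractions: np.ndarray
    group_n: dict | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.times) != len(self.fractions) or len(self.times) < 2:
            raise ValueError("need >= 2 (time, fraction) knots")
        bad = _non_increasing_knots(self.times, self.fractions)
        if bad:
            raise ValueError(f"non-monotone knots at positions {bad}")

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_fix(self) -> float:
        return float(self.times[-1])

    def save(self, path) -> None:
        payload = {
            "times": self.times.tolist(),
            "fractions": self.fractions.tolist(),
            "group_n": self.group_n,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @staticmethod
    def load(path) -> "TimeCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        return TimeCalibration(
            times=payload["times"],
            fractions=payload["fractions"],
            group_n=payload.get("group_n"),
        )


def _non_increasing_knots(times, fractions) -> list[int]:
    bad = []
    for i in range(1, len(times)):
        if times[i] <= times[i - 1] or fractions[i] <= fractions[i - 1]:
            bad.append(i)
    return bad


def build_calibration(
    groups: dict,
    t_fix: float,
    t_start: float | None = None,
    include_origin: bool = True,
    stat: str = "mean",
) -> TimeCalibration:
    """Build the calibration from per-induction-time onset samples.

    ``groups`` maps induction time (days) to a sequence of decoded onset
    fractions.  One knot is placed per group at (time, mean fraction) —
    or median with ``stat="median"`` — then the terminal anchor
    ``(t_fix, 1.0)`` is appended and, when ``t_start`` is given and
    ``include_origin`` is true, the origin anchor ``(t_start, 0.0)`` is
    prepended.  Raises when fewer than 2 groups are given or the knots are
    not strictly increasing (listing the offending knots).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 induction-time groups")
    summarize = np.median if stat == "median" else np.mean
    times, fracs, n = [], [], {}
    for t in sorted(groups):
        samples = np.asarray(list(groups[t]), dtype=float)
        samples = samples[np.isfinite(samples)]
        if samples.size == 0:
            raise ValueError(f"group at day {t} has no usable onset estimates")
        times.append(float(t))
        fracs.append(float(summarize(samples)))
        n[float(t)] = int(samples.size)
    if times[-1] >= t_fix:
        raise ValueError("all group times must precede t_fix")
    times.append(float(t_fix))
    fracs.append(1.0)
    if include_origin and t_start is not None and t_start < times[0]:
        times.insert(0, float(t_start))
        fracs.insert(0, 0.0)
    return TimeCalibration(times=np.array(times), fractions=np.array(fracs), group_n=n)


def _interp_extend(x, xp, fp):
    """Piecewise-linear interpolation with linear extension of end segments."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    hi = x > xp[-1]
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


def fraction_to_time(calib: TimeCalibration, f) -> np.ndarray | float:
    """Recovered time (days) for clock fraction(s) ``f``.

    Exact at knots; outside the knot span the terminal segment is extended
    linearly and the result clamped to ``[t_start, t_fix]``.
    """
    t = _interp_extend(f, calib.fractions, calib.times)
    t = np.clip(t, calib.times[0], calib.times[-1])
    return float(t) if np.isscalar(f) else t


def time_to_fraction(calib: TimeCalibration, t) -> np.ndarray | float:
    """Clock fraction for time(s) ``t`` (days); inverse of fraction_to_time."""
    f = _interp_extend(t, calib.times, calib.fractions)
    f = np.clip(f, calib.fractions[0], calib.fractions[-1])
    return float(f) if np.isscalar(t) else f


@dataclass
class TimeTrace:
    """A decoded trace resampled onto a uniform recovered-time grid."""

    times: np.ndarray
    values: np.ndarray
    tag: str = ""
    xri_id: str = ""
    cell_id: str = ""


def apply_calibration(
    signal: DecodedSignal,
    calib: TimeCalibration,
    values: np.ndarray | None = None,
    time_step: float = 0.05,
) -> TimeTrace:
    """Map a decoded signal from the clock axis to recovered time.

    Grid fractions map through :func:`fraction_to_time`; values are
    unchanged, then resampled onto a uniform time grid (default step 0.05
    day) spanning ``[t_start, t_fix]`` for cohort averaging.  Pass
    ``values`` to calibrate a derived trace (e.g. relative change) defined
    on the same grid.
    """
    v = signal.f_signal if values is None else np.asarray(values, dtype=float)
    t_of_f = fraction_to_time(calib, signal.grid)
    t_grid = np.arange(calib.t_start, calib.t_fix + time_step / 2.0, time_step)
    # t_of_f is nondecreasing; make strictly increasing for interp stability
    t_mono = np.maximum.accumulate(t_of_f)
    out = np.interp(t_grid, t_mono, v)
    return TimeTrace(
        times=t_grid, values=out, tag=signal.tag,
        xri_id=signal.xri_id, cell_id=signal.cell_id,
    )
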