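"""Decoding expression history from filament intensity profiles.

The decoder turns a per-channel line profile into the induced-channel
expression-history trace.  Each profile is split at a point near its
geometric center into two halves (the filament grows bidirectionally, so
the two halves carry mirrored copies of the same history).  On each half,
with arc distance ``d`` measured outward from the split:

* ``H_integral(p) = sum_{d=0}^{p} H(d) * dd`` — cumulative constitutive
  (HA) intensity, a left-Riemann sum on the native samples;
* ``H_fraction_integral(p) = H_integral(p) / H_integral(End)`` — the
  molecular clock axis, 0 at the split and 1 at the filament end;
* ``F_integral(p) = sum_{d=0}^{p} F(d) * dd`` — cumulative induced
  (FLAG/V5) intensity, not normalized;
* ``F_signal = dF_integral / dH_fraction_integral`` — induced intensity
  accumulated per unit of the clock, i.e. the decoded expression history.

The split point is optimized within +/-25% of the total length around the
geometric center to minimize the sum of squared differences between the
two half signals on a shared uniform fraction grid; the decoded signal is
the point-by-point mean of the two halves at the optimal split.  The onset
of an induced event is estimated by fitting a line to the initial rising
phase of the baseline-subtracted signal (the samples between 10% and 50%
of its peak) and extrapolating to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy.ndimage import gaussian_filter1d

from .profile_io import LineProfile

__all__ = [
    "trim_to_support",
    "HalfProfile",
    "DecodedSignal",
    "OnsetEstimate",
    "split_at",
    "fraction_integral",
    "signal_from_half",
    "optimal_split",
    "baseline",
    "end_center_ratio",
    "relative_change",
    "onset_fraction",
    "fraction_grid",
]


def fraction_grid(n: int = 201) -> np.ndarray:
    """Uniform grid on [0, 1] for the clock axis (default 201 points)."""
    return np.linspace(0.0, 1.0, n)


@dataclass
class HalfProfile:
    """One half of a split profile; ``d`` measured outward from the split.

    By the midpoint convention the first sample sits at ``d = dd/2`` (the
    sample at the split itself belongs to neither half).
    """

    h: np.ndarray
    f: np.ndarray
    delta_d: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.h.shape != self.f.shape:
            raise ValueError("H and F must share shape")
        if self.delta_d <= 0:
            raise ValueError("delta_d must be positive")

    @property
    def d(self) -> np.ndarray:
        return (np.arange(len(self.h)) + 0.5) * self.delta_d

    @property
    def h_integral(self) -> np.ndarray:
        return np.cumsum(self.h) * self.delta_d

    @property
    def f_integral(self) -> np.ndarray:
        return np.cumsum(self.f) * self.delta_d


@dataclass
class DecodedSignal:
    """Decoded induced-channel signal on the uniform clock grid."""

    grid: np.ndarray
    f_signal: np.ndarray
    tag: str = "FLAG"
    split_arc_um: float = np.nan
    split_index: int = -1
    ssd: float = np.nan
    xri_id: str = ""
    cell_id: str = ""

    @property
    def baseline_value(self) -> float:
        return baseline(self)


@dataclass
class OnsetEstimate:
    """Onset of the induced signal on the clock axis, with fit diagnostics."""

    onset: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    baseline: float = np.nan
    peak: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def trim_to_support(
    profile: LineProfile,
    constitutive: str = "HA",
    support_frac: float = 0.2,
) -> LineProfile:
    """Trim profile ends to the filament's constitutive support.

    The filament "end" anchors the clock at fraction 1, so samples beyond
    the visible constitutive signal (PSF rolloff, tracing overshoot) must
    not enter the integrals: in that region the clock increment vanishes
    while any residual induced background does not, which would blow up
    the ratio near fraction 1.  Keeps the maximal contiguous run where the
    constitutive intensity is at least ``support_frac`` times its median
    over the centerline; mirrors ending a hand-drawn centerline where the
    filament visibly ends.
    """
    h = profile.channel(constitutive)
    thr = support_frac * float(np.median(h))
    above = h >= thr
    if not np.any(above):
        return profile
    lo = int(np.argmax(above))
    hi = len(h) - int(np.argmax(above[::-1]))
    if hi - lo < 2:
        return profile
    return LineProfile(
        d_um=profile.d_um[: hi - lo],
        intensities={k: v[lo:hi] for k, v in profile.intensities.items()},
        delta_d_um=profile.delta_d_um,
        cell_id=profile.cell_id,
        xri_id=profile.xri_id,
        meta=dict(profile.meta),
    )


def split_at(
    profile: LineProfile,
    split_arc_um: float,
    constitutive: str = "HA",
    induced: str = "FLAG",
) -> tuple[HalfProfile, HalfProfile]:
    """Split a profile at an arc position into two outward half profiles.

    The native sample nearest ``split_arc_um`` is the split point and is
    shared by neither half; the left half runs back toward ``d = 0`` and
    the right half onward, both with distance measured outward from the
    split.
    """
    h = profile.channel(constitutive)
    f = profile.channel(induced)
    dd = profile.delta_d_um
    L = profile.length_um
    if not 0 < split_arc_um < L:
        raise ValueError(f"split {split_arc_um} outside (0, {L})")
    k = int(round(split_arc_um / dd))
    k = min(max(k, 1), len(h) - 2)
    left = HalfProfile(h=h[k - 1 :: -1], f=f[k - 1 :: -1], delta_d=dd)
    right = HalfProfile(h=h[k + 1 :], f=f[k + 1 :], delta_d=dd)
    return left, right


def fraction_integral(half: HalfProfile) -> np.ndarray:
    """Fraction of the constitutive line integral at each native sample.

    Left-Riemann cumulative sum of H normalized by its final value; raises
    when the half carries no constitutive intensity (clock undefined).
    """
    hint = half.h_integral
    if hint[-1] <= 0:
        raise ValueError("clock undefined: zero constitutive integral on half")
    return hint / hint[-1]


def signal_from_half(half: HalfProfile, grid: np.ndarray) -> np.ndarray:
    """Decoded signal of one half on the uniform clock grid.

    Difference quotients dF_integral / dH_fraction_integral are formed on
    the native samples (values assigned to the right edge of each
    increment); samples with a zero clock increment are merged into the
    next nonzero increment; the result is linearly interpolated onto
    ``grid`` with constant extension at both ends.
    """
    if len(half.h) < 3:
        raise ValueError("need at least 3 native samples")
    hfrac = fraction_integral(half)
    fint = half.f_integral
    keep = np.nonzero(np.diff(hfrac, prepend=0.0) > 0)[0]
    if keep.size == 0:
        raise ValueError("clock has no increments")
    x = hfrac[keep]
    prev_f = np.concatenate([[0.0], fint[keep[:-1]]])
    prev_h = np.concatenate([[0.0], hfrac[keep[:-1]]])
    y = (fint[keep] - prev_f) / (x - prev_h)
    return np.interp(grid, x, y)


def optimal_split(
    profile: LineProfile,
    constitutive: str = "HA",
    induced: str = "FLAG",
    grid: np.ndarray | None = None,
    min_half_samples: int = 3,
    smooth_sd_samples: float | None = None,
) -> DecodedSignal:
    """Search the optimal split point and decode the profile.

    Every native sample position within +/-25% of the total length around
    the geometric center is a candidate split; for each, both half signals
    are computed on the shared clock grid and scored by their sum of
    squared differences.  The split with the least SSD wins (ties go to the
    candidate nearest the geometric center); the decoded signal is the
    point-by-point mean of the two half signals at that split.

    ``smooth_sd_samples`` optionally Gaussian-smooths the raw profiles
    before decoding (off by default; useful for sampling-noise-limited
    profiles such as raw monomer line densities, where it plays the role
    the optical blur plays for imaged filaments).
    """
    if grid is None:
        grid = fraction_grid()
    if smooth_sd_samples:
        profile = LineProfile(
            d_um=profile.d_um,
            intensities={
                k: gaussian_filter1d(v, smooth_sd_samples)
                for k, v in profile.intensities.items()
            },
            delta_d_um=profile.delta_d_um,
            cell_id=profile.cell_id,
            xri_id=profile.xri_id,
            meta=dict(profile.meta),
        )
    h = profile.channel(constitutive)
    if len(h) < 8:
        raise ValueError("profile too short (need >= 8 samples)")
    dd = profile.delta_d_um
    L = profile.length_um
    center = L / 2.0
    d = profile.d_um
    cand = np.nonzero((d >= center - 0.25 * L) & (d <= center + 0.25 * L))[0]
    cand = cand[(cand >= min_half_samples) & (cand <= len(h) - 1 - min_half_samples)]
    if cand.size == 0:
        raise ValueError("no admissible split candidates")
    best = None
    for k in cand:
        try:
            left, right = split_at(profile, d[k], constitutive, induced)
            sig_l = signal_from_half(left, grid)
            sig_r = signal_from_half(right, grid)
        except ValueError:
            continue
        ssd = float(np.sum((sig_l - sig_r) ** 2))
        key = (ssd, abs(d[k] - center), k)
        if best is None or key < best[0]:
            best = (key, k, sig_l, sig_r)
    if best is None:
        raise ValueError("all candidate splits invalid (zero-clock half)")
    _, k, sig_l, sig_r = best
    return DecodedSignal(
        grid=grid,
        f_signal=0.5 * (sig_l + sig_r),
        tag=induced,
        split_arc_um=float(d[k]),
        split_index=int(k),
        ssd=best[0][0],
        xri_id=profile.xri_id,
        cell_id=profile.cell_id,
    )


def baseline(signal: DecodedSignal, window: float = 0.05) -> float:
    """Signal level at the filament center: mean over clock <= ``window``.

    A narrow window replaces the single center sample for noise
    robustness.
    """
    mask = signal.grid <= window + 1e-12
    return float(np.mean(signal.f_signal[mask]))


def end_center_ratio(signal: DecodedSignal, window: float = 0.05) -> float:
    """Signal at the filament end over signal at the center.

    Means over the last and first ``window`` of the clock axis; ~1 for an
    uninduced filament, > 1 when induction happened before fixation.
    Raises on a nonpositive center value.
    """
    base = baseline(signal, window)
    if base <= 0:
        raise ValueError("nonpositive center value; ratio undefined")
    end = float(np.mean(signal.f_signal[signal.grid >= 1.0 - window - 1e-12]))
    return end / base


def relative_change(signal: DecodedSignal, window: float = 0.05) -> np.ndarray:
    """Pointwise (signal / center value) - 1; scale invariant."""
    base = baseline(signal, window)
    if base <= 0:
        raise ValueError("nonpositive center value; relative change undefined")
    return signal.f_signal / base - 1.0


def onset_fraction(
    signal: DecodedSignal,
    noise_floor_mult: float = 3.0,
    rel_floor: float = 0.75,
    baseline_window: float = 0.05,
) -> OnsetEstimate:
    """Clock fraction at which the induced signal begins to rise.

    The baseline-subtracted (net) signal must show a peak above a noise
    floor: ``noise_floor_mult`` times the standard deviation of the first
    baseline window, and at least ``rel_floor`` times the (positive)
    center level.  The second term flags uninduced controls as
    ``no-rise``: their decoded signal is a flat band of residual
    background whose maximum scales with the band level itself, while a
    genuine induction rises severalfold above the center level (set
    ``rel_floor=0`` to disable).  The
    initial rising phase is the contiguous run of grid samples immediately
    preceding the peak with net values between 10% and 50% of the peak; an
    ordinary least-squares line through that run is extrapolated to net =
    0, and its crossing is the onset.  Flags: ``no-rise``,
    ``too-few-points``, ``bad-fit``, ``out-of-range``.
    """
    base = baseline(signal, baseline_window)
    net = signal.f_signal - base
    first = net[signal.grid <= baseline_window + 1e-12]
    sd = float(np.std(first, ddof=1)) if len(first) > 1 else 0.0
    floor = max(
        noise_floor_mult * sd,
        rel_floor * max(base, 0.0),
        1e-9 * max(1.0, abs(base)),
    )
    ip = int(np.argmax(net))
    peak = float(net[ip])
    est = OnsetEstimate(baseline=base, peak=peak)
    if peak <= floor:
        est.flags.append("no-rise")
        return est
    lo, hi = 0.1 * peak, 0.5 * peak
    j = ip - 1
    while j >= 0 and net[j] > hi:
        j -= 1
    run_hi = j  # last index at or below 50% of peak, walking back from it
    while j >= 0 and lo <= net[j] <= hi:
        j -= 1
    run = np.arange(j + 1, run_hi + 1)
    if run.size < 2:
        est.flags.append("too-few-points")
        return est
    x = signal.grid[run]
    y = net[run]
    slope, intercept = np.polyfit(x, y, 1)
    est.slope = float(slope)
    est.intercept = float(intercept)
    if slope <= 0:
        est.flags.append("bad-fit")
        return est
    onset = -intercept / slope
    est.onset = float(onset)
    if not 0.0 <= onset <= 1.0:
        est.flags.append("out-of-range")
    return est
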