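# Methods

## Growth model

A recording filament is modeled as two independent growing ends ("minus"
and "plus" sides) nucleated at a center. Each tagged monomer species *s*
has a nonnegative incorporation rate `r_s(t)` (monomers·day⁻¹ per end).
Within a simulation step of width `dt` (default 0.01 day), the number of
monomers of species *s* added to one side is Poisson with mean
`r_s(t_mid)·dt`, drawn from a dedicated random stream per (chain, species
entry, side). Monomers are appended in program order then draw order;
the monomer with index *i* on a side sits at `(i + 0.5)·spacing` from the
center, with `spacing = 4 nm` fixed.

Per-species streams make the independence postulate — no competition
between species for incorporation — hold *by construction*: adding an
induced species to a program cannot perturb the constitutive species'
draws, so the cumulative constitutive trajectory is bit-identical with or
without induction. Because total line density is fixed at `1/spacing`,
induced monomers dilute the constitutive line density exactly as the
rate ratio dictates, which is the physical basis of the clock.

Rate laws:

- constitutive: `constant` (r₀), `linear` (r₀·(1 + a·(t−T_start))), or
  `exponential` (r₀·eᵃᵗ, the default with a = 0.3 day⁻¹ — expression from
  a viral vector keeps accelerating slowly over the first week);
- induced: `step` (amplitude from the induction time onward; models a
  chemically induced recombinase that stays active) or `alpha`
  (difference-of-exponentials pulse, rise 0.1 day, decay 1 day by default;
  models an immediate-early-gene response to a brief stimulus).

Recording starts abruptly at `T_start` (default day 3): the filament
stabilization phase before `T_start` is summarized entirely by that hard
start, and nothing incorporated earlier is modeled.

The ground-truth onset fraction for an induced species at `T_induce` is
`C(T_induce)/C(T_fix)` with `C(t)` the integral of the constitutive rate
from `T_start`, evaluated by the midpoint rule on the `dt` grid.

## Synthetic imaging

Chains are laid along a smooth arc-length-parameterized curve (chain
center at the curve midpoint, physical scale 1 µm of curve per µm of
chain), each monomer depositing unit mass bilinearly on a 0.1 µm pixel
grid. Rendering convolves with an isotropic Gaussian PSF (σ = 0.15 µm,
truncated at 6σ so point masses conserve integral to <10⁻⁶), multiplies by
a per-channel gain (20 counts/monomer), adds a constant background
(10 counts), then draws Poisson shot noise plus Gaussian read noise
(σ = 1 count). Rendering is 2D — a single in-plane slice — because the
decoder consumes 1D profiles regardless. Uninduced scenarios still render
the induced staining channel as pure background, as an uninduced
immunostain would appear.

Scenario fixtures mirror the study designs: timed step inductions on day
k (k = 1…6) of a 7-day window, an uninduced control, single and dual
alpha-pulse inductions (days 5, or 5 and 6; the dual-pulse kernels use a
0.4-day decay so pulses one day apart stay resolvable, matching the
briefer stimulations of that design), and a 14-day design with induction
on day 10. Constitutive r₀ = 100 day⁻¹·side⁻¹ for 7-day scenarios
(≈2,000 monomers/side, ≈8 µm half-length) and 10 day⁻¹·side⁻¹ for the
14-day scenario; step amplitude 100, pulse amplitude 300. Every fixture
writes a truth manifest (chain files, true centerline in pixels, induction
times, expected onset fractions) so downstream stages are scored by
parameter recovery. Identical seeds reproduce fixtures byte for byte.

What the generator does *not* emulate: 3D volumetric PSFs, chromatic
shifts, nonuniform or structured background (e.g. nonspecific antibody
binding localized to the filament or soma), filament curvature in z,
antibody saturation, and expression delays between an induction event and
monomer availability. Passing recovery tests therefore demonstrate the
correctness of the readout mathematics under a faithful but simplified
imaging model, not robustness to every artifact of real confocal data.

## Profile measurement

Centerlines are polylines in 0-based pixel coordinates, drawn manually
(CSV input) or traced automatically (Otsu threshold → connected component
at a seed → skeleton → longest geodesic path → moving-average smoothing).
The filament width is the median FWHM of background-subtracted
perpendicular cuts through the constitutive channel; profiles average
bilinear samples across a perpendicular breadth of *half* that width, at
an arc step equal to the pixel size. Within one soma, the longest filament
plus any filament strictly longer than half of it is kept for analysis
(ties at exactly half are excluded). Constant background (default: 1st
percentile of the channel image; median also available) is subtracted
before integration and profiles clipped at zero; pass `background=None`
for raw intensities.

## Decoding

Integrals are left-Riemann sums on the native samples, exactly as defined
above; the derivative signal uses right-edge difference quotients with
zero-clock-increment samples merged into the next nonzero increment, then
linear interpolation onto a uniform 201-point grid on [0, 1]. The split
search evaluates every native sample position within ±25% of the filament
length around the geometric center, excluding the split sample from both
halves (first half sample at Δd/2); the SSD objective is evaluated on raw
(not normalized) half signals, and ties go to the candidate nearest the
geometric center. Baseline ("signal at the center") and end values use 5%
windows of the clock axis rather than single grid points.

Two pre-decoding trims are applied by the imaging pipeline
(`pipeline.analyze_stack`), not by the decoder itself:

- *support trim*: samples where the constitutive intensity falls below
  20% of its median over the centerline are dropped from the profile ends
  (a hand-drawn centerline would end where the filament visibly ends);
- *tip trim*: a further 0.3 µm (~2 PSF σ) is dropped from each end.
  Within the blur zone the measured constitutive signal decays while any
  residual induced background does not, so the clock increment shrinks
  faster than the induced increment and the decoded signal spuriously
  inflates near fraction 1. Without this trim the uninduced cohort's
  end/center ratio averages ≈1.09; with it, ≈0.97.

Optional Gaussian pre-smoothing of the raw profiles is off by default in
the decoder (all analytic results hold without it) and set to σ = 1.5
samples by the imaging pipeline, a measured bias/variance compromise:
smoothing widens the rising edge of a step response, and because the
10–50% rising-phase chord of a blurred edge extrapolates to zero about
1.2 blur widths before the edge center, onset estimates carry a small
negative bias proportional to (blur width)/(half length) — about −0.03 on
the default fixtures. The cohort calibration absorbs any bias shared
across cohorts.

Onset estimation requires the baseline-subtracted signal's peak to exceed
both 3× the s.d. of the first 5% window and 75% of the (positive) center
level. The second, relative criterion is what actually separates
uninduced controls from inductions on imaged data: a control's decoded
signal is a flat band of residual background whose maximum scales with the
band level (measured net-peak/center ≤ 0.46 across controls), while
genuine inductions rise severalfold (≥ 1.84 across all induced fixtures).
Set `rel_floor=0` to disable. The rising phase is the contiguous run of
grid samples immediately preceding the global peak with net values in
[0.1, 0.5]× peak; estimates with fewer than 2 run points, nonpositive
slope, or an onset outside [0, 1] are flagged, never silently reported.

## Calibration

One knot per induction-time cohort at (time, mean onset fraction of
unflagged estimates; median optional), the terminal anchor (T_fix, 1), and
by default the origin anchor (T_start, 0). Knots must be strictly
increasing in both coordinates. Interpolation is piecewise linear; outside
the knot span the terminal segment extends linearly and is clamped to
[T_start, T_fix] × [0, 1]. A cohort whose induction coincides with
`T_start` yields no rise to detect (the induced signal is elevated from
the center on); it is excluded by the preconditions, and its information
is exactly the origin anchor. Calibrated traces are resampled to a uniform
0.05-day grid for cohort averaging.

## Statistics

Group comparisons use Kruskal–Wallis (identical data across groups is
reported as statistic 0, p = 1), post hoc Dunn z tests on pooled
tie-corrected ranks (all pairs, or versus a named control group) with p
values reported both raw and Holm-adjusted, and the two-sided Wilcoxon
rank-sum test for two groups (exact where sample sizes permit). Summary
bands are pointwise mean, s.d. (n−1), and s.e.m.; traces can be
peak-normalized before averaging, and flagged decodes are excluded and
counted.

## Problem sizes

The validation suite uses 20 filaments per timed-induction condition,
100 for the uninduced control, 15 per calibration cohort, 12 for the
dual-pulse design, 30 center-aligned chains for noise-free decoder
recovery, and 200 chains for the independence check — sizes comparable to
the per-group filament counts of the experiments the scenarios emulate,
at which cohort means are stable to well within the tolerances tested.

## Known limitations

- Single induced channel per decode; multiplexed tags are run per channel.
- The onset estimator's blur bias (above) is uncorrected by design — the
  estimator is kept exactly as defined; calibration compensates in
  time-recovery applications.
- The piecewise-linear calibration does not extrapolate before the first
  cohort except through the origin anchor.
- Automatic tracing assumes a single, non-branching, supra-threshold
  filament at the seed; it is a convenience for synthetic fixtures, with
  manual centerlines remaining first-class input.
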