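"""Synthetic multichannel microscopy of simulated recording filaments.

Renders a :class:`~xrikit.forward_model.MonomerChain` laid out along a
smooth curve into a diffraction-limited multichannel image: each monomer is
a unit point emitter in the channel of its tag, blurred by an isotropic
Gaussian point-spread function, scaled by a per-channel gain, offset by a
constant background and corrupted by Poisson shot noise plus Gaussian read
noise.  A truth manifest (chain reference, centerline, induction times and
expected onset fractions) is written alongside every fixture so the
extraction and decoding stages can be scored by parameter recovery.

The imaging parameters are engineering choices for a plausible confocal
setting (0.1 um pixels, 0.15 um PSF sigma, counts-scale gains); rendering
is 2D, a single in-plane slice, because the decoder consumes 1D profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import interpolate, ndimage

from .forward_model import (
    GrowthParams,
    MonomerChain,
    SpeciesProgram,
    expected_onset_fraction,
    save_chains,
    simulate_chain,
)
from .profile_io import Centerline, ImageStack, write_centerlines, write_image

__all__ = [
    "OpticsParams",
    "CenterlineSpec",
    "layout_chain",
    "render",
    "make_fixture",
    "SCENARIOS",
    "scenario_program",
]

DEFAULT_GAINS = {"HA": 20.0, "FLAG": 20.0, "V5": 20.0}


@dataclass(frozen=True)
class OpticsParams:
    """Imaging forward-model parameters.

    ``psf_sigma_um`` is the standard deviation of the Gaussian PSF;
    ``gains`` are intensity counts per monomer per channel; ``background``
    is the mean count added to every pixel before the noise draw;
    ``read_noise_sd`` the Gaussian read-noise standard deviation in counts.
    Set ``shot_noise=False`` and ``read_noise_sd=0`` for noiseless
    expectation images.
    """

    pixel_size_um: float = 0.1
    psf_sigma_um: float = 0.15
    gains: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))
    background: float = 10.0
    read_noise_sd: float = 1.0
    shot_noise: bool = True
    shape: tuple[int, int] = (64, 256)  # (ny, nx) pixels

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.psf_sigma_um < 0:
            raise ValueError("psf_sigma_um must be nonnegative")
        if any(g < 0 for g in self.gains.values()):
            raise ValueError("gains must be nonnegative")


class CenterlineSpec:
    """Arc-length-parameterized smooth curve in micrometer coordinates.

    Built from control points through a cubic (or lower-order) spline and
    densely resampled, so positions at any arc length are available by
    interpolation.
    """

    def __init__(self, control_points_um: np.ndarray, n_dense: int = 2000):
        pts = np.asarray(control_points_um, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("control_points_um must be (n>=2, 2)")
        k = min(3, len(pts) - 1)
        tck, _ = interpolate.splprep([pts[:, 0], pts[:, 1]], s=0, k=k)
        u = np.linspace(0, 1, n_dense)
        x, y = interpolate.splev(u, tck)
        self._xy = np.column_stack([x, y])
        seg = np.diff(self._xy, axis=0)
        self._arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def length_um(self) -> float:
        return float(self._arc[-1])

    def point_at_arc(self, s: np.ndarray | float) -> np.ndarray:
        """(x, y) in um at arc length(s) ``s`` from the curve start."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        x = np.interp(s, self._arc, self._xy[:, 0])
        y = np.interp(s, self._arc, self._xy[:, 1])
        return np.column_stack([x, y])

    @staticmethod
    def straight(length_um: float, center_um: tuple[float, float], angle_deg: float = 0.0):
        ang = np.deg2rad(angle_deg)
        d = np.array([np.cos(ang), np.sin(ang)])
        c = np.asarray(center_um, dtype=float)
        pts = c + np.outer(np.linspace(-0.5, 0.5, 5) * length_um, d)
        return CenterlineSpec(pts)

    @staticmethod
    def bowed(length_um: float, center_um: tuple[float, float], bow_um: float = 0.8):
        """Horizontal curve with a gentle sinusoidal bow (non-self-intersecting)."""
        cx, cy = center_um
        x = cx + np.linspace(-0.5, 0.5, 9) * length_um
        y = cy + bow_um * np.sin(np.linspace(0, np.pi, 9))
        return CenterlineSpec(np.column_stack([x, y]))


def layout_chain(
    chain: MonomerChain,
    curve: CenterlineSpec,
    optics: OpticsParams,
    scale: float = 1.0,
    channel_of_tag: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Deposit monomer point masses along the curve onto the pixel grid.

    The chain's nucleation center maps to the curve's arc midpoint; the
    plus side extends toward increasing arc.  ``scale`` is micrometers of
    curve per micrometer of physical chain (1 = physical size).  Returns a
    per-channel 2D array of deposited mass (monomer counts, bilinearly
    split over the four neighboring pixels); total mass per channel equals
    the monomer count of that tag.
    """
    extent_um = chain.extent_nm() * 1e-3 * scale
    if extent_um > curve.length_um:
        raise ValueError(
            f"chain ({extent_um:.2f} um) longer than curve ({curve.length_um:.2f} um)"
        )
    channel_of_tag = channel_of_tag or {}
    ny, nx = optics.shape
    mid = curve.length_um / 2.0
    out: dict[str, np.ndarray] = {}
    for tag in sorted(chain.tags_present()):
        pos_um = chain.signed_positions(tag) * 1e-3 * scale
        xy = curve.point_at_arc(mid + pos_um)
        px = xy[:, 0] / optics.pixel_size_um
        py = xy[:, 1] / optics.pixel_size_um
        img = np.zeros((ny, nx))
        x0 = np.floor(px).astype(int)
        y0 = np.floor(py).astype(int)
        fx = px - x0
        fy = py - y0
        for dy in (0, 1):
            for dx in (0, 1):
                w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
                xs = np.clip(x0 + dx, 0, nx - 1)
                ys = np.clip(y0 + dy, 0, ny - 1)
                np.add.at(img, (ys, xs), w)
        out[channel_of_tag.get(tag, tag)] = img
    return out


def render(
    densities: Mapping[str, np.ndarray],
    optics: OpticsParams,
    seed: int | np.random.Generator,
) -> ImageStack:
    """PSF-blur, scale, offset and noise-corrupt per-channel densities.

    image = PSF(sigma) * (gain * density) + background, then a Poisson draw
    plus Gaussian read noise; channels are rendered independently.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sigma_px = optics.psf_sigma_um / optics.pixel_size_um
    channels: dict[str, np.ndarray] = {}
    for role, dens in densities.items():
        gain = optics.gains.get(role, 1.0)
        expected = gain * np.asarray(dens, dtype=float)
        if sigma_px > 0:
            expected = ndimage.gaussian_filter(expected, sigma_px, truncate=6.0)
        expected = expected + optics.background
        if optics.shot_noise:
            img = rng.poisson(np.clip(expected, 0, None)).astype(float)
        else:
            img = expected
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        channels[role] = img
    return ImageStack(channels=channels, pixel_size_um=optics.pixel_size_um)


# ---------------------------------------------------------------------------
# scenario fixtures

def _seven_day_params() -> GrowthParams:
    return GrowthParams(t_start=3.0, t_fix=7.0)


def _ha_constitutive(rate0: float = 100.0, accel: float = 0.3) -> SpeciesProgram:
    return SpeciesProgram(
        tag="HA", kind="constitutive", rate0=rate0,
        acceleration="exponential", accel=accel,
    )


def scenario_program(name: str) -> tuple[list[SpeciesProgram], GrowthParams]:
    """Growth program and parameters for a named experimental scenario.

    Scenarios mirror the study designs: timed chemical induction on day k
    of a 7-day culture experiment (persistent, step-kernel expression of a
    FLAG-tagged species), an uninduced control, activity-driven V5 pulses
    (alpha kernel) on day 5 or on days 5 and 6, and a 14-day scenario with
    induction on day 10.
    """
    if name in SCENARIOS:
        return SCENARIOS[name]()
    raise ValueError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")


def _induction_day(k: int):
    def build():
        program = [
            _ha_constitutive(),
            SpeciesProgram(
                tag="FLAG", kind="induced", rate0=100.0,
                t_induce=float(k), kernel="step",
            ),
        ]
        return program, _seven_day_params()

    return build


def _no_induction():
    return [_ha_constitutive()], _seven_day_params()


def _cfos_single():
    program = [
        _ha_constitutive(),
        SpeciesProgram(
            tag="V5", kind="induced", rate0=300.0, t_induce=5.0,
            kernel="alpha", tau_rise=0.1, tau_decay=1.0,
        ),
    ]
    return program, _seven_day_params()


def _cfos_double():
    program = [
        _ha_constitutive(),
        SpeciesProgram(
            tag="V5", kind="induced", rate0=300.0, t_induce=5.0,
            kernel="alpha", tau_rise=0.1, tau_decay=0.4,
        ),
        SpeciesProgram(
            tag="V5", kind="induced", rate0=300.0, t_induce=6.0,
            kernel="alpha", tau_rise=0.1, tau_decay=0.4,
        ),
    ]
    return program, _seven_day_params()


def _invivo():
    program = [
        _ha_constitutive(rate0=10.0),
        SpeciesProgram(
            tag="FLAG", kind="induced", rate0=100.0, t_induce=10.0, kernel="step",
        ),
    ]
    return program, GrowthParams(t_start=3.0, t_fix=14.0)


SCENARIOS = {
    **{f"induction-day-{k}-of-7": _induction_day(k) for k in range(1, 7)},
    "no-induction": _no_induction,
    "cfos-single-pulse-day5": _cfos_single,
    "cfos-two-pulse-day5-day6": _cfos_double,
    "invivo-day10-of-14": _invivo,
}


def _scenario_truth(program, params) -> tuple[list[float], list[float]]:
    """Induction times and expected onset fractions (clipped to the window)."""
    times, fracs = [], []
    cons = [p for p in program if p.kind == "constitutive"]
    for sp in program:
        if sp.kind != "induced":
            continue
        times.append(float(sp.t_induce))
        t_eff = float(np.clip(sp.t_induce, params.t_start, params.t_fix))
        probe = [cons[0], SpeciesProgram(
            tag=sp.tag, kind="induced", rate0=sp.rate0, t_induce=t_eff,
            kernel=sp.kernel, tau_rise=sp.tau_rise, tau_decay=sp.tau_decay,
        )]
        fracs.append(expected_onset_fraction(probe, params))
    return times, fracs


def make_fixture(
    scenario: str,
    seed: int,
    out_dir,
    n_chains: int = 20,
    optics: OpticsParams | None = None,
) -> dict:
    """Simulate, lay out and render ``n_chains`` filaments for a scenario.

    Writes per-chain multipage TIFFs, a centerline CSV (true centerlines
    with a nominal PSF-limited width), the simulated chains as JSON, and a
    ``manifest.json`` holding the ground truth per rendered filament.
    Image width is sized per chain; the centerline is the rendering curve
    restricted to the chain span plus a 2-sigma PSF margin.  All
    randomness derives from ``seed``.  Returns the manifest dict.
    """
    program, params = scenario_program(scenario)
    base = optics or OpticsParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), 0xF1B])
    times, fracs = _scenario_truth(program, params)
    channel_map = sorted({p.tag for p in program})
    if not any(p.kind == "induced" for p in program):
        # uninduced controls are still stained in the induced channel:
        # it images as pure background
        channel_map = sorted(set(channel_map) | {"FLAG"})
    entries = []
    chains = []
    centerlines = []
    width_nominal = 2.0 * np.sqrt(2.0 * np.log(2.0)) * base.psf_sigma_um  # PSF FWHM
    for i in range(n_chains):
        chain = simulate_chain(program, params, seed, chain_index=i)
        chains.append(chain)
        extent = chain.extent_nm() * 1e-3
        span = extent * 1.08 + 3.0
        nx = int(np.ceil(span / base.pixel_size_um / 16.0)) * 16
        ny = base.shape[0]
        optics_i = OpticsParams(
            pixel_size_um=base.pixel_size_um,
            psf_sigma_um=base.psf_sigma_um,
            gains=dict(base.gains),
            background=base.background,
            read_noise_sd=base.read_noise_sd,
            shot_noise=base.shot_noise,
            shape=(ny, nx),
        )
        center = (nx * base.pixel_size_um / 2.0, ny * base.pixel_size_um / 2.0)
        bow = float(rng.uniform(0.4, 1.0))
        curve = CenterlineSpec.bowed(extent * 1.02 + 2.0, center, bow_um=bow)
        densities = layout_chain(chain, curve, optics_i)
        for ch in channel_map:
            densities.setdefault(ch, np.zeros(optics_i.shape))
        stack = render(densities, optics_i, np.random.default_rng([int(seed), 1 + i]))
        img_name = f"chain_{i:03d}.tif"
        write_image(stack, out_dir / img_name, channel_order=channel_map)
        # true centerline over the chain span (+ PSF margin), in pixels
        mid = curve.length_um / 2.0
        margin = 2.0 * base.psf_sigma_um
        minus_ext = len(chain.side("minus")) * chain.spacing_nm * 1e-3
        plus_ext = len(chain.side("plus")) * chain.spacing_nm * 1e-3
        arcs = np.linspace(
            max(0.0, mid - minus_ext - margin),
            min(curve.length_um, mid + plus_ext + margin),
            max(int(extent / 0.5), 8),
        )
        verts_um = curve.point_at_arc(arcs)
        cl = Centerline(
            vertices=verts_um / base.pixel_size_um,
            width_um=width_nominal,
            cell_id=f"cell{i:03d}",
            xri_id="xri0",
        )
        centerlines.append(cl)
        entries.append(
            {
                "image": img_name,
                "chain_index": i,
                "cell_id": cl.cell_id,
                "xri_id": cl.xri_id,
                "centerline_px": cl.vertices.tolist(),
                "width_um": width_nominal,
                "induction_times": times,
                "expected_onset_fractions": fracs,
                "channel_map": {name: j for j, name in enumerate(channel_map)},
            }
        )
    save_chains(out_dir / "chains.json", chains, program, params)
    write_centerlines(centerlines, out_dir / "centerlines.csv")
    manifest = {
        "scenario": scenario,
        "seed": int(seed),
        "n_chains": n_chains,
        "t_start": params.t_start,
        "t_fix": params.t_fix,
        "pixel_size_um": base.pixel_size_um,
        "optics": {
            **{k: v for k, v in asdict(base).items() if k != "gains"},
            "gains": dict(base.gains),
        },
        "entries": entries,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
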