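"""Stochastic forward model of bidirectional recording-filament growth.

An expression recording island (XRI) is an intracellular protein filament
that elongates at both ends by incorporating epitope-tagged monomers as they
are synthesized.  Monomers carrying a constitutively expressed tag (HA by
convention) are incorporated at a slowly accelerating rate beginning at
``T_start`` (filament stabilization, ~3 days after gene delivery), while
monomers carrying an induced tag (FLAG or V5) are incorporated only after an
induction event.  The central modeling postulate is *independence*: species
do not compete for incorporation, so adding an induced species never changes
the incorporation rate of the constitutive species — induced monomers merely
space the constitutive ones further apart along the filament.

Each growing end is modeled as an independent marked Poisson process: within
a time step of width ``dt``, the number of monomers of species *s* added to
one side is Poisson with mean ``r_s(t) * dt``, drawn from a per-species
random stream so that the independence postulate holds by construction.
Monomer-to-monomer spacing along the filament is fixed (~4 nm), so the
spatial order of tags is a faithful record of the temporal order of
incorporation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SpeciesProgram",
    "GrowthParams",
    "MonomerChain",
    "simulate_chain",
    "simulate_chains",
    "expected_onset_fraction",
    "cumulative_constitutive",
    "chain_density",
    "save_chains",
    "load_chains",
]

SIDES = ("minus", "plus")


@dataclass(frozen=True)
class SpeciesProgram:
    """Incorporation-rate program for one tagged monomer species.

    Parameters
    ----------
    tag :
        Epitope label (``"HA"``, ``"FLAG"``, ``"V5"`` or user defined).
    kind :
        ``"constitutive"`` (always on after ``T_start``) or ``"induced"``
        (on after the induction event at ``t_induce``).
    rate0 :
        Base rate (constitutive) or amplitude (induced), in monomers per
        day per growing end.
    acceleration :
        Constitutive rate shape: ``"constant"`` (r0), ``"linear"``
        (r0 * (1 + a*(t - T_start))) or ``"exponential"`` (r0 * exp(a*t)).
    accel :
        Acceleration constant ``a`` in 1/day.
    t_induce :
        Induction time in days (induced species only).
    kernel :
        Induced rate shape: ``"step"`` (rate0 from induction onwards, e.g.
        a chemically induced Cre that stays on) or ``"alpha"`` (transient
        pulse with exponential rise/decay, e.g. an immediate-early-gene
        response to a brief stimulus).
    tau_rise, tau_decay :
        Rise and decay constants of the alpha pulse, days.
    """

    tag: str
    kind: str = "constitutive"
    rate0: float = 100.0
    acceleration: str = "exponential"
    accel: float = 0.3
    t_induce: float | None = None
    kernel: str = "step"
    tau_rise: float = 0.1
    tau_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constitutive", "induced"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.rate0 < 0:
            raise ValueError("rate0 must be nonnegative")
        if self.kind == "constitutive" and self.acceleration not in (
            "constant",
            "linear",
            "exponential",
        ):
            raise ValueError(f"unknown acceleration {self.acceleration!r}")
        if self.kind == "induced":
            if self.t_induce is None:
                raise ValueError("induced species requires t_induce")
            if self.kernel not in ("step", "alpha"):
                raise ValueError(f"unknown kernel {self.kernel!r}")
            if self.tau_rise <= 0 or self.tau_decay <= 0:
                raise ValueError("alpha time constants must be positive")

    def rate(self, t: np.ndarray | float, t_start: float) -> np.ndarray:
        """Incorporation rate r_s(t) in monomers/day per growing end."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constitutive":
            if self.acceleration == "constant":
                r = np.full_like(t, self.rate0)
            elif self.acceleration == "linear":
                r = self.rate0 * np.clip(1.0 + self.accel * (t - t_start), 0.0, None)
            else:  # exponential
                r = self.rate0 * np.exp(self.accel * t)
            return np.where(t >= t_start, r, 0.0)
        onset = max(t_start, float(self.t_induce))
        s = t - onset
        if self.kernel == "step":
            r = np.full_like(t, self.rate0)
        else:
            # difference-of-exponentials pulse, normalized to unit peak
            t_peak = (
                np.log(self.tau_decay / self.tau_rise)
                / (1.0 / self.tau_rise - 1.0 / self.tau_decay)
            )
            peak = np.exp(-t_peak / self.tau_decay) - np.exp(-t_peak / self.tau_rise)
            g = np.exp(-np.clip(s, 0, None) / self.tau_decay) - np.exp(
                -np.clip(s, 0, None) / self.tau_rise
            )
            r = self.rate0 * g / peak
        return np.where(t >= onset, r, 0.0)


@dataclass(frozen=True)
class GrowthParams:
    """Global growth-experiment parameters.

    ``t_start`` is the day the filament stabilizes and starts recording,
    ``t_fix`` the fixation day (growth stops), ``monomer_spacing_nm`` the
    fixed longitudinal monomer-to-monomer distance, and ``dt`` the
    simulation step in days.  Growth is bidirectional (two sides).
    """

    t_start: float = 3.0
    t_fix: float = 7.0
    monomer_spacing_nm: float = 4.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.t_start < self.t_fix:
            raise ValueError("need 0 <= t_start < t_fix")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.monomer_spacing_nm <= 0:
            raise ValueError("monomer_spacing_nm must be positive")


@dataclass
class ChainSide:
    """Ordered monomers on one side of the nucleation center."""

    tags: list[str] = field(default_factory=list)
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __len__(self) -> int:
        return len(self.tags)


@dataclass
class MonomerChain:
    """A simulated filament: time-ordered tagged monomers on two sides.

    The monomer with (0-based) index ``i`` on a side sits at distance
    ``(i + 0.5) * spacing`` nm from the nucleation center along that side.
    """

    sides: dict[str, ChainSide]
    spacing_nm: float = 4.0

    def side(self, name: str) -> ChainSide:
        return self.sides[name]

    @property
    def n_monomers(self) -> int:
        return sum(len(s) for s in self.sides.values())

    def tags_present(self) -> set[str]:
        out: set[str] = set()
        for s in self.sides.values():
            out.update(s.tags)
        return out

    def positions(self, side: str, tag: str | None = None) -> np.ndarray:
        """Distances (nm, positive) of monomers from the center on a side."""
        s = self.sides[side]
        idx = np.arange(len(s), dtype=float)
        if tag is not None:
            mask = np.asarray([t == tag for t in s.tags], dtype=bool)
            idx = idx[mask]
        return (idx + 0.5) * self.spacing_nm

    def signed_positions(self, tag: str | None = None) -> np.ndarray:
        """Signed positions (nm) across both sides; minus side negative."""
        neg = -self.positions("minus", tag)
        pos = self.positions("plus", tag)
        return np.concatenate([neg[::-1], pos])

    def extent_nm(self) -> float:
        """Tip-to-tip physical length of the chain."""
        return self.n_monomers * self.spacing_nm

    def count(self, tag: str) -> int:
        return sum(sum(1 for t in s.tags if t == tag) for s in self.sides.values())


def _species_rng(seed: int, chain_index: int, tag: str) -> np.random.Generator:
    # fixed per-(chain, species) stream: adding a species can never perturb
    # the draws of another, which realizes the no-competition postulate
    return np.random.default_rng(
        [int(seed), int(chain_index), zlib.crc32(tag.encode()) & 0x7FFFFFFF]
    )


def simulate_chain(
    program: Sequence[SpeciesProgram],
    params: GrowthParams,
    seed: int,
    chain_index: int = 0,
) -> MonomerChain:
    """Simulate one bidirectional chain.

    Per time step of width ``dt``, per side, per species, the number of
    incorporated monomers is Poisson with mean ``r_s(t_mid) * dt``, drawn
    independently across species.  Within a step, monomers are appended in
    program order then draw order.  Identical ``(program, params, seed,
    chain_index)`` give identical chains.
    """
    if len(program) == 0:
        raise ValueError("program must contain at least one species")
    if params.dt >= params.t_fix - params.t_start:
        raise ValueError("dt must be smaller than the recording window")
    tags = [p.tag + "/" + p.kind + str(i) for i, p in enumerate(program)]
    if len(set(tags)) != len(tags):  # pragma: no cover - defensive
        raise ValueError("duplicate species entries")

    n_steps = int(np.ceil((params.t_fix - params.t_start) / params.dt))
    edges = params.t_start + params.dt * np.arange(n_steps + 1)
    edges[-1] = params.t_fix
    widths = np.diff(edges)
    mids = 0.5 * (edges[:-1] + edges[1:])

    sides: dict[str, ChainSide] = {}
    for side_i, side_name in enumerate(SIDES):
        all_times: list[np.ndarray] = []
        all_tags: list[np.ndarray] = []
        all_step: list[np.ndarray] = []
        all_order: list[np.ndarray] = []
        for order, sp in enumerate(program):
            # distinct stream per (species entry, side)
            rng = _species_rng(seed, chain_index, f"{sp.tag}#{order}#{side_name}")
            lam = sp.rate(mids, params.t_start) * widths
            counts = rng.poisson(lam)
            total = int(counts.sum())
            if total == 0:
                continue
            step_idx = np.repeat(np.arange(n_steps), counts)
            all_times.append(mids[step_idx])
            all_tags.append(np.full(total, sp.tag, dtype=object))
            all_step.append(step_idx)
            all_order.append(np.full(total, order))
        if all_times:
            times = np.concatenate(all_times)
            tag_arr = np.concatenate(all_tags)
            key = np.lexsort(
                (np.concatenate(all_order), np.concatenate(all_step))
            )
            sides[side_name] = ChainSide(
                tags=list(tag_arr[key]), times=times[key]
            )
        else:
            sides[side_name] = ChainSide()
    return MonomerChain(sides=sides, spacing_nm=params.monomer_spacing_nm)


def simulate_chains(
    program: Sequence[SpeciesProgram],
    params: GrowthParams,
    seed: int,
    n_chains: int,
) -> list[MonomerChain]:
    """Simulate ``n_chains`` chains on derived per-chain streams."""
    return [
        simulate_chain(program, params, seed, chain_index=i) for i in range(n_chains)
    ]


def _constitutive_species(program: Sequence[SpeciesProgram]) -> SpeciesProgram:
    cons = [p for p in program if p.kind == "constitutive"]
    if len(cons) != 1:
        raise ValueError("program must contain exactly one constitutive species")
    return cons[0]


def cumulative_constitutive(
    program: Sequence[SpeciesProgram], params: GrowthParams
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative expected constitutive count C(t) on the dt grid.

    Returns ``(t_edges, C)`` with ``C[0] = 0`` at ``t_start``; midpoint rule.
    """
    cons = _constitutive_species(program)
    n_steps = int(np.ceil((params.t_fix - params.t_start) / params.dt))
    edges = params.t_start + params.dt * np.arange(n_steps + 1)
    edges[-1] = params.t_fix
    widths = np.diff(edges)
    mids = 0.5 * (edges[:-1] + edges[1:])
    c = np.concatenate([[0.0], np.cumsum(cons.rate(mids, params.t_start) * widths)])
    return edges, c


def expected_onset_fraction(
    program: Sequence[SpeciesProgram], params: GrowthParams
) -> float:
    """Ground-truth fraction of cumulative constitutive expression at induction.

    For a program with exactly one constitutive and one induced species,
    returns ``C(T_induce) / C(T_fix)`` where ``C`` integrates the
    constitutive rate from ``T_start``.  This is the value the decoder's
    onset estimate targets: because spacing is fixed and species are
    independent, the fraction of the constitutive line integral at a
    position equals the fraction of cumulative constitutive expression at
    the time that position was the growing tip.
    """
    induced = [p for p in program if p.kind == "induced"]
    if len(induced) != 1:
        raise ValueError("program must contain exactly one induced species")
    t_induce = float(induced[0].t_induce)
    if not params.t_start <= t_induce <= params.t_fix:
        raise ValueError(
            f"t_induce={t_induce} outside [{params.t_start}, {params.t_fix}]"
        )
    edges, c = cumulative_constitutive(program, params)
    if c[-1] <= 0:
        raise ValueError("constitutive species has zero cumulative rate")
    return float(np.interp(t_induce, edges, c) / c[-1])


def time_to_true_fraction(
    program: Sequence[SpeciesProgram], params: GrowthParams, t: np.ndarray | float
) -> np.ndarray:
    """Map time(s) to the true fraction of cumulative constitutive expression."""
    edges, c = cumulative_constitutive(program, params)
    return np.interp(np.asarray(t, dtype=float), edges, c / c[-1])


def chain_density(
    chain: MonomerChain, tag: str, bin_width_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Line density of one tag along the chain.

    Returns ``(bin_centers_nm, density)`` where density is monomer count per
    unit ``bin_width_nm`` of signed position (minus side negative).  The
    total ``sum(density) * bin_width_nm`` equals the monomer count of the
    tag; bins are aligned so that 0 is a bin edge.
    """
    if bin_width_nm <= 0:
        raise ValueError("bin_width_nm must be positive")
    if tag not in chain.tags_present():
        raise ValueError(f"tag {tag!r} not present in chain")
    pos = chain.signed_positions(tag)
    lo = -len(chain.side("minus")) * chain.spacing_nm
    hi = len(chain.side("plus")) * chain.spacing_nm
    n_lo = int(np.ceil(max(0.0, -lo) / bin_width_nm))
    n_hi = int(np.ceil(max(0.0, hi) / bin_width_nm))
    n_hi = max(n_hi, 1)
    edges = bin_width_nm * np.arange(-n_lo, n_hi + 1)
    counts, _ = np.histogram(pos, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / bin_width_nm


# ---------------------------------------------------------------------------
# chain file I/O

def save_chains(
    path,
    chains: Sequence[MonomerChain],
    program: Sequence[SpeciesProgram],
    params: GrowthParams,
) -> None:
    """Write chains to JSON with the generating program echoed in a header."""
    payload = {
        "program": [asdict(p) for p in program],
        "params": asdict(params),
        "chains": [
            {
                side: {
                    "tags": list(chain.side(side).tags),
                    "addition_times": np.asarray(chain.side(side).times).tolist(),
                }
                for side in SIDES
            }
            for chain in chains
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_chains(path):
    """Read chains written by :func:`save_chains`.

    Returns ``(chains, program, params)``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    program = [SpeciesProgram(**p) for p in payload["program"]]
    params = GrowthParams(**payload["params"])
    chains = []
    for entry in payload["chains"]:
        sides = {
            side: ChainSide(
                tags=list(entry[side]["tags"]),
                times=np.asarray(entry[side]["addition_times"], dtype=float),
            )
            for side in SIDES
        }
        chains.append(MonomerChain(sides=sides, spacing_nm=params.monomer_spacing_nm))
    return chains, program, params
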