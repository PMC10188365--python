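"""Shared fixtures and profile builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from xrikit.forward_model import GrowthParams, SpeciesProgram
from xrikit.profile_io import LineProfile


def make_profile(h, f, delta_d=1.0, **kw) -> LineProfile:
    """LineProfile from raw HA/FLAG sample arrays (uniform arc grid)."""
    h = np.asarray(h, dtype=float)
    return LineProfile(
        d_um=delta_d * np.arange(len(h)),
        intensities={"HA": h, "FLAG": np.asarray(f, dtype=float)},
        delta_d_um=delta_d,
        **kw,
    )


@pytest.fixture
def constant_program() -> list[SpeciesProgram]:
    return [
        SpeciesProgram(
            tag="HA", kind="constitutive", rate0=100.0, acceleration="constant"
        ),
        SpeciesProgram(
            tag="FLAG", kind="induced", rate0=100.0, t_induce=5.0, kernel="step"
        ),
    ]


@pytest.fixture
def default_params() -> GrowthParams:
    return GrowthParams(t_start=3.0, t_fix=7.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
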