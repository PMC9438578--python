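"""Shared fixtures: the published ascending-aorta parameter set and
synthetic curves generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from aortaflow import (
    BloodProperties,
    PressureState,
    VesselGeometry,
    WallMaterial,
)
from aortaflow.synthetic_data import (
    SEGMENT_FIXTURES,
    gen_pressure_diameter,
    gen_stress_strain,
)


@pytest.fixture(scope="session")
def aorta_geom() -> VesselGeometry:
    """Ascending aorta: outer D 32.0 mm, wall 1.46 mm, equal-state."""
    return VesselGeometry.from_mm(32.0, 1.46)


@pytest.fixture(scope="session")
def wall_normal() -> WallMaterial:
    """Normal-state wall: E = 3.5e5 Pa, φ = 0.0565."""
    return WallMaterial(E=3.5e5, phi=0.0565)


@pytest.fixture(scope="session")
def blood() -> BloodProperties:
    return BloodProperties()


@pytest.fixture(scope="session")
def bp_120_80() -> PressureState:
    return PressureState.from_mmhg(120.0, 80.0)


@pytest.fixture(scope="session")
def sigmoid_curve():
    """Noiseless ascending-segment inflation curve (synthetic stand-in)."""
    return gen_pressure_diameter(SEGMENT_FIXTURES["ascending"], n_points=60)


@pytest.fixture(scope="session")
def exp_curve():
    """Noiseless exponential stress–strain curve, a = 20 kPa, b = 6."""
    return gen_stress_strain(a=20e3, b=6.0, n_points=50)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
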