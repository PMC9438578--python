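"""Seeded synthetic data generators.

The porcine inflation and biaxial measurements behind the model are not
published, so every curve-processing and cohort routine in this package is
exercised on synthetic stand-ins that reproduce their qualitative shapes:

- pressure–outer-diameter curves: bounded monotone sigmoids (inflation of a
  collagen-recruiting wall saturates at high pressure),
- circumferential stress–strain curves: convex origin-anchored
  exponentials σ = a(e^{bε} − 1),
- cohort parameter sets: truncated-normal draws around clinically plausible
  means.

All generators are deterministic under a fixed seed. Fixture parameters for
the three aortic segments are illustrative, not measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError, GeneratorError
from .types import CohortParams, PressureState
from .units import mmhg
from .vessel_mechanics import PressureDiameterCurve, StressStrainCurve

__all__ = [
    "SigmoidPDParams",
    "CohortSpec",
    "ParamDist",
    "SEGMENT_FIXTURES",
    "sigmoid_diameter",
    "gen_pressure_diameter",
    "gen_stress_strain",
    "gen_cohort",
    "DEFAULT_COHORT_SPEC",
]

_REJECTION_CAP = 100


@dataclass(frozen=True)
class SigmoidPDParams:
    """Parameters of the sigmoidal diameter–pressure model.

    D(p) = D_o + (D_max − D_o)/(1 + e^{−(p − p_half)/slope}) is bounded in
    (D_o, D_max) and strictly increasing in p.
    """

    D_o: float  # unstressed outer diameter [m]
    D_max: float  # saturation outer diameter [m]
    p_half: float  # pressure of half-maximal dilation [Pa]
    slope: float  # pressure scale of the transition [Pa]
    noise_sd: float = 0.0  # diameter noise s.d. [m]
    seed: int = 0
    segment: str = "ascending"
    axial_stretch: float = 1.2

    def __post_init__(self) -> None:
        if self.D_max <= self.D_o:
            raise DomainError("D_max must exceed D_o")
        if self.slope <= 0:
            raise DomainError("slope must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


#: Illustrative segment fixtures shaped like inflation-test records
#: (synthetic: qualitative match only, not measured values).
SEGMENT_FIXTURES: dict[str, SigmoidPDParams] = {
    "ascending": SigmoidPDParams(
        D_o=26e-3, D_max=34e-3, p_half=mmhg(70), slope=mmhg(30),
        segment="ascending", axial_stretch=1.2,
    ),
    "proximal_descending": SigmoidPDParams(
        D_o=22e-3, D_max=27.5e-3, p_half=mmhg(75), slope=mmhg(32),
        segment="proximal_descending", axial_stretch=1.3,
    ),
    "distal_descending": SigmoidPDParams(
        D_o=18e-3, D_max=21.5e-3, p_half=mmhg(80), slope=mmhg(35),
        segment="distal_descending", axial_stretch=1.4,
    ),
}


def sigmoid_diameter(params: SigmoidPDParams, p):
    """Closed-form noiseless sigmoid D(p); the oracle for generated curves."""
    p = np.asarray(p, dtype=float)
    return params.D_o + (params.D_max - params.D_o) / (
        1.0 + np.exp(-(p - params.p_half) / params.slope)
    )


def gen_pressure_diameter(
    params: SigmoidPDParams,
    n_points: int = 40,
    p_min: float = mmhg(10),
    p_max: float = mmhg(200),
) -> PressureDiameterCurve:
    """Generate a seeded inflation-test curve from the sigmoid model.

    Noise is truncated-normal on the diameters and accepted only if the
    curve stays non-decreasing; after 100 rejected resamples a
    :class:`GeneratorError` is raised (the noise is then too large for the
    requested grid).
    """
    if n_points < 3:
        raise DomainError("need at least 3 points")
    if not 0 < p_min < p_max:
        raise DomainError("need 0 < p_min < p_max")
    pressures = np.linspace(p_min, p_max, n_points)
    d_clean = sigmoid_diameter(params, pressures)
    if params.noise_sd == 0:
        diameters = d_clean
    else:
        rng = np.random.default_rng(params.seed)
        for _ in range(_REJECTION_CAP):
            noise = rng.normal(0.0, params.noise_sd, size=n_points)
            np.clip(noise, -3 * params.noise_sd, 3 * params.noise_sd, out=noise)
            candidate = d_clean + noise
            if np.all(np.diff(candidate) >= 0):
                diameters = candidate
                break
        else:
            raise GeneratorError(
                f"noise_sd={params.noise_sd:g} m breaks monotonicity on a "
                f"{n_points}-point grid after {_REJECTION_CAP} resamples"
            )
    return PressureDiameterCurve(
        pressures=pressures,
        outer_diameters=diameters,
        D_o=params.D_o,
        axial_stretch=params.axial_stretch,
        segment=params.segment,
    )


def gen_stress_strain(
    a: float,
    b: float,
    noise_sd: float = 0.0,
    n_points: int = 50,
    seed: int = 0,
    strain_max: float = 0.4,
    quadrant: str = "mean",
) -> StressStrainCurve:
    """Generate a seeded stress–strain curve σ = a(e^{bε}−1) + noise.

    The strain grid spans [0, strain_max]; wall strain stays below 0.4
    under physiological loading, hence the default. Noise is
    truncated-normal with monotonicity enforced by rejection.
    """
    if a <= 0 or b <= 0:
        raise DomainError("a and b must be positive")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    if n_points < 3:
        raise DomainError("need at least 3 points")
    strains = np.linspace(0.0, strain_max, n_points)
    clean = a * np.expm1(b * strains)
    if noise_sd == 0:
        stresses = clean
    else:
        # per-point truncated-normal noise, resampled until the running
        # curve stays non-decreasing (noise can exceed the flat low-strain
        # increments, so whole-curve rejection would never terminate)
        rng = np.random.default_rng(seed)
        stresses = np.empty(n_points)
        prev = 0.0
        for i in range(n_points):
            for _ in range(_REJECTION_CAP):
                value = clean[i] + float(
                    np.clip(rng.normal(0.0, noise_sd), -3 * noise_sd, 3 * noise_sd)
                )
                if i == 0:
                    value = max(value, 0.0)
                if value >= prev:
                    break
            else:
                raise GeneratorError(
                    f"noise_sd={noise_sd:g} Pa breaks monotonicity at point "
                    f"{i} after {_REJECTION_CAP} resamples"
                )
            stresses[i] = value
            prev = value
    return StressStrainCurve(strains=strains, stresses=stresses, quadrant=quadrant)


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal specification (mean, sd, lower, upper)."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise DomainError("need lower < upper")
        if self.sd < 0:
            raise DomainError("sd must be non-negative")
        if not (self.lower <= self.mean <= self.upper):
            raise DomainError("mean must lie within the bounds")


@dataclass(frozen=True)
class CohortSpec:
    """Distributional spec of a synthetic clinical cohort.

    Units are clinical: pressures mmHg, diameters/thicknesses mm,
    modulus Pa, heart rate min⁻¹, viscosity Pa·s, compliance ml/mmHg.
    """

    n_subjects: int
    p_s: ParamDist = ParamDist(120.0, 12.0, 90.0, 200.0)
    p_d: ParamDist = ParamDist(78.0, 9.0, 50.0, 110.0)
    E: ParamDist = ParamDist(3.5e5, 5e4, 1.5e5, 8e5)
    D: ParamDist = ParamDist(32.0, 2.0, 24.0, 40.0)
    h: ParamDist = ParamDist(1.46, 0.15, 1.0, 2.2)
    phi: ParamDist = ParamDist(0.05, 0.008, 0.02, 0.12)
    hr: ParamDist = ParamDist(70.0, 8.0, 45.0, 110.0)
    mu: ParamDist = ParamDist(4.0e-3, 5e-4, 2.5e-3, 7e-3)
    compliance: ParamDist = ParamDist(1.7, 0.2, 0.8, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise DomainError("n_subjects must be non-negative")


DEFAULT_COHORT_SPEC = CohortSpec(n_subjects=100)


def _draw_truncated(rng: np.random.Generator, dist: ParamDist) -> float:
    if dist.sd == 0:
        return dist.mean
    for _ in range(_REJECTION_CAP):
        x = rng.normal(dist.mean, dist.sd)
        if dist.lower <= x <= dist.upper:
            return float(x)
    raise GeneratorError(
        f"could not draw within bounds [{dist.lower}, {dist.upper}] "
        f"from N({dist.mean}, {dist.sd}²) in {_REJECTION_CAP} attempts"
    )


def gen_cohort(spec: CohortSpec) -> list[dict]:
    """Draw a seeded cohort of subject parameter dictionaries.

    Each subject carries clinical-unit keys (``p_s_mmHg``, ``p_d_mmHg``,
    ``E_Pa``, ``D_mm``, ``h_mm``, ``phi``, ``hr_per_min``, ``mu_Pa_s``,
    ``compliance_ml_per_mmHg``) and satisfies p_s > p_d by rejection.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[dict] = []
    for i in range(spec.n_subjects):
        for _ in range(_REJECTION_CAP):
            p_s = _draw_truncated(rng, spec.p_s)
            p_d = _draw_truncated(rng, spec.p_d)
            if p_s > p_d:
                break
        else:
            raise GeneratorError("could not draw p_s > p_d within attempt cap")
        subjects.append(
            {
                "label": f"subject_{i:04d}",
                "p_s_mmHg": p_s,
                "p_d_mmHg": p_d,
                "E_Pa": _draw_truncated(rng, spec.E),
                "D_mm": _draw_truncated(rng, spec.D),
                "h_mm": _draw_truncated(rng, spec.h),
                "phi": _draw_truncated(rng, spec.phi),
                "hr_per_min": _draw_truncated(rng, spec.hr),
                "mu_Pa_s": _draw_truncated(rng, spec.mu),
                "compliance_ml_per_mmHg": _draw_truncated(rng, spec.compliance),
            }
        )
    return subjects
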