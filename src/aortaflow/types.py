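"""Domain types for the arterial strain-energy blood-supply model.

All quantities are SI: pressures in Pa, lengths in m, moduli in Pa,
compliances in m³/Pa. Construction helpers accept clinical units
(mmHg, mm, ml/mmHg) and convert immediately.

The vessel is a thin-walled elastic cylinder. Pressure states carry the
clinical mean-pressure convention MBP = (2·DBP + SBP)/3; the wall obeys
circumferential incompressibility h·D = const between load states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import DomainError
from .units import MMHG_TO_PA, STANDARD_GRAVITY, ml_per_mmhg, mm, mmhg

__all__ = [
    "PressureState",
    "VesselGeometry",
    "WallMaterial",
    "BloodProperties",
    "FlowSolution",
    "EnergyBudget",
    "CohortParams",
]


@dataclass(frozen=True)
class PressureState:
    """Systolic/diastolic pressure pair with derived mean and pulse pressure.

    ``p_mean`` follows the clinical convention (2·p_d + p_s)/3 — diastole
    occupies roughly two thirds of the cardiac cycle.
    """

    p_s: float  # systolic pressure [Pa]
    p_d: float  # diastolic pressure [Pa]

    def __post_init__(self) -> None:
        if not (self.p_s > 0 and self.p_d > 0):
            raise DomainError(
                f"pressures must be positive: p_s={self.p_s}, p_d={self.p_d}"
            )
        if self.p_s < self.p_d:
            raise DomainError(
                f"systolic pressure below diastolic: p_s={self.p_s} < p_d={self.p_d}"
            )

    @property
    def pp(self) -> float:
        """Pulse pressure p_s − p_d [Pa]."""
        return self.p_s - self.p_d

    @property
    def p_mean(self) -> float:
        """Mean blood pressure (2·p_d + p_s)/3 [Pa]."""
        return (2.0 * self.p_d + self.p_s) / 3.0

    @classmethod
    def from_mmhg(cls, p_s: float, p_d: float) -> "PressureState":
        return cls(p_s=mmhg(p_s), p_d=mmhg(p_d))

    def as_mmhg(self) -> tuple[float, float]:
        return self.p_s / MMHG_TO_PA, self.p_d / MMHG_TO_PA


_THIN_WALL_RATIO = 10.0
_INCOMPRESSIBILITY_RTOL = 1e-12


@dataclass(frozen=True)
class VesselGeometry:
    """Reference, diastolic and systolic geometry of a thin-walled aorta.

    ``D`` and ``h`` are the reference **outer** diameter and wall thickness
    used for α ratios and Laplace stresses; ``D_inner`` (= D − 2h) is the
    reference inner diameter used for the lumen flow area and for the
    pressure–area strain relation.
    """

    D: float  # reference outer diameter [m]
    h: float  # reference wall thickness [m]
    D_o: float  # initial (unstressed) outer diameter [m]
    D_d: float  # diastolic outer diameter [m]
    D_s: float  # systolic outer diameter [m]
    h_d: float  # diastolic wall thickness [m]
    h_s: float  # systolic wall thickness [m]

    def __post_init__(self) -> None:
        for name in ("D", "h", "D_o", "D_d", "D_s", "h_d", "h_s"):
            if getattr(self, name) <= 0:
                raise DomainError(f"geometry field {name} must be positive")
        if self.D_s < self.D_d:
            raise DomainError(
                f"systolic diameter below diastolic: D_s={self.D_s} < D_d={self.D_d}"
            )
        if self.D <= 2.0 * self.h:
            raise DomainError("reference lumen closed: D <= 2h")
        if self.D / self.h < _THIN_WALL_RATIO:
            warnings.warn(
                f"D/h = {self.D / self.h:.2f} < {_THIN_WALL_RATIO:g}: "
                "thin-wall (Laplace) approximation is questionable",
                stacklevel=2,
            )

    @property
    def D_inner(self) -> float:
        """Reference inner diameter [m]."""
        return self.D - 2.0 * self.h

    @property
    def A_f(self) -> float:
        """Lumen (blood flow) area from the reference inner diameter [m²]."""
        return math.pi * self.D_inner**2 / 4.0

    @classmethod
    def uniform(cls, D: float, h: float, D_o: Optional[float] = None) -> "VesselGeometry":
        """Geometry with identical diastolic/systolic state (α_s = α_d)."""
        return cls(D=D, h=h, D_o=D_o if D_o is not None else D,
                   D_d=D, D_s=D, h_d=h, h_s=h)

    @classmethod
    def from_mm(cls, D_mm: float, h_mm: float) -> "VesselGeometry":
        return cls.uniform(mm(D_mm), mm(h_mm))

    @classmethod
    def from_area_strain(cls, D: float, h: float, eps_A: float) -> "VesselGeometry":
        """Derive systolic geometry from a diastole→systole area strain.

        The diastolic state is pinned to the reference (D_d = D), the systolic
        outer diameter follows D_s = D·√(1+ε_A), and wall incompressibility
        h_i·D_i = h·D fixes the thicknesses.
        """
        if eps_A < 0:
            raise DomainError(f"area strain must be non-negative, got {eps_A}")
        D_s = D * math.sqrt(1.0 + eps_A)
        geom = cls(D=D, h=h, D_o=D, D_d=D, D_s=D_s,
                   h_d=h, h_s=h * D / D_s)
        geom._check_incompressibility()
        return geom

    def _check_incompressibility(self) -> None:
        ref = self.h * self.D
        for hi, Di in ((self.h_d, self.D_d), (self.h_s, self.D_s)):
            if abs(hi * Di - ref) > _INCOMPRESSIBILITY_RTOL * ref:
                raise DomainError("wall incompressibility h_i·D_i = h·D violated")


@dataclass(frozen=True)
class WallMaterial:
    """Circumferential elastic wall behaviour.

    ``E`` is the secant circumferential modulus over the physiological
    window; ``phi`` is the expansion constraint coefficient — the fraction
    of free dilation the surrounding soft tissue permits (0 < φ ≤ 1).
    """

    E: float  # circumferential elastic modulus [Pa]
    phi: float  # expansion constraint coefficient [-]

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise DomainError(f"elastic modulus must be positive, got {self.E}")
        if not (0.0 < self.phi <= 1.0):
            raise DomainError(f"phi must lie in (0, 1], got {self.phi}")


@dataclass(frozen=True)
class BloodProperties:
    """Bulk blood properties and the laminar-flow coefficients.

    ``eta`` is the kinetic-energy correction factor (2 for laminar viscous
    flow), ``K`` the wall-shear dissipation coefficient (1 for laminar flow).

    ``gamma_convention`` selects how the per-unit-volume weight γ is formed:

    - ``"kgf"`` (default): γ is numerically equal to ρ (weight expressed in
      kilogram-force per m³). Selected by the worked-example calibration.
    - ``"si"``: γ = ρ·g [N/m³].

    An explicit ``gamma`` overrides either convention.
    """

    rho: float = 1050.0  # density [kg/m³]
    mu: float = 4.0e-3  # dynamic viscosity [Pa·s]
    eta: float = 2.0  # kinetic-energy correction factor [-]
    K: float = 1.0  # laminar dissipation coefficient [-]
    g: float = STANDARD_GRAVITY  # gravitational acceleration [m/s²]
    gamma_convention: str = "kgf"
    gamma_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise DomainError("blood density and viscosity must be positive")
        if self.gamma_convention not in ("kgf", "si"):
            raise DomainError(
                f"unknown gamma convention {self.gamma_convention!r}; "
                "expected 'kgf' or 'si'"
            )

    @property
    def gamma(self) -> float:
        """Per-unit-volume weight under the active convention."""
        if self.gamma_override is not None:
            return self.gamma_override
        if self.gamma_convention == "si":
            return self.rho * self.g
        return self.rho

    @property
    def nu(self) -> float:
        """Kinematic viscosity μ/ρ [m²/s]."""
        return self.mu / self.rho

    def with_convention(self, convention: str) -> "BloodProperties":
        return replace(self, gamma_convention=convention, gamma_override=None)


@dataclass(frozen=True)
class FlowSolution:
    """Full audit record of one per-pulse flow computation."""

    alpha_s: float  # systolic wall ratio D_s/h_s − 2 [-]
    alpha_d: float  # diastolic wall ratio D_d/h_d − 2 [-]
    beta: float  # coupling energy dissipation coefficient [-]
    V: float  # characteristic velocity: flow distance per pulse [m]
    Q0: float  # base per-pulse flow A_f·V [m³]
    dQ: float  # incremental per-pulse flow (φDp/Eh)·A_f·V [m³]
    Re: float  # Reynolds number of the per-second mean velocity [-]
    lam: float  # laminar friction loss factor 64/Re [-]
    n: float  # pulse frequency [min⁻¹]

    @property
    def Q(self) -> float:
        """Per-pulse flow Q0 + ΔQ [m³]."""
        return self.Q0 + self.dQ

    @property
    def Qbar(self) -> float:
        """Mean flow n·Q [m³/min]."""
        return self.n * self.Q

    @property
    def Qbar_L_min(self) -> float:
        """Mean flow in litres per minute."""
        return self.Qbar * 1e3


@dataclass(frozen=True)
class EnergyBudget:
    """Per-pulse energy terms of the coupled wall/flow functional.

    ``delta_u`` is the strain energy density increment [J/m³]; ``delta_A``
    the lumen area increment [m²]; ``delta_K`` the kinetic energy increment
    and ``delta_w_tau`` the (negative) wall-shear dissipation increment, both
    per unit vessel length under the adopted reading; ``chi`` the Hamilton
    functional per pulse per unit length.
    """

    delta_u: float
    delta_A: float
    delta_K: float
    delta_w_tau: float
    chi: float


@dataclass(frozen=True)
class CohortParams:
    """Clinically measured parameters of one cohort."""

    pressure: PressureState
    hr: float  # pulse / heart rate [min⁻¹]
    compliance: float  # volumetric compliance [m³/Pa]
    label: str = ""

    def __post_init__(self) -> None:
        if self.hr <= 0:
            raise DomainError(f"heart rate must be positive, got {self.hr}")
        if self.compliance <= 0:
            raise DomainError(f"compliance must be positive, got {self.compliance}")

    @classmethod
    def from_clinical(
        cls,
        p_s_mmHg: float,
        p_d_mmHg: float,
        hr: float,
        compliance_ml_per_mmHg: float,
        label: str = "",
    ) -> "CohortParams":
        return cls(
            pressure=PressureState.from_mmhg(p_s_mmHg, p_d_mmHg),
            hr=hr,
            compliance=ml_per_mmhg(compliance_ml_per_mmHg),
            label=label,
        )
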