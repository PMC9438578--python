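"""Closed-form strain-energy and blood-supply model of the elastic aorta.

The aorta is treated as a pre-stretched thin-walled elastic cylinder whose
pulse-wise deformation stores strain energy that is returned to the blood as
mechanical work. The module provides:

- the strain energy density increment (SEDI) between diastole and systole,
  both from stress/strain pairs and directly from pressures,
- Laplace hoop stress and the secant modulus from expansion tests,
- the characteristic velocity V (flow distance per pulse) from the coupled
  wall/flow energy balance, with the coupling dissipation coefficient β,
- per-pulse and per-minute blood flow, and
- an inverse solver recovering diastolic pressure from a flow-matching rule.

All pressures are Pa, lengths m; the mean-pressure convention is
p̄ = (2·p_d + p_s)/3. The flow equations use the frozen calibrated reading
described in :mod:`aortaflow.calibration`:

    V  = κ · φ·h·(α_s p_s − α_d p_d) / (D_inner · γ · (1+β))
    β  = 4·E·λ·(h_d − h_s) / (D_inner · (p_s − p_d) · φ)
    Q̄  = n · (1 + φ·D_inner·p̄/(E·h)) · A_f · V

where α_i = D_i/h_i − 2 uses outer diameters, λ = 64/Re is the laminar
friction factor, and γ is the per-unit-volume weight of blood.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Callable, Optional, Sequence

from .errors import DomainError, ModelRegimeError, SolverError
from .types import (
    BloodProperties,
    CohortParams,
    EnergyBudget,
    FlowSolution,
    PressureState,
    VesselGeometry,
    WallMaterial,
)
from .units import MMHG_TO_PA

logger = logging.getLogger(__name__)

__all__ = [
    "mean_pressure",
    "laplace_stress",
    "modulus_from_expansion",
    "alpha_ratio",
    "sedi_linear",
    "sedi_pressure_form",
    "area_strain",
    "phi_for_area_strain",
    "reynolds",
    "friction_factor",
    "beta_coefficient",
    "characteristic_velocity",
    "energy_budget",
    "mean_flow",
    "relative_flow_change",
    "solve_diastolic_pressure",
    "LAMINAR_CRITICAL_RE",
]

#: Reynolds number above which the laminar assumption is logged as violated.
LAMINAR_CRITICAL_RE = 2100.0


def mean_pressure(ps: PressureState) -> float:
    """Mean blood pressure (2·p_d + p_s)/3 [Pa]."""
    if ps.p_s < ps.p_d:
        raise DomainError("systolic below diastolic pressure")
    return ps.p_mean


def laplace_stress(p_i: float, D_i: float, h_i: float, phi: float) -> float:
    """Constrained thin-wall hoop stress σ_i = φ·p_i·D_i/(2·h_i) [Pa].

    ``D_i`` is the outer diameter of the load state; φ scales the free
    Laplace stress down by the soft-tissue expansion constraint.
    """
    if D_i <= 0 or h_i <= 0:
        raise DomainError("diameter and thickness must be positive")
    return phi * p_i * D_i / (2.0 * h_i)


def modulus_from_expansion(D: float, p: float, h: float, eps_theta: float) -> float:
    """Secant circumferential modulus E = D·p/(2·h·ε_θ) from an expansion test.

    ``eps_theta`` is the relative circumferential strain between diastole and
    systole; an undeformed vessel has no finite secant modulus.
    """
    if eps_theta <= 0:
        raise DomainError(
            f"relative strain must be positive, got {eps_theta} "
            "(undeformed vessel has no finite secant modulus)"
        )
    if D <= 0 or h <= 0:
        raise DomainError("diameter and thickness must be positive")
    return D * p / (2.0 * h * eps_theta)


def alpha_ratio(D_i: float, h_i: float) -> float:
    """Wall ratio α_i = D_i/h_i − 2 (outer diameter over thickness)."""
    if h_i <= 0:
        raise DomainError("thickness must be positive")
    if D_i <= 2.0 * h_i:
        raise DomainError(f"lumen closed: D_i={D_i} <= 2·h_i={2 * h_i}")
    return D_i / h_i - 2.0


def sedi_linear(
    sigma_s: float, sigma_d: float, eps_s: float, eps_d: float
) -> float:
    """SEDI from stress/strain pairs: Δu = (σ_s−σ_d)(ε_s−ε_d)/2 [J/m³].

    The triangular area between the diastolic and systolic operating points
    of a linear-elastic wall.
    """
    if sigma_s < sigma_d or eps_s < eps_d:
        raise DomainError(
            "systolic stress/strain must not be below diastolic "
            f"(σ: {sigma_s} vs {sigma_d}, ε: {eps_s} vs {eps_d})"
        )
    return 0.5 * (sigma_s - sigma_d) * (eps_s - eps_d)


def sedi_pressure_form(
    material: WallMaterial, alpha_s: float, alpha_d: float, ps: PressureState
) -> float:
    """SEDI from pressures: Δu = φ²(α_s p_s − α_d p_d)²/(8E) [J/m³]."""
    drive = alpha_s * ps.p_s - alpha_d * ps.p_d
    return material.phi**2 * drive**2 / (8.0 * material.E)


def area_strain(material: WallMaterial, p: float, D: float, h: float) -> float:
    """Cross-section area strain ε_A = φ·p·D/(E·h) at pressure p.

    ``D`` is the inner diameter of the lumen whose area strains.
    """
    if D <= 0 or h <= 0:
        raise DomainError("diameter and thickness must be positive")
    return material.phi * p * D / (material.E * h)


def phi_for_area_strain(
    eps_A: float, p: float, D: float, h: float, E: float
) -> float:
    """Expansion constraint coefficient producing a given operating strain.

    Inverts ε_A = φ·p·D/(E·h): φ = ε_A·E·h/(p·D). Under a constant operating
    strain, φ is positively correlated with stiffness and wall thickness and
    negatively with mean pressure and inner diameter.
    """
    if p <= 0 or D <= 0 or h <= 0 or E <= 0:
        raise DomainError("inputs must be positive")
    return eps_A * E * h / (p * D)


def reynolds(V_char: float, n: float, D: float, mu: float, rho: float) -> float:
    """Reynolds number of the pulse-averaged flow.

    The characteristic velocity is a flow distance per pulse; it is converted
    to a per-second mean velocity with the pulse frequency (n/60) before
    forming Re = ρ·v·D/μ. Crossing the laminar critical value logs a warning.
    """
    if n <= 0 or D <= 0 or mu <= 0 or rho <= 0:
        raise DomainError("n, D, mu and rho must be positive")
    v_sec = V_char * n / 60.0
    re = rho * v_sec * D / mu
    if re > LAMINAR_CRITICAL_RE:
        logger.warning(
            "Re = %.0f exceeds the laminar critical value %.0f; "
            "the λ = 64/Re friction law is extrapolated",
            re,
            LAMINAR_CRITICAL_RE,
        )
    return re


def friction_factor(Re: float) -> float:
    """Laminar (Darcy) friction loss factor λ = 64/Re."""
    if Re <= 0:
        raise DomainError(f"Reynolds number must be positive, got {Re}")
    if Re > LAMINAR_CRITICAL_RE:
        logger.warning(
            "Re = %.0f exceeds the laminar critical value %.0f", Re, LAMINAR_CRITICAL_RE
        )
    return 64.0 / Re


def beta_coefficient(
    material: WallMaterial,
    lam: float,
    geom: VesselGeometry,
    ps: PressureState,
) -> float:
    """Coupling energy dissipation coefficient β = 4Eλ(h_d−h_s)/(D·Δp·φ).

    Folds wall-shear friction losses into the characteristic-velocity
    solution. β = 0 for a wall with no systolic thinning; a wall that
    *thickens* in systole contradicts incompressibility and yields a
    negative β with a warning.
    """
    if ps.p_s <= ps.p_d:
        raise DomainError("pulse pressure must be positive for beta")
    dh = geom.h_d - geom.h_s
    if dh < 0:
        warnings.warn(
            "h_d < h_s: wall thickening in systole contradicts "
            "incompressibility; returning negative beta",
            stacklevel=2,
        )
    return 4.0 * material.E * lam * dh / (geom.D_inner * ps.pp * material.phi)


def _drive(
    geom: VesselGeometry,
    material: WallMaterial,
    ps: PressureState,
    sigma_d_literal: bool = False,
) -> float:
    """Driving term α_s p_s − α_d p_d of the energy balance.

    With ``sigma_d_literal`` the diastolic term uses the hoop stress σ_d in
    place of p_d (audit variant of the typeset form; dimensionally
    inconsistent and off by the factor φ(α_d+2)/2, kept only for inspection).
    """
    a_s = alpha_ratio(geom.D_s, geom.h_s)
    a_d = alpha_ratio(geom.D_d, geom.h_d)
    if sigma_d_literal:
        p_d_term = laplace_stress(ps.p_d, geom.D_d, geom.h_d, material.phi)
    else:
        p_d_term = ps.p_d
    return a_s * ps.p_s - a_d * p_d_term


def characteristic_velocity(
    geom: VesselGeometry,
    material: WallMaterial,
    ps: PressureState,
    blood: BloodProperties,
    mode: str = "fixed_beta",
    *,
    beta: Optional[float] = None,
    Re: Optional[float] = None,
    n: float = 72.0,
    kappa: float = 1.0,
    sigma_d_literal: bool = False,
) -> tuple[float, float, float, float]:
    """Characteristic velocity V: flow distance per pulse [m].

    V solves the coupled wall/flow energy balance
    V·(1+β) = κ·φ·h·(α_s p_s − α_d p_d)/(D_inner·γ); the friction factor
    λ = 64/Re needed by β itself depends on V, and three closures are
    offered:

    - ``fixed_beta``: β supplied directly (default for the published worked
      examples, which print β).
    - ``fixed_Re``: Re supplied; λ = 64/Re and β follows from the wall
      thinning h_d − h_s.
    - ``self_consistent``: β(V) ∝ 1/V, so the balance has the closed form
      V = c − b with c the undamped drive and b = β·V a constant.

    Returns ``(V, beta, lam, Re)``. Raises :class:`ModelRegimeError` in
    self-consistent mode when dissipation exceeds the driving term.
    """
    drv = _drive(geom, material, ps, sigma_d_literal)
    pref = kappa * material.phi * geom.h / (geom.D_inner * blood.gamma)
    c = pref * drv  # undamped drive, [m] per pulse

    if mode == "fixed_beta":
        if beta is None:
            raise DomainError("fixed_beta mode requires beta")
        V = c / (1.0 + beta)
        re_out = reynolds(abs(V), n, geom.D_inner, blood.mu, blood.rho)
        lam = friction_factor(re_out) if re_out > 0 else math.inf
        return V, beta, lam, re_out

    if mode == "fixed_Re":
        if Re is None:
            raise DomainError("fixed_Re mode requires Re")
        lam = friction_factor(Re)
        b = beta_coefficient(material, lam, geom, ps)
        V = c / (1.0 + b)
        return V, b, lam, Re

    if mode == "self_consistent":
        # λ·V = 64·(60·μ)/(n·D·ρ) is V-free, so b = β·V is a constant.
        lam_times_v = 64.0 * 60.0 * blood.mu / (n * geom.D_inner * blood.rho)
        b = (
            4.0
            * material.E
            * (geom.h_d - geom.h_s)
            * lam_times_v
            / (geom.D_inner * ps.pp * material.phi)
        )
        V = c - b
        if V < 0:
            raise ModelRegimeError(
                f"dissipation exceeds driving term: drive c={c:.3e} m, "
                f"dissipation b={b:.3e} m"
            )
        if V == 0:
            beta_out = math.inf if b > 0 else 0.0
            return 0.0, beta_out, math.inf, 0.0
        re_out = reynolds(V, n, geom.D_inner, blood.mu, blood.rho)
        return V, b / V, friction_factor(re_out), re_out

    raise DomainError(
        f"unknown mode {mode!r}; expected fixed_beta, fixed_Re or self_consistent"
    )


def energy_budget(
    geom: VesselGeometry,
    material: WallMaterial,
    ps: PressureState,
    blood: BloodProperties,
    V: float,
    *,
    lam: float = 0.064,
    sigma_d_literal: bool = False,
) -> EnergyBudget:
    """Per-pulse energy budget of the coupled wall/flow system.

    - ΔA = φ·(D_s p_s/h_s − D_d p_d/h_d)·A_f/E  (lumen area increment)
    - ΔK = ΔA·γ·V²                              (kinetic energy increment)
    - Δw_τ = −γ·λ·(D_s−D_d)·K²·V²               (wall-shear dissipation, ≤ 0)
    - χ = πD²φγ·drv·V²/4E − πDhφ²·drv²/8E − π(D_s−D_d)φγλD·K²·V²

    with drv = α_s p_s − α_d p_d and the bare D the reference inner
    diameter. ``lam`` defaults to the laminar value at Re = 1000.

    The stationarity of χ at the closed-form V is not asserted — it does not
    hold under any single fraction reading of the typeset source — but can be
    probed numerically via :func:`chi_stationarity_diagnostic`.
    """
    if V < 0:
        raise DomainError("characteristic velocity must be non-negative")
    drv = _drive(geom, material, ps, sigma_d_literal)
    phi, E = material.phi, material.E
    gamma, K = blood.gamma, blood.K
    D, h = geom.D_inner, geom.h

    delta_u = phi**2 * drv**2 / (8.0 * E)
    delta_A = (
        phi
        * (geom.D_s * ps.p_s / geom.h_s - geom.D_d * ps.p_d / geom.h_d)
        * geom.A_f
        / E
    )
    delta_K = delta_A * gamma * V**2
    delta_w_tau = -gamma * lam * (geom.D_s - geom.D_d) * K**2 * V**2
    chi = (
        math.pi * D**2 * phi * gamma * drv * V**2 / (4.0 * E)
        - math.pi * D * h * phi**2 * drv**2 / (8.0 * E)
        - math.pi * (geom.D_s - geom.D_d) * phi * gamma * lam * D * K**2 * V**2
    )
    return EnergyBudget(
        delta_u=delta_u,
        delta_A=delta_A,
        delta_K=delta_K,
        delta_w_tau=delta_w_tau,
        chi=chi,
    )


def chi_stationarity_diagnostic(
    geom: VesselGeometry,
    material: WallMaterial,
    ps: PressureState,
    blood: BloodProperties,
    V: float,
    rel_step: float = 1e-4,
) -> float:
    """Informational: central-difference dχ/dV at V, normalised by χ/V.

    Returns a dimensionless stationarity defect; not an assertion anywhere.
    """
    if V <= 0:
        raise DomainError("V must be positive for the diagnostic")
    dv = V * rel_step
    hi = energy_budget(geom, material, ps, blood, V + dv).chi
    lo = energy_budget(geom, material, ps, blood, V - dv).chi
    mid = energy_budget(geom, material, ps, blood, V).chi
    dchi_dv = (hi - lo) / (2.0 * dv)
    scale = abs(mid / V) if mid != 0 else 1.0
    return dchi_dv / scale


def mean_flow(
    geom: VesselGeometry,
    material: WallMaterial,
    ps: PressureState,
    blood: BloodProperties,
    n: float,
    mode: str = "fixed_beta",
    *,
    beta: Optional[float] = None,
    Re: Optional[float] = None,
    kappa: float = 1.0,
) -> FlowSolution:
    """Per-pulse and per-minute blood flow through the aortic cross-section.

    Q0 = A_f·V is the base flow; ΔQ = (φ·D_inner·p̄/(E·h))·A_f·V is the
    incremental flow carried by the elastic expansion of the lumen at mean
    pressure; Q̄ = n·(Q0 + ΔQ). The model is entirely pulse-driven: the flow
    vanishes when α_s p_s = α_d p_d.
    """
    if n <= 0:
        raise DomainError(f"pulse frequency must be positive, got {n}")
    V, beta_out, lam, re_out = characteristic_velocity(
        geom, material, ps, blood, mode, beta=beta, Re=Re, n=n, kappa=kappa
    )
    q0 = geom.A_f * V
    eps_a = area_strain(material, ps.p_mean, geom.D_inner, geom.h)
    dq = eps_a * geom.A_f * V
    return FlowSolution(
        alpha_s=alpha_ratio(geom.D_s, geom.h_s),
        alpha_d=alpha_ratio(geom.D_d, geom.h_d),
        beta=beta_out,
        V=V,
        Q0=q0,
        dQ=dq,
        Re=re_out,
        lam=lam,
        n=n,
    )


def relative_flow_change(
    state_a: tuple[VesselGeometry, WallMaterial, PressureState, BloodProperties, float],
    state_b: tuple[VesselGeometry, WallMaterial, PressureState, BloodProperties, float],
    mode: str = "fixed_beta",
    *,
    beta: Optional[float] = None,
    Re: Optional[float] = None,
    kappa: float = 1.0,
) -> float:
    """Percent change of mean flow, 100·(Q̄_a − Q̄_b)/Q̄_b.

    Dimensionless and invariant to global unit rescaling: γ conventions and
    the calibration constant cancel in the ratio.
    """
    qa = mean_flow(*state_a, mode=mode, beta=beta, Re=Re, kappa=kappa).Qbar
    qb = mean_flow(*state_b, mode=mode, beta=beta, Re=Re, kappa=kappa).Qbar
    if qb == 0:
        raise DomainError("reference state has zero mean flow")
    return 100.0 * (qa - qb) / qb


_MATCHING_RULES = ("equal_mean_flow", "equal_pulse_flow", "equal_flow_per_compliance")
_PHI_POLICIES = ("iso_strain", "from_compliance")


def solve_diastolic_pressure(
    reference: CohortParams,
    subject_p_s: float,
    subject_hr: float,
    *,
    geom: VesselGeometry,
    E: float,
    blood: BloodProperties,
    subject_compliance: Optional[float] = None,
    phi_policy: str = "iso_strain",
    matching_rule: str = "equal_mean_flow",
    beta: float = 0.290,
    kappa: float = 1.0,
    L_eff: float = 6.0,
    tol_mmHg: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """Diastolic pressure of a subject whose mean flow matches a reference.

    The reference cohort's compliance fixes its operating area strain
    ε_A = C·p̄/(L_eff·A_f) and hence its expansion constraint coefficient
    φ = ε_A·E·h/(p̄·D_inner). For the subject, two φ policies are offered:

    - ``iso_strain`` (default): the subject operates at the *same* area
      strain as the reference, so its φ adapts to its own mean pressure,
      φ(p_d) = ε_A·E·h/(p̄(p_d)·D_inner). This strain-homeostasis convention
      reproduces the published cohort inversion.
    - ``from_compliance``: the subject's φ comes from its own printed
      compliance and is independent of p_d (requires
      ``subject_compliance``).

    The root of Q̄_subject(p_d) − Q̄_reference is found by bisection on
    (1 mmHg, p_s − 1 mmHg) to ``tol_mmHg``; the result is returned in mmHg
    (clinical convention — all inputs remain SI).
    """
    if matching_rule not in _MATCHING_RULES:
        raise DomainError(
            f"unknown matching rule {matching_rule!r}; expected one of {_MATCHING_RULES}"
        )
    if matching_rule != "equal_mean_flow":
        raise NotImplementedError(
            f"matching rule {matching_rule!r} is reserved but not implemented"
        )
    if phi_policy not in _PHI_POLICIES:
        raise DomainError(
            f"unknown phi policy {phi_policy!r}; expected one of {_PHI_POLICIES}"
        )
    if phi_policy == "from_compliance" and subject_compliance is None:
        raise DomainError("phi_policy='from_compliance' requires subject_compliance")
    if subject_p_s <= 2 * MMHG_TO_PA:
        raise DomainError("subject systolic pressure too low to bracket a root")

    p_ref = reference.pressure
    eps_a_ref = reference.compliance * p_ref.p_mean / (L_eff * geom.A_f)
    phi_ref = phi_for_area_strain(
        eps_a_ref, p_ref.p_mean, geom.D_inner, geom.h, E
    )
    q_ref = mean_flow(
        geom, WallMaterial(E=E, phi=phi_ref), p_ref, blood, reference.hr,
        mode="fixed_beta", beta=beta, kappa=kappa,
    ).Qbar

    if phi_policy == "from_compliance":
        from .vessel_mechanics import phi_from_compliance

        phi_subj_const = phi_from_compliance(
            subject_compliance, E, geom.h, geom.A_f, geom.D_inner, L_eff
        )

    def q_subject(p_d_pa: float) -> float:
        ps = PressureState(p_s=subject_p_s, p_d=p_d_pa)
        if phi_policy == "iso_strain":
            phi = phi_for_area_strain(eps_a_ref, ps.p_mean, geom.D_inner, geom.h, E)
        else:
            phi = phi_subj_const
        return mean_flow(
            geom, WallMaterial(E=E, phi=phi), ps, blood, subject_hr,
            mode="fixed_beta", beta=beta, kappa=kappa,
        ).Qbar

    lo = MMHG_TO_PA  # 1 mmHg
    hi = subject_p_s - MMHG_TO_PA
    f_lo = q_subject(lo) - q_ref
    f_hi = q_subject(hi) - q_ref
    if f_lo == 0.0:
        return lo / MMHG_TO_PA
    if f_hi == 0.0:
        return hi / MMHG_TO_PA
    if f_lo * f_hi > 0:
        raise SolverError(
            "no sign change of Q̄_subject − Q̄_reference in the bracket: "
            f"Q̄(1 mmHg) − Q̄_ref = {f_lo:.4e} m³/min, "
            f"Q̄(p_s − 1 mmHg) − Q̄_ref = {f_hi:.4e} m³/min"
        )

    tol = tol_mmHg * MMHG_TO_PA
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = q_subject(mid) - q_ref
        if f_mid == 0.0 or (hi - lo) / 2.0 < tol:
            return mid / MMHG_TO_PA
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    raise SolverError(f"bisection did not converge in {max_iter} iterations")
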