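"""Processing of expansion-test and biaxial stress–strain curves.

Expansion (inflation) tests record internal pressure against outer diameter
of a tubular artery segment held at its in-vivo axial stretch; biaxial
planar tests give circumferential engineering stress–strain curves. This
module turns those tables into relative strains at clinical pressures,
exponential and linear fits, strain-energy integrals, and the
linear-vs-nonlinear energy comparison that justifies the linear-elastic
treatment over the physiological window.

Engineering strain throughout; tabulated curves are interpolated with
monotone piecewise-linear interpolation and never extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, FitError, InterpolationError

__all__ = [
    "PressureDiameterCurve",
    "StressStrainCurve",
    "ExpFit",
    "LinearFit",
    "relative_strain",
    "strain_at_pressures",
    "fit_exponential",
    "fit_linear_window",
    "strain_energy_integral",
    "linear_vs_integral_ratio",
    "phi_from_compliance",
]

_SEGMENTS = ("ascending", "proximal_descending", "distal_descending")


@dataclass(frozen=True)
class PressureDiameterCurve:
    """Inflation-test record: internal pressure vs outer diameter.

    ``D_o`` is the unstressed outer diameter against which engineering
    strains are formed; ``axial_stretch`` the in-vivo longitudinal stretch
    ratio λ_z at which the segment was held.
    """

    pressures: np.ndarray  # [Pa], strictly increasing
    outer_diameters: np.ndarray  # [m], non-decreasing
    D_o: float  # unstressed outer diameter [m]
    axial_stretch: float = 1.2
    segment: str = "ascending"

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        d = np.asarray(self.outer_diameters, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "outer_diameters", d)
        if p.ndim != 1 or d.ndim != 1 or p.size != d.size or p.size < 3:
            raise DomainError("need equal-length 1-D sequences with >= 3 points")
        if self.D_o <= 0:
            raise DomainError("unstressed diameter must be positive")
        if np.any(np.diff(p) <= 0):
            raise DomainError("pressures must be strictly increasing")
        if np.any(np.diff(d) < 0):
            warnings.warn(
                "outer diameters are not non-decreasing; curve kept but flagged",
                stacklevel=2,
            )
        if self.segment not in _SEGMENTS:
            raise DomainError(
                f"unknown segment {self.segment!r}; expected one of {_SEGMENTS}"
            )


@dataclass(frozen=True)
class StressStrainCurve:
    """Circumferential engineering stress–strain record of a wall specimen."""

    strains: np.ndarray  # engineering strain [-], strictly increasing
    stresses: np.ndarray  # [Pa], non-decreasing
    quadrant: str = "mean"  # ANT | LNT | POST | MED | mean

    def __post_init__(self) -> None:
        e = np.asarray(self.strains, dtype=float)
        s = np.asarray(self.stresses, dtype=float)
        object.__setattr__(self, "strains", e)
        object.__setattr__(self, "stresses", s)
        if e.ndim != 1 or s.ndim != 1 or e.size != s.size or e.size < 3:
            raise DomainError("need equal-length 1-D sequences with >= 3 points")
        if np.any(np.diff(e) <= 0):
            raise DomainError("strains must be strictly increasing")
        if np.any(np.diff(s) < 0):
            warnings.warn(
                "stresses are not non-decreasing; curve kept but flagged",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ExpFit:
    """Origin-anchored exponential stress model σ(ε) = a·(e^{bε} − 1)."""

    a: float  # stress scale [Pa]
    b: float  # strain exponent [-]
    r2: float  # goodness of fit [-]

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise DomainError("exponential fit requires a > 0 and b > 0")

    def __call__(self, eps: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        return self.a * np.expm1(self.b * np.asarray(eps, dtype=float))

    def tangent_modulus(self, eps: float) -> float:
        """dσ/dε = a·b·e^{bε} [Pa]."""
        return self.a * self.b * np.exp(self.b * eps)


@dataclass(frozen=True)
class LinearFit:
    """Linear approximation over a strain window."""

    E_lin: float  # secant/chord modulus [Pa]
    intercept: float  # stress at zero strain of the fitted line [Pa]
    window: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo < hi:
            raise DomainError(f"window must satisfy lo < hi, got {self.window}")

    def __call__(self, eps: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        return self.E_lin * np.asarray(eps, dtype=float) + self.intercept


def relative_strain(D_s: float, D_d: float, D_o: float) -> float:
    """Relative circumferential strain ε_θ = (D_s − D_d)/D_o.

    The difference of the systolic and diastolic engineering strains
    against the unstressed diameter — the telescoping identity makes the
    unstressed reference cancel from the numerator.
    """
    if D_o <= 0:
        raise DomainError("unstressed diameter must be positive")
    if D_s < D_d:
        raise DomainError(f"D_s={D_s} < D_d={D_d}")
    return (D_s - D_d) / D_o


def strain_at_pressures(
    curve: PressureDiameterCurve, p_d: float, p_s: float
) -> tuple[float, float, float]:
    """Engineering strains at the diastolic and systolic pressures.

    Diameters are obtained by monotone piecewise-linear interpolation of the
    tabulated curve (never extrapolated); returns
    ``(eps_d, eps_s, eps_theta)`` with ε_θ = ε_s − ε_d.
    """
    p = curve.pressures
    for name, val in (("p_d", p_d), ("p_s", p_s)):
        if not (p[0] <= val <= p[-1]):
            raise InterpolationError(
                f"{name} = {val:.1f} Pa outside curve range "
                f"[{p[0]:.1f}, {p[-1]:.1f}] Pa (no extrapolation)"
            )
    d_d, d_s = np.interp([p_d, p_s], p, curve.outer_diameters)
    eps_d = (d_d - curve.D_o) / curve.D_o
    eps_s = (d_s - curve.D_o) / curve.D_o
    return eps_d, eps_s, eps_s - eps_d


def _exp_model(eps: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.expm1(b * eps)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_exponential(curve: StressStrainCurve) -> ExpFit:
    """Least-squares fit of σ = a(e^{bε} − 1) to a stress–strain curve.

    Initialisation is deterministic: b₀ from the log-stress slope over the
    upper third of the curve, a₀ from the last point. Soft-tissue curves of
    physiological convexity fit this model with R² ≥ 0.99.
    """
    eps, sig = curve.strains, curve.stresses
    if eps.size < 5:
        raise DomainError("exponential fit requires at least 5 points")

    upper = slice(max(2 * eps.size // 3, eps.size - max(eps.size // 3, 2)), None)
    e_u, s_u = eps[upper], sig[upper]
    pos = s_u > 0
    if pos.sum() >= 2 and np.ptp(e_u[pos]) > 0:
        slope = np.polyfit(e_u[pos], np.log(s_u[pos]), 1)[0]
        b0 = max(slope, 1e-6)
    else:
        b0 = 1.0
    denom = np.expm1(b0 * eps[-1])
    a0 = max(sig[-1] / denom if denom > 0 else 1.0, 1e-12)

    try:
        popt, _ = curve_fit(
            _exp_model, eps, sig, p0=(a0, b0), maxfev=20000,
            bounds=((0.0, 0.0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:
        raise FitError(
            f"exponential fit did not converge (p0=({a0:.3g}, {b0:.3g})): {exc}"
        ) from exc
    a, b = float(popt[0]), float(popt[1])
    r2 = _r_squared(sig, _exp_model(eps, a, b))
    return ExpFit(a=a, b=b, r2=r2)


def fit_linear_window(
    curve: StressStrainCurve,
    window: tuple[float, float],
    method: str = "chord",
) -> LinearFit:
    """Linear approximation of a stress–strain curve over a strain window.

    ``chord`` connects the two window endpoints (the dashed-line
    construction used to justify linear elasticity over the physiological
    pressure range); ``least_squares`` fits all tabulated points inside the
    window.
    """
    lo, hi = window
    e = curve.strains
    if not (e[0] <= lo < hi <= e[-1]):
        raise DomainError(
            f"window {window} outside curve domain [{e[0]}, {e[-1]}] or empty"
        )
    if method == "chord":
        s_lo, s_hi = np.interp([lo, hi], e, curve.stresses)
        slope = (s_hi - s_lo) / (hi - lo)
        return LinearFit(E_lin=slope, intercept=s_lo - slope * lo, window=window)
    if method == "least_squares":
        mask = (e >= lo) & (e <= hi)
        xs = np.concatenate([[lo], e[mask], [hi]])
        ys = np.concatenate(
            [[np.interp(lo, e, curve.stresses)], curve.stresses[mask],
             [np.interp(hi, e, curve.stresses)]]
        )
        xs, idx = np.unique(xs, return_index=True)
        ys = ys[idx]
        slope, intercept = np.polyfit(xs, ys, 1)
        return LinearFit(E_lin=float(slope), intercept=float(intercept), window=window)
    raise DomainError(f"unknown method {method!r}; expected chord or least_squares")


def strain_energy_integral(
    curve_or_fit: Union[StressStrainCurve, ExpFit],
    eps_lo: float,
    eps_hi: float,
    *,
    n_panels: int = 200,
) -> float:
    """Strain energy density ∫σ dε over [ε_lo, ε_hi] [J/m³].

    Tabulated curves are integrated with the composite trapezoid rule on the
    tabulated knots plus interpolated endpoints; exponential fits use the
    closed-form antiderivative a·(e^{bε}−1)/b − a·ε evaluated at the bounds
    (``n_panels`` is ignored in that case).
    """
    if eps_lo > eps_hi:
        raise DomainError(f"need eps_lo <= eps_hi, got ({eps_lo}, {eps_hi})")
    if eps_lo == eps_hi:
        return 0.0

    if isinstance(curve_or_fit, ExpFit):
        a, b = curve_or_fit.a, curve_or_fit.b

        def antider(eps: float) -> float:
            return a * np.expm1(b * eps) / b - a * eps

        return antider(eps_hi) - antider(eps_lo)

    curve = curve_or_fit
    e = curve.strains
    if not (e[0] <= eps_lo and eps_hi <= e[-1]):
        raise DomainError(
            f"bounds ({eps_lo}, {eps_hi}) outside curve domain [{e[0]}, {e[-1]}]"
        )
    interior = e[(e > eps_lo) & (e < eps_hi)]
    grid = np.concatenate([[eps_lo], interior, [eps_hi]])
    if grid.size - 1 < n_panels:
        grid = np.union1d(grid, np.linspace(eps_lo, eps_hi, n_panels + 1))
    vals = np.interp(grid, e, curve.stresses)
    return float(np.trapezoid(vals, grid))


def linear_vs_integral_ratio(
    curve: Union[StressStrainCurve, ExpFit],
    window: tuple[float, float],
) -> float:
    """Percent by which the chord (linear) energy exceeds the integral.

    The linear estimate is the full trapezoid between the window endpoints,
    (σ_lo + σ_hi)/2 · (ε_hi − ε_lo) — the diastole-to-systole chord area
    including the rectangle below the diastolic stress, matching the region
    measured by the integral ∫σ dε. Positive for convex (stiffening)
    curves; 0 for exactly linear ones.
    """
    lo, hi = window
    if not lo < hi:
        raise DomainError(f"empty window {window}")
    if isinstance(curve, ExpFit):
        s_lo, s_hi = curve(lo), curve(hi)
    else:
        e = curve.strains
        if not (e[0] <= lo and hi <= e[-1]):
            raise DomainError(f"window {window} outside curve domain")
        s_lo, s_hi = np.interp([lo, hi], e, curve.stresses)
    chord_area = 0.5 * (s_lo + s_hi) * (hi - lo)
    integral = strain_energy_integral(curve, lo, hi)
    if integral == 0:
        raise DomainError("zero strain-energy integral over the window")
    return 100.0 * (chord_area - integral) / integral


def phi_from_compliance(
    C: float, E: float, h: float, A: float, D: float, L: float
) -> float:
    """Expansion constraint coefficient from volumetric compliance.

    Inverts the segment compliance implied by the pressure–area relation
    dA/dp = φ·A·D/(E·h) integrated over an effective length L:
    φ = C·E·h/(L·A·D). Round-trips exactly with the area-strain relation.

    ``D`` is the inner diameter, ``A`` the lumen area, ``L`` the effective
    length over which the compliance C [m³/Pa] is attributed.
    """
    if min(C, E, h, A, D, L) <= 0:
        raise DomainError("all inputs must be positive")
    return C * E * h / (L * A * D)
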