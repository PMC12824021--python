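"""Quasi-static inflation-extension of an incompressible anisotropic
thick-walled tube.

This is the forward model of the estimation pipeline: it maps a zero-pressure
tube geometry, a luminal pressure and an axial stretch to the deformed lumen
perimeter and the transmural stress profile.  The kinematics are the
classical inflation-extension family

    r(R)^2 = r_i^2 + (R^2 - R_i^2) / lambda_z,

which conserves wall volume exactly, with circumferential stretch
lambda_theta = r/R and radial stretch 1/(lambda_theta * lambda_z).  Radial
equilibrium integrates to the pressure relation

    P = int_{r_i}^{r_o} (sigma_theta - sigma_r) / r dr,

where the stress difference follows from the strain energy with the radial
stretch eliminated; the Lagrange pressure cancels in the difference and is
recovered afterwards from the traction condition sigma_r(r_o) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

from .constitutive import MaterialParams, _EXP_LIMIT

__all__ = [
    "TubeGeometry",
    "LoadState",
    "DeformedTube",
    "mmhg_to_kpa",
    "luminal_pressure",
    "deformed_inner_radius",
    "inflate",
]

#: kPa per mmHg (one standard atmosphere = 760 mmHg = 101.325 kPa).
KPA_PER_MMHG = 101.325 / 760.0


@dataclass(frozen=True)
class TubeGeometry:
    """Zero-pressure (reference) tube cross-section, in millimetres."""

    inner_radius_0: float
    thickness_0: float

    def __post_init__(self) -> None:
        if self.inner_radius_0 <= 0 or self.thickness_0 <= 0:
            raise ValueError("tube dimensions must be positive")
        if self.thickness_0 >= self.inner_radius_0:
            raise ValueError(
                "wall thicker than the lumen radius is outside the physiological "
                f"regime (t0={self.thickness_0}, Ri0={self.inner_radius_0})"
            )

    @property
    def outer_radius_0(self) -> float:
        return self.inner_radius_0 + self.thickness_0


@dataclass(frozen=True)
class LoadState:
    """Luminal pressure (kPa) and imposed axial stretch."""

    pressure: float
    axial_stretch: float = 1.25

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be nonnegative")
        if self.axial_stretch <= 0:
            raise ValueError("axial stretch must be positive")


@dataclass
class DeformedTube:
    """Deformed configuration and transmural stress profile."""

    inner_radius: float  # mm
    outer_radius: float  # mm
    lumen_perimeter: float  # cm
    profile: pd.DataFrame  # radius_mm, sigma_theta_kPa, sigma_r_kPa, sigma_z_kPa
    max_principal_stress_lumen: float  # kPa

    def profile_to_csv(self, path) -> None:
        self.profile.to_csv(path, index=False)


def mmhg_to_kpa(pressure_mmHg: float) -> float:
    """Convert a cuff pressure from mmHg to kPa."""
    if pressure_mmHg < 0:
        raise ValueError("pressure must be nonnegative")
    return pressure_mmHg * KPA_PER_MMHG


def _stress_differences(params: MaterialParams, lt, lz):
    """(sigma_theta - sigma_r, sigma_z - sigma_r) for stretches (lt, lz),
    vectorized over lt.  The Lagrange pressure cancels in each difference."""
    lt = np.asarray(lt, dtype=float)
    lr = 1.0 / (lt * lz)
    I1 = lt * lt + lz * lz + lr * lr
    th = params.theta_rad
    cos2, sin2 = math.cos(th) ** 2, math.sin(th) ** 2
    I4 = lt * lt * cos2 + lz * lz * sin2
    arg1 = params.D2 * (I1 - 3.0)
    e = I4 - 1.0
    arg2 = params.K2 * e * e
    if np.any(arg1 > _EXP_LIMIT) or np.any(arg2 > _EXP_LIMIT):
        raise OverflowError("wall stretch outside the model's validity range")
    psi1 = params.c1 + params.D1 * params.D2 * np.exp(arg1)
    fiber = 2.0 * params.K1 * e * np.exp(arg2)
    lr2 = lr * lr
    d_theta = 2.0 * psi1 * (lt * lt - lr2) + 2.0 * fiber * lt * lt * cos2
    d_axial = 2.0 * psi1 * (lz * lz - lr2) + 2.0 * fiber * lz * lz * sin2
    return d_theta, d_axial


_GAUSS_ORDER = 16
_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(_GAUSS_ORDER)


def luminal_pressure(
    geometry: TubeGeometry,
    params: MaterialParams,
    inner_radius_current: float,
    axial_stretch: float,
    quadrature_order: int | None = None,
) -> float:
    """Luminal pressure (kPa) holding the tube at a given deformed inner
    radius under the imposed axial stretch.

    Evaluates P = int (sigma_theta - sigma_r)/r dr across the wall by
    fixed-order Gauss-Legendre quadrature over the reference radius.
    """
    if inner_radius_current <= 0:
        raise ValueError("deformed inner radius must be positive")
    if quadrature_order is None:
        nodes, weights = _GAUSS_NODES, _GAUSS_WEIGHTS
    else:
        nodes, weights = np.polynomial.legendre.leggauss(quadrature_order)
    Ri, Ro = geometry.inner_radius_0, geometry.outer_radius_0
    lz = axial_stretch
    half = 0.5 * (Ro - Ri)
    R = Ri + half * (nodes + 1.0)
    r2 = inner_radius_current**2 + (R * R - Ri * Ri) / lz
    r = np.sqrt(r2)
    lt = r / R
    d_theta, _ = _stress_differences(params, lt, lz)
    # dr/dR = R / (lambda_z * r)  =>  integrand over R is d_theta * R/(lz r^2)
    integrand = d_theta * R / (lz * r2)
    value = half * float(np.dot(weights, integrand))
    if not np.isfinite(value):
        raise OverflowError("pressure integral is non-finite")
    return value


def deformed_inner_radius(
    geometry: TubeGeometry,
    params: MaterialParams,
    load: LoadState,
    radius_tol: float = 1e-10,
) -> float:
    """Deformed inner radius (mm) at which the equilibrium pressure integral
    matches the applied luminal pressure (safeguarded bracketing root find).
    """
    Ri = geometry.inner_radius_0
    lz = load.axial_stretch
    target = load.pressure

    def f(ri: float) -> float:
        return luminal_pressure(geometry, params, ri, lz) - target

    lo = 0.2 * Ri / math.sqrt(lz)
    hi = Ri
    f_hi = f(hi)
    n_expand = 0
    while f_hi < 0.0:
        hi *= 1.3
        n_expand += 1
        if n_expand > 40:
            raise RuntimeError(
                f"pressure {target:.4g} kPa exceeds the inflation limit of the tube"
            )
        try:
            f_hi = f(hi)
        except OverflowError as err:
            raise RuntimeError(
                f"pressure {target:.4g} kPa exceeds the inflation limit of the tube"
            ) from err
    if f(lo) > 0.0:
        raise RuntimeError("lower bracket does not enclose the equilibrium radius")
    return brentq(f, lo, hi, xtol=radius_tol, rtol=8.9e-16)


def inflate(
    geometry: TubeGeometry,
    params: MaterialParams,
    load: LoadState,
    radius_tol: float = 1e-10,
    n_profile: int = 201,
) -> DeformedTube:
    """Solve the inflation-extension boundary-value problem.

    Finds the deformed inner radius matching the applied luminal pressure,
    then reconstructs the transmural Cauchy stress profile with the Lagrange
    pressure set by sigma_r = -P at the lumen and sigma_r = 0 at the outer
    surface.
    """
    Ri = geometry.inner_radius_0
    lz = load.axial_stretch
    target = load.pressure
    ri = deformed_inner_radius(geometry, params, load, radius_tol)

    # transmural profile on a dense reference grid
    R = np.linspace(Ri, geometry.outer_radius_0, n_profile)
    r = np.sqrt(ri * ri + (R * R - Ri * Ri) / lz)
    lt = r / R
    d_theta, d_axial = _stress_differences(params, lt, lz)
    # sigma_r(r) = -P + int_{r_i}^{r} d_theta/rho drho
    integrand = d_theta / r
    sigma_r = -target + cumulative_trapezoid(integrand, r, initial=0.0)
    sigma_theta = sigma_r + d_theta
    sigma_z = sigma_r + d_axial
    profile = pd.DataFrame(
        {
            "radius_mm": r,
            "sigma_theta_kPa": sigma_theta,
            "sigma_r_kPa": sigma_r,
            "sigma_z_kPa": sigma_z,
        }
    )
    r_out = float(r[-1])
    return DeformedTube(
        inner_radius=ri,
        outer_radius=r_out,
        lumen_perimeter=2.0 * math.pi * ri / 10.0,  # mm -> cm
        profile=profile,
        max_principal_stress_lumen=float(sigma_theta[0]),
    )
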