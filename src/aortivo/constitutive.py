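"""Anisotropic Mooney-Rivlin constitutive model for arterial wall tissue.

The strain-energy density combines an isotropic Mooney-Rivlin/exponential
matrix response with an exponential contribution from two collagen-fiber
families lying in the circumferential-axial plane, symmetric about the
circumferential direction at half-angle ``theta``:

    W = c1*(I1 - 3) + D1*(exp(D2*(I1 - 3)) - 1)
      + K1/(2*K2) * [exp(K2*(J4 - 1)^2) + exp(K2*(J6 - 1)^2) - 2]

where I1 is the first invariant of the right Cauchy-Green tensor C, and
J4 = I4 * I3^(-1/3), J6 = I6 * I3^(-1/3) are the volume-normalized squared
fiber stretches of the two families.  The material is treated as
incompressible; shear-free loading aligned with the (circumferential, axial,
radial) material frame is assumed throughout, so C is diagonal and I4 = I6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "KinematicState",
    "StressState",
    "invariants_from_stretches",
    "strain_energy",
    "biaxial_cauchy_stress",
    "stress_stretch_curve",
]

#: Positive floor replacing K2 = 0, guarding the 1/K2 factor in the energy.
K2_FLOOR = 1e-6

#: Largest exponent accepted inside the exponentials before an explicit
#: range error is raised (exp(700) is near the float64 overflow threshold).
_EXP_LIMIT = 500.0


@dataclass(frozen=True)
class MaterialParams:
    """The six coefficients of the anisotropic Mooney-Rivlin model.

    Parameters
    ----------
    c1, D1, K1 : float
        Stress-like coefficients (kPa); the response is homogeneous of
        degree one in this triple.
    D2, K2 : float
        Dimensionless exponents of the isotropic and fiber exponentials.
    theta : float
        Fiber half-angle from the circumferential direction, in degrees.
        Fitting constrains it to (0, 45); storage allows values below 90
        for sensitivity studies.
    """

    c1: float
    D1: float
    D2: float
    K1: float
    K2: float
    theta: float

    def __post_init__(self) -> None:
        for name in ("c1", "D1", "D2", "K1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.K2 <= 0:
            object.__setattr__(self, "K2", K2_FLOOR)
        if not (0.0 <= self.theta < 90.0):
            raise ValueError(f"theta must lie in [0, 90) degrees, got {self.theta}")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    def scaled(self, k: float) -> "MaterialParams":
        """Scale the stress-like triple (c1, D1, K1) by ``k``; exponents and
        fiber angle are unchanged.  This is the stiffness-scale operation of
        the inverse algorithm's inner loop."""
        if k <= 0:
            raise ValueError(f"stiffness scale must be positive, got {k}")
        return replace(self, c1=self.c1 * k, D1=self.D1 * k, K1=self.K1 * k)

    def to_dict(self) -> dict:
        return {
            "c1_kPa": self.c1,
            "D1_kPa": self.D1,
            "D2": self.D2,
            "K1_kPa": self.K1,
            "K2": self.K2,
            "theta_deg": self.theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParams":
        return cls(
            c1=float(d["c1_kPa"]),
            D1=float(d["D1_kPa"]),
            D2=float(d["D2"]),
            K1=float(d["K1_kPa"]),
            K2=float(d["K2"]),
            theta=float(d["theta_deg"]),
        )


@dataclass(frozen=True)
class KinematicState:
    """Diagonal deformation state in the (circumferential, axial, radial)
    material frame, with the scalar invariants used by the energy."""

    lambda_c: float
    lambda_a: float
    lambda_r: float
    theta: float  # fiber half-angle, degrees
    I1: float = field(init=False)
    I2: float = field(init=False)
    I3: float = field(init=False)
    I4: float = field(init=False)
    I6: float = field(init=False)
    J4: float = field(init=False)
    J6: float = field(init=False)

    def __post_init__(self) -> None:
        lc, la, lr = self.lambda_c, self.lambda_a, self.lambda_r
        if lc <= 0 or la <= 0 or lr <= 0:
            raise ValueError("principal stretches must be positive")
        if not (0.0 <= self.theta < 90.0):
            raise ValueError(f"theta must lie in [0, 90) degrees, got {self.theta}")
        c_diag = (lc * lc, la * la, lr * lr)
        I1 = sum(c_diag)
        I2 = 0.5 * (I1 * I1 - sum(x * x for x in c_diag))
        I3 = c_diag[0] * c_diag[1] * c_diag[2]
        th = math.radians(self.theta)
        cos2, sin2 = math.cos(th) ** 2, math.sin(th) ** 2
        # both families lie at +/-theta from circumferential: I4 = I6
        I4 = c_diag[0] * cos2 + c_diag[1] * sin2
        scale = I3 ** (-1.0 / 3.0)
        for name, value in (
            ("I1", I1), ("I2", I2), ("I3", I3),
            ("I4", I4), ("I6", I4), ("J4", I4 * scale), ("J6", I4 * scale),
        ):
            object.__setattr__(self, name, value)

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor (diagonal in the material frame)."""
        return np.diag([self.lambda_c**2, self.lambda_a**2, self.lambda_r**2])

    @property
    def fiber_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit fiber vectors (na, nb) at +/-theta from circumferential."""
        th = math.radians(self.theta)
        na = np.array([math.cos(th), math.sin(th), 0.0])
        nb = np.array([math.cos(th), -math.sin(th), 0.0])
        return na, nb


@dataclass(frozen=True)
class StressState:
    """Cauchy and engineering stresses of a plane-stress biaxial state."""

    sigma_c: float
    sigma_a: float
    sigma_r: float
    P_c: float
    P_a: float
    p: float  # Lagrange pressure enforcing incompressibility (kPa)


def invariants_from_stretches(
    lambda_c: float, lambda_a: float, lambda_r: float, theta: float
) -> KinematicState:
    """Build a :class:`KinematicState` from principal stretches and the fiber
    half-angle ``theta`` (degrees)."""
    return KinematicState(lambda_c, lambda_a, lambda_r, theta)


def _checked_exp(x: float) -> float:
    if x > _EXP_LIMIT:
        raise OverflowError(
            f"exponential argument {x:.3g} exceeds the supported range; "
            "the deformation is outside the model's validity"
        )
    return math.exp(x)


def strain_energy(params: MaterialParams, state: KinematicState) -> float:
    """Strain-energy density (kPa) of the anisotropic Mooney-Rivlin model.

    For ``K2`` below the positive floor the fiber term uses its analytic
    limit ``(K1/2) * [(J4-1)^2 + (J6-1)^2]``.
    """
    iso = params.c1 * (state.I1 - 3.0) + params.D1 * (
        _checked_exp(params.D2 * (state.I1 - 3.0)) - 1.0
    )
    e4, e6 = state.J4 - 1.0, state.J6 - 1.0
    if params.K2 <= K2_FLOOR:
        aniso = 0.5 * params.K1 * (e4 * e4 + e6 * e6)
    else:
        aniso = (
            params.K1
            / (2.0 * params.K2)
            * (_checked_exp(params.K2 * e4 * e4) + _checked_exp(params.K2 * e6 * e6) - 2.0)
        )
    return iso + aniso


def _dW_terms(params: MaterialParams, lc: float, la: float):
    """Energy derivatives of the incompressible plane state (lr eliminated).

    Returns (psi1, fiber, lr, I4) where psi1 = dW/dI1 and
    fiber = dW/dJ4 + dW/dJ6 evaluated at J4 = J6 = I4 (I3 = 1).
    """
    lr = 1.0 / (lc * la)
    I1 = lc * lc + la * la + lr * lr
    th = params.theta_rad
    I4 = lc * lc * math.cos(th) ** 2 + la * la * math.sin(th) ** 2
    psi1 = params.c1 + params.D1 * params.D2 * _checked_exp(params.D2 * (I1 - 3.0))
    e = I4 - 1.0
    # d/dJ4 of K1/(2 K2) exp(K2 (J4-1)^2) = K1 (J4-1) exp(K2 (J4-1)^2);
    # identical for J6, and continuous through the K2 -> 0 limit.
    fiber = 2.0 * params.K1 * e * _checked_exp(params.K2 * e * e)
    return psi1, fiber, lr, I4


def biaxial_cauchy_stress(
    params: MaterialParams, lambda_c: float, lambda_a: float
) -> StressState:
    """Cauchy and engineering stresses of an incompressible plane-stress
    biaxial state with in-plane stretches (lambda_c, lambda_a).

    Incompressibility sets ``lambda_r = 1/(lambda_c * lambda_a)``; the
    traction-free radial face (sigma_r = 0) determines the Lagrange
    pressure.  With the radial stretch eliminated,

        sigma_i = lambda_i * dW^/dlambda_i,   i in {c, a},

    where W^ is the strain energy as a function of the in-plane stretches.
    """
    if lambda_c <= 0 or lambda_a <= 0:
        raise ValueError("stretches must be positive")
    psi1, fiber, lr, _ = _dW_terms(params, lambda_c, lambda_a)
    th = params.theta_rad
    lr2 = lr * lr
    sigma_c = 2.0 * psi1 * (lambda_c**2 - lr2) + fiber * 2.0 * lambda_c**2 * math.cos(th) ** 2
    sigma_a = 2.0 * psi1 * (lambda_a**2 - lr2) + fiber * 2.0 * lambda_a**2 * math.sin(th) ** 2
    # sigma_r = 2 psi1 lr^2 - p = 0  =>  p = 2 psi1 lr^2
    p = 2.0 * psi1 * lr2
    return StressState(
        sigma_c=sigma_c,
        sigma_a=sigma_a,
        sigma_r=0.0,
        P_c=sigma_c / lambda_c,
        P_a=sigma_a / lambda_a,
        p=p,
    )


def _uniaxial_transverse_stretch(params: MaterialParams, lam: float, axis: str) -> float:
    """Transverse in-plane stretch that zeroes the transverse Cauchy stress
    in a uniaxial test at longitudinal stretch ``lam``."""
    from scipy.optimize import brentq

    def resid(lt: float) -> float:
        if axis == "c":
            return biaxial_cauchy_stress(params, lam, lt).sigma_a
        return biaxial_cauchy_stress(params, lt, lam).sigma_c

    lo, hi = 0.2, max(1.05, lam)
    flo, fhi = resid(lo), resid(hi)
    if flo * fhi > 0:
        raise RuntimeError(
            f"uniaxial transverse equilibrium not bracketed at stretch {lam:.4f} "
            f"(residuals {flo:.3g}, {fhi:.3g})"
        )
    return brentq(resid, lo, hi, xtol=1e-12, rtol=1e-12)


def stress_stretch_curve(
    params: MaterialParams,
    direction: str = "c",
    protocol: str = "equibiaxial",
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Cauchy stress-stretch curve in one direction under a standard loading
    protocol.

    Parameters
    ----------
    direction : {"c", "a"}
        Circumferential or axial response.
    protocol : {"equibiaxial", "uniaxial", "strip"}
        equibiaxial: both in-plane stretches equal the grid value;
        uniaxial: transverse in-plane stress driven to zero by a nested
        root find; strip: transverse stretch held at 1 (strip-biaxial).
    grid : array of stretches, default 31 uniform points on [1.0, 1.3].

    Returns
    -------
    (n, 2) array of (stretch, Cauchy stress in kPa) rows.
    """
    if direction not in ("c", "a"):
        raise ValueError(f"direction must be 'c' or 'a', got {direction!r}")
    if protocol not in ("equibiaxial", "uniaxial", "strip"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if grid is None:
        grid = np.linspace(1.0, 1.3, 31)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array of length >= 2")

    out = np.empty((grid.size, 2))
    for i, lam in enumerate(grid):
        if protocol == "equibiaxial":
            lc = la = lam
        elif protocol == "strip":
            lc, la = (lam, 1.0) if direction == "c" else (1.0, lam)
        else:  # uniaxial
            lt = _uniaxial_transverse_stretch(params, lam, direction)
            lc, la = (lam, lt) if direction == "c" else (lt, lam)
        s = biaxial_cauchy_stress(params, lc, la)
        out[i] = (lam, s.sigma_c if direction == "c" else s.sigma_a)
    return out
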