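"""Planar biaxial test simulation and constitutive parameter identification.

Force-controlled biaxial rigs load a square tissue sample along its
circumferential and axial edges at a fixed force ratio; engineering (first
Piola-Kirchhoff) stress vs stretch is recorded per protocol.  Five protocols
with circumferential:axial force ratios 1:1, 1:0.75, 0.75:1, 1:0.5 and 0.5:1
at a 2.0 N maximal force are the standard battery for aortic samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, root

from .constitutive import K2_FLOOR, MaterialParams, biaxial_cauchy_stress

__all__ = [
    "BiaxialProtocol",
    "SampleGeometry",
    "BiaxialDataset",
    "FitResult",
    "STANDARD_PROTOCOLS",
    "force_to_stress",
    "simulate_protocol",
    "fit_parameters",
]

DATASET_COLUMNS = ["protocol_id", "load_fraction", "lambda_c", "lambda_a", "Pc_kPa", "Pa_kPa"]


@dataclass(frozen=True)
class BiaxialProtocol:
    """One force-controlled loading protocol."""

    force_ratio_c: float
    force_ratio_a: float
    max_force: float = 2.0  # N
    n_steps: int = 20

    def __post_init__(self) -> None:
        for r in (self.force_ratio_c, self.force_ratio_a):
            if not (0.0 < r <= 1.0):
                raise ValueError(f"force ratios must lie in (0, 1], got {r}")
        if self.max_force <= 0:
            raise ValueError("max_force must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def id(self) -> str:
        return f"{self.force_ratio_c:g}:{self.force_ratio_a:g}"


#: The five standard protocols (circumferential:axial force ratio, 2.0 N max).
STANDARD_PROTOCOLS: tuple[BiaxialProtocol, ...] = (
    BiaxialProtocol(1.0, 1.0),
    BiaxialProtocol(1.0, 0.75),
    BiaxialProtocol(0.75, 1.0),
    BiaxialProtocol(1.0, 0.5),
    BiaxialProtocol(0.5, 1.0),
)


@dataclass(frozen=True)
class SampleGeometry:
    """Undeformed square-sample geometry (edge ~2 cm, subject-specific
    thickness)."""

    edge_length: float = 20.0  # mm
    thickness: float = 2.0  # mm

    def __post_init__(self) -> None:
        if self.edge_length <= 0 or self.thickness <= 0:
            raise ValueError("sample dimensions must be positive")


@dataclass
class BiaxialDataset:
    """Stretch/engineering-stress records pooled over loading protocols."""

    data: pd.DataFrame
    provenance: str = "measured"
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BiaxialDataset":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"empty biaxial dataset: {path}")
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset {path} missing columns: {missing}")
        return cls(data=df[DATASET_COLUMNS].astype(float, errors="ignore"))


@dataclass
class FitResult:
    """Outcome of a bounded least-squares constitutive fit."""

    params: MaterialParams
    r_squared: float
    residual_norm: float
    n_records: int
    n_restarts: int
    converged: bool
    message: str = ""


def force_to_stress(force_N: float, geometry: SampleGeometry) -> float:
    """Engineering (first Piola-Kirchhoff) stress in kPa from an applied edge
    force in newtons: P = F / (edge_length * thickness)."""
    if geometry.edge_length <= 0 or geometry.thickness <= 0:
        raise ValueError("sample cross-section must have positive area")
    area_m2 = (geometry.edge_length * 1e-3) * (geometry.thickness * 1e-3)
    return force_N / area_m2 / 1e3  # Pa -> kPa


def _solve_stretches(
    params: MaterialParams, target_Pc: float, target_Pa: float, x0: np.ndarray
) -> np.ndarray:
    """In-plane stretches at which the engineering stresses equal the
    targets (plane stress, incompressible)."""

    def resid(x):
        lc, la = x
        if lc <= 0.05 or la <= 0.05:
            return [1e6, 1e6]
        s = biaxial_cauchy_stress(params, lc, la)
        return [s.P_c - target_Pc, s.P_a - target_Pa]

    sol = root(resid, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8 * max(1.0, target_Pc, target_Pa):
        raise RuntimeError(
            f"biaxial stretch solve failed at targets ({target_Pc:.4g}, {target_Pa:.4g}) kPa: "
            f"{sol.message}"
        )
    return sol.x


def simulate_protocol(
    params: MaterialParams,
    geometry: SampleGeometry,
    protocol: BiaxialProtocol,
) -> pd.DataFrame:
    """Simulate one force-controlled protocol.

    Each load fraction t in (0, 1] prescribes target engineering stresses
    (t * ratio_c * Pmax, t * ratio_a * Pmax); the in-plane stretches solving
    the plane-stress equilibrium are found by a warm-started 2-D root find.
    """
    p_max = force_to_stress(protocol.max_force, geometry)
    rows = []
    guess = np.array([1.0, 1.0])
    for step in range(1, protocol.n_steps + 1):
        t = step / protocol.n_steps
        tc = t * protocol.force_ratio_c * p_max
        ta = t * protocol.force_ratio_a * p_max
        try:
            guess = _solve_stretches(params, tc, ta, guess)
        except RuntimeError as err:
            raise RuntimeError(f"protocol {protocol.id}, step {step}: {err}") from err
        rows.append((protocol.id, t, guess[0], guess[1], tc, ta))
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


_DEFAULT_BOUNDS = {
    "c1": (0.0, 100.0),
    "D1": (0.0, 500.0),
    "D2": (0.0, 30.0),
    "K1": (0.0, 500.0),
    "K2": (K2_FLOOR, 200.0),
    "theta": (1e-3, 45.0 - 1e-3),
}


def _pack(p: MaterialParams) -> np.ndarray:
    return np.array([p.c1, p.D1, p.D2, p.K1, p.K2, p.theta])


def _unpack(x: np.ndarray) -> MaterialParams:
    return MaterialParams(c1=x[0], D1=x[1], D2=x[2], K1=x[3], K2=x[4], theta=x[5])


def _predict(params: MaterialParams, lc: np.ndarray, la: np.ndarray) -> np.ndarray:
    """Stacked engineering stresses (Pc then Pa) at the observed stretches."""
    pc = np.empty(lc.size)
    pa = np.empty(lc.size)
    for i in range(lc.size):
        s = biaxial_cauchy_stress(params, lc[i], la[i])
        pc[i], pa[i] = s.P_c, s.P_a
    return np.concatenate([pc, pa])


def fit_parameters(
    dataset: BiaxialDataset,
    bounds: dict | None = None,
    initial_guess: MaterialParams | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Identify the six constitutive coefficients from biaxial data by
    bounded trust-region-reflective least squares.

    Residuals pool both stress components over every record of every
    protocol with equal weight.  The landscape is nonconvex; seeded
    multi-start over log-uniform coefficient ranges guards against local
    minima, the lowest residual wins (ties broken by lower K1).  R^2 is
    computed about the pooled mean of both stress components.
    """
    df = dataset.data
    protocols = df["protocol_id"].nunique()
    if protocols < 2:
        raise ValueError(
            f"anisotropy is not identifiable from {protocols} protocol(s); need >= 2"
        )
    lc = df["lambda_c"].to_numpy(float)
    la = df["lambda_a"].to_numpy(float)
    obs = np.concatenate([df["Pc_kPa"].to_numpy(float), df["Pa_kPa"].to_numpy(float)])
    if obs.size <= 6:
        raise ValueError(f"{obs.size} residuals cannot identify 6 parameters")

    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[k][0] for k in ("c1", "D1", "D2", "K1", "K2", "theta")])
    hi = np.array([b[k][1] for k in ("c1", "D1", "D2", "K1", "K2", "theta")])

    def residuals(x):
        try:
            return _predict(_unpack(x), lc, la) - obs
        except OverflowError:
            return np.full(obs.size, 1e6)

    rng = np.random.default_rng(seed)
    starts = []
    if initial_guess is not None:
        starts.append(np.clip(_pack(initial_guess), lo, hi))
    starts.append(np.clip(np.array([1.0, 10.0, 1.0, 1.0, 1.0, 10.0]), lo, hi))
    while len(starts) < n_restarts:
        x = np.array(
            [
                10.0 ** rng.uniform(-2, 1.3),   # c1
                10.0 ** rng.uniform(-1, 2),     # D1
                rng.uniform(0.2, 3.0),          # D2
                10.0 ** rng.uniform(-2, 1.5),   # K1
                10.0 ** rng.uniform(-2, 1.3),   # K2
                rng.uniform(2.0, 43.0),         # theta
            ]
        )
        starts.append(np.clip(x, lo, hi))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        key = (sol.cost, sol.x[3])  # ties broken by lower K1
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError("all least-squares restarts failed")
    sol = best[1]
    fitted = _unpack(sol.x)
    pred = _predict(fitted, lc, la)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(
        params=fitted,
        r_squared=r2,
        residual_norm=math.sqrt(ss_res),
        n_records=len(df),
        n_restarts=len(starts),
        converged=bool(sol.success),
        message=sol.message,
    )
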