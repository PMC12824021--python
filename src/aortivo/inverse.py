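"""Triple-loop inverse estimation of in vivo vessel material properties.

Two in vivo observations are available per subject: the lumen perimeter at
diastolic pressure (its minimum over the cardiac cycle) and at systolic
pressure (its maximum).  Two unknowns are therefore identifiable: the
circumferential shrinkage ratio ``S`` mapping the in vivo reference
perimeter to the zero-pressure perimeter, and the stiffness scale ``k``
multiplying the stress-like coefficients (c1, D1, K1) of the initial
constitutive guess.  The inner loop solves for (S, k) with the exponents
K2 and the fiber angle theta held fixed.  When no (S, k) within the
physiological constraints 0 < S <= 1, k > 0 matches both perimeters — which
happens when the initial guess's anisotropy deviates strongly from the
tissue's — the middle loop steps K2 (step 0.01) and the outer loop steps
theta (step 1 degree) until a feasible solution is found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constitutive import K2_FLOOR, MaterialParams
from .metrics import anisotropy_index, effective_young_modulus, relative_error
from .tube import (
    LoadState,
    TubeGeometry,
    deformed_inner_radius,
    luminal_pressure,
    mmhg_to_kpa,
)

__all__ = [
    "SubjectRecord",
    "IterationConfig",
    "InnerLoopResult",
    "InverseResult",
    "NoSolutionError",
    "zero_pressure_geometry",
    "inner_loop",
    "triple_loop",
    "run_setting",
]


class NoSolutionError(RuntimeError):
    """Raised when the full middle/outer correction budget is exhausted."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's non-invasive measurements.

    Pressures are cuff pressures in mmHg; perimeters are TEE lumen
    perimeters in cm (minimum at diastole, maximum at systole); thickness is
    the in vivo wall thickness in mm.  The reference perimeter anchoring the
    shrinkage defaults to the systolic (maximum) perimeter; only the product
    S * reference_perimeter enters the physics, so this convention rescales
    S, not the recovered material.
    """

    id: str
    pressure_sys: float
    pressure_dia: float
    perimeter_min: float
    perimeter_max: float
    thickness: float
    reference_perimeter: float | None = None
    axial_stretch: float = 1.25

    def __post_init__(self) -> None:
        if not (self.pressure_sys > self.pressure_dia > 0):
            raise ValueError(
                f"{self.id}: need pressure_sys > pressure_dia > 0, got "
                f"{self.pressure_sys}/{self.pressure_dia}"
            )
        if not (self.perimeter_max >= self.perimeter_min > 0):
            raise ValueError(
                f"{self.id}: need perimeter_max >= perimeter_min > 0, got "
                f"{self.perimeter_max}/{self.perimeter_min}"
            )
        if self.thickness <= 0:
            raise ValueError(f"{self.id}: thickness must be positive")
        if self.axial_stretch <= 0:
            raise ValueError(f"{self.id}: axial stretch must be positive")

    @property
    def reference(self) -> float:
        return (
            self.reference_perimeter
            if self.reference_perimeter is not None
            else self.perimeter_max
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "pressure_sys_mmHg": self.pressure_sys,
            "pressure_dia_mmHg": self.pressure_dia,
            "perimeter_min_cm": self.perimeter_min,
            "perimeter_max_cm": self.perimeter_max,
            "thickness_mm": self.thickness,
            "reference_perimeter_cm": self.reference_perimeter,
            "axial_stretch": self.axial_stretch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectRecord":
        return cls(
            id=str(d["id"]),
            pressure_sys=float(d["pressure_sys_mmHg"]),
            pressure_dia=float(d["pressure_dia_mmHg"]),
            perimeter_min=float(d["perimeter_min_cm"]),
            perimeter_max=float(d["perimeter_max_cm"]),
            thickness=float(d["thickness_mm"]),
            reference_perimeter=(
                float(d["reference_perimeter_cm"])
                if d.get("reference_perimeter_cm") is not None
                else None
            ),
            axial_stretch=float(d.get("axial_stretch", 1.25)),
        )


@dataclass(frozen=True)
class IterationConfig:
    """Numerical settings of the triple-loop algorithm."""

    delta_K2: float = 0.01
    delta_theta: float = 1.0  # degrees
    k_bracket: tuple[float, float] = (1e-3, 1e3)
    perimeter_rtol: float = 1e-5
    max_inner: int = 200
    max_middle: int = 40
    max_outer: int = 45
    s_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.delta_K2 <= 0 or self.delta_theta <= 0 or self.perimeter_rtol <= 0:
            raise ValueError("steps and tolerances must be positive")
        if not (0 < self.k_bracket[0] < self.k_bracket[1]):
            raise ValueError("k bracket must be ordered and positive")


@dataclass
class InnerLoopResult:
    """Outcome of one inner-loop solve (feasible or an infeasibility signal).

    ``roots`` lists every exact (S, k) solution found: with only two
    observations the inverse problem can admit two solutions, and the pair
    requiring the least stiffness adjustment of the initial guess (smallest
    |log k|) is the one reported in ``S``/``k``.  The solution set itself
    does not depend on the stress scale of the initial guess — only the
    selection among multiple solutions does.
    """

    feasible: bool
    S: float | None = None
    k: float | None = None
    iterations: int = 0
    residual_sys: float | None = None
    residual_dia: float | None = None
    reason: str = ""
    roots: list = field(default_factory=list)


@dataclass
class InverseResult:
    """Recovered shrinkage and stiffness scale for one subject."""

    subject_id: str
    S: float
    k: float
    final_params: MaterialParams
    inner_iterations: int
    middle_iterations: int
    outer_iterations: int
    trace: list = field(default_factory=list)
    feasible: bool = True


def zero_pressure_geometry(subject: SubjectRecord, S: float) -> TubeGeometry:
    """Zero-pressure tube geometry implied by circumferential shrinkage S.

    The zero-pressure inner radius shrinks the reference lumen perimeter:
    Ri0 = S * reference / (2 pi).  The zero-pressure thickness preserves the
    wall cross-section area under the axial shrink (area_0 = area_invivo *
    lambda_z), consistent with incompressibility of the wall.
    """
    if not (0.0 < S <= 1.0):
        raise ValueError(f"shrinkage S must lie in (0, 1], got {S}")
    ref_mm = subject.reference * 10.0
    r_iv = ref_mm / (2.0 * math.pi)  # in vivo inner radius, mm
    area_iv = math.pi * ((r_iv + subject.thickness) ** 2 - r_iv**2)
    area_0 = area_iv * subject.axial_stretch
    Ri0 = S * r_iv
    t0 = math.sqrt(Ri0**2 + area_0 / math.pi) - Ri0
    return TubeGeometry(inner_radius_0=Ri0, thickness_0=t0)


def _perimeter_at(
    subject: SubjectRecord, params: MaterialParams, S: float, pressure_kpa: float
) -> float:
    """Deformed lumen perimeter (cm) of the shrunk tube at a pressure."""
    geom = zero_pressure_geometry(subject, S)
    ri = deformed_inner_radius(
        geom, params, LoadState(pressure=pressure_kpa, axial_stretch=subject.axial_stretch)
    )
    return 2.0 * math.pi * ri / 10.0


def _solve_shrinkage(
    subject: SubjectRecord,
    params: MaterialParams,
    pressure_kpa: float,
    target_cm: float,
    config: IterationConfig,
) -> float | None:
    """S in (s_floor, 1] whose diastolic perimeter matches the target, or
    None when no such S exists.  The perimeter is monotone increasing in S.
    """
    from scipy.optimize import brentq

    def f(S: float) -> float:
        return _perimeter_at(subject, params, S, pressure_kpa) - target_cm

    try:
        f_hi = f(1.0)
    except (RuntimeError, OverflowError, ValueError):
        return None
    if f_hi < 0.0:
        return None  # even the unshrunk tube is too small at this pressure
    lo = 1.0
    f_lo = f_hi
    while f_lo > 0.0:
        lo *= 0.8
        if lo < config.s_floor:
            return None
        try:
            f_lo = f(lo)
        except (RuntimeError, OverflowError, ValueError):
            return None
    if lo == 1.0:
        return 1.0
    return brentq(f, lo, lo / 0.8, xtol=1e-12, rtol=1e-12)


def inner_loop(
    subject: SubjectRecord,
    base_params: MaterialParams,
    K2: float | None = None,
    theta: float | None = None,
    config: IterationConfig = IterationConfig(),
) -> InnerLoopResult:
    """Solve for the shrinkage S and stiffness scale k at fixed (K2, theta).

    The solve exploits the degree-one homogeneity of the stress response in
    (c1, D1, K1): at a matched diastole and systole the deformed inner
    radii are known outright (r = perimeter / 2 pi), so the pressures
    P^_dia(S), P^_sys(S) holding the shrunk tube at those radii under the
    UNSCALED coefficients determine the scale k = P_dia / P^_dia(S)
    exactly, and S alone must solve the pressure-ratio equation
    P^_sys(S) / P^_dia(S) = P_sys / P_dia.  The ratio residual is scanned
    over S in (s_floor, 1]; every sign-change interval is resolved by
    Brent's method (the residual need not be monotone and strongly
    exponential materials can admit two solutions), and the candidate with
    the smallest |log k| — the least stiffness adjustment of the initial
    guess — is selected.  The recovered pair is then verified against both
    perimeters through the full forward model.  Infeasibility (no ratio
    root with positive pressures and k inside the bracket) is returned as a
    signal, not raised.
    """
    from scipy.optimize import brentq

    work = base_params
    if K2 is not None or theta is not None:
        work = replace(
            base_params,
            K2=base_params.K2 if K2 is None else max(K2, K2_FLOOR),
            theta=base_params.theta if theta is None else theta,
        )
    p_dia = mmhg_to_kpa(subject.pressure_dia)
    p_sys = mmhg_to_kpa(subject.pressure_sys)
    if subject.perimeter_max <= subject.perimeter_min and p_sys > p_dia:
        return InnerLoopResult(
            feasible=False, reason="no systolic distension: k -> infinity limit"
        )
    r_dia = subject.perimeter_min * 10.0 / (2.0 * math.pi)  # mm
    r_sys = subject.perimeter_max * 10.0 / (2.0 * math.pi)
    target_log_ratio = math.log(p_sys / p_dia)

    n_eval = 0

    def base_pressures(S: float):
        """(P^_dia, P^_sys) of the unscaled coefficients, or None."""
        nonlocal n_eval
        n_eval += 1
        try:
            geom = zero_pressure_geometry(subject, S)
            Pd = luminal_pressure(geom, work, r_dia, subject.axial_stretch)
            Ps = luminal_pressure(geom, work, r_sys, subject.axial_stretch)
        except (ValueError, RuntimeError, OverflowError):
            return None
        if Pd <= 0.0 or Ps <= 0.0:
            return None  # shrinkage too small to pre-stretch the wall
        return Pd, Ps

    def h(S: float):
        bp = base_pressures(S)
        if bp is None:
            return None
        return math.log(bp[1] / bp[0]) - target_log_ratio

    grid = np.linspace(config.s_floor, 1.0, 97)
    values = [(S, h(S)) for S in grid]
    valid = [(S, v) for S, v in values if v is not None]
    if not valid:
        return InnerLoopResult(
            feasible=False,
            iterations=n_eval,
            reason="no shrinkage in (0, 1] pre-stretches the wall at both pressures",
        )

    def h_strict(S: float) -> float:
        v = h(S)
        if v is None:
            raise RuntimeError(f"{subject.id}: pressure ratio lost inside the S bracket")
        return v

    ratio_tol = 0.5 * config.perimeter_rtol
    s_roots = [S for S, v in valid if abs(v) <= ratio_tol]
    step = grid[1] - grid[0]
    for (S0, v0), (S1, v1) in zip(valid, valid[1:]):
        if S1 - S0 > 1.01 * step:
            continue  # interval interrupted by an invalid shrinkage
        if abs(v0) <= ratio_tol or abs(v1) <= ratio_tol:
            continue
        if v0 * v1 < 0.0:
            try:
                s_roots.append(brentq(h_strict, S0, S1, xtol=1e-14, rtol=8.9e-16))
            except RuntimeError:
                continue
    candidates = []
    k_lo, k_hi = config.k_bracket
    for S in s_roots:
        bp = base_pressures(S)
        if bp is None:
            continue
        k = p_dia / bp[0]
        if k_lo <= k <= k_hi:
            candidates.append((S, k))
    if not candidates:
        return InnerLoopResult(
            feasible=False,
            iterations=n_eval,
            reason="pressure-ratio equation has no root with k inside the bracket",
        )
    S, k = min(candidates, key=lambda c: abs(math.log(c[1])))
    trial = work.scaled(k)
    res_dia = _perimeter_at(subject, trial, S, p_dia) - subject.perimeter_min
    res_sys = _perimeter_at(subject, trial, S, p_sys) - subject.perimeter_max
    ok = (
        abs(res_dia) <= config.perimeter_rtol * subject.perimeter_min
        and abs(res_sys) <= config.perimeter_rtol * subject.perimeter_max
    )
    if not ok:
        return InnerLoopResult(
            feasible=False,
            iterations=n_eval,
            residual_dia=res_dia,
            residual_sys=res_sys,
            reason="perimeter residuals exceed tolerance at the solved (S, k)",
        )
    return InnerLoopResult(
        feasible=True,
        S=S,
        k=k,
        iterations=n_eval,
        residual_dia=res_dia,
        residual_sys=res_sys,
        roots=sorted(candidates),
    )


def _middle_schedule(K2_0: float, delta: float, budget: int):
    """Expanding alternating-sign K2 corrections: +d, -d, +2d, -2d, ...
    (negative excursions floored at the positive K2 floor)."""
    seen = set()
    for m in range(1, budget + 1):
        step = (m + 1) // 2 * delta
        cand = K2_0 + step if m % 2 == 1 else max(K2_0 - step, K2_FLOOR)
        if cand in seen:
            continue
        seen.add(cand)
        yield cand


def _outer_schedule(theta_0: float, delta: float, budget: int):
    """Expanding alternating-sign theta corrections within (0, 45]."""
    for n in range(1, budget + 1):
        step = (n + 1) // 2 * delta
        cand = theta_0 + step if n % 2 == 1 else theta_0 - step
        if 0.0 < cand <= 45.0:
            yield cand


def triple_loop(
    subject: SubjectRecord,
    initial_params: MaterialParams,
    config: IterationConfig = IterationConfig(),
) -> InverseResult:
    """Run the full triple-loop algorithm for one subject.

    The inner loop is attempted at the initial (K2, theta).  On
    infeasibility the middle loop perturbs K2 in an expanding alternating
    schedule (step ``delta_K2``); when its budget is exhausted the outer
    loop perturbs theta (step ``delta_theta``, staying within (0, 45]
    degrees) and restarts the middle loop.  The first feasible (S, k) wins.

    Raises :class:`NoSolutionError` with the full residual trace when the
    total correction budget is exhausted.
    """
    trace: list[dict] = []

    def attempt(K2: float, theta: float, middle: int, outer: int) -> InverseResult | None:
        res = inner_loop(subject, initial_params, K2=K2, theta=theta, config=config)
        trace.append(
            {
                "K2": K2,
                "theta": theta,
                "middle": middle,
                "outer": outer,
                "feasible": res.feasible,
                "S": res.S,
                "k": res.k,
                "reason": res.reason,
            }
        )
        if not res.feasible:
            return None
        final = replace(initial_params, K2=max(K2, K2_FLOOR), theta=theta).scaled(res.k)
        return InverseResult(
            subject_id=subject.id,
            S=res.S,
            k=res.k,
            final_params=final,
            inner_iterations=res.iterations,
            middle_iterations=middle,
            outer_iterations=outer,
            trace=trace,
        )

    K2_0, theta_0 = initial_params.K2, initial_params.theta
    out = attempt(K2_0, theta_0, middle=0, outer=0)
    if out is not None:
        return out
    # middle loop at the initial theta
    for m, K2 in enumerate(_middle_schedule(K2_0, config.delta_K2, config.max_middle), 1):
        out = attempt(K2, theta_0, middle=m, outer=0)
        if out is not None:
            return out
    # outer loop: step theta, restart the middle loop at each step
    for n, theta in enumerate(_outer_schedule(theta_0, config.delta_theta, config.max_outer), 1):
        out = attempt(K2_0, theta, middle=0, outer=n)
        if out is not None:
            return out
        for m, K2 in enumerate(_middle_schedule(K2_0, config.delta_K2, config.max_middle), 1):
            out = attempt(K2, theta, middle=m, outer=n)
            if out is not None:
                return out
    raise NoSolutionError(
        f"{subject.id}: correction budget exhausted without a feasible (S, k)", trace
    )


def _m03_perturb(params: MaterialParams, seed: int) -> MaterialParams:
    """Signed +/-5% per-coefficient perturbation from a seeded pattern."""
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=6)
    vals = [params.c1, params.D1, params.D2, params.K1, params.K2, params.theta]
    c1, D1, D2, K1, K2, theta = (v * (1.0 + 0.05 * s) for v, s in zip(vals, signs))
    return MaterialParams(c1=c1, D1=D1, D2=D2, K1=K1, K2=K2, theta=min(theta, 44.99))


def run_setting(
    subjects: list[SubjectRecord],
    initial_mode: str = "M02",
    ex_vivo_params: dict[str, MaterialParams] | None = None,
    custom_initial: MaterialParams | None = None,
    config: IterationConfig = IterationConfig(),
    protocol: str = "equibiaxial",
    m03_seed: int = 0,
) -> pd.DataFrame:
    """Run the inverse algorithm over a cohort under one initial-guess
    setting and summarize stiffness per subject.

    Modes: ``M01`` uses each subject's own ex vivo coefficients (requires
    ``ex_vivo_params``); ``M02`` the packaged common guess (the
    median-stiffness subject's ex vivo fit); ``M03`` the packaged 5%-varied
    guess — or, for a custom base, a seeded signed +/-5% perturbation;
    ``custom`` uses ``custom_initial`` for every subject.

    Returns a DataFrame with the recovered (S, k), final coefficients,
    effective moduli, anisotropy index and relative errors vs the ex vivo
    stiffness when ex vivo coefficients are available.  Infeasible subjects
    are flagged and the run continues.
    """
    from . import fixtures

    if initial_mode not in ("M01", "M02", "M03", "custom"):
        raise ValueError(f"unknown initial mode {initial_mode!r}")
    if initial_mode == "M01" and not ex_vivo_params:
        raise ValueError("M01 mode requires per-subject ex vivo parameters")
    if initial_mode == "custom" and custom_initial is None:
        raise ValueError("custom mode requires custom_initial")

    def initial_for(subject: SubjectRecord) -> MaterialParams:
        if initial_mode == "M01":
            if subject.id not in ex_vivo_params:
                raise ValueError(f"no ex vivo parameters for subject {subject.id}")
            return ex_vivo_params[subject.id]
        if initial_mode == "M02":
            return custom_initial if custom_initial else fixtures.load_initial_guess("M02")
        if initial_mode == "M03":
            if custom_initial is None:
                return fixtures.load_initial_guess("M03")
            return _m03_perturb(custom_initial, m03_seed)
        return custom_initial

    rows = []
    for subject in subjects:
        init = initial_for(subject)
        row: dict = {"subject": subject.id, "initial_mode": initial_mode}
        try:
            res = triple_loop(subject, init, config=config)
        except NoSolutionError as err:
            row.update({"feasible": False, "note": str(err)})
            rows.append(row)
            continue
        fp = res.final_params
        ymc = effective_young_modulus(fp, "c", protocol)
        yma = effective_young_modulus(fp, "a", protocol)
        row.update(
            {
                "feasible": True,
                "S_pct": 100.0 * res.S,
                "k": res.k,
                "c1_kPa": fp.c1,
                "D1_kPa": fp.D1,
                "D2": fp.D2,
                "K1_kPa": fp.K1,
                "K2": fp.K2,
                "theta_deg": fp.theta,
                "YMc_kPa": ymc,
                "YMa_kPa": yma,
                "AI": anisotropy_index(ymc, yma),
                "inner_iters": res.inner_iterations,
                "middle_iters": res.middle_iterations,
                "outer_iters": res.outer_iterations,
            }
        )
        if ex_vivo_params and subject.id in ex_vivo_params:
            ref = ex_vivo_params[subject.id]
            ymc_ref = effective_young_modulus(ref, "c", protocol)
            yma_ref = effective_young_modulus(ref, "a", protocol)
            row["YMc_exvivo_kPa"] = ymc_ref
            row["YMa_exvivo_kPa"] = yma_ref
            row["RE_YMc_pct"] = relative_error(ymc, ymc_ref)
            row["RE_YMa_pct"] = relative_error(yma, yma_ref)
        rows.append(row)
    return pd.DataFrame(rows)
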