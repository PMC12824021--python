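"""Seeded generators for synthetic biaxial datasets and virtual subjects.

Virtual subjects carry a known ground truth: material coefficients and a
true shrinkage ratio are sampled, the zero-pressure tube is built, and the
forward model produces the diastolic/systolic lumen perimeters a TEE
examination would observe.  Biaxial datasets are produced by simulating the
five standard force-ratio protocols with optional additive stress noise.
Both generators are deterministic in (seed, index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biaxial import STANDARD_PROTOCOLS, BiaxialDataset, SampleGeometry, simulate_protocol
from .constitutive import MaterialParams
from .inverse import SubjectRecord, zero_pressure_geometry
from .tube import LoadState, deformed_inner_radius, mmhg_to_kpa

__all__ = ["CohortSpec", "generate_subject", "generate_cohort", "generate_biaxial"]


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges of a virtual cohort.

    Geometry, pressure and coefficient ranges default to the spans observed
    in the clinical cohort: lumen perimeters 8-15 cm, wall thickness
    1.2-2.8 mm, systolic 79-140 / diastolic 45-91 mmHg, and stress-like
    coefficients spanning three orders of magnitude (sampled log-uniformly).
    """

    n_subjects: int = 10
    seed: int = 0
    c1_range: tuple[float, float] = (0.1, 20.0)  # kPa, log-uniform
    D1_range: tuple[float, float] = (5.0, 30.0)  # kPa, log-uniform
    D2_range: tuple[float, float] = (0.5, 2.3)
    K1_range: tuple[float, float] = (0.01, 2.5)  # kPa, log-uniform
    K2_range: tuple[float, float] = (0.01, 15.0)
    theta_range: tuple[float, float] = (5.0, 41.0)  # degrees
    perimeter_range: tuple[float, float] = (8.0, 15.0)  # cm, in vivo reference
    thickness_range: tuple[float, float] = (1.2, 2.8)  # mm
    pressure_sys_range: tuple[float, float] = (79.0, 140.0)  # mmHg
    pressure_dia_range: tuple[float, float] = (45.0, 91.0)  # mmHg
    shrink_range: tuple[float, float] = (0.55, 0.90)  # true S
    axial_stretch: float = 1.25
    perimeter_noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in (
            "c1_range", "D1_range", "D2_range", "K1_range", "K2_range",
            "theta_range", "perimeter_range", "thickness_range",
            "pressure_sys_range", "pressure_dia_range", "shrink_range",
        ):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")


def _sample_params(rng: np.random.Generator, spec: CohortSpec) -> MaterialParams:
    def logu(lo, hi):
        return float(np.exp(rng.uniform(math.log(lo), math.log(hi))))

    return MaterialParams(
        c1=logu(*spec.c1_range),
        D1=logu(*spec.D1_range),
        D2=float(rng.uniform(*spec.D2_range)),
        K1=logu(*spec.K1_range),
        K2=float(rng.uniform(*spec.K2_range)),
        theta=float(rng.uniform(*spec.theta_range)),
    )


def generate_subject(
    spec: CohortSpec, index: int, max_retries: int = 20
) -> tuple[SubjectRecord, MaterialParams, float]:
    """One virtual subject: (record, true parameters, true shrinkage).

    The true shrinkage S* and the reference (systolic) perimeter fix the
    zero-pressure tube; the forward model then produces the perimeters at
    diastolic and systolic pressure.  With zero perimeter noise the record
    satisfies the forward model exactly.  Sampled configurations whose
    inflation fails (e.g. pressure beyond the inflation limit of a very soft
    draw) are resampled, up to ``max_retries``.
    """
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, index, attempt])
        params = _sample_params(rng, spec)
        ref_perim = float(rng.uniform(*spec.perimeter_range))
        thickness = float(rng.uniform(*spec.thickness_range))
        p_sys = float(rng.uniform(*spec.pressure_sys_range))
        p_dia = float(rng.uniform(*spec.pressure_dia_range))
        if p_dia >= p_sys:
            p_dia = 0.99 * p_sys
        s_true = float(rng.uniform(*spec.shrink_range))
        try:
            # provisional record supplying geometry conventions
            proto = SubjectRecord(
                id=f"VS{index:03d}",
                pressure_sys=p_sys,
                pressure_dia=p_dia,
                perimeter_min=ref_perim,  # placeholder, replaced below
                perimeter_max=ref_perim,
                thickness=thickness,
                reference_perimeter=ref_perim,
                axial_stretch=spec.axial_stretch,
            )
            geom = zero_pressure_geometry(proto, s_true)
            per = {}
            for tag, p_mmhg in (("dia", p_dia), ("sys", p_sys)):
                ri = deformed_inner_radius(
                    geom,
                    params,
                    LoadState(pressure=mmhg_to_kpa(p_mmhg), axial_stretch=spec.axial_stretch),
                )
                per[tag] = 2.0 * math.pi * ri / 10.0
        except (RuntimeError, OverflowError, ValueError):
            continue
        if spec.perimeter_noise_cv > 0:
            per["dia"] *= 1.0 + spec.perimeter_noise_cv * rng.standard_normal()
            per["sys"] *= 1.0 + spec.perimeter_noise_cv * rng.standard_normal()
        if not (0 < per["dia"] < per["sys"]):
            continue
        record = SubjectRecord(
            id=f"VS{index:03d}",
            pressure_sys=p_sys,
            pressure_dia=p_dia,
            perimeter_min=per["dia"],
            perimeter_max=per["sys"],
            thickness=thickness,
            reference_perimeter=ref_perim,
            axial_stretch=spec.axial_stretch,
        )
        return record, params, s_true
    raise RuntimeError(
        f"could not generate a feasible virtual subject at index {index} "
        f"after {max_retries} retries"
    )


def generate_cohort(
    spec: CohortSpec,
) -> list[tuple[SubjectRecord, MaterialParams, float]]:
    """A full virtual cohort of ``spec.n_subjects`` subjects."""
    return [generate_subject(spec, i) for i in range(spec.n_subjects)]


def cohort_to_json(cohort, path, ground_truth_path=None) -> None:
    """Write a cohort in the subject-record JSON format, with an optional
    ground-truth sidecar (never read by the estimator)."""
    import json

    records = [rec.to_dict() for rec, _, _ in cohort]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"subjects": records}, fh, indent=1)
    if ground_truth_path is not None:
        truth = [
            {"id": rec.id, "params": params.to_dict(), "S_true": s}
            for rec, params, s in cohort
        ]
        with open(ground_truth_path, "w", encoding="utf-8") as fh:
            json.dump({"ground_truth": truth}, fh, indent=1)


def generate_biaxial(
    params: MaterialParams,
    geometry: SampleGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocols=STANDARD_PROTOCOLS,
) -> BiaxialDataset:
    """Synthetic biaxial dataset over the five standard protocols, with
    optional additive Gaussian noise (kPa) on both stress components."""
    geometry = geometry or SampleGeometry()
    frames = [simulate_protocol(params, geometry, p) for p in protocols]
    df = pd.concat(frames, ignore_index=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        df = df.copy()
        df["Pc_kPa"] += noise_sd * rng.standard_normal(len(df))
        df["Pa_kPa"] += noise_sd * rng.standard_normal(len(df))
    return BiaxialDataset(
        data=df,
        provenance="synthetic" if noise_sd == 0 else f"synthetic+noise({noise_sd:g} kPa)",
        seed=seed,
    )
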