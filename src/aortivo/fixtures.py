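"""Loaders for the packaged reference data.

Three JSON files ship with the package: the clinical cohort (cuff pressures,
wall thickness, TEE lumen-perimeter extrema), the ex vivo constitutive
coefficients of the ten subjects, and the published in vivo/ex vivo
stiffness comparison consumed by the statistics layer.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .constitutive import MaterialParams

__all__ = [
    "load_cohort",
    "load_cohort_table",
    "load_exvivo_params",
    "load_stiffness_comparison",
    "load_initial_guess",
    "SUBJECT_IDS",
]

SUBJECT_IDS = ("AD1", "AD2", "AD3", "AD4", "AD5", "N1", "N2", "N3", "N4", "N5")


def _read_json(name: str) -> dict:
    with resources.files("aortivo.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_cohort() -> list:
    """The ten-subject clinical cohort as :class:`~aortivo.inverse.SubjectRecord`s."""
    from .inverse import SubjectRecord

    raw = _read_json("cohort_clinical.json")["subjects"]
    return [
        SubjectRecord(
            id=s["id"],
            pressure_sys=s["pressure_sys_mmHg"],
            pressure_dia=s["pressure_dia_mmHg"],
            perimeter_min=s["perimeter_min_cm"],
            perimeter_max=s["perimeter_max_cm"],
            thickness=s["thickness_mm"],
        )
        for s in raw
    ]


def load_cohort_table() -> pd.DataFrame:
    """The clinical cohort as a raw table, including the published cyclic
    perimeter-change column (percent)."""
    raw = _read_json("cohort_clinical.json")["subjects"]
    return pd.DataFrame(raw).set_index("id")


def load_exvivo_params() -> dict[str, MaterialParams]:
    """Ex vivo constitutive coefficients per subject, from biaxial fits."""
    raw = _read_json("exvivo_params.json")["params"]
    return {sid: MaterialParams.from_dict(d) for sid, d in raw.items()}


def load_exvivo_r_squared() -> dict[str, float]:
    raw = _read_json("exvivo_params.json")["params"]
    return {sid: d["r_squared"] for sid, d in raw.items()}


def load_stiffness_comparison() -> pd.DataFrame:
    """Published in vivo vs ex vivo stiffness comparison (moduli in kPa,
    shrinkage and relative errors in percent), one row per subject."""
    raw = _read_json("stiffness_comparison.json")["rows"]
    df = pd.DataFrame.from_dict(raw, orient="index")
    df.index.name = "subject"
    return df


def load_initial_guess(mode: str) -> MaterialParams:
    """The common initial guesses M02 (median-stiffness subject's ex vivo
    coefficients) and M03 (the same with a 5% variation)."""
    raw = _read_json("initial_guesses.json")
    if mode not in ("M02", "M03"):
        raise KeyError(f"unknown initial-guess mode {mode!r}; expected 'M02' or 'M03'")
    return MaterialParams.from_dict(raw[mode])
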