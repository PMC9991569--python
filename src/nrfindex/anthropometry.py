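"""BMI, waist-hip ratio, and binary overweight / central-obesity outcomes.

Cut-offs follow the Working Group on Obesity in China (WGOC) for BMI classes
and waist circumference, and the WHO recommendation for waist-hip ratio.
BMI classes are contiguous half-open intervals with inclusive lower bounds:
underweight [0, 18.5), normal [18.5, 24), overweight [24, 28), obese
[28, inf).  Central-obesity cut-offs are applied inclusively (>=).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "BMI_CLASS_BOUNDS",
    "WC_CUTOFF_CM",
    "WHR_CUTOFF",
    "ObesityFlags",
    "bmi_classify",
    "central_obesity_wc",
    "central_obesity_whr",
    "derive_flags",
]

BMI_CLASS_BOUNDS = (18.5, 24.0, 28.0)
BMI_CLASSES = ("underweight", "normal", "overweight", "obese")
WC_CUTOFF_CM = {"male": 85.0, "female": 80.0}
WHR_CUTOFF = {"male": 0.90, "female": 0.85}


@dataclass(frozen=True)
class ObesityFlags:
    bmi: float
    bmi_class: str
    overweight_incl_obese: bool
    whr: float
    central_wc: bool
    central_whr: bool


def bmi_classify(weight_kg: float, height_cm: float) -> tuple[float, str]:
    """BMI in kg/m^2 and its WGOC class."""
    if weight_kg <= 0 or height_cm <= 0:
        raise DomainError("weight and height must be positive")
    if not 100 <= height_cm <= 250:
        warnings.warn(f"height {height_cm} cm outside the plausible 100-250 cm range")
    bmi = weight_kg / (height_cm / 100.0) ** 2
    idx = int(np.searchsorted(BMI_CLASS_BOUNDS, bmi, side="right"))
    return bmi, BMI_CLASSES[idx]


def central_obesity_wc(wc_cm: float, sex: str) -> bool:
    """Central obesity by waist circumference (WGOC: >=85 cm M, >=80 cm F)."""
    if wc_cm <= 0:
        raise DomainError("waist circumference must be positive")
    if sex not in WC_CUTOFF_CM:
        raise DomainError(f"unknown sex {sex!r}")
    return wc_cm >= WC_CUTOFF_CM[sex]


def central_obesity_whr(wc_cm: float, hc_cm: float, sex: str) -> tuple[float, bool]:
    """Waist-hip ratio and its central-obesity flag (>=0.90 M, >=0.85 F)."""
    if hc_cm <= 0:
        raise DomainError("hip circumference must be positive")
    if sex not in WHR_CUTOFF:
        raise DomainError(f"unknown sex {sex!r}")
    whr = wc_cm / hc_cm
    return whr, whr >= WHR_CUTOFF[sex]


def derive_flags(participants: pd.DataFrame) -> pd.DataFrame:
    """Join BMI, WHR and obesity flags onto a participant table.

    Needs columns sex, weight_kg, height_cm, wc_cm, hc_cm.  Vectorised
    equivalent of the scalar operations above.
    """
    bmi = participants["weight_kg"] / (participants["height_cm"] / 100.0) ** 2
    cls = pd.cut(
        bmi,
        bins=[0, *BMI_CLASS_BOUNDS, np.inf],
        labels=BMI_CLASSES,
        right=False,
        include_lowest=True,
    ).astype(str)
    whr = participants["wc_cm"] / participants["hc_cm"]
    wc_cut = participants["sex"].map(WC_CUTOFF_CM)
    whr_cut = participants["sex"].map(WHR_CUTOFF)
    out = participants.copy()
    out["bmi"] = bmi
    out["bmi_class"] = cls
    out["overweight_incl_obese"] = (bmi >= 24.0).astype(int)
    out["whr"] = whr
    out["central_wc"] = (participants["wc_cm"] >= wc_cut).astype(int)
    out["central_whr"] = (whr >= whr_cut).astype(int)
    return out
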