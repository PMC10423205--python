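"""Liver-function scores: image-based MELIF and blood-based ALBI/MELD/Child-Pugh.

The MELIF score aggregates the voxelwise T1 reduction rate over the whole
liver and scales it by patient factors:

    MELIF = 0.694 * height^0.6 / (weight^0.3 * liverVolume^0.6) * 100 * A,

where A is the rrT1 aggregate over valid liver voxels.  The printed equation
sums rr over voxels, which makes the score depend on voxel size; both the
``sum`` and ``mean`` aggregations are supported and the choice is recorded
next to every score (see MelifParameters).

Blood-based comparators:

    MELD = 3.78 ln(bilirubin mg/dL) + 11.2 ln(INR) + 9.57 ln(creatinine mg/dL) + 6.43
    ALBI = 0.66 log10(bilirubin umol/L) - 0.085 albumin(g/L)

with ALBI grades 1/2/3 at cut-offs -2.6 and -1.39, and the five-component
Child-Pugh score (5-15 points, classes A/B/C).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import VoxelGeometry
from .relaxometry import FunctionalMap

#: fixed molar-mass conversion for bilirubin, umol/L per mg/dL
BILIRUBIN_UMOL_PER_MG_DL = 17.1

AscitesGrade = Literal["none", "mild", "moderate_severe"]
EncephalopathyGrade = Literal["none", "grade_1_2", "grade_3_4"]

_ASCITES_POINTS = {"none": 1, "mild": 2, "moderate_severe": 3}
_ENCEPHALOPATHY_POINTS = {"none": 1, "grade_1_2": 2, "grade_3_4": 3}


@dataclass
class PatientRecord:
    """Demographics, blood panel and clinical grades for one patient.

    Units follow the score definitions: height m, weight kg, bilirubin
    umol/L, albumin g/L, creatinine mg/dL, INR dimensionless.
    """

    id: str
    height: float
    weight: float
    bilirubin: float
    albumin: float
    creatinine: float
    inr: float
    ascites_grade: AscitesGrade = "none"
    encephalopathy_grade: EncephalopathyGrade = "none"
    cirrhosis: bool = False

    def __post_init__(self) -> None:
        for name in ("height", "weight", "bilirubin", "albumin", "creatinine", "inr"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.ascites_grade not in _ASCITES_POINTS:
            raise ValueError(f"unknown ascites grade {self.ascites_grade!r}")
        if self.encephalopathy_grade not in _ENCEPHALOPATHY_POINTS:
            raise ValueError(f"unknown encephalopathy grade {self.encephalopathy_grade!r}")


@dataclass(frozen=True)
class MelifParameters:
    """Constants and conventions of the MELIF equation.

    The exponents and prefactor are the published constants; ``aggregation``
    and ``volume_unit`` pin down the conventions the publication leaves to
    its prototype software, and travel with every reported score.
    """

    prefactor: float = 0.694
    height_exp: float = 0.6
    weight_exp: float = 0.3
    volume_exp: float = 0.6
    scale: float = 100.0
    aggregation: Literal["sum", "mean"] = "sum"
    volume_unit: Literal["ml", "l"] = "ml"


@dataclass
class ScorePanel:
    """Per-patient computed scores."""

    id: str
    melif: float | None
    albi: float
    albi_grade: int
    meld_raw: float
    meld_rounded: int
    meld_group: str
    child_pugh_points: int
    child_pugh_class: str
    liver_volume_ml: float | None = None
    aggregation: str | None = None
    volume_unit: str | None = None


def liver_volume(mask, unit: Literal["ml", "l"] = "ml") -> float:
    """Liver volume from a binary mask: set-voxel count times voxel volume."""
    values = np.asarray(getattr(mask, "values", mask), dtype=bool)
    geometry: VoxelGeometry = mask.geometry
    n = int(values.sum())
    if n == 0:
        raise ValueError("empty liver mask")
    volume_ml = n * geometry.voxel_volume_mm3 / 1000.0
    return volume_ml / 1000.0 if unit == "l" else volume_ml


def melif_score(fmap: FunctionalMap, mask, patient: PatientRecord,
                params: MelifParameters = MelifParameters()) -> tuple[float, dict]:
    """MELIF score from a functional map, liver mask and patient factors.

    Returns the score together with a provenance record (aggregate A, liver
    volume, aggregation and volume unit) — the conventions must accompany
    the number because ``sum`` aggregation scales with voxel count.
    """
    mask_values = np.asarray(getattr(mask, "values", mask), dtype=bool)
    if mask_values.shape != fmap.geometry.shape:
        raise ValueError("mask and functional map must share geometry")
    use = mask_values & fmap.valid_mask
    n_valid = int(use.sum())
    if n_valid == 0:
        raise ValueError("no valid masked voxels to aggregate")
    if not (patient.height > 0 and patient.weight > 0):
        raise ValueError("patient height and weight must be positive")

    aggregate = float(fmap.rr[use].sum())
    if params.aggregation == "mean":
        aggregate /= n_valid
    elif params.aggregation != "sum":
        raise ValueError(f"unknown aggregation {params.aggregation!r}")

    volume = liver_volume(mask, unit=params.volume_unit)
    patient_factor = patient.height ** params.height_exp / (
        patient.weight ** params.weight_exp * volume ** params.volume_exp
    )
    score = params.prefactor * patient_factor * params.scale * aggregate
    info = {
        "aggregate": aggregate,
        "n_valid_voxels": n_valid,
        "liver_volume": volume,
        "aggregation": params.aggregation,
        "volume_unit": params.volume_unit,
        "implausible_policy": fmap.implausible_policy,
    }
    return score, info


def albi_score(bilirubin_umol_l: float, albumin_g_l: float) -> float:
    """ALBI = 0.66 log10(bilirubin umol/L) - 0.085 albumin (g/L)."""
    if not bilirubin_umol_l > 0:
        raise ValueError("bilirubin must be positive")
    return math.log10(bilirubin_umol_l) * 0.66 + albumin_g_l * (-0.085)


def albi_grade(score: float) -> int:
    """ALBI grade: 1 if score <= -2.6, 2 if -2.6 < score <= -1.39, else 3."""
    if not math.isfinite(score):
        raise ValueError("ALBI score must be finite")
    if score <= -2.6:
        return 1
    if score <= -1.39:
        return 2
    return 3


def meld_score(bilirubin_mg_dl: float, inr: float, creatinine_mg_dl: float,
               clamping: Literal["raw", "unos"] = "raw") -> float:
    """MELD from bilirubin (mg/dL), INR and creatinine (mg/dL), unrounded.

    ``raw`` evaluates the bare log-linear formula; ``unos`` applies the
    clinical clamps (inputs floored at 1.0, creatinine capped at 4.0) first.
    """
    if not (bilirubin_mg_dl > 0 and inr > 0 and creatinine_mg_dl > 0):
        raise ValueError("MELD inputs must be positive")
    if clamping == "unos":
        bilirubin_mg_dl = max(bilirubin_mg_dl, 1.0)
        inr = max(inr, 1.0)
        creatinine_mg_dl = min(max(creatinine_mg_dl, 1.0), 4.0)
    elif clamping != "raw":
        raise ValueError(f"unknown clamping mode {clamping!r}")
    return (3.78 * math.log(bilirubin_mg_dl) + 11.2 * math.log(inr)
            + 9.57 * math.log(creatinine_mg_dl) + 6.43)


def round_half_away(x: float) -> int:
    """Nearest integer, halves away from zero (matches reported integer MELDs)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def meld_group(score: float) -> str:
    """Dichotomise MELD: <= 10 (rounded) = good liver function, >= 11 = impaired."""
    return "good" if round_half_away(score) <= 10 else "impaired"


def child_pugh(patient: PatientRecord) -> tuple[int, str]:
    """Child-Pugh points (5-15) and class (A/B/C) from the five components.

    Bands: bilirubin <2 / 2-3 / >3 mg/dL; albumin >3.5 / 2.8-3.5 / <2.8 g/dL;
    INR <1.7 / 1.7-2.3 / >2.3; plus ascites and encephalopathy grades.
    Class A = 5-6 points, B = 7-9, C = 10-15.
    """
    bili_mg = convert_units(patient.bilirubin, "bilirubin_umol_L", "bilirubin_mg_dL")
    alb_g_dl = convert_units(patient.albumin, "albumin_g_L", "albumin_g_dL")

    if bili_mg < 2.0:
        points = 1
    elif bili_mg <= 3.0:
        points = 2
    else:
        points = 3
    if alb_g_dl > 3.5:
        points += 1
    elif alb_g_dl >= 2.8:
        points += 2
    else:
        points += 3
    if patient.inr < 1.7:
        points += 1
    elif patient.inr <= 2.3:
        points += 2
    else:
        points += 3
    points += _ASCITES_POINTS[patient.ascites_grade]
    points += _ENCEPHALOPATHY_POINTS[patient.encephalopathy_grade]

    cls = "A" if points <= 6 else ("B" if points <= 9 else "C")
    return points, cls


_CONVERSIONS = {
    ("bilirubin_mg_dL", "bilirubin_umol_L"): BILIRUBIN_UMOL_PER_MG_DL,
    ("bilirubin_umol_L", "bilirubin_mg_dL"): 1.0 / BILIRUBIN_UMOL_PER_MG_DL,
    ("albumin_g_dL", "albumin_g_L"): 10.0,
    ("albumin_g_L", "albumin_g_dL"): 0.1,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact multiplicative conversion between the supported clinical units."""
    if from_unit == to_unit:
        return value
    try:
        return value * _CONVERSIONS[(from_unit, to_unit)]
    except KeyError:
        raise ValueError(f"unsupported unit conversion {from_unit!r} -> {to_unit!r}") from None


def score_patient(patient: PatientRecord, melif: float | None = None,
                  fmap: FunctionalMap | None = None, mask=None,
                  params: MelifParameters = MelifParameters(),
                  meld_clamping: Literal["raw", "unos"] = "raw") -> ScorePanel:
    """Compute the full score panel for one patient.

    MELIF comes either precomputed (``melif``) or from an imaging pair
    (``fmap`` + ``mask``); blood scores come from the record's panel.
    """
    volume = aggregation = volume_unit = None
    if fmap is not None:
        if mask is None:
            raise ValueError("a liver mask is required to score a functional map")
        melif, info = melif_score(fmap, mask, patient, params)
        aggregation, volume_unit = info["aggregation"], info["volume_unit"]
        volume = liver_volume(mask, unit="ml")
    albi = albi_score(patient.bilirubin, patient.albumin)
    bili_mg = convert_units(patient.bilirubin, "bilirubin_umol_L", "bilirubin_mg_dL")
    meld = meld_score(bili_mg, patient.inr, patient.creatinine, clamping=meld_clamping)
    points, cls = child_pugh(patient)
    return ScorePanel(
        id=patient.id,
        melif=melif,
        albi=albi,
        albi_grade=albi_grade(albi),
        meld_raw=meld,
        meld_rounded=round_half_away(meld),
        meld_group=meld_group(meld),
        child_pugh_points=points,
        child_pugh_class=cls,
        liver_volume_ml=volume,
        aggregation=aggregation,
        volume_unit=volume_unit,
    )
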