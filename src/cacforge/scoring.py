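"""Calcium scoring: lesions, pseudomass, Agatston score and risk categories.

Two lesion-extraction routes are provided:

* the clinical, threshold-based route: connected components of voxels
  >= 130 HU inside the heart (the standard Agatston procedure), and
* the threshold-free, map-based route: the calcium area is taken from a
  nonnegative CAC-map produced by the decomposition network, and lesion
  *intensities* are then read from the original image at those voxels —
  so values below 130 HU contribute, which is the point of the method on
  motion-degraded thick-slice scans.

Pseudomass is the uncalibrated calcium mass: the sum of CT numbers over
lesion voxels times the voxel volume (HU*mm^3). Scan grids here are not
mass-calibrated, so no mg conversion is attempted.

The continuous risk score maps pseudomass through a calibrated logarithm,

    vis = alpha * log_beta(gamma * mass) - delta   (mass > 0; vis = 0 at mass 0)

and is rounded/clamped onto the standard five Agatston risk categories
(I: 0, II: 1-10, III: 11-100, IV: 101-400, V: > 400).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CTVolume

AGATSTON_THRESHOLD_HU = 130.0

#: 3-D 26-connectivity for lesion formation; in-plane 8-connectivity for areas
_STRUCT_3D = np.ones((3, 3, 3), dtype=int)
_STRUCT_2D = np.ones((3, 3), dtype=int)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Lesion:
    voxels: np.ndarray  # (n, 3) int array of (z, y, x) indices
    slice_areas_mm2: dict  # z -> area in mm^2
    slice_max_hu: dict  # z -> max original HU in that slice
    volume_mm3: float

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class LesionSet:
    lesions: list[Lesion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)


@dataclass(frozen=True)
class CalciumScore:
    pseudomass: float  # HU*mm^3
    agatston: float
    volume: float  # mm^3
    scan_id: str = ""
    method: str = "threshold_based"  # map_based | threshold_based | ground_truth

    def __post_init__(self):
        for name in ("pseudomass", "agatston", "volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class CalibrationParams:
    alpha: float
    beta: float
    gamma: float
    delta: float
    condition: str = "rest"

    def __post_init__(self):
        if self.beta <= 1:
            raise ValueError("log base beta must be > 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


#: calibration presets for the published rest/stress CTAC formula; these
#: constants live on the source study's pseudomass scale and are shipped
#: for forward evaluation — re-run calibrate() for any other data scale.
REST_PARAMS = CalibrationParams(alpha=3.1, beta=9.0, gamma=1.1, delta=1.6, condition="rest")
STRESS_PARAMS = CalibrationParams(alpha=3.5, beta=9.0, gamma=1.0, delta=1.5, condition="stress")


@dataclass(frozen=True)
class RiskCategory:
    category: int  # 1..5 == I..V
    continuous_score: float | None = None

    def __post_init__(self):
        if self.category not in (1, 2, 3, 4, 5):
            raise ValueError(f"category must be 1..5, got {self.category}")

    @property
    def roman(self) -> str:
        return ["I", "II", "III", "IV", "V"][self.category - 1]


# ---------------------------------------------------------------------------
# Lesion extraction
# ---------------------------------------------------------------------------

def _components_to_lesions(area_mask, volume, min_area_mm2):
    """Group an area mask into 26-connected lesions; intensities from ``volume``."""
    dx, dy, dz = volume.spacing
    pixel_area = dx * dy
    voxvol = dx * dy * dz
    hu = volume.voxels
    labels, n = ndimage.label(area_mask, structure=_STRUCT_3D)
    lesions = []
    for lab in range(1, n + 1):
        comp = labels == lab
        zs = np.unique(np.nonzero(comp)[0])
        slice_areas = {}
        slice_max = {}
        for z in zs:
            plane = comp[z]
            slice_areas[int(z)] = float(plane.sum() * pixel_area)
            slice_max[int(z)] = float(hu[z][plane].max())
        # drop components in which no slice reaches the minimum area
        if all(a < min_area_mm2 for a in slice_areas.values()):
            continue
        idx = np.argwhere(comp)
        lesions.append(
            Lesion(
                voxels=idx,
                slice_areas_mm2=slice_areas,
                slice_max_hu=slice_max,
                volume_mm3=float(comp.sum() * voxvol),
            )
        )
    return LesionSet(lesions)


def extract_lesions_threshold(
    volume: CTVolume,
    heart_mask: np.ndarray,
    threshold_hu: float = AGATSTON_THRESHOLD_HU,
    min_area_mm2: float = 1.0,
) -> LesionSet:
    """Clinical lesion extraction: voxels >= ``threshold_hu`` inside the heart."""
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if heart_mask.shape != volume.shape:
        raise ValueError(f"mask shape {heart_mask.shape} != volume shape {volume.shape}")
    area = (volume.voxels >= threshold_hu) & heart_mask
    return _components_to_lesions(area, volume, min_area_mm2)


def extract_lesions_from_map(
    cac_map: np.ndarray,
    volume: CTVolume,
    heart_mask: np.ndarray,
    map_floor_hu: float = 30.0,
    min_area_mm2: float = 1.0,
) -> LesionSet:
    """Threshold-free lesion extraction from a nonnegative CAC-map.

    The calcium *area* is where the map exceeds ``map_floor_hu`` (a noise
    floor on the map itself, not a tissue threshold); lesion intensities
    are read from the original volume at those voxels, keeping values
    below 130 HU.
    """
    cac_map = np.asarray(cac_map)
    heart_mask = np.asarray(heart_mask, dtype=bool)
    if cac_map.shape != volume.shape or heart_mask.shape != volume.shape:
        raise ValueError(
            f"grid mismatch: map {cac_map.shape}, heart {heart_mask.shape}, "
            f"volume {volume.shape}"
        )
    area = (cac_map >= map_floor_hu) & heart_mask
    return _components_to_lesions(area, volume, min_area_mm2)


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def pseudomass(lesions: LesionSet, volume: CTVolume) -> float:
    """Sum of original HU over lesion voxels x voxel volume (HU*mm^3).

    Negative HU inside a lesion (possible on noisy scans along the lesion
    rim) are clipped to zero before summing, so the score stays >= 0.
    """
    voxvol = volume.voxel_volume_mm3
    hu = volume.voxels
    total = 0.0
    for lesion in lesions:
        z, y, x = lesion.voxels.T
        vals = hu[z, y, x].astype(np.float64)
        total += float(np.clip(vals, 0, None).sum()) * voxvol
    return total


def agatston_weight(max_hu: float) -> int:
    """Density weight of a lesion slice from its maximum HU."""
    if max_hu < 130:
        return 0
    if max_hu < 200:
        return 1
    if max_hu < 300:
        return 2
    if max_hu < 400:
        return 3
    return 4


def agatston_from_lesions(lesions: LesionSet) -> float:
    """Agatston score of pre-extracted (>=130 HU) lesions."""
    score = 0.0
    for lesion in lesions:
        for z, area in lesion.slice_areas_mm2.items():
            score += area * agatston_weight(lesion.slice_max_hu[z])
    return score


def agatston(
    volume: CTVolume,
    heart_mask: np.ndarray,
    threshold_hu: float = AGATSTON_THRESHOLD_HU,
    min_area_mm2: float = 1.0,
) -> float:
    """Agatston score: per lesion and slice, area (mm^2) x density weight.

    Weights 1/2/3/4 for slice maximum HU in 130-199/200-299/300-399/>=400.
    No slice-thickness correction factor is applied (scores are computed
    on whatever grid the volume is on).
    """
    lesions = extract_lesions_threshold(volume, heart_mask, threshold_hu, min_area_mm2)
    return agatston_from_lesions(lesions)


def agatston_from_array(voxels: np.ndarray, spacing, heart_mask: np.ndarray) -> float:
    """Agatston score for a bare HU array (convenience for generators/tests)."""
    return agatston(CTVolume(np.asarray(voxels), spacing), np.asarray(heart_mask, dtype=bool))


def score_volume(
    volume: CTVolume,
    heart_mask: np.ndarray,
    cac_map: np.ndarray | None = None,
    map_floor_hu: float = 30.0,
    min_area_mm2: float = 1.0,
) -> CalciumScore:
    """Full per-scan score via the map route (if a map is given) or the
    threshold route."""
    if cac_map is not None:
        lesions = extract_lesions_from_map(cac_map, volume, heart_mask, map_floor_hu, min_area_mm2)
        method = "map_based"
    else:
        lesions = extract_lesions_threshold(volume, heart_mask, min_area_mm2=min_area_mm2)
        method = "threshold_based"
    return CalciumScore(
        pseudomass=pseudomass(lesions, volume),
        agatston=agatston_from_lesions(lesions) if method == "threshold_based" else 0.0,
        volume=float(sum(l.volume_mm3 for l in lesions)),
        scan_id=volume.patient_id,
        method=method,
    )


# ---------------------------------------------------------------------------
# Risk categorization
# ---------------------------------------------------------------------------

def categorize_agatston(score: float) -> RiskCategory:
    """Map an Agatston score onto the five clinical risk categories."""
    if score < 0:
        raise ValueError(f"Agatston score must be >= 0, got {score}")
    if score == 0:
        cat = 1
    elif score <= 10:
        cat = 2
    elif score <= 100:
        cat = 3
    elif score <= 400:
        cat = 4
    else:
        cat = 5
    return RiskCategory(category=cat)


def vis_auto(cac_mass: float, params: CalibrationParams) -> float:
    """Continuous automated risk score from calcium pseudomass.

    ``alpha * log_beta(gamma * mass) - delta`` for positive mass, and
    exactly 0 for zero mass.
    """
    if cac_mass < 0:
        raise ValueError(f"mass must be >= 0, got {cac_mass}")
    if cac_mass == 0:
        return 0.0
    return params.alpha * (np.log(params.gamma * cac_mass) / np.log(params.beta)) - params.delta


def categorize_auto(vis_score: float, mass: float) -> RiskCategory:
    """Round the continuous risk score onto the five categories.

    Zero mass is always category I; otherwise round-half-up and clamp to
    [1, 5] (the calibration targets were integer visual scores 2-5, so
    rounding is the natural inverse of the fit).
    """
    if mass == 0:
        return RiskCategory(category=1, continuous_score=float(vis_score))
    cat = int(np.floor(vis_score + 0.5))  # round half up
    cat = min(5, max(1, cat))
    return RiskCategory(category=cat, continuous_score=float(vis_score))


def risk_category(mass: float, params: CalibrationParams) -> RiskCategory:
    """Pseudomass -> continuous score -> category, in one step."""
    return categorize_auto(vis_auto(mass, params), mass)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    masses,
    visual_categories,
    beta_fixed: float = 9.0,
    gamma_fixed: float = 1.0,
    condition: str = "rest",
) -> tuple[CalibrationParams, float]:
    """Fit alpha and delta by least squares on log-transformed mass.

    ``log_beta(gamma*m)`` is affine in ``ln m``, so beta and gamma are not
    identifiable jointly with alpha and delta; they are held fixed and the
    regression ``category ~ alpha * log_beta(gamma*m) - delta`` is solved
    for alpha and delta. Returns the parameters and the residual sum of
    squares.
    """
    masses = np.asarray(masses, dtype=float)
    cats = np.asarray(visual_categories, dtype=float)
    if masses.ndim != 1 or masses.shape != cats.shape:
        raise ValueError("masses and visual_categories must be equal-length 1-D")
    if np.any(masses <= 0):
        raise ValueError("calibration requires strictly positive masses")
    x = np.log(gamma_fixed * masses) / np.log(beta_fixed)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate calibration design: all masses equal")
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, cats, rcond=None)
    alpha, intercept = float(coef[0]), float(coef[1])
    resid = cats - design @ coef
    rss = float(resid @ resid)
    return (
        CalibrationParams(
            alpha=alpha, beta=beta_fixed, gamma=gamma_fixed, delta=-intercept,
            condition=condition,
        ),
        rss,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def score_table(scores, params: CalibrationParams | None = None) -> pd.DataFrame:
    """Scores as a tidy CSV-ready table, optionally with risk columns."""
    rows = []
    for s in scores:
        row = {
            "scan_id": s.scan_id,
            "method": s.method,
            "pseudomass": s.pseudomass,
            "agatston": s.agatston,
            "volume": s.volume,
        }
        if params is not None:
            v = vis_auto(s.pseudomass, params)
            row["vis_auto"] = v
            row["category"] = categorize_auto(v, s.pseudomass).category
        rows.append(row)
    return pd.DataFrame(rows)
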