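"""Volume standardisation, GAP staging and the LV+CRP prognostic classifier.

The standardised lung volume expresses a CT-measured lung volume as a
percentage of the subject's predicted forced vital capacity:

    stdLV(region) [%] = 100 * volume(region) [L] / FVC_pred [L]

The GAP (Gender-Age-Physiology) index scores sex, age, FVC% and DLCO% on a
0-8 point scale binned into stages I (0-3), II (4-5) and III (6-8).  The
modified GAP index replaces the FVC% component by the standardised total
lung volume, mapped onto the FVC% scale through a least-squares line fitted
on paired (stdLV%, FVC%) observations, then scored with the original FVC
cutoffs.

The three-group prognostic classifier combines the standardised total LV
and C-reactive protein (CRP, mg/dL) at their cohort medians: above-median
LV with below-median CRP is favorable, below-median LV with above-median
CRP is poor, everything else intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .volumetry import VolumeReport

__all__ = [
    "StandardizedLV",
    "GapResult",
    "LinearMap",
    "RiskGroup",
    "RiskLabel",
    "standardized_lv",
    "gap_score",
    "gap_stage",
    "fit_lv_to_fvc_map",
    "modified_gap_score",
    "median_cutoff",
    "lv_crp_group",
    "DLCO_CANNOT_PERFORM",
    "DEFAULT_LV_CUTOFF_DIAGNOSIS",
    "DEFAULT_LV_CUTOFF_AE",
]

#: Sentinel for DLCO that could not be measured (scores 3 GAP points).
DLCO_CANNOT_PERFORM = "cannot_perform"

#: Cohort-derived default cutoffs for the standardised total LV (%), at
#: diagnosis and at acute exacerbation.  These are the medians of one
#: published cohort, shipped as convenient defaults — not universal
#: constants; prefer the median of your own cohort.
DEFAULT_LV_CUTOFF_DIAGNOSIS = 108.0
DEFAULT_LV_CUTOFF_AE = 74.0


@dataclass
class StandardizedLV:
    """Per-region standardised volumes (% of predicted FVC)."""

    pct: dict[str, float]
    fvc_pred_l: float

    def __getitem__(self, region: str) -> float:
        return self.pct[region]

    @property
    def total(self) -> float:
        return self.pct["total_lung"]


def standardized_lv(report: VolumeReport, fvc_pred: float) -> StandardizedLV:
    """Standardise every region of a volume report by predicted FVC (L)."""
    if not fvc_pred > 0:
        raise ValueError(f"predicted FVC must be positive, got {fvc_pred}")
    pct = {
        region: 100.0 * (ml / 1000.0) / fvc_pred
        for region, ml in report.volumes_ml.items()
    }
    report.standardized_pct = dict(pct)
    return StandardizedLV(pct=pct, fvc_pred_l=float(fvc_pred))


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"


@dataclass(frozen=True)
class GapResult:
    """Component points, total and stage of a GAP evaluation."""

    sex_points: int
    age_points: int
    fvc_points: int
    dlco_points: int
    variant: str = "original"

    def __post_init__(self) -> None:
        if self.sex_points not in (0, 1):
            raise ValueError("sex_points must be 0 or 1")
        if self.age_points not in (0, 1, 2):
            raise ValueError("age_points must be 0..2")
        if self.fvc_points not in (0, 1, 2):
            raise ValueError("fvc_points must be 0..2")
        if self.dlco_points not in (0, 1, 2, 3):
            raise ValueError("dlco_points must be 0..3")

    @property
    def total(self) -> int:
        return self.sex_points + self.age_points + self.fvc_points + self.dlco_points

    @property
    def stage(self) -> Stage:
        return gap_stage(self.total)


def _sex_points(sex: str) -> int:
    if sex == "female":
        return 0
    if sex == "male":
        return 1
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def _age_points(age: float) -> int:
    if not age > 0:
        raise ValueError("age must be positive")
    if age <= 60:
        return 0
    if age <= 65:
        return 1
    return 2


def _fvc_points(fvc_pct: float) -> int:
    if not fvc_pct > 0:
        raise ValueError("FVC% must be positive")
    if fvc_pct > 75:
        return 0
    if fvc_pct >= 50:
        return 1
    return 2


def _dlco_points(dlco) -> int:
    if dlco == DLCO_CANNOT_PERFORM or dlco is None:
        return 3
    dlco = float(dlco)
    if dlco < 0:
        raise ValueError("DLCO% must be non-negative")
    if dlco > 55:
        return 0
    if dlco > 35:
        return 1
    return 2


def gap_score(sex: str, age_years: float, fvc_pct: float, dlco_pct=None) -> GapResult:
    """Original GAP index.

    Point table: sex (female 0 / male 1); age (<=60: 0, 61-65: 1, >65: 2);
    FVC% (>75: 0, 50-75: 1, <50: 2); DLCO% (>55: 0, 36-55: 1, <=35: 2,
    cannot perform: 3).  ``dlco_pct`` accepts a number, ``None`` or the
    :data:`DLCO_CANNOT_PERFORM` sentinel — both of the latter score 3.
    """
    return GapResult(
        sex_points=_sex_points(sex),
        age_points=_age_points(age_years),
        fvc_points=_fvc_points(fvc_pct),
        dlco_points=_dlco_points(dlco_pct),
        variant="original",
    )


def gap_stage(total: int) -> Stage:
    """Stage I for 0-3 points, II for 4-5, III for 6-8."""
    total = int(total)
    if not 0 <= total <= 8:
        raise ValueError(f"GAP total must be in [0, 8], got {total}")
    if total <= 3:
        return Stage.I
    if total <= 5:
        return Stage.II
    return Stage.III


@dataclass(frozen=True)
class LinearMap:
    """Least-squares line FVC% = slope * stdLV% + intercept, with fit diagnostics."""

    slope: float
    intercept: float
    r: float
    n: int

    def __call__(self, std_lv_pct: float) -> float:
        return self.slope * std_lv_pct + self.intercept

    @classmethod
    def identity(cls) -> "LinearMap":
        return cls(slope=1.0, intercept=0.0, r=1.0, n=0)


def fit_lv_to_fvc_map(pairs) -> LinearMap:
    """Fit the stdLV% -> FVC% calibration line by ordinary least squares.

    ``pairs`` is a sequence of ``(std_lv_pct, fvc_pct)`` tuples, at least
    three, with non-constant stdLV.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (stdLV%, FVC%) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("stdLV is constant: degenerate fit")
    res = stats.linregress(x, y)
    return LinearMap(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(x),
    )


def modified_gap_score(
    sex: str,
    age_years: float,
    std_lv_total_pct: float,
    dlco_pct=None,
    map: LinearMap | None = None,
    direct_threshold: bool = False,
) -> GapResult:
    """Modified GAP index: standardised total LV replaces the FVC% component.

    The stdLV% is converted to an FVC-equivalent through ``map`` and scored
    with the original FVC cutoffs (>75: 0, 50-75: 1, <50: 2).  With
    ``direct_threshold=True`` the stdLV% itself is thresholded at the FVC
    cutoffs instead — a simpler alternative to the fitted calibration.
    """
    if std_lv_total_pct < 0:
        raise ValueError("stdLV% must be non-negative")
    if direct_threshold:
        fvc_equiv = float(std_lv_total_pct)
    else:
        if map is None:
            raise ValueError("a fitted LinearMap is required unless direct_threshold")
        fvc_equiv = map(std_lv_total_pct)
    return GapResult(
        sex_points=_sex_points(sex),
        age_points=_age_points(age_years),
        fvc_points=_fvc_points(fvc_equiv),
        dlco_points=_dlco_points(dlco_pct),
        variant="modified",
    )


def median_cutoff(values) -> float:
    """Sample median (mean of the middle two for even n)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("need at least one finite value")
    return float(np.median(arr))


class RiskLabel(str, Enum):
    FAVORABLE = "favorable"
    INTERMEDIATE = "intermediate"
    POOR = "poor"


@dataclass(frozen=True)
class RiskGroup:
    label: RiskLabel
    lv_cutoff_pct: float
    crp_cutoff_mg_dl: float


def lv_crp_group(
    std_lv_pct: float, crp: float, lv_cut: float, crp_cut: float
) -> RiskGroup:
    """Three-group classifier from standardised LV and CRP medians.

    Strictly above-median LV with strictly below-median CRP is favorable;
    strictly below-median LV with strictly above-median CRP is poor; all
    remaining patients — including any value exactly at a cutoff — are
    intermediate.
    """
    for name, v in (("stdLV", std_lv_pct), ("CRP", crp),
                    ("lv_cut", lv_cut), ("crp_cut", crp_cut)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if std_lv_pct > lv_cut and crp < crp_cut:
        label = RiskLabel.FAVORABLE
    elif std_lv_pct < lv_cut and crp > crp_cut:
        label = RiskLabel.POOR
    else:
        label = RiskLabel.INTERMEDIATE
    return RiskGroup(label=label, lv_cutoff_pct=float(lv_cut),
                     crp_cutoff_mg_dl=float(crp_cut))
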