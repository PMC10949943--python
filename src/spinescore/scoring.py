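"""Deterministic prognostic-score calculators for spinal metastasis.

Implements three point systems used in preoperative evaluation of spinal
metastatic disease:

* the **revised Tokuhashi score** (RTS), a six-parameter 0-15 point system
  whose total predicts life expectancy in three bands;
* the **New England Spinal Metastasis Score** (NESMS), a 0-3 score built
  from the modified Bauer score, ambulatory function and serum albumin;
* a **combined score** in which the NESMS shifts the RTS by -2/-1/+1/+2
  points (for NESMS 0/1/2/3), yielding a 0-17 scale re-categorised into
  low / moderate / good prognosis groups.

All calculators are pure functions of their typed inputs and raise
:class:`ScoreValidationError` on out-of-vocabulary or out-of-range values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class ScoreValidationError(ValueError):
    """Raised when a scoring input is missing, out of range, or inconsistent."""


# ---------------------------------------------------------------------------
# Input vocabularies (revised Tokuhashi parameters)
# ---------------------------------------------------------------------------

class PerformanceStatus(enum.Enum):
    """General condition, banded from the Karnofsky performance status."""

    POOR = "poor"          # KPS 10-40%
    MODERATE = "moderate"  # KPS 50-70%
    GOOD = "good"          # KPS 80-100%


def performance_status_from_kps(kps_percent: int) -> PerformanceStatus:
    """Map a raw Karnofsky percentage (10-100, steps of 10) to its band."""
    if kps_percent not in range(10, 101, 10):
        raise ScoreValidationError(
            f"performance_status: KPS percentage must be one of 10,20,...,100, got {kps_percent!r}"
        )
    if kps_percent <= 40:
        return PerformanceStatus.POOR
    if kps_percent <= 70:
        return PerformanceStatus.MODERATE
    return PerformanceStatus.GOOD


class MetastasisCount(enum.Enum):
    """Count band shared by extraspinal bone foci and vertebral-body metastases."""

    THREE_OR_MORE = "three_or_more"
    ONE_TO_TWO = "one_to_two"
    NONE = "none"


class OrganMetastases(enum.Enum):
    """Metastases to major internal organs."""

    NONREMOVABLE = "nonremovable"
    REMOVABLE = "removable"
    NONE = "none"


class PrimarySiteGroup(enum.Enum):
    """Primary cancer site, grouped by prognostic weight (0-5 points)."""

    LUNG_STOMACH_ESOPHAGUS = "lung_stomach_esophagus"        # + osteosarcoma, bladder, pancreas
    LIVER_GALLBLADDER_UNKNOWN = "liver_gallbladder_unknown"
    OTHERS = "others"
    KIDNEY_UTERUS = "kidney_uterus"
    RECTUM = "rectum"
    THYROID_BREAST_PROSTATE = "thyroid_breast_prostate"      # + carcinoid tumour


_SITE_NAME_TO_GROUP = {
    "lung": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "osteosarcoma": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "stomach": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "bladder": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "oesophagus": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "esophagus": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "pancreas": PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    "liver": PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN,
    "gallbladder": PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN,
    "unidentified": PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN,
    "unknown": PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN,
    "kidney": PrimarySiteGroup.KIDNEY_UTERUS,
    "renal": PrimarySiteGroup.KIDNEY_UTERUS,
    "uterus": PrimarySiteGroup.KIDNEY_UTERUS,
    "rectum": PrimarySiteGroup.RECTUM,
    "thyroid": PrimarySiteGroup.THYROID_BREAST_PROSTATE,
    "breast": PrimarySiteGroup.THYROID_BREAST_PROSTATE,
    "prostate": PrimarySiteGroup.THYROID_BREAST_PROSTATE,
    "carcinoid": PrimarySiteGroup.THYROID_BREAST_PROSTATE,
}


def primary_site_from_name(site: str) -> PrimarySiteGroup:
    """Resolve a primary cancer site name (e.g. ``"breast"``) to its score group.

    Unlisted sites fall in the residual ``OTHERS`` (2-point) group.
    """
    return _SITE_NAME_TO_GROUP.get(site.strip().lower(), PrimarySiteGroup.OTHERS)


class Palsy(enum.Enum):
    """Spinal cord palsy, banded from the Frankel grade."""

    COMPLETE = "complete"      # Frankel A-B
    INCOMPLETE = "incomplete"  # Frankel C-D
    NONE = "none"              # Frankel E


class Ambulatory(enum.Enum):
    """Ambulatory function for the NESMS."""

    DEPENDENT_OR_NONAMBULATORY = "dependent_or_nonambulatory"
    INDEPENDENT = "independent"


class PrognosisCategory(enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    GOOD = "good"


class PredictedSurvival(enum.Enum):
    LT_6_MONTHS = "lt_6_months"
    GE_6_MONTHS = "ge_6_months"
    GE_12_MONTHS = "ge_12_months"


class BauerWeighting(enum.Enum):
    """Point weighting of the modified Bauer criterion inside the NESMS.

    ``TWO_POINT_CLAMPED`` follows the printed component table (modified
    Bauer >= 3 contributes 2 points) and clamps the NESMS total at 3.
    ``ONE_POINT`` assigns 1 point instead, so the raw sum already lies in
    0-3 and no clamping occurs.
    """

    TWO_POINT_CLAMPED = "two_point_clamped"
    ONE_POINT = "one_point"


# ---------------------------------------------------------------------------
# Point tables
# ---------------------------------------------------------------------------

RTS_POINTS: dict[str, dict[enum.Enum, int]] = {
    "performance_status": {
        PerformanceStatus.POOR: 0,
        PerformanceStatus.MODERATE: 1,
        PerformanceStatus.GOOD: 2,
    },
    "extraspinal_foci": {
        MetastasisCount.THREE_OR_MORE: 0,
        MetastasisCount.ONE_TO_TWO: 1,
        MetastasisCount.NONE: 2,
    },
    "vertebral_mets": {
        MetastasisCount.THREE_OR_MORE: 0,
        MetastasisCount.ONE_TO_TWO: 1,
        MetastasisCount.NONE: 2,
    },
    "internal_organ_mets": {
        OrganMetastases.NONREMOVABLE: 0,
        OrganMetastases.REMOVABLE: 1,
        OrganMetastases.NONE: 2,
    },
    "primary_site": {
        PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS: 0,
        PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN: 1,
        PrimarySiteGroup.OTHERS: 2,
        PrimarySiteGroup.KIDNEY_UTERUS: 3,
        PrimarySiteGroup.RECTUM: 4,
        PrimarySiteGroup.THYROID_BREAST_PROSTATE: 5,
    },
    "palsy": {
        Palsy.COMPLETE: 0,
        Palsy.INCOMPLETE: 1,
        Palsy.NONE: 2,
    },
}

#: RTS shift applied for each NESMS total when forming the combined score.
NESMS_ADJUSTMENT: dict[int, int] = {0: -2, 1: -1, 2: +1, 3: +2}

ALBUMIN_THRESHOLD_G_PER_DL = 3.5  # inclusive: >= 3.5 g/dl scores 1 point

COMBINED_SCORE_MAX = 17
RTS_MAX = 15
NESMS_MAX = 3


# ---------------------------------------------------------------------------
# Input / result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RTSInputs:
    """The six revised-Tokuhashi parameters for one patient."""

    performance_status: PerformanceStatus
    extraspinal_foci: MetastasisCount
    vertebral_mets: MetastasisCount
    internal_organ_mets: OrganMetastases
    primary_site: PrimarySiteGroup
    palsy: Palsy

    def __post_init__(self) -> None:
        expected = {
            "performance_status": PerformanceStatus,
            "extraspinal_foci": MetastasisCount,
            "vertebral_mets": MetastasisCount,
            "internal_organ_mets": OrganMetastases,
            "primary_site": PrimarySiteGroup,
            "palsy": Palsy,
        }
        for name, enum_cls in expected.items():
            value = getattr(self, name)
            if not isinstance(value, enum_cls):
                raise ScoreValidationError(
                    f"{name}: expected a {enum_cls.__name__} value, got {value!r}"
                )


@dataclass(frozen=True)
class RTSResult:
    component_points: dict[str, int]
    total: int


@dataclass(frozen=True)
class BauerInputs:
    """The four modified-Bauer criteria (each satisfied criterion scores 1)."""

    has_visceral_mets: bool
    primary_is_lung: bool
    primary_is_favorable: bool  # breast, renal, lymphoma, or myeloma
    single_skeletal_metastasis: bool

    def __post_init__(self) -> None:
        for name in (
            "has_visceral_mets",
            "primary_is_lung",
            "primary_is_favorable",
            "single_skeletal_metastasis",
        ):
            if not isinstance(getattr(self, name), bool):
                raise ScoreValidationError(f"{name}: expected a boolean")
        if self.primary_is_lung and self.primary_is_favorable:
            raise ScoreValidationError(
                "primary_is_lung and primary_is_favorable cannot both be true"
            )


@dataclass(frozen=True)
class NESMSInputs:
    bauer: BauerInputs
    ambulatory: Ambulatory
    serum_albumin_g_per_dl: float

    def __post_init__(self) -> None:
        if not isinstance(self.ambulatory, Ambulatory):
            raise ScoreValidationError(
                f"ambulatory: expected an Ambulatory value, got {self.ambulatory!r}"
            )
        alb = self.serum_albumin_g_per_dl
        if not (0 < alb < 10):
            raise ScoreValidationError(
                f"serum_albumin_g_per_dl: implausible value {alb!r} (must be in (0, 10) g/dl)"
            )


@dataclass(frozen=True)
class NESMSResult:
    modified_bauer: int
    bauer_points: int
    ambulatory_points: int
    albumin_points: int
    total: int


@dataclass(frozen=True)
class RTSClassification:
    category: PrognosisCategory
    life_expectancy: PredictedSurvival


@dataclass(frozen=True)
class CombinedScoreResult:
    rts_total: int
    nesms_total: int
    adjustment: int
    combined: int
    category: PrognosisCategory
    predicted_survival: PredictedSurvival


# ---------------------------------------------------------------------------
# Calculators
# ---------------------------------------------------------------------------

def compute_rts(inputs: RTSInputs) -> RTSResult:
    """Score the six revised-Tokuhashi parameters and sum them (0-15)."""
    points = {
        name: RTS_POINTS[name][getattr(inputs, name)] for name in RTS_POINTS
    }
    return RTSResult(component_points=points, total=sum(points.values()))


def classify_rts(total: int) -> RTSClassification:
    """Prognosis band of an RTS total: 0-8 low (<6 mo), 9-11 moderate (>=6 mo), 12-15 good (>=1 yr)."""
    _check_int_range("rts total", total, 0, RTS_MAX)
    if total <= 8:
        return RTSClassification(PrognosisCategory.LOW, PredictedSurvival.LT_6_MONTHS)
    if total <= 11:
        return RTSClassification(PrognosisCategory.MODERATE, PredictedSurvival.GE_6_MONTHS)
    return RTSClassification(PrognosisCategory.GOOD, PredictedSurvival.GE_12_MONTHS)


def compute_modified_bauer(inputs: BauerInputs) -> int:
    """Count of satisfied Bauer criteria (0-4).

    One point each for: no visceral metastases, primary not lung cancer,
    favorable primary (breast, renal, lymphoma or myeloma), and a single
    skeletal metastasis.
    """
    return (
        int(not inputs.has_visceral_mets)
        + int(not inputs.primary_is_lung)
        + int(inputs.primary_is_favorable)
        + int(inputs.single_skeletal_metastasis)
    )


def compute_nesms(
    inputs: NESMSInputs,
    bauer_weighting: BauerWeighting = BauerWeighting.TWO_POINT_CLAMPED,
) -> NESMSResult:
    """Score the NESMS components and return the 0-3 total.

    Under the default weighting a modified Bauer score >= 3 contributes 2
    points (as the component table prints) and the total is clamped at 3 to
    keep the documented 0-3 range; the alternative one-point weighting
    yields a 0-3 raw sum with no clamping.
    """
    mb = compute_modified_bauer(inputs.bauer)
    if mb <= 2:
        bauer_points = 0
    elif bauer_weighting is BauerWeighting.TWO_POINT_CLAMPED:
        bauer_points = 2
    else:
        bauer_points = 1
    ambulatory_points = int(inputs.ambulatory is Ambulatory.INDEPENDENT)
    albumin_points = int(inputs.serum_albumin_g_per_dl >= ALBUMIN_THRESHOLD_G_PER_DL)
    raw = bauer_points + ambulatory_points + albumin_points
    return NESMSResult(
        modified_bauer=mb,
        bauer_points=bauer_points,
        ambulatory_points=ambulatory_points,
        albumin_points=albumin_points,
        total=min(raw, NESMS_MAX),
    )


def classify_combined(combined: int) -> tuple[PrognosisCategory, PredictedSurvival]:
    """Prognosis band of the combined score: 0-8 low, 9-12 moderate, 13-17 good."""
    _check_int_range("combined score", combined, 0, COMBINED_SCORE_MAX)
    if combined <= 8:
        return PrognosisCategory.LOW, PredictedSurvival.LT_6_MONTHS
    if combined <= 12:
        return PrognosisCategory.MODERATE, PredictedSurvival.GE_6_MONTHS
    return PrognosisCategory.GOOD, PredictedSurvival.GE_12_MONTHS


def combine_scores(rts_total: int, nesms_total: int) -> CombinedScoreResult:
    """Adjust the RTS by the NESMS (-2/-1/+1/+2 for 0/1/2/3) and categorise.

    The adjusted score is clamped to the 0-17 scale; the lower clamp only
    engages for RTS 0-1 with NESMS 0-1 and never changes the (low) category.
    """
    _check_int_range("rts_total", rts_total, 0, RTS_MAX)
    _check_int_range("nesms_total", nesms_total, 0, NESMS_MAX)
    adjustment = NESMS_ADJUSTMENT[nesms_total]
    combined = min(max(rts_total + adjustment, 0), COMBINED_SCORE_MAX)
    category, predicted = classify_combined(combined)
    return CombinedScoreResult(
        rts_total=rts_total,
        nesms_total=nesms_total,
        adjustment=adjustment,
        combined=combined,
        category=category,
        predicted_survival=predicted,
    )


def _check_int_range(name: str, value: int, lo: int, hi: int) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ScoreValidationError(f"{name}: expected an integer, got {value!r}")
    if not (lo <= value <= hi):
        raise ScoreValidationError(f"{name}: {value} outside [{lo}, {hi}]")
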