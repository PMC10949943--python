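"""Patient-level record containers shared by the scoring, cohort and I/O layers."""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .scoring import (
    BauerWeighting,
    NESMSInputs,
    RTSInputs,
    ScoreValidationError,
    classify_rts,
    combine_scores,
    compute_nesms,
    compute_rts,
)


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class SurvivalObservation:
    """An observed follow-up time in months; ``event`` is True if death was observed."""

    time_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_months < 0:
            raise ScoreValidationError(
                f"time_months: must be non-negative, got {self.time_months!r}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One patient's scoring inputs, demographics and (optional) survival outcome."""

    patient_id: str
    rts: RTSInputs
    nesms: NESMSInputs
    age_years: float | None = None
    sex: Sex | None = None
    cancer_type: str | None = None
    survival: SurvivalObservation | None = None


@dataclass(frozen=True)
class ScoredPatient:
    """A patient record together with every derived score and category."""

    record: PatientRecord
    rts_total: int
    nesms_total: int
    combined_score: int
    prognosis_category: str
    predicted_survival: str
    rts_category: str


def score_patient(
    record: PatientRecord,
    bauer_weighting: BauerWeighting = BauerWeighting.TWO_POINT_CLAMPED,
) -> ScoredPatient:
    """Compute RTS, NESMS and the combined score for one patient."""
    rts = compute_rts(record.rts)
    nesms = compute_nesms(record.nesms, bauer_weighting)
    combined = combine_scores(rts.total, nesms.total)
    return ScoredPatient(
        record=record,
        rts_total=rts.total,
        nesms_total=nesms.total,
        combined_score=combined.combined,
        prognosis_category=combined.category.value,
        predicted_survival=combined.predicted_survival.value,
        rts_category=classify_rts(rts.total).category.value,
    )
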