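"""Synthetic spinal-metastasis cohorts with NESMS-calibrated survival.

The patient-level data behind the combined-score study are unpublished, so
this module generates stand-in cohorts that reproduce the study's printed
structure: the categorical marginals of the six Tokuhashi parameters, the
cancer-type mix, the age/sex distribution (n = 64 by default), and survival
times drawn from a per-NESMS-stratum piecewise-exponential model calibrated
to the published 6-month / 1-year / overall mortality fractions.

Parameters are sampled independently across columns (only the marginals are
published; no joint structure is supportable), and the Bauer flags of each
record are derived deterministically from its sampled Tokuhashi categories
so that every generated record passes the scoring validators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .records import PatientRecord, Sex, SurvivalObservation
from .scoring import (
    Ambulatory,
    BauerInputs,
    BauerWeighting,
    MetastasisCount,
    NESMSInputs,
    OrganMetastases,
    Palsy,
    PerformanceStatus,
    PrimarySiteGroup,
    RTSInputs,
    ScoreValidationError,
    compute_nesms,
)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month, for day-denominated inputs

#: Published mortality fractions (6-month, 1-year, overall) by NESMS stratum.
DEFAULT_MORTALITY: dict[int, tuple[float, float, float]] = {
    0: (0.85, 1.00, 1.00),
    1: (0.63, 0.78, 0.83),
    2: (0.27, 0.48, 0.60),
    3: (0.10, 0.15, 0.30),
}

# Category orders match the point tables (worst band first).
_PS_LEVELS = (PerformanceStatus.POOR, PerformanceStatus.MODERATE, PerformanceStatus.GOOD)
_COUNT_LEVELS = (MetastasisCount.THREE_OR_MORE, MetastasisCount.ONE_TO_TWO, MetastasisCount.NONE)
_ORGAN_LEVELS = (OrganMetastases.NONREMOVABLE, OrganMetastases.REMOVABLE, OrganMetastases.NONE)
_SITE_LEVELS = (
    PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
    PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN,
    PrimarySiteGroup.OTHERS,
    PrimarySiteGroup.KIDNEY_UTERUS,
    PrimarySiteGroup.RECTUM,
    PrimarySiteGroup.THYROID_BREAST_PROSTATE,
)
_PALSY_LEVELS = (Palsy.COMPLETE, Palsy.INCOMPLETE, Palsy.NONE)
_SEX_LEVELS = (Sex.MALE, Sex.FEMALE)
_CANCER_LEVELS = ("lung", "breast", "hematological", "sarcoma", "other")


@dataclass(frozen=True)
class CohortSpec:
    """Marginal distributions and survival-model settings driving the generator.

    Count tuples are ordered as the point tables list the categories (worst
    band first); in ``exact_counts`` mode each tuple must sum to ``n``, in
    ``multinomial`` mode counts are normalised to sampling probabilities.
    """

    n: int = 64
    performance_status: tuple[int, ...] = (5, 37, 22)
    extraspinal_foci: tuple[int, ...] = (4, 19, 41)
    vertebral_mets: tuple[int, ...] = (25, 14, 25)
    organ_mets: tuple[int, ...] = (10, 21, 33)
    primary_site: tuple[int, ...] = (27, 2, 0, 18, 2, 15)
    palsy: tuple[int, ...] = (3, 58, 3)
    sex: tuple[int, ...] = (31, 33)
    cancer_type: tuple[int, ...] = (19, 16, 11, 10, 8)
    age_mean: float = 64.8
    age_sd: float = 13.3
    # NESMS component marginals are not published; see docs/methods.md.
    p_independent_ambulator: float = 0.906
    p_albumin_ge_threshold: float = 0.5
    sampling_mode: str = "exact_counts"  # or "multinomial"
    seed: int = 0
    bauer_weighting: BauerWeighting = BauerWeighting.TWO_POINT_CLAMPED
    mortality: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MORTALITY)
    )
    epsilon_floor: float = 0.001
    horizon_months: float = 24.0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ScoreValidationError(f"n must be positive, got {self.n}")
        if self.sampling_mode not in ("exact_counts", "multinomial"):
            raise ScoreValidationError(
                f"sampling_mode must be 'exact_counts' or 'multinomial', got {self.sampling_mode!r}"
            )
        for prob_name in ("p_independent_ambulator", "p_albumin_ge_threshold"):
            p = getattr(self, prob_name)
            if not (0.0 <= p <= 1.0):
                raise ScoreValidationError(f"{prob_name} must be in [0, 1], got {p}")
        if self.sampling_mode == "exact_counts":
            for name in (
                "performance_status", "extraspinal_foci", "vertebral_mets",
                "organ_mets", "primary_site", "palsy", "sex", "cancer_type",
            ):
                counts = getattr(self, name)
                if sum(counts) != self.n:
                    raise ScoreValidationError(
                        f"{name}: counts {counts} sum to {sum(counts)}, expected n={self.n}"
                    )


# ---------------------------------------------------------------------------
# Piecewise-exponential survival model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalModel:
    """Per-stratum piecewise-constant hazards on [0,6), [6,12), [12,horizon) months."""

    hazards: dict[int, tuple[float, float, float]]
    horizon_months: float
    epsilon_floor: float

    def cumulative_hazard(self, stratum: int, t: float) -> float:
        l1, l2, l3 = self._rates(stratum)
        t = min(t, self.horizon_months)
        h = l1 * min(t, 6.0)
        if t > 6.0:
            h += l2 * (min(t, 12.0) - 6.0)
        if t > 12.0:
            h += l3 * (t - 12.0)
        return h

    def survival_function(self, stratum: int, t: float) -> float:
        return math.exp(-self.cumulative_hazard(stratum, t))

    def mortality(self, stratum: int, t: float) -> float:
        return 1.0 - self.survival_function(stratum, t)

    def sample_times(
        self, stratum: int, size: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Inverse-transform draws; returns (times, event flags).

        Times exceeding the horizon are administratively censored at it.
        """
        l1, l2, l3 = self._rates(stratum)
        target = -np.log(rng.random(size))  # exponential cumulative-hazard targets
        h6 = 6.0 * l1
        h12 = h6 + 6.0 * l2
        h_end = h12 + (self.horizon_months - 12.0) * l3
        times = np.full(size, self.horizon_months)
        seg1 = target < h6
        if l1 > 0:
            times[seg1] = target[seg1] / l1
        seg2 = (~seg1) & (target < h12)
        if l2 > 0:
            times[seg2] = 6.0 + (target[seg2] - h6) / l2
        seg3 = (target >= h12) & (target < h_end)
        if l3 > 0:
            times[seg3] = 12.0 + (target[seg3] - h12) / l3
        events = target < h_end
        return times, events

    def _rates(self, stratum: int) -> tuple[float, float, float]:
        if stratum not in self.hazards:
            raise ScoreValidationError(f"no hazard rates for stratum {stratum!r}")
        return self.hazards[stratum]


def calibrate_survival_model(
    mortality_table: dict[int, tuple[float, float, float]] | None = None,
    *,
    epsilon_floor: float = 0.001,
    horizon_months: float = 24.0,
) -> SurvivalModel:
    """Invert mortality fractions into piecewise-exponential hazard rates.

    For each stratum with (m6, m12, m_overall): the first-interval hazard is
    ``-ln(1 - m6)/6``; the second comes from the 6->12 month survival drop;
    100% mortality is floored at ``1 - epsilon_floor`` so hazards stay
    finite; the overall fraction is read at ``horizon_months`` and sets the
    tail hazard on [12, horizon).
    """
    if mortality_table is None:
        mortality_table = DEFAULT_MORTALITY
    if horizon_months <= 12.0:
        raise ScoreValidationError("horizon_months must exceed 12")
    cap = 1.0 - epsilon_floor
    hazards: dict[int, tuple[float, float, float]] = {}
    for stratum, (m6, m12, mo) in mortality_table.items():
        if not (0.0 <= m6 <= m12 <= mo <= 1.0):
            raise ScoreValidationError(
                f"stratum {stratum}: mortality must satisfy 0 <= m6 <= m12 <= m_overall <= 1, "
                f"got ({m6}, {m12}, {mo})"
            )
        m6c, m12c, moc = min(m6, cap), min(m12, cap), min(mo, cap)
        l1 = -math.log(1.0 - m6c) / 6.0
        l2 = (math.log(1.0 - m6c) - math.log(1.0 - m12c)) / 6.0
        l3 = (math.log(1.0 - m12c) - math.log(1.0 - moc)) / (horizon_months - 12.0)
        hazards[stratum] = (l1, l2, l3)
    return SurvivalModel(
        hazards=hazards, horizon_months=horizon_months, epsilon_floor=epsilon_floor
    )


def sample_survival(
    nesms_total: int, model: SurvivalModel, rng: np.random.Generator
) -> SurvivalObservation:
    """Draw one survival observation for a patient in the given NESMS stratum."""
    times, events = model.sample_times(nesms_total, 1, rng)
    return SurvivalObservation(time_months=float(times[0]), event=bool(events[0]))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_categorical(
    levels: tuple, counts: tuple[int, ...], n: int, mode: str, rng: np.random.Generator
) -> list:
    if len(levels) != len(counts):
        raise ScoreValidationError(
            f"expected {len(levels)} counts for levels {levels}, got {counts}"
        )
    if mode == "exact_counts":
        pool = [lvl for lvl, c in zip(levels, counts) for _ in range(c)]
        return [pool[i] for i in rng.permutation(n)]
    probs = np.asarray(counts, dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=n, p=probs)
    return [levels[i] for i in idx]


def _derive_bauer(
    site: PrimarySiteGroup,
    organ: OrganMetastases,
    foci: MetastasisCount,
    vertebral: MetastasisCount,
) -> BauerInputs:
    """Bauer flags consistent with the sampled Tokuhashi categories.

    Lung-group primaries set the lung flag; kidney/breast-containing groups
    set the favorable flag (the groups are disjoint, so the exclusivity
    invariant holds). A record counts as a single skeletal metastasis when
    it has no extraspinal bone foci and 1-2 vertebral lesions.
    """
    return BauerInputs(
        has_visceral_mets=organ is not OrganMetastases.NONE,
        primary_is_lung=site is PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
        primary_is_favorable=site
        in (PrimarySiteGroup.KIDNEY_UTERUS, PrimarySiteGroup.THYROID_BREAST_PROSTATE),
        single_skeletal_metastasis=(
            foci is MetastasisCount.NONE and vertebral is MetastasisCount.ONE_TO_TWO
        ),
    )


def _sample_albumin(ge_threshold: bool, rng: np.random.Generator) -> float:
    # Half-normal spread (sd 0.4 g/dl) on the requested side of 3.5 g/dl.
    offset = 0.4 * abs(rng.normal())
    if ge_threshold:
        return float(np.clip(3.5 + offset, 3.5, 6.0))
    return float(np.clip(3.5 - offset - 0.01, 1.2, 3.49))


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate ``spec.n`` patient records with scores' inputs and survival.

    One master seed drives everything: covariates come from one stream and
    each patient's survival draw from its own deterministically derived
    sub-stream, so cohorts are reproducible regardless of draw order.
    """
    master = np.random.SeedSequence(spec.seed)
    cov_ss, surv_ss = master.spawn(2)
    rng = np.random.default_rng(cov_ss)
    patient_streams = surv_ss.spawn(spec.n)

    n, mode = spec.n, spec.sampling_mode
    ps = _sample_categorical(_PS_LEVELS, spec.performance_status, n, mode, rng)
    foci = _sample_categorical(_COUNT_LEVELS, spec.extraspinal_foci, n, mode, rng)
    vert = _sample_categorical(_COUNT_LEVELS, spec.vertebral_mets, n, mode, rng)
    organ = _sample_categorical(_ORGAN_LEVELS, spec.organ_mets, n, mode, rng)
    site = _sample_categorical(_SITE_LEVELS, spec.primary_site, n, mode, rng)
    palsy = _sample_categorical(_PALSY_LEVELS, spec.palsy, n, mode, rng)
    sex = _sample_categorical(_SEX_LEVELS, spec.sex, n, mode, rng)
    cancer = _sample_categorical(_CANCER_LEVELS, spec.cancer_type, n, mode, rng)
    ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18.0, 99.0)
    independent = rng.random(n) < spec.p_independent_ambulator
    albumin_high = rng.random(n) < spec.p_albumin_ge_threshold

    model = calibrate_survival_model(
        spec.mortality,
        epsilon_floor=spec.epsilon_floor,
        horizon_months=spec.horizon_months,
    )

    width = len(str(n))
    records: list[PatientRecord] = []
    for i in range(n):
        rts_inputs = RTSInputs(
            performance_status=ps[i],
            extraspinal_foci=foci[i],
            vertebral_mets=vert[i],
            internal_organ_mets=organ[i],
            primary_site=site[i],
            palsy=palsy[i],
        )
        nesms_inputs = NESMSInputs(
            bauer=_derive_bauer(site[i], organ[i], foci[i], vert[i]),
            ambulatory=(
                Ambulatory.INDEPENDENT
                if independent[i]
                else Ambulatory.DEPENDENT_OR_NONAMBULATORY
            ),
            serum_albumin_g_per_dl=_sample_albumin(bool(albumin_high[i]), rng),
        )
        stratum = compute_nesms(nesms_inputs, spec.bauer_weighting).total
        obs = sample_survival(stratum, model, np.random.default_rng(patient_streams[i]))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                rts=rts_inputs,
                nesms=nesms_inputs,
                age_years=round(float(ages[i]), 1),
                sex=sex[i],
                cancer_type=cancer[i],
                survival=obs,
            )
        )
    return records
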