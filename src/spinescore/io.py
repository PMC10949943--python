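"""CSV/JSON/YAML input-output for patient records, cohorts and reports.

The patient CSV schema is one row per patient (RFC 4180, UTF-8, header row
required, case-insensitive headers). Enum columns use the lowercase
snake-case codes of the scoring vocabularies; ``performance_status``
additionally accepts a raw Karnofsky percentage (10-100 in steps of 10),
and ``primary_site`` accepts either a group code or a plain site name
(``"breast"``, ``"lung"``, ...). Survival columns are optional for scoring
but required for validation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec
from .records import PatientRecord, ScoredPatient, Sex, SurvivalObservation, score_patient
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
    _SITE_NAME_TO_GROUP,
    performance_status_from_kps,
)

#: Columns required to score a patient; survival columns are optional extras.
REQUIRED_COLUMNS = (
    "patient_id",
    "performance_status",
    "extraspinal_foci",
    "vertebral_mets",
    "internal_organ_mets",
    "primary_site",
    "palsy",
    "has_visceral_mets",
    "primary_is_lung",
    "primary_is_favorable",
    "single_skeletal_metastasis",
    "ambulatory",
    "serum_albumin_g_per_dl",
)

OPTIONAL_COLUMNS = ("age_years", "sex", "cancer_type", "survival_months", "event")

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


class SchemaError(ScoreValidationError):
    """A patient CSV is missing columns or a cell cannot be parsed."""


def _parse_bool(value, column: str):
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"{column}: cannot parse boolean from {value!r}")


def _parse_enum(value, enum_cls, column: str):
    text = str(value).strip().lower()
    for member in enum_cls:
        if member.value == text:
            return member
    raise SchemaError(
        f"{column}: {value!r} not in vocabulary "
        f"{[m.value for m in enum_cls]}"
    )


def _parse_performance_status(value):
    text = str(value).strip().lower()
    if text.rstrip("%").isdigit():
        return performance_status_from_kps(int(text.rstrip("%")))
    return _parse_enum(text, PerformanceStatus, "performance_status")


def _parse_primary_site(value):
    text = str(value).strip().lower()
    for member in PrimarySiteGroup:
        if member.value == text:
            return member
    if text in _SITE_NAME_TO_GROUP:
        return _SITE_NAME_TO_GROUP[text]
    raise SchemaError(
        f"primary_site: {value!r} is neither a group code nor a known site name"
    )


def _parse_ambulatory(value):
    text = str(value).strip().lower()
    if text in ("dependent", "nonambulatory", "dependent_or_nonambulatory"):
        return Ambulatory.DEPENDENT_OR_NONAMBULATORY
    if text == "independent":
        return Ambulatory.INDEPENDENT
    raise SchemaError(f"ambulatory: {value!r} not a recognised code")


def _parse_row(row: pd.Series, row_number: int) -> PatientRecord:
    try:
        rts = RTSInputs(
            performance_status=_parse_performance_status(row["performance_status"]),
            extraspinal_foci=_parse_enum(
                row["extraspinal_foci"], MetastasisCount, "extraspinal_foci"
            ),
            vertebral_mets=_parse_enum(
                row["vertebral_mets"], MetastasisCount, "vertebral_mets"
            ),
            internal_organ_mets=_parse_enum(
                row["internal_organ_mets"], OrganMetastases, "internal_organ_mets"
            ),
            primary_site=_parse_primary_site(row["primary_site"]),
            palsy=_parse_enum(row["palsy"], Palsy, "palsy"),
        )
        try:
            albumin = float(row["serum_albumin_g_per_dl"])
        except (TypeError, ValueError):
            raise SchemaError(
                f"serum_albumin_g_per_dl: cannot parse {row['serum_albumin_g_per_dl']!r}"
            )
        nesms = NESMSInputs(
            bauer=BauerInputs(
                has_visceral_mets=_parse_bool(row["has_visceral_mets"], "has_visceral_mets"),
                primary_is_lung=_parse_bool(row["primary_is_lung"], "primary_is_lung"),
                primary_is_favorable=_parse_bool(
                    row["primary_is_favorable"], "primary_is_favorable"
                ),
                single_skeletal_metastasis=_parse_bool(
                    row["single_skeletal_metastasis"], "single_skeletal_metastasis"
                ),
            ),
            ambulatory=_parse_ambulatory(row["ambulatory"]),
            serum_albumin_g_per_dl=albumin,
        )
        survival = None
        if "survival_months" in row.index and pd.notna(row.get("survival_months")):
            if "event" not in row.index or pd.isna(row.get("event")):
                raise SchemaError("survival_months present but event flag missing")
            survival = SurvivalObservation(
                time_months=float(row["survival_months"]),
                event=_parse_bool(row["event"], "event"),
            )
        age = float(row["age_years"]) if pd.notna(row.get("age_years")) else None
        sex = (
            _parse_enum(row["sex"], Sex, "sex") if pd.notna(row.get("sex")) else None
        )
        cancer = (
            str(row["cancer_type"]) if pd.notna(row.get("cancer_type")) else None
        )
    except ScoreValidationError as exc:
        raise SchemaError(f"row {row_number}: {exc}") from exc
    return PatientRecord(
        patient_id=str(row["patient_id"]),
        rts=rts,
        nesms=nesms,
        age_years=age,
        sex=sex,
        cancer_type=cancer,
        survival=survival,
    )


def read_patient_csv(path: str | Path) -> list[PatientRecord]:
    """Read and validate a patient CSV; errors cite the offending row number.

    Row numbers count the header as row 1, so the first patient is row 2.
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    ids = df["patient_id"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise SchemaError(f"{path}: duplicate patient_id value(s) {sorted(dupes)}")
    return [_parse_row(row, idx + 2) for idx, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Writing cohorts and scored cohorts
# ---------------------------------------------------------------------------

def cohort_to_dataframe(records: list[PatientRecord]) -> pd.DataFrame:
    """Flatten patient records into the CSV row schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age_years": r.age_years,
                "sex": r.sex.value if r.sex else None,
                "cancer_type": r.cancer_type,
                "performance_status": r.rts.performance_status.value,
                "extraspinal_foci": r.rts.extraspinal_foci.value,
                "vertebral_mets": r.rts.vertebral_mets.value,
                "internal_organ_mets": r.rts.internal_organ_mets.value,
                "primary_site": r.rts.primary_site.value,
                "palsy": r.rts.palsy.value,
                "has_visceral_mets": int(r.nesms.bauer.has_visceral_mets),
                "primary_is_lung": int(r.nesms.bauer.primary_is_lung),
                "primary_is_favorable": int(r.nesms.bauer.primary_is_favorable),
                "single_skeletal_metastasis": int(
                    r.nesms.bauer.single_skeletal_metastasis
                ),
                "ambulatory": r.nesms.ambulatory.value,
                "serum_albumin_g_per_dl": round(r.nesms.serum_albumin_g_per_dl, 3),
                "survival_months": (
                    round(r.survival.time_months, 4) if r.survival else None
                ),
                "event": int(r.survival.event) if r.survival else None,
            }
        )
    return pd.DataFrame(rows)


def score_records(
    records: list[PatientRecord],
    bauer_weighting: BauerWeighting = BauerWeighting.TWO_POINT_CLAMPED,
) -> pd.DataFrame:
    """Score every record and append the derived columns to the row schema."""
    df = cohort_to_dataframe(records)
    scored = [score_patient(r, bauer_weighting) for r in records]
    df["rts_total"] = [s.rts_total for s in scored]
    df["nesms_total"] = [s.nesms_total for s in scored]
    df["combined_score"] = [s.combined_score for s in scored]
    df["prognosis_category"] = [s.prognosis_category for s in scored]
    df["predicted_survival"] = [s.predicted_survival for s in scored]
    df["rts_category"] = [s.rts_category for s in scored]
    return df


def read_scored_csv(path: str | Path) -> pd.DataFrame:
    """Read a scored-cohort CSV, checking the validation-ready columns."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = (
        "rts_total",
        "combined_score",
        "prognosis_category",
        "rts_category",
        "survival_months",
        "event",
    )
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df["survival_months"].isna().any() or df["event"].isna().any():
        raise SchemaError(f"{path}: survival_months/event required for validation")
    df["event"] = df["event"].astype(bool)
    return df


def write_report(report, path: str | Path, fmt: str = "json") -> None:
    """Serialise a validation report to JSON (full) or CSV (accuracy table)."""
    payload = report.to_dict()
    if not payload.get("n_patients"):
        raise ScoreValidationError("refusing to write an empty report")
    path = Path(path)
    if fmt == "json":
        payload["software_version"] = __version__
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        rows = payload["accuracy_by_policy"][payload["censor_policy"]]
        table = pd.DataFrame(rows)
        score_ranges = {"low": "0-8", "moderate": "9-12", "good": "13-17"}
        predictions = {"low": "<6 months", "moderate": ">=6 months", "good": ">=1 year"}
        table.insert(1, "score_range", table["category"].map(score_ranges))
        table.insert(2, "predicted_prognosis", table["category"].map(predictions))
        table = table.rename(columns={"n_patients": "n"})
        table[
            ["category", "score_range", "predicted_prognosis", "n", "n_accurate",
             "accuracy_percent"]
        ].to_csv(path, index=False)
    else:
        raise ScoreValidationError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# Cohort-spec configuration
# ---------------------------------------------------------------------------

def cohort_spec_from_yaml(path: str | Path, **overrides) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML mapping of its field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ScoreValidationError(f"{path}: config must be a mapping")
    raw.update(overrides)
    return cohort_spec_from_dict(raw)


def cohort_spec_from_dict(raw: dict) -> CohortSpec:
    field_names = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(raw) - field_names
    if unknown:
        raise ScoreValidationError(f"unknown cohort-spec key(s): {sorted(unknown)}")
    kwargs = dict(raw)
    if "bauer_weighting" in kwargs and isinstance(kwargs["bauer_weighting"], str):
        kwargs["bauer_weighting"] = BauerWeighting(kwargs["bauer_weighting"])
    if "mortality" in kwargs and isinstance(kwargs["mortality"], dict):
        kwargs["mortality"] = {
            int(k): tuple(v) for k, v in kwargs["mortality"].items()
        }
    for name, value in kwargs.items():
        if isinstance(value, list):
            kwargs[name] = tuple(value)
    return CohortSpec(**kwargs)


def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    """The full effective configuration, JSON-serialisable, for report echoing."""
    out = dataclasses.asdict(spec)
    out["bauer_weighting"] = spec.bauer_weighting.value
    out["mortality"] = {str(k): list(v) for k, v in spec.mortality.items()}
    return out
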