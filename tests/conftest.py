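import numpy as np
import pandas as pd
import pytest

from spinescore import (
    Ambulatory,
    BauerInputs,
    MetastasisCount,
    NESMSInputs,
    OrganMetastases,
    Palsy,
    PatientRecord,
    PerformanceStatus,
    PrimarySiteGroup,
    RTSInputs,
    SurvivalObservation,
)


def make_rts_inputs(**overrides) -> RTSInputs:
    base = dict(
        performance_status=PerformanceStatus.MODERATE,
        extraspinal_foci=MetastasisCount.NONE,
        vertebral_mets=MetastasisCount.ONE_TO_TWO,
        internal_organ_mets=OrganMetastases.NONE,
        primary_site=PrimarySiteGroup.THYROID_BREAST_PROSTATE,
        palsy=Palsy.INCOMPLETE,
    )
    base.update(overrides)
    return RTSInputs(**base)


def make_nesms_inputs(**overrides) -> NESMSInputs:
    base = dict(
        bauer=BauerInputs(
            has_visceral_mets=False,
            primary_is_lung=False,
            primary_is_favorable=True,
            single_skeletal_metastasis=True,
        ),
        ambulatory=Ambulatory.INDEPENDENT,
        serum_albumin_g_per_dl=4.0,
    )
    base.update(overrides)
    return NESMSInputs(**base)


def make_patient(patient_id="P1", time_months=None, event=True, **overrides) -> PatientRecord:
    survival = (
        SurvivalObservation(time_months=time_months, event=event)
        if time_months is not None
        else None
    )
    return PatientRecord(
        patient_id=patient_id,
        rts=overrides.pop("rts", make_rts_inputs()),
        nesms=overrides.pop("nesms", make_nesms_inputs()),
        survival=survival,
        **overrides,
    )


def accuracy_frame(rows) -> pd.DataFrame:
    """rows: (category, survival_months, event) triples."""
    return pd.DataFrame(
        rows, columns=["prognosis_category", "survival_months", "event"]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)
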