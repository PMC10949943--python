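"""Score a single patient: RTS, NESMS, and the combined prognosis.

A 68-year-old with a breast primary, one or two vertebral lesions, no
extraspinal bone foci, removable organ metastases, incomplete palsy,
walking independently, albumin 3.8 g/dl.
"""

from spinescore import (
    Ambulatory,
    BauerInputs,
    MetastasisCount,
    NESMSInputs,
    OrganMetastases,
    Palsy,
    PrimarySiteGroup,
    RTSInputs,
    classify_rts,
    combine_scores,
    compute_nesms,
    compute_rts,
    performance_status_from_kps,
)

rts_inputs = RTSInputs(
    performance_status=performance_status_from_kps(70),
    extraspinal_foci=MetastasisCount.NONE,
    vertebral_mets=MetastasisCount.ONE_TO_TWO,
    internal_organ_mets=OrganMetastases.REMOVABLE,
    primary_site=PrimarySiteGroup.THYROID_BREAST_PROSTATE,
    palsy=Palsy.INCOMPLETE,
)
nesms_inputs = NESMSInputs(
    bauer=BauerInputs(
        has_visceral_mets=True,        # removable organ metastases still count
        primary_is_lung=False,
        primary_is_favorable=True,     # breast primary
        single_skeletal_metastasis=False,
    ),
    ambulatory=Ambulatory.INDEPENDENT,
    serum_albumin_g_per_dl=3.8,
)

rts = compute_rts(rts_inputs)
nesms = compute_nesms(nesms_inputs)
combined = combine_scores(rts.total, nesms.total)

print("RTS component points:", rts.component_points)
print(f"RTS total: {rts.total}  (band: {classify_rts(rts.total).category.value})")
print(
    f"NESMS: modified Bauer {nesms.modified_bauer} -> {nesms.bauer_points} pts, "
    f"ambulatory {nesms.ambulatory_points}, albumin {nesms.albumin_points}; "
    f"total {nesms.total}"
)
print(
    f"Combined score: {combined.rts_total} {combined.adjustment:+d} = "
    f"{combined.combined} -> {combined.category.value} prognosis, "
    f"predicted survival {combined.predicted_survival.value}"
)
# The NESMS shifts the RTS up or down by up to two points; the combined
# 0-17 score is then banded 0-8 / 9-12 / 13-17 into low / moderate / good.
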