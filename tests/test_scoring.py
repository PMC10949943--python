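"""Scoring calculators: point lookups, classifications, combination rule."""

import itertools

import pytest

from spinescore import (
    Ambulatory,
    BauerInputs,
    BauerWeighting,
    MetastasisCount,
    OrganMetastases,
    Palsy,
    PerformanceStatus,
    PrimarySiteGroup,
    PrognosisCategory,
    PredictedSurvival,
    RTSInputs,
    ScoreValidationError,
    classify_combined,
    classify_rts,
    combine_scores,
    compute_modified_bauer,
    compute_nesms,
    compute_rts,
    performance_status_from_kps,
    primary_site_from_name,
)
from conftest import make_nesms_inputs

# Independent point-table oracle: points re-stated by category order rather
# than looked up through the implementation's table.
ORACLE_POINTS = {
    "performance_status": {
        PerformanceStatus.POOR: 0, PerformanceStatus.MODERATE: 1, PerformanceStatus.GOOD: 2,
    },
    "extraspinal_foci": {
        MetastasisCount.THREE_OR_MORE: 0, MetastasisCount.ONE_TO_TWO: 1, MetastasisCount.NONE: 2,
    },
    "vertebral_mets": {
        MetastasisCount.THREE_OR_MORE: 0, MetastasisCount.ONE_TO_TWO: 1, MetastasisCount.NONE: 2,
    },
    "internal_organ_mets": {
        OrganMetastases.NONREMOVABLE: 0, OrganMetastases.REMOVABLE: 1, OrganMetastases.NONE: 2,
    },
    "primary_site": {
        PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS: 0,
        PrimarySiteGroup.LIVER_GALLBLADDER_UNKNOWN: 1,
        PrimarySiteGroup.OTHERS: 2,
        PrimarySiteGroup.KIDNEY_UTERUS: 3,
        PrimarySiteGroup.RECTUM: 4,
        PrimarySiteGroup.THYROID_BREAST_PROSTATE: 5,
    },
    "palsy": {Palsy.COMPLETE: 0, Palsy.INCOMPLETE: 1, Palsy.NONE: 2},
}


def all_rts_inputs():
    names = list(ORACLE_POINTS)
    for combo in itertools.product(*(ORACLE_POINTS[n] for n in names)):
        yield RTSInputs(**dict(zip(names, combo)))


class TestRTS:
    def test_exhaustive_against_table_oracle(self):
        """All 1,458 input combinations match an independent table lookup."""
        for inputs in all_rts_inputs():
            result = compute_rts(inputs)
            expected = {
                name: ORACLE_POINTS[name][getattr(inputs, name)]
                for name in ORACLE_POINTS
            }
            assert result.component_points == expected
            assert result.total == sum(expected.values())
            assert 0 <= result.total <= 15

    @pytest.mark.parametrize(
        "overrides, total",
        [
            # best case on every parameter
            (dict(performance_status=PerformanceStatus.GOOD,
                  extraspinal_foci=MetastasisCount.NONE,
                  vertebral_mets=MetastasisCount.NONE,
                  internal_organ_mets=OrganMetastases.NONE,
                  primary_site=PrimarySiteGroup.THYROID_BREAST_PROSTATE,
                  palsy=Palsy.NONE), 15),
            # worst case on every parameter
            (dict(performance_status=PerformanceStatus.POOR,
                  extraspinal_foci=MetastasisCount.THREE_OR_MORE,
                  vertebral_mets=MetastasisCount.THREE_OR_MORE,
                  internal_organ_mets=OrganMetastases.NONREMOVABLE,
                  primary_site=PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS,
                  palsy=Palsy.COMPLETE), 0),
            # mixed case, hand-summed: 1+1+0+1+3+1
            (dict(performance_status=PerformanceStatus.MODERATE,
                  extraspinal_foci=MetastasisCount.ONE_TO_TWO,
                  vertebral_mets=MetastasisCount.THREE_OR_MORE,
                  internal_organ_mets=OrganMetastases.REMOVABLE,
                  primary_site=PrimarySiteGroup.KIDNEY_UTERUS,
                  palsy=Palsy.INCOMPLETE), 7),
        ],
    )
    def test_reference_cases(self, overrides, total):
        assert compute_rts(RTSInputs(**overrides)).total == total

    def test_rejects_non_enum_field(self):
        with pytest.raises(ScoreValidationError, match="palsy"):
            RTSInputs(
                performance_status=PerformanceStatus.GOOD,
                extraspinal_foci=MetastasisCount.NONE,
                vertebral_mets=MetastasisCount.NONE,
                internal_organ_mets=OrganMetastases.NONE,
                primary_site=PrimarySiteGroup.RECTUM,
                palsy="none",
            )

    @pytest.mark.parametrize("kps, expected", [
        (10, PerformanceStatus.POOR), (40, PerformanceStatus.POOR),
        (50, PerformanceStatus.MODERATE), (70, PerformanceStatus.MODERATE),
        (80, PerformanceStatus.GOOD), (100, PerformanceStatus.GOOD),
    ])
    def test_kps_banding(self, kps, expected):
        assert performance_status_from_kps(kps) is expected

    def test_kps_rejects_off_scale(self):
        for bad in (0, 45, 110):
            with pytest.raises(ScoreValidationError):
                performance_status_from_kps(bad)

    def test_site_name_resolution(self):
        assert primary_site_from_name("breast") is PrimarySiteGroup.THYROID_BREAST_PROSTATE
        assert primary_site_from_name("Lung") is PrimarySiteGroup.LUNG_STOMACH_ESOPHAGUS
        assert primary_site_from_name("melanoma") is PrimarySiteGroup.OTHERS


class TestClassifications:
    @pytest.mark.parametrize("total, category, expectancy", [
        (0, PrognosisCategory.LOW, PredictedSurvival.LT_6_MONTHS),
        (8, PrognosisCategory.LOW, PredictedSurvival.LT_6_MONTHS),
        (9, PrognosisCategory.MODERATE, PredictedSurvival.GE_6_MONTHS),
        (11, PrognosisCategory.MODERATE, PredictedSurvival.GE_6_MONTHS),
        (12, PrognosisCategory.GOOD, PredictedSurvival.GE_12_MONTHS),
        (15, PrognosisCategory.GOOD, PredictedSurvival.GE_12_MONTHS),
    ])
    def test_rts_bands(self, total, category, expectancy):
        result = classify_rts(total)
        assert result.category is category
        assert result.life_expectancy is expectancy

    def test_rts_band_rejects_out_of_range(self):
        for bad in (-1, 16):
            with pytest.raises(ScoreValidationError):
                classify_rts(bad)

    @pytest.mark.parametrize("combined, category", [
        (0, PrognosisCategory.LOW), (8, PrognosisCategory.LOW),
        (9, PrognosisCategory.MODERATE), (12, PrognosisCategory.MODERATE),
        (13, PrognosisCategory.GOOD), (17, PrognosisCategory.GOOD),
    ])
    def test_combined_bands(self, combined, category):
        assert classify_combined(combined)[0] is category

    def test_combined_band_boundaries_flip_exactly_at_cut_points(self):
        cats = [classify_combined(s)[0] for s in range(18)]
        changes = [s for s in range(1, 18) if cats[s] != cats[s - 1]]
        assert changes == [9, 13]

    def test_combined_band_rejects_out_of_range(self):
        for bad in (-1, 18):
            with pytest.raises(ScoreValidationError):
                classify_combined(bad)


class TestBauerAndNESMS:
    @pytest.mark.parametrize("flags, expected", [
        ((False, False, True, True), 4),   # all four criteria met
        ((True, True, False, False), 0),   # none met
        ((False, False, False, False), 2), # no visceral + non-lung primary
    ])
    def test_modified_bauer_counts_criteria(self, flags, expected):
        assert compute_modified_bauer(BauerInputs(*flags)) == expected

    def test_lung_favorable_exclusivity(self):
        with pytest.raises(ScoreValidationError):
            BauerInputs(False, True, True, False)

    def test_all_zero_components_give_zero(self):
        inputs = make_nesms_inputs(
            bauer=BauerInputs(False, False, False, False),  # modified Bauer = 2
            ambulatory=Ambulatory.DEPENDENT_OR_NONAMBULATORY,
            serum_albumin_g_per_dl=3.0,
        )
        result = compute_nesms(inputs)
        assert result.modified_bauer == 2
        assert (result.bauer_points, result.ambulatory_points, result.albumin_points) == (0, 0, 0)
        assert result.total == 0

    def test_raw_four_clamps_to_three(self):
        result = compute_nesms(make_nesms_inputs(serum_albumin_g_per_dl=3.6))
        assert result.modified_bauer == 4
        assert result.bauer_points + result.ambulatory_points + result.albumin_points == 4
        assert result.total == 3

    def test_albumin_threshold_inclusive_at_3_5(self):
        inputs = make_nesms_inputs(
            bauer=BauerInputs(False, False, True, False),  # modified Bauer = 3
            ambulatory=Ambulatory.DEPENDENT_OR_NONAMBULATORY,
            serum_albumin_g_per_dl=3.5,
        )
        result = compute_nesms(inputs)
        assert result.albumin_points == 1
        assert result.total == 3  # min(2 + 0 + 1, 3)

    def test_albumin_plausibility_bounds(self):
        for bad in (0.0, -1.0, 10.0):
            with pytest.raises(ScoreValidationError):
                make_nesms_inputs(serum_albumin_g_per_dl=bad)

    @pytest.mark.parametrize("weighting", list(BauerWeighting))
    def test_total_always_in_range_exhaustively(self, weighting):
        """Totals stay in 0-3 for every Bauer x ambulatory x albumin-side combo."""
        flag_combos = [
            (v, l, f, s)
            for v in (False, True) for l in (False, True)
            for f in (False, True) for s in (False, True)
            if not (l and f)
        ]
        for flags in flag_combos:
            for amb in Ambulatory:
                for albumin in (3.0, 3.5):
                    result = compute_nesms(
                        make_nesms_inputs(
                            bauer=BauerInputs(*flags),
                            ambulatory=amb,
                            serum_albumin_g_per_dl=albumin,
                        ),
                        weighting,
                    )
                    assert result.total in (0, 1, 2, 3)
                    if weighting is BauerWeighting.ONE_POINT:
                        # raw sum already fits 0-3: clamping is a no-op
                        raw = (result.bauer_points + result.ambulatory_points
                               + result.albumin_points)
                        assert raw == result.total


class TestCombineScores:
    @pytest.mark.parametrize("rts, nesms, combined", [
        (15, 3, 17),  # maximum attainable
        (10, 0, 8),   # minus two points at NESMS 0
        (0, 0, 0),    # clamped up from -2, stays in the low band
    ])
    def test_reference_cases(self, rts, nesms, combined):
        result = combine_scores(rts, nesms)
        assert result.combined == combined

    def test_lower_clamp_keeps_low_category(self):
        result = combine_scores(0, 0)
        assert result.adjustment == -2
        assert result.category is PrognosisCategory.LOW

    def test_monotone_in_both_arguments(self):
        for rts in range(16):
            for nesms in range(4):
                here = combine_scores(rts, nesms).combined
                if rts < 15:
                    assert combine_scores(rts + 1, nesms).combined >= here
                if nesms < 3:
                    assert combine_scores(rts, nesms + 1).combined >= here

    def test_rejects_out_of_range(self):
        for rts, nesms in ((-1, 0), (16, 0), (0, -1), (0, 4)):
            with pytest.raises(ScoreValidationError):
                combine_scores(rts, nesms)
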