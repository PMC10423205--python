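"""Blood- and image-based score calculations against hand-computed oracles."""
import math

import numpy as np
import pytest

from hepatoscore import (
    FunctionalMap,
    LiverMask,
    MelifParameters,
    PatientRecord,
    VoxelGeometry,
    albi_grade,
    albi_score,
    child_pugh,
    convert_units,
    liver_volume,
    meld_group,
    meld_score,
    melif_score,
    score_patient,
)


def make_patient(**kw):
    defaults = dict(id="p", height=1.7, weight=83.0, bilirubin=17.1,
                    albumin=35.0, creatinine=1.0, inr=1.1)
    defaults.update(kw)
    return PatientRecord(**defaults)


class TestMeld:
    @pytest.mark.parametrize("bili, inr, creat, expected", [
        (1.0, 1.0, 1.0, 6.43),                 # ln 1 = 0 leaves the constant
        (2.0, 1.5, 1.2, 15.336122851846179),   # hand evaluation of the formula
    ])
    def test_raw_values(self, bili, inr, creat, expected):
        assert meld_score(bili, inr, creat) == pytest.approx(expected, abs=1e-9)

    def test_unos_clamp_floors_inputs(self):
        assert meld_score(0.5, 1, 1, "unos") == meld_score(1.0, 1, 1, "raw")
        assert meld_score(1, 1, 9.0, "unos") == meld_score(1, 1, 4.0, "raw")

    def test_strictly_increasing_in_each_input(self):
        base = meld_score(2.0, 1.5, 1.2)
        assert meld_score(2.5, 1.5, 1.2) > base
        assert meld_score(2.0, 1.6, 1.2) > base
        assert meld_score(2.0, 1.5, 1.3) > base

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            meld_score(0.0, 1, 1)

    @pytest.mark.parametrize("score, group", [
        (10, "good"), (11, "impaired"), (6.43, "good"), (22, "impaired"),
        (10.4, "good"), (10.5, "impaired"),  # nearest-integer, half away from zero
    ])
    def test_dichotomy(self, score, group):
        assert meld_group(score) == group


class TestAlbi:
    def test_log10_oracle(self):
        # log10(10) = 1, so score = 0.66 - 0.085*40 = -2.74
        assert albi_score(10.0, 40.0) == pytest.approx(-2.74, abs=1e-12)

    def test_hand_value(self):
        assert albi_score(17.1, 35.0) == pytest.approx(-2.1612225671411784, abs=1e-12)

    @pytest.mark.parametrize("albumin", [20.0, 30.0, 47.0])
    def test_albumin_term_isolated(self, albumin):
        # bilirubin 1 umol/L: log10(1) = 0, leaving only the albumin term
        assert albi_score(1.0, albumin) == pytest.approx(-0.085 * albumin, abs=1e-14)

    def test_rejects_nonpositive_bilirubin(self):
        with pytest.raises(ValueError):
            albi_score(0.0, 35.0)

    @pytest.mark.parametrize("score, grade", [
        (-2.6, 1), (-2.61, 1), (-10.0, 1),
        (-2.59, 2), (-1.39, 2),
        (-1.3899, 3), (0.0, 3),
    ])
    def test_grade_boundaries(self, score, grade):
        assert albi_grade(score) == grade

    def test_grade_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            albi_grade(float("nan"))

    def test_grade_monotone_in_panel(self):
        bilis = [5.0, 10.0, 20.0, 40.0, 80.0]
        grades = [albi_grade(albi_score(b, 35.0)) for b in bilis]
        assert grades == sorted(grades)
        albs = [20.0, 28.0, 35.0, 45.0]
        grades = [albi_grade(albi_score(17.1, a)) for a in albs]
        assert grades == sorted(grades, reverse=True)


class TestChildPugh:
    def test_all_best(self):
        p = make_patient(bilirubin=17.1, albumin=40.0, inr=1.0)  # 1 mg/dL, 4 g/dL
        assert child_pugh(p) == (5, "A")

    def test_all_worst(self):
        p = make_patient(bilirubin=4.0 * 17.1, albumin=20.0, inr=3.0,
                         ascites_grade="moderate_severe",
                         encephalopathy_grade="grade_3_4")
        assert child_pugh(p) == (15, "C")

    def test_mixed_class_b(self):
        # bilirubin 2.5 mg/dL, albumin 3.0 g/dL, INR 2.0, mild ascites:
        # 2 + 2 + 2 + 2 + 1 = 9 points, class B
        p = make_patient(bilirubin=2.5 * 17.1, albumin=30.0, inr=2.0,
                         ascites_grade="mild")
        assert child_pugh(p) == (9, "B")

    def test_class_boundaries(self):
        six = make_patient(bilirubin=17.1, albumin=40.0, inr=1.0, ascites_grade="mild")
        assert child_pugh(six) == (6, "A")
        seven = make_patient(bilirubin=2.5 * 17.1, albumin=40.0, inr=1.0,
                             ascites_grade="mild")
        assert child_pugh(seven) == (7, "B")

    def test_rejects_unknown_grade(self):
        with pytest.raises(ValueError):
            make_patient(ascites_grade="massive")


class TestUnits:
    def test_bilirubin_factor(self):
        assert convert_units(1.0, "bilirubin_mg_dL", "bilirubin_umol_L") == pytest.approx(17.1)

    def test_albumin_decimal_shift(self):
        assert convert_units(3.5, "albumin_g_dL", "albumin_g_L") == pytest.approx(35.0)

    @pytest.mark.parametrize("pair", [
        ("bilirubin_mg_dL", "bilirubin_umol_L"), ("albumin_g_L", "albumin_g_dL"),
    ])
    def test_round_trip(self, pair):
        assert convert_units(convert_units(2.31, *pair), *pair[::-1]) == pytest.approx(2.31, rel=1e-15)

    def test_unsupported_pair(self):
        with pytest.raises(ValueError):
            convert_units(1.0, "bilirubin_mg_dL", "albumin_g_L")


class TestLiverVolume:
    def test_protocol_spacing(self, flat_mask):
        # 1000 voxels * 1.3*1.3*3.0 mm3 = 5.07 ml
        assert liver_volume(flat_mask) == pytest.approx(5.07, abs=1e-12)

    def test_single_unit_voxel(self):
        geom = VoxelGeometry((1, 1, 1), (1.0, 1.0, 1.0))
        mask = LiverMask(np.ones((1, 1, 1), dtype=bool), geom)
        assert liver_volume(mask) == pytest.approx(0.001)

    def test_empty_mask_rejected(self):
        geom = VoxelGeometry((2, 2, 2), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            liver_volume(LiverMask(np.zeros((2, 2, 2), dtype=bool), geom))


def constant_fmap(mask, rr_value):
    rr = np.full(mask.geometry.shape, float(rr_value))
    return FunctionalMap(rr, mask.geometry, mask.values.copy())


class TestMelif:
    def test_zero_field_gives_zero(self, flat_mask):
        score, _ = melif_score(constant_fmap(flat_mask, 0.0), flat_mask, make_patient())
        assert score == 0.0

    def test_linear_in_aggregate(self, flat_mask):
        p = make_patient()
        s1, _ = melif_score(constant_fmap(flat_mask, 0.3), flat_mask, p)
        s2, _ = melif_score(constant_fmap(flat_mask, 0.6), flat_mask, p)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_frozen_sum_value(self, flat_mask):
        # V = 5.07 ml, A = 1000 * 0.5 = 500, h = 1.7 m, w = 83 kg
        score, info = melif_score(constant_fmap(flat_mask, 0.5), flat_mask, make_patient())
        assert score == pytest.approx(4784.8753034930, rel=1e-10)
        assert info["aggregation"] == "sum" and info["volume_unit"] == "ml"

    def test_mean_aggregation(self, flat_mask):
        params = MelifParameters(aggregation="mean")
        score, _ = melif_score(constant_fmap(flat_mask, 0.5), flat_mask,
                               make_patient(), params)
        assert score == pytest.approx(4.7848753034930, rel=1e-10)

    def test_cohort_mean_patient_factor_scale(self):
        # mask of 1547 one-ml voxels reproduces the cohort-mean liver volume;
        # with aggregate A = 161.7 the score lands at ~50
        geom = VoxelGeometry((1547, 1, 1), (10.0, 10.0, 10.0))
        mask = LiverMask(np.ones((1547, 1, 1), dtype=bool), geom)
        fmap = constant_fmap(mask, 161.7 / 1547)
        score, info = melif_score(fmap, mask, make_patient())
        assert info["liver_volume"] == pytest.approx(1547.0)
        assert score == pytest.approx(49.9944, abs=1e-3)

    def test_monotonicity_in_patient_factors(self, flat_mask):
        fmap = constant_fmap(flat_mask, 0.5)
        base, _ = melif_score(fmap, flat_mask, make_patient())
        taller, _ = melif_score(fmap, flat_mask, make_patient(height=1.9))
        heavier, _ = melif_score(fmap, flat_mask, make_patient(weight=95.0))
        assert taller > base > heavier

    def test_mean_invariant_to_grid_refinement(self, flat_mask):
        # same rr field on a 2x-finer grid along z: mean aggregation unchanged
        p, params = make_patient(), MelifParameters(aggregation="mean")
        coarse, _ = melif_score(constant_fmap(flat_mask, 0.42), flat_mask, p, params)
        geom2 = VoxelGeometry((10, 10, 20), (1.3, 1.3, 1.5))
        mask2 = LiverMask(np.ones((10, 10, 20), dtype=bool), geom2)
        fine, _ = melif_score(constant_fmap(mask2, 0.42), mask2, p, params)
        assert fine == pytest.approx(coarse, rel=1e-12)

    def test_sum_scales_with_voxel_count(self, flat_mask):
        p = make_patient()
        coarse, _ = melif_score(constant_fmap(flat_mask, 0.42), flat_mask, p)
        geom2 = VoxelGeometry((10, 10, 20), (1.3, 1.3, 1.5))
        mask2 = LiverMask(np.ones((10, 10, 20), dtype=bool), geom2)
        fine, _ = melif_score(constant_fmap(mask2, 0.42), mask2, p)
        assert fine == pytest.approx(2 * coarse, rel=1e-12)

    def test_no_valid_voxels_rejected(self, flat_mask):
        fmap = constant_fmap(flat_mask, 0.5)
        fmap.valid_mask[:] = False
        with pytest.raises(ValueError):
            melif_score(fmap, flat_mask, make_patient())


def test_score_patient_panel_consistency(flat_mask):
    p = make_patient(bilirubin=2.0 * 17.1, inr=1.5, creatinine=1.2)
    panel = score_patient(p, fmap=constant_fmap(flat_mask, 0.5), mask=flat_mask)
    assert panel.meld_raw == pytest.approx(15.336122851846179)
    assert panel.meld_rounded == 15 and panel.meld_group == "impaired"
    assert panel.albi_grade == albi_grade(panel.albi)
    assert panel.aggregation == "sum" and panel.volume_unit == "ml"
    assert panel.liver_volume_ml == pytest.approx(5.07)
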