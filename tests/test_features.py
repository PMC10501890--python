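"""Semantic-feature rules: reference stats, per-feature rules, composition."""

import numpy as np
import pytest

from pedbrain import (FeatureThresholds, MRIStudy, PhantomSpec,
                      SemanticFeatures, assign_location,
                      classify_cyst_necrosis, classify_enhancement_pattern,
                      classify_intensity, detect_diffusion_restriction,
                      detect_haemorrhage, extract_features, generate_phantom,
                      grade_enhancement, reference_stats)
from pedbrain.core import ReferenceStats
from pedbrain.phantom import sample_class_features

THR = FeatureThresholds()


def make_study(**sequences):
    return MRIStudy(sequences={k: np.asarray(v, dtype=float)
                               for k, v in sequences.items()})


def flat_ref(median=730.0, sd=25.0):
    seqs = ("t1", "t1c", "t2", "flair", "dwi", "adc")
    return ReferenceStats(medians={s: median for s in seqs},
                          sds={s: sd for s in seqs})


class TestReferenceStats:
    def test_constant_gm(self):
        vol = np.full((6, 6, 6), 730.0)
        gm = np.zeros((6, 6, 6), dtype=bool)
        gm[2:4] = True
        ref = reference_stats(make_study(t1=vol), gm)
        assert ref.median("t1") == 730.0
        assert ref.sd("t1") == 0.0

    def test_noise_sd_estimated_within_25_percent(self):
        rng = np.random.default_rng(0)
        vol = 730.0 + rng.normal(scale=36.0, size=(20, 20, 20))
        gm = np.ones((20, 20, 20), dtype=bool)
        ref = reference_stats(make_study(flair=vol), gm)
        assert abs(ref.sd("flair") - 36.0) / 36.0 < 0.25

    def test_missing_sequences_flagged(self):
        gm = np.ones((4, 4, 4), dtype=bool)
        ref = reference_stats(make_study(t1=np.full((4, 4, 4), 700.0)), gm)
        assert "t2" in ref.missing
        with pytest.raises(KeyError):
            ref.median("t2")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reference_stats(make_study(t1=np.zeros((4, 4, 4))),
                            np.zeros((4, 4, 4), dtype=bool))


class TestIntensityClass:
    def test_equal_medians_isointense(self):
        vol = np.full((4, 4, 4), 730.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        assert classify_intensity(vol, mask, 730.0) == "isointense"

    def test_half_gm_is_hypointense(self):
        vol = np.full((4, 4, 4), 365.0)
        mask = np.ones((4, 4, 4), dtype=bool)
        assert classify_intensity(vol, mask, 730.0, iso_band=0.10) == "hypointense"

    def test_agrees_with_direct_median_comparison(self):
        rng = np.random.default_rng(1)
        mask = np.ones((5, 5, 5), dtype=bool)
        for _ in range(30):
            vol = rng.uniform(300, 1200, size=(5, 5, 5))
            got = classify_intensity(vol, mask, 730.0, 0.10)
            med = np.median(vol)
            if abs(med - 730) <= 73:
                assert got == "isointense"
            else:
                assert got == ("hyperintense" if med > 730 else "hypointense")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_intensity(np.zeros((3, 3, 3)),
                               np.zeros((3, 3, 3), bool), 730.0)


class TestHaemorrhage:
    def test_uniform_tumor_at_gm_level_negative(self):
        t1 = np.full((8, 8, 8), 730.0)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        assert detect_haemorrhage(t1, mask, flat_ref(), THR) is False

    def test_single_bright_voxel_below_size_filter(self):
        t1 = np.full((8, 8, 8), 730.0)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        t1[3, 3, 3] = 1500.0
        assert detect_haemorrhage(t1, mask, flat_ref(), THR) is False

    def test_focus_at_least_min_size_detected(self):
        t1 = np.full((8, 8, 8), 730.0)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        t1[3, 3:5, 3] = 1500.0
        t1[4, 3:5, 3] = 1500.0
        t1[3, 3, 4] = 1500.0  # 5-voxel connected focus, boundary inclusive
        assert detect_haemorrhage(t1, mask, flat_ref(), THR) is True


class TestCystNecrosis:
    def lesion_volumes(self, flair_value):
        """One fluid-like (T2-bright, T1-dark) 27-voxel component."""
        shape = (10, 10, 10)
        t1 = np.full(shape, 620.0)
        t2 = np.full(shape, 750.0)
        flair = np.full(shape, 730.0)
        nonenh = np.zeros(shape, dtype=bool)
        nonenh[2:8, 2:8, 2:8] = True
        t1[4:7, 4:7, 4:7] = 365.0
        t2[4:7, 4:7, 4:7] = 1170.0
        flair[4:7, 4:7, 4:7] = flair_value
        return t1, t2, flair, nonenh

    def test_empty_mask_gives_neither(self):
        z = np.zeros((4, 4, 4))
        assert classify_cyst_necrosis(z, z, z, np.zeros((4, 4, 4), bool),
                                      flat_ref(), THR) == (False, False)

    def test_suppressed_component_is_cyst(self):
        t1, t2, flair, mask = self.lesion_volumes(flair_value=480.0)
        cyst, nec = classify_cyst_necrosis(t1, t2, flair, mask, flat_ref(), THR)
        assert (cyst, nec) == (True, False)

    def test_unsuppressed_component_is_necrosis(self):
        t1, t2, flair, mask = self.lesion_volumes(flair_value=800.0)
        cyst, nec = classify_cyst_necrosis(t1, t2, flair, mask, flat_ref(), THR)
        assert (cyst, nec) == (False, True)

    def test_half_suppressed_component_sets_neither_flag(self):
        t1, t2, flair, mask = self.lesion_volumes(flair_value=800.0)
        # suppress exactly half the 27 lesion voxels (fraction ~0.48 in band)
        lesion = np.argwhere(flair == 800.0)
        for i, (x, y, z) in enumerate(lesion):
            if i % 2 == 0:
                flair[x, y, z] = 480.0
        cyst, nec = classify_cyst_necrosis(t1, t2, flair, mask, flat_ref(), THR)
        assert (cyst, nec) == (False, False)

    def test_supp_hi_monotonicity(self):
        """Raising the cyst threshold can only switch cyst off, never on."""
        t1, t2, flair, mask = self.lesion_volumes(flair_value=480.0)
        previous = True
        for supp_hi in (0.5, 0.75, 0.9, 0.999):
            thr = FeatureThresholds(supp_hi=supp_hi)
            cyst, _ = classify_cyst_necrosis(t1, t2, flair, mask,
                                             flat_ref(), thr)
            assert not (cyst and not previous)
            previous = cyst


class TestDiffusionRestriction:
    def tumor_mask(self):
        m = np.zeros((8, 8, 8), dtype=bool)
        m[2:6, 2:6, 2:6] = True
        return m

    def test_equal_dwi_negative(self):
        m = self.tumor_mask()
        assert detect_diffusion_restriction(
            np.full(m.shape, 730.0), np.full(m.shape, 730.0), m,
            flat_ref(), THR) is False

    def test_t2_shine_through_rejected_by_adc(self):
        m = self.tumor_mask()
        dwi = np.full(m.shape, 730.0)
        adc = np.full(m.shape, 730.0)
        dwi[m] = 1100.0  # bright DWI but normal ADC -> not restriction
        assert detect_diffusion_restriction(dwi, adc, m, flat_ref(), THR) is False

    def test_high_dwi_low_adc_positive(self):
        m = self.tumor_mask()
        dwi = np.full(m.shape, 730.0)
        adc = np.full(m.shape, 730.0)
        dwi[m], adc[m] = 1100.0, 400.0
        assert detect_diffusion_restriction(dwi, adc, m, flat_ref(), THR) is True

    def test_missing_adc_judged_on_dwi_alone(self):
        m = self.tumor_mask()
        dwi = np.full(m.shape, 730.0)
        dwi[m] = 1100.0
        assert detect_diffusion_restriction(dwi, None, m, flat_ref(), THR) is True


class TestEnhancementGrade:
    def map_with_fraction(self, n_et, n_net):
        m = np.zeros(n_et + n_net + 4, dtype=np.int16)
        m[:n_et] = 1
        m[n_et:n_et + n_net] = 2
        return m

    @pytest.mark.parametrize("n_et, n_net, expected", [
        (1, 9, "mild"),        # f = 0.10
        (1, 3, "moderate"),    # f = 0.25 boundary -> moderate (closed band)
        (3, 1, "moderate"),    # f = 0.75 boundary -> moderate
        (9, 1, "severe"),      # f = 0.90
    ])
    def test_band_assignment(self, n_et, n_net, expected):
        assert grade_enhancement(self.map_with_fraction(n_et, n_net)) == expected

    def test_partition_of_unit_interval(self):
        """Every feasible fraction maps to exactly one grade."""
        for n_et in range(0, 41):
            grade = grade_enhancement(self.map_with_fraction(n_et, 40 - n_et))
            f = n_et / 40
            expected = "mild" if f < 0.25 else ("moderate" if f <= 0.75
                                                else "severe")
            assert grade == expected

    def test_empty_tumor_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grade_enhancement(np.zeros(8, dtype=np.int16))


class TestEnhancementPattern:
    def test_constant_is_homogeneous(self):
        t1c = np.full((6, 6), 1500.0)
        mask = np.ones((6, 6), dtype=bool)
        assert classify_enhancement_pattern(t1c, mask) == "homogeneous"

    def test_bimodal_is_heterogeneous_with_hand_computed_cv(self):
        vals = np.array([400.0] * 8 + [1600.0] * 8)
        cv = vals.std() / vals.mean()  # = 600/1000 = 0.6 > 0.3
        assert cv == pytest.approx(0.6)
        t1c = vals.reshape(4, 4)
        assert classify_enhancement_pattern(
            t1c, np.ones((4, 4), bool), cv_threshold=0.3) == "heterogeneous"

    def test_empty_mask_undefined(self):
        assert classify_enhancement_pattern(np.zeros((3, 3)),
                                            np.zeros((3, 3), bool)) is None


class TestLocation:
    def lobe_map(self):
        lobes = np.zeros((12, 12, 6), dtype=np.int16)
        lobes[:6] = 1   # forebrain
        lobes[6:9] = 2  # brainstem
        lobes[9:] = 3   # cerebellum
        return lobes

    def test_fully_inside_brainstem(self):
        tumor = np.zeros((12, 12, 6), dtype=np.int16)
        tumor[7, 2:5, 2:5] = 2
        assert assign_location(tumor, self.lobe_map()) == "brainstem"

    def test_majority_overlap_wins(self):
        tumor = np.zeros((12, 12, 6), dtype=np.int16)
        tumor[7:9, 0:2, 0] = 2   # 4 voxels brainstem
        tumor[9:11, 0:3, 0] = 2  # 6 voxels cerebellum
        assert assign_location(tumor, self.lobe_map()) == \
            "cerebellum_fourth_ventricle"

    def test_tie_breaks_to_forebrain_with_warning(self, caplog):
        tumor = np.zeros((12, 12, 6), dtype=np.int16)
        tumor[5, 0, 0] = 2  # 1 voxel forebrain
        tumor[6, 0, 0] = 2  # 1 voxel brainstem
        with caplog.at_level("WARNING"):
            assert assign_location(tumor, self.lobe_map()) == "forebrain"
        assert "tie" in caplog.text

    def test_outside_all_lobes_indeterminate(self, caplog):
        lobes = np.zeros((6, 6, 6), dtype=np.int16)
        tumor = np.zeros((6, 6, 6), dtype=np.int16)
        tumor[1, 1, 1] = 1
        with caplog.at_level("WARNING"):
            assert assign_location(tumor, lobes) is None


class TestExtractFeatures:
    def test_phantom_truth_recovered_from_ground_truth_masks(self, tumor_case):
        got = extract_features(tumor_case.study, tumor_case.tumor,
                               tumor_case.lobes, tumor_case.gm_mask)
        assert tumor_case.truth.agreement(got) >= 0.8

    def test_prevalence_sampled_case_recovery(self):
        rng = np.random.default_rng(8)
        feats = sample_class_features("medulloblastoma", rng, "prevalence")
        case = generate_phantom(PhantomSpec(
            tumor_class="medulloblastoma", target_features=feats, seed=17))
        got = extract_features(case.study, case.tumor, case.lobes,
                               case.gm_mask)
        assert case.truth.agreement(got) >= 0.8

    def test_normal_case_rejected(self, normal_case):
        with pytest.raises(ValueError, match="no tumor"):
            extract_features(normal_case.study, normal_case.tumor,
                             normal_case.lobes, normal_case.gm_mask)
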