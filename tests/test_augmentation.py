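"""Mask insertion, classical augmentation, SMOTE and training-set assembly."""

import numpy as np
import pytest

from cmbforge.analytical import AnalyticalLesionConfig, make_analytical_mask
from cmbforge.augmentation import (
    apply_mask,
    build_training_set,
    classic_augment,
    implant_lesions,
    smote_augment,
)
from cmbforge.phantom import extract_patch, sample_negative_locations
from cmbforge.types import LabeledPatch, LocationSample, mask_volume
from cmbforge.volume_model import estimate_lesion_volume, smooth_volume_distribution


@pytest.fixture()
def neg(rng):
    return rng.uniform(0.3, 0.9, size=(11, 11, 11))


class TestApplyMask:
    def test_identity_mask(self, neg):
        out = apply_mask(neg, np.ones((11, 11, 11)))
        np.testing.assert_array_equal(out.patch, neg)
        assert out.label == 1

    def test_dark_center_propagates(self, neg):
        m = np.ones((11, 11, 11))
        m[5, 5, 5] = 0.0
        out = apply_mask(neg, m)
        assert out.patch[5, 5, 5] == 0.0

    def test_support_identity(self, neg):
        m = make_analytical_mask(AnalyticalLesionConfig(target_volume=10, seed=1))
        out = apply_mask(neg, m)
        changed = out.patch != neg
        assert (changed == (m < 1.0) & (neg != 0)).all()
        # voxels where the mask is exactly 1 are bit-identical to background
        np.testing.assert_array_equal(out.patch[m == 1.0], neg[m == 1.0])

    def test_shape_mismatch_rejected(self, neg):
        with pytest.raises(ValueError):
            apply_mask(neg[:7, :7, :7], np.ones((11, 11, 11)))


class TestImplant:
    def test_zero_locations_unchanged(self, small_phantom):
        out, truth = implant_lesions(small_phantom, [], [])
        np.testing.assert_array_equal(out.intensities, small_phantom.intensities)
        assert truth.empty

    def test_all_ones_mask_unchanged(self, small_phantom):
        loc = LocationSample((24, 24, 16))
        out, truth = implant_lesions(small_phantom, [loc], [np.ones((11, 11, 11))])
        np.testing.assert_array_equal(out.intensities, small_phantom.intensities)
        assert truth.volume_mm3.iloc[0] == 0.0

    def test_overlapping_implants_rejected(self, small_phantom):
        locs = [LocationSample((24, 24, 16)), LocationSample((26, 24, 16))]
        masks = [np.ones((11, 11, 11))] * 2
        with pytest.raises(ValueError, match="overlapping"):
            implant_lesions(small_phantom, locs, masks)

    def test_implant_then_estimate_round_trip(self, clean_phantom, rng):
        target = 12.0
        mask = make_analytical_mask(AnalyticalLesionConfig(target_volume=target, seed=3),
                                    clean_phantom.spacing)
        # add mild texture so the EM mixture is identifiable
        vol = clean_phantom
        noisy = vol.intensities + rng.normal(0, 4, vol.shape) * vol.brain_mask
        from cmbforge.types import SWIVolume

        vol = SWIVolume(np.clip(noisy, 0, 255), vol.spacing, vol.brain_mask)
        loc = sample_negative_locations(vol, 1, min_boundary_mm=5.0, seed=2)[0]
        lesioned, truth = implant_lesions(vol, [loc], [mask])
        patch = extract_patch(lesioned, loc, 7)
        est = estimate_lesion_volume(patch, spacing=vol.spacing)
        implanted = truth.volume_mm3.iloc[0]
        assert implanted == pytest.approx(target, rel=0.25)
        assert est == pytest.approx(implanted, rel=0.45)


class TestClassicAugment:
    def test_count_multiplier_is_seven(self, neg):
        out = classic_augment([LabeledPatch(neg, 1)])
        assert len(out) == 7
        assert all(p.provenance == "classic_aug" for p in out)

    def test_rotation_and_flip_involutions(self, neg):
        np.testing.assert_array_equal(np.rot90(np.rot90(neg, 2, (0, 1)), 2, (0, 1)), neg)
        np.testing.assert_array_equal(np.flip(np.flip(neg, 0), 0), neg)

    def test_histograms_preserved(self, neg):
        out = classic_augment([LabeledPatch(neg, 1)])
        ref = np.sort(neg.ravel())
        for p in out:
            np.testing.assert_array_equal(np.sort(p.patch.ravel()), ref)

    def test_asymmetric_patch_gives_distinct_augments(self):
        p = np.arange(11**3, dtype=float).reshape(11, 11, 11) / 11**3
        out = classic_augment([LabeledPatch(p, 1)])
        flat = {a.patch.tobytes() for a in out}
        assert len(flat) == 7
        assert p.tobytes() not in flat


class TestSmote:
    def _minority(self, rng, n=10):
        return [LabeledPatch(rng.uniform(0, 1, (5, 5, 5)), 1, "real", f"s{i}")
                for i, _ in enumerate(range(n))]

    def test_zero_new_empty(self, rng):
        assert smote_augment(self._minority(rng), 0) == []

    def test_outputs_are_convex_combinations(self, rng):
        minority = self._minority(rng)
        x = np.stack([m.patch.ravel() for m in minority])
        out = smote_augment(minority, 50, k=3, seed=1)
        for s in out:
            v = s.patch.ravel()
            # within the coordinate-wise min/max envelope of the minority set
            assert (v >= x.min(axis=0) - 1e-12).all()
            assert (v <= x.max(axis=0) + 1e-12).all()

    def test_two_point_set_interpolates_on_segment(self, rng):
        a = np.zeros((3, 3, 3))
        b = np.ones((3, 3, 3))
        minority = [LabeledPatch(a, 1), LabeledPatch(b, 1)]
        out = smote_augment(minority, 20, k=1, seed=2)
        for s in out:
            vals = np.unique(np.round(s.patch, 12))
            assert len(vals) == 1  # exactly a + u*(b-a), constant per sample
            assert 0.0 <= vals[0] <= 1.0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            smote_augment(self._minority(rng, 3), 5, k=5)


class TestBuildTrainingSet:
    @pytest.fixture()
    def sources(self, rng):
        negs = rng.uniform(0.2, 0.9, size=(40, 11, 11, 11))
        dist = smooth_volume_distribution(np.clip(rng.gamma(2, 6, 100), 0.5, 79))
        return {"neg_patches": negs, "dist": dist}

    def test_balanced_small_set(self, sources):
        out = build_training_set("M1", sources, target_pos=10, target_neg=10, seed=1)
        labels = [p.label for p in out]
        assert len(out) == 20 and sum(labels) == 10

    def test_m5_provenance(self, sources, rng):
        sources["real_positives"] = [
            LabeledPatch(rng.uniform(0, 1, (11, 11, 11)), 1, "real", f"s{i}")
            for i in range(20)
        ]
        out = build_training_set("M5", sources, target_pos=15, target_neg=5, seed=2)
        pos = [p for p in out if p.label == 1]
        assert all(p.provenance == "smote" for p in pos)

    def test_m4_positives_differ_only_under_mask(self, sources):
        from cmbforge.lesion_gan import GanConfig, Generator

        gen = Generator(GanConfig(conditioning_mode="volume+background", seed=0))
        sources["generator"] = gen
        out = build_training_set("M4", sources, target_pos=6, target_neg=2, seed=3)
        pos = [p for p in out if p.label == 1]
        assert len(pos) == 6 and all(p.provenance == "lesiongan" for p in pos)
        negs = np.asarray(sources["neg_patches"])
        for p in pos:
            # each positive is neg * mask for some stored negative: the ratio
            # patch/neg must lie in [0, 1] for its source background
            ratios = np.array([
                np.nanmax(np.where(n > 0, p.patch / np.where(n > 0, n, 1), 0))
                for n in negs
            ])
            assert (ratios <= 1.0 + 1e-9).any()

    def test_strategy_source_mismatch(self, sources):
        with pytest.raises(ValueError, match="generator"):
            build_training_set("M4", sources, 4, 4)
        with pytest.raises(ValueError, match="real_positives"):
            build_training_set("M5", sources, 4, 4)
        with pytest.raises(ValueError, match="strategy"):
            build_training_set("M9", sources, 4, 4)
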