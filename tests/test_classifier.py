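"""CNN classifier: architecture contracts, training, ensembling, subject CV."""

import numpy as np
import pytest

from cmbforge.classifier import (
    ClassifierConfig,
    EnsembleModel,
    build_classifier,
    count_parameters,
    predict,
    subject_kfold,
    train_classifier,
)
from cmbforge.types import LabeledPatch


def _expected_param_count(cfg: ClassifierConfig) -> int:
    """Closed-form parameter count of the default architecture."""
    total = 0
    in_ch, size = 1, cfg.input_size
    for c in cfg.conv_channels:
        total += c * in_ch * cfg.kernel**3 + c  # conv W + b
        total += 2 * c + 0  # batchnorm gamma + beta (running stats untrained)
        in_ch = c
        size //= 2
    n = cfg.conv_channels[-1] * size**3
    for f in cfg.fc_layout:
        total += n * f + f
        n = f
    total += n * 1 + 1
    return total


class TestArchitecture:
    def test_output_in_unit_interval(self, rng):
        net = build_classifier(ClassifierConfig(seed=1))
        x = rng.uniform(0, 1, (4, 11, 11, 11, 1)).astype(np.float32)
        y = net.forward(x, train=False)
        assert ((y > 0) & (y < 1)).all()

    def test_parameter_count_matches_closed_form(self):
        cfg = ClassifierConfig()
        net = build_classifier(cfg)
        assert count_parameters(net) == _expected_param_count(cfg)

    def test_same_seed_identical_weights(self):
        a = build_classifier(ClassifierConfig(seed=7))
        b = build_classifier(ClassifierConfig(seed=7))
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_fc_order_flag(self):
        assert ClassifierConfig(fc_order="printed").fc_layout == (10, 70, 30)
        assert ClassifierConfig(fc_order="sorted").fc_layout == (70, 30, 10)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            ClassifierConfig(input_size=7).validate()


def _toy_patches(rng, n=60):
    """Separable toy task: dark-center blobs vs flat background."""
    out = []
    for i in range(n):
        p = rng.uniform(0.5, 0.8, (11, 11, 11))
        label = i % 2
        if label:
            p[3:8, 3:8, 3:8] *= 0.3
        out.append(LabeledPatch(p, label, "real", subject_id=f"s{i % 6}"))
    return out


class TestTraining:
    def test_learns_separable_toy_task(self, rng):
        patches = _toy_patches(rng)
        cfg = ClassifierConfig(epochs=30, lr=3e-3, batch=16, ensemble_size=1, seed=2)
        model = train_classifier(patches, cfg)
        scores = predict(model, patches)
        labels = np.array([p.label for p in patches])
        acc = ((scores > 0.5) == labels).mean()
        assert acc == 1.0

    def test_loss_log_length(self, rng):
        patches = _toy_patches(rng, 20)
        cfg = ClassifierConfig(epochs=5, lr=1e-3, ensemble_size=2, seed=0)
        model = train_classifier(patches, cfg)
        assert all(len(log) == 5 for log in model.loss_logs)

    def test_single_class_rejected(self, rng):
        patches = [LabeledPatch(rng.uniform(0, 1, (11, 11, 11)), 1)] * 4
        with pytest.raises(ValueError):
            train_classifier(patches, ClassifierConfig(epochs=1))

    def test_retraining_reproduces_scores_bitwise(self, rng):
        patches = _toy_patches(rng, 24)
        cfg = ClassifierConfig(epochs=3, lr=1e-3, ensemble_size=1, seed=11)
        s1 = predict(train_classifier(patches, cfg), patches)
        s2 = predict(train_classifier(patches, cfg), patches)
        np.testing.assert_array_equal(s1, s2)


class TestEnsemble:
    class _Const:
        def __init__(self, value):
            self.value = value

        def forward(self, x, train=False):
            return np.full((x.shape[0], 1), self.value, dtype=np.float32)

    def test_mean_of_constant_members(self):
        model = EnsembleModel([self._Const(0.2), self._Const(0.4)],
                              ClassifierConfig(), [])
        out = model.predict(np.zeros((3, 11, 11, 11)))
        np.testing.assert_allclose(out, 0.3, atol=1e-7)

    def test_singleton_ensemble_equals_member(self, rng):
        patches = _toy_patches(rng, 16)
        cfg = ClassifierConfig(epochs=2, lr=1e-3, ensemble_size=1, seed=3)
        model = train_classifier(patches, cfg)
        x = np.stack([p.patch for p in patches]).astype(np.float32)
        member = model.members[0].forward(x[..., None], train=False)[:, 0]
        np.testing.assert_allclose(model.predict(x), member, rtol=1e-6)

    def test_permutation_equivariance(self, rng):
        patches = _toy_patches(rng, 16)
        cfg = ClassifierConfig(epochs=2, lr=1e-3, ensemble_size=1, seed=3)
        model = train_classifier(patches, cfg)
        x = np.stack([p.patch for p in patches])
        perm = rng.permutation(len(x))
        np.testing.assert_allclose(model.predict(x)[perm], model.predict(x[perm]),
                                   rtol=1e-6)


class TestSubjectKfold:
    def _patches(self, rng, n_subjects=8, per_subject=5):
        return [
            LabeledPatch(rng.uniform(0, 1, (3, 3, 3)), i % 2, "real", f"subj{s}")
            for s in range(n_subjects)
            for i in range(per_subject)
        ]

    def test_partition_is_exact(self, rng):
        patches = self._patches(rng)
        splits = subject_kfold(patches, k=4, repeats=2, seed=0)
        assert len(splits) == 8
        subjects = np.array([p.subject_id for p in patches])
        for r in range(2):
            seen = []
            for train_idx, test_idx in splits[r * 4:(r + 1) * 4]:
                seen.extend(np.unique(subjects[test_idx]))
            assert sorted(seen) == sorted(np.unique(subjects))

    def test_no_subject_leaks(self, rng):
        patches = self._patches(rng, 10, 7)
        subjects = np.array([p.subject_id for p in patches])
        for train_idx, test_idx in subject_kfold(patches, k=5, repeats=3, seed=1):
            assert not set(subjects[train_idx]) & set(subjects[test_idx])

    def test_leave_one_subject_out(self, rng):
        patches = self._patches(rng, 6, 3)
        splits = subject_kfold(patches, k=6, seed=2)
        subjects = np.array([p.subject_id for p in patches])
        for _, test_idx in splits:
            assert len(set(subjects[test_idx])) == 1

    def test_k_exceeding_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            subject_kfold(self._patches(rng, 3), k=5)

    def test_missing_subject_rejected(self, rng):
        patches = [LabeledPatch(rng.uniform(0, 1, (3, 3, 3)), 0)]
        with pytest.raises(ValueError, match="subject_id"):
            subject_kfold(patches, k=1)
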