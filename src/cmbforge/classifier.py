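"""Patch classifier: a small 3D CNN trained on augmented sets.

Architecture: three convolution blocks (kernel 3, feature maps 16/32/64,
each conv -> batch norm -> ReLU -> max pool 2) followed by fully connected
layers of 10, 70 and 30 neurons with 50% dropout, ending in a sigmoid.
Training minimizes binary cross-entropy with Adam.  Predictions come from
an ensemble: `ensemble_size` networks trained from distinct derived seeds,
averaged at inference.  Cross-validation folds partition *subjects*, never
patches, so augmented copies of a subject's data can never leak across the
train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._rng import spawn_seed
from .types import LabeledPatch

__all__ = [
    "ClassifierConfig",
    "EnsembleModel",
    "build_classifier",
    "train_classifier",
    "predict",
    "subject_kfold",
    "count_parameters",
]

_EPS = 1e-7


@dataclass
class ClassifierConfig:
    """CNN classifier hyperparameters (defaults are the full-scale recipe)."""

    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 3
    fc_sizes: tuple[int, int, int] = (10, 70, 30)
    fc_order: str = "printed"  # or "sorted" for (70, 30, 10)
    dropout: float = 0.5
    lr: float = 1e-5
    epochs: int = 200
    batch: int = 128
    ensemble_size: int = 10
    input_size: int = 11
    seed: int = 0

    def validate(self) -> None:
        if self.input_size % 2 == 0:
            raise ValueError("input_size must be odd")
        size = self.input_size
        for _ in range(3):
            size //= 2
        if size < 1:
            raise ValueError(
                f"input_size {self.input_size} incompatible with three pool-by-2 "
                "stages; the minimal valid size is 8 (smallest odd size: 9)"
            )
        if min(self.conv_channels + self.fc_sizes) <= 0 or self.lr <= 0:
            raise ValueError("all sizes and the learning rate must be positive")

    @property
    def fc_layout(self) -> tuple[int, int, int]:
        return tuple(sorted(self.fc_sizes, reverse=True)) if self.fc_order == "sorted" \
            else tuple(self.fc_sizes)


def build_classifier(cfg: ClassifierConfig, rng: np.random.Generator | None = None,
                     dtype=np.float32) -> nn.Sequential:
    """Untrained network per the config; same seed gives identical weights."""
    cfg.validate()
    rng = rng or np.random.default_rng(spawn_seed(cfg.seed, "classifier.init"))
    c1, c2, c3 = cfg.conv_channels
    k, pad = cfg.kernel, cfg.kernel // 2
    size = cfg.input_size
    layers: list[nn.Layer] = []
    in_ch = 1
    for c in (c1, c2, c3):
        layers += [
            nn.Conv3d(in_ch, c, k, 1, pad, rng=rng, dtype=dtype),
            nn.BatchNorm3d(c, dtype=dtype),
            nn.ReLU(),
            nn.MaxPool3d(2),
        ]
        in_ch = c
        size //= 2
    layers.append(nn.Flatten())
    n_flat = c3 * size**3
    drop_rng = np.random.default_rng(spawn_seed(cfg.seed, "classifier.dropout"))
    for f in cfg.fc_layout:
        layers += [
            nn.Linear(n_flat, f, rng=rng, dtype=dtype),
            nn.ReLU(),
            nn.Dropout(cfg.dropout, rng=drop_rng),
        ]
        n_flat = f
    layers.append(nn.Linear(n_flat, 1, rng=rng, dtype=dtype))
    layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


def count_parameters(net: nn.Sequential) -> int:
    return sum(p.size for p, _ in net.parameters())


def _forward_scores(net: nn.Sequential, x: np.ndarray, train: bool) -> np.ndarray:
    return net.forward(x[..., None].astype(np.float32), train=train)[:, 0]


def _train_member(net, x, y, cfg, rng_shuffle) -> list[float]:
    opt = nn.Adam(net.parameters(), lr=cfg.lr, beta1=0.9, beta2=0.999)
    n = x.shape[0]
    losses = []
    for _ in range(cfg.epochs):
        order = rng_shuffle.permutation(n)
        ep_loss, n_b = 0.0, 0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            xb, yb = x[idx], y[idx]
            p = _forward_scores(net, xb, train=True)
            pc = np.clip(p, _EPS, 1 - _EPS)
            loss = float(-np.mean(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            # BCE + sigmoid fused gradient w.r.t. the logit
            dlogit = ((p - yb) / idx.size).astype(np.float32)[:, None]
            for layer in reversed(net.layers[:-1]):  # skip the Sigmoid
                dlogit = layer.backward(dlogit)
            opt.step()
            ep_loss += loss
            n_b += 1
        losses.append(ep_loss / n_b)
    return losses


@dataclass
class EnsembleModel:
    """Seeded ensemble of identically configured networks."""

    members: list
    config: ClassifierConfig
    loss_logs: list[list[float]]

    def predict(self, patches: np.ndarray, batch: int = 512) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)
        out = np.zeros(x.shape[0])
        for net in self.members:
            for s in range(0, x.shape[0], batch):
                out[s:s + batch] += _forward_scores(net, x[s:s + batch], train=False)
        return out / len(self.members)


def train_classifier(train: list[LabeledPatch], cfg: ClassifierConfig) -> EnsembleModel:
    """Train the seeded ensemble on labeled patches (both classes required)."""
    cfg.validate()
    x = np.stack([lp.patch for lp in train]).astype(np.float32)
    y = np.array([lp.label for lp in train], dtype=np.float32)
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    members, logs = [], []
    for m in range(cfg.ensemble_size):
        init_rng = np.random.default_rng(spawn_seed(cfg.seed, f"classifier.init.{m}"))
        net = build_classifier(cfg, rng=init_rng)
        shuf_rng = np.random.default_rng(spawn_seed(cfg.seed, f"classifier.shuffle.{m}"))
        logs.append(_train_member(net, x, y, cfg, shuf_rng))
        members.append(net)
    return EnsembleModel(members, cfg, logs)


def predict(model: EnsembleModel, patches) -> np.ndarray:
    """Ensemble-mean scores in (0, 1), order-preserving with the input."""
    if isinstance(patches, list) and patches and isinstance(patches[0], LabeledPatch):
        patches = np.stack([lp.patch for lp in patches])
    return model.predict(np.asarray(patches))


def subject_kfold(patches: list[LabeledPatch], k: int = 10, repeats: int = 1,
                  seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-level k-fold splits, repeated with reshuffled subject order.

    Returns (train_idx, test_idx) pairs — k per repeat.  Folds partition
    subjects: all patches of a subject (real or derived) land on one side.
    """
    subjects = []
    for lp in patches:
        if lp.subject_id is None:
            raise ValueError("subject_kfold requires subject_id on every patch")
        subjects.append(lp.subject_id)
    subjects = np.array(subjects)
    uniq = np.unique(subjects)
    if k > uniq.size:
        raise ValueError(f"k={k} exceeds the number of subjects ({uniq.size})")
    rng = np.random.default_rng(spawn_seed(seed, "kfold"))
    splits = []
    for _ in range(repeats):
        order = rng.permutation(uniq)
        folds = np.array_split(order, k)
        for fold in folds:
            test_mask = np.isin(subjects, fold)
            splits.append((np.nonzero(~test_mask)[0], np.nonzero(test_mask)[0]))
    return splits
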