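"""Conditional 3D lesion GAN.

The generator maps a latent vector z ~ N(0, I) — optionally conditioned on a
normalized target lesion volume and on the healthy background patch the
lesion will be implanted into — to an 11x11x11 multiplicative partial-volume
mask G(z) in [0, 1].  Multiplying the mask into the background patch
implants a synthetic microbleed; mask values of 1 leave the background
untouched.  The discriminator judges 11^3 patches: real microbleed patches
versus background * G(z).

Three loss terms train the generator:

* adversarial: log(1 - D(G(z, c))) (the literal minimax objective; a
  non-saturating -log D(G(z, c)) variant is available behind a flag),
* volume: mean relative error between the mask's attenuated volume
  sum(1 - G) * voxel_volume and the requested volume,
* border: mean absolute deviation of the outermost one-voxel shell from 1,
  which makes the implanted lesion blend seamlessly into the background.

Conditioning modes select the model family: ``none`` is a vanilla GAN,
``volume`` a volume-conditioned CGAN, and ``volume+background`` the full
lesion GAN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from ._rng import spawn_seed
from .types import DEFAULT_SPACING, MASK_SIZE, VOLUME_CAP, VolumeDistribution, border_shell, voxel_volume
from .volume_model import sample_volumes

__all__ = [
    "GanConfig",
    "Generator",
    "Discriminator",
    "mask_volume_batch",
    "volume_loss",
    "border_loss",
    "adversarial_losses",
    "train_lesion_gan",
    "volume_fidelity_regression",
]

_EPS = 1e-7  # clamp inside adversarial logs

CONDITIONING_MODES = ("none", "volume", "volume+background")


@dataclass
class GanConfig:
    """Hyperparameters of the lesion GAN.

    Defaults follow the full-scale training recipe (Adam 2e-4 with
    beta1=0.5/beta2=0.999, batch 64, 2500 epochs); desk-scale runs override
    `epochs`.  `channels` are the three channel counts (Ch1, Ch2, Ch3) of
    the generator: Ch1 feature maps in the hidden stages, Ch2 = 1 output
    channel, Ch3 channels of the low-resolution latent grid.
    """

    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 2500
    batch: int = 64
    latent_dim: int = 100
    channels: tuple[int, int, int] = (6, 1, 8)
    border_weight: float = 1.0
    volume_weight: float = 1.0
    conditioning_mode: str = "volume+background"
    non_saturating: bool = False
    lr_schedule: str = "constant"  # or "cosine": anneal both optimizers to 0
    adv_schedule: str = "constant"  # or "anneal": fade the adversarial term
    adv_anneal_start: float = 0.6  # fraction of training where the fade begins
    d_sees_volume: bool = False
    volume_cap: float = VOLUME_CAP
    min_target_volume: float = 1.5  # mm^3, ~one voxel: sub-voxel requests are
    # unresolvable and their relative-error gradients (1/V) destabilize training
    seed: int = 0

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.conditioning_mode not in CONDITIONING_MODES:
            raise ValueError(f"conditioning_mode must be one of {CONDITIONING_MODES}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if self.adv_schedule not in ("constant", "anneal"):
            raise ValueError("adv_schedule must be 'constant' or 'anneal'")


# ---------------------------------------------------------------------------
# losses (shared closed forms)
# ---------------------------------------------------------------------------

def mask_volume_batch(masks: np.ndarray, spacing=DEFAULT_SPACING) -> np.ndarray:
    """Attenuated volume sum(1 - G) * voxel_volume, per mask in a batch."""
    m = np.asarray(masks, dtype=np.float64)
    flat = m.reshape(m.shape[0], -1)
    return (1.0 - flat).sum(axis=1) * voxel_volume(spacing)


def volume_loss(masks: np.ndarray, targets_mm3: np.ndarray, spacing=DEFAULT_SPACING) -> float:
    """Mean relative volume error (1/N) sum |V_fake_i - V_in_i| / V_in_i."""
    targets = np.asarray(targets_mm3, dtype=np.float64)
    if np.any(targets <= 0):
        raise ValueError("all target volumes must be > 0")
    v_fake = mask_volume_batch(masks, spacing)
    return float(np.mean(np.abs(v_fake - targets) / targets))


def border_loss(mask: np.ndarray) -> float:
    """Mean |1 - G| over the outermost one-voxel shell (batched or single)."""
    m = np.asarray(mask, dtype=np.float64)
    single = m.ndim == 3
    if single:
        m = m[None]
    shell = border_shell(m.shape[-1])
    vals = m[:, shell]
    return float(np.abs(1.0 - vals).mean())


def adversarial_losses(d_real: np.ndarray, d_fake: np.ndarray) -> tuple[float, float]:
    """(loss_D, loss_G_adv) of the minimax game at the given D outputs.

    loss_D = -E[log D(real)] - E[log(1 - D(fake))]; the generator's
    adversarial term is E[log(1 - D(fake))], which it minimizes.
    """
    dr = np.clip(np.asarray(d_real, dtype=np.float64), _EPS, 1 - _EPS)
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1 - _EPS)
    loss_d = float(-np.mean(np.log(dr)) - np.mean(np.log(1.0 - df)))
    loss_g = float(np.mean(np.log(1.0 - df)))
    return loss_d, loss_g


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class Generator:
    """Latent + conditions -> 11^3 multiplicative mask in [0, 1].

    Wiring: z (and the normalized volume, when conditioned) are projected
    to a Ch3-channel 2^3 grid and upsampled by a transposed-convolution
    ladder 2 -> 5 -> 11: a learned 3^3 stride-2 transposed convolution to
    5^3, then a fixed triangle-kernel (trilinear) transposed convolution to
    11^3.  At full resolution the Ch1 feature maps are concatenated with
    the condition channels (background patch, broadcast volume) and fused
    voxel-wise by two 1^3 convolutions down to one sigmoid-squashed
    channel.  The sigmoid hard-guarantees the [0, 1] mask range for any
    weights.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        cfg.validate()
        self.cfg = cfg
        rng = rng or np.random.default_rng(spawn_seed(cfg.seed, "gan.generator"))
        ch1, ch2, ch3 = cfg.channels
        self.dtype = dtype
        head_in = cfg.latent_dim + (0 if cfg.conditioning_mode == "none" else 1)
        self.head = nn.Sequential(
            nn.Linear(head_in, ch3 * 8, rng=rng, dtype=dtype),
            nn.ReLU(),
        )
        self.tower = nn.Sequential(
            nn.ConvTranspose3d(ch3, ch1, 3, 2, 0, rng=rng, dtype=dtype),
            nn.BatchNorm3d(ch1, dtype=dtype),
            nn.ReLU(),
            nn.FixedUpsample3d(5, MASK_SIZE, dtype=dtype),
        )
        n_cond = {"none": 0, "volume": 1, "volume+background": 2}[cfg.conditioning_mode]
        self.concat = nn.Concat()
        out_conv = nn.Conv3d(ch3, ch2, 1, 1, 0, rng=rng, dtype=dtype)
        # start near the identity mask (sigmoid(4) ~ 0.98): a fresh generator
        # should perturb the background barely at all, and learn to darken
        out_conv.b[...] = 4.0
        self.fuse = nn.Sequential(
            nn.Conv3d(ch1 + n_cond, ch3, 1, 1, 0, rng=rng, dtype=dtype),
            nn.BatchNorm3d(ch3, dtype=dtype),
            nn.ReLU(),
            out_conv,
            nn.Sigmoid(),
        )
        self._ch3 = ch3

    def parameters(self):
        return self.head.parameters() + self.tower.parameters() + self.fuse.parameters()

    def forward(self, z: np.ndarray, vol_norm: np.ndarray | None = None,
                neg: np.ndarray | None = None, train: bool = True) -> np.ndarray:
        """Masks (N, 11, 11, 11). Conditions not used by the mode are ignored."""
        z = np.asarray(z, dtype=self.dtype)
        if z.ndim != 2 or z.shape[1] != self.cfg.latent_dim:
            raise ValueError(f"z must be (N, {self.cfg.latent_dim}), got {z.shape}")
        n = z.shape[0]
        mode = self.cfg.conditioning_mode
        if mode != "none":
            if vol_norm is None:
                raise ValueError(f"conditioning_mode={mode!r} requires vol_norm")
            v = np.asarray(vol_norm, dtype=self.dtype).reshape(n, 1)
            h = self.head.forward(np.concatenate([z, v], axis=1), train=train)
        else:
            h = self.head.forward(z, train=train)
        x = h.reshape(n, 2, 2, 2, self._ch3)
        x = self.tower.forward(x, train=train)
        feeds = [x]
        if mode == "volume+background":
            if neg is None:
                raise ValueError("conditioning_mode='volume+background' requires neg")
            neg = np.asarray(neg, dtype=self.dtype)
            if neg.shape != (n, MASK_SIZE, MASK_SIZE, MASK_SIZE):
                raise ValueError(f"neg must be (N, 11, 11, 11), got {neg.shape}")
            feeds.append(neg[..., None])
        if mode != "none":
            vol_channel = np.ascontiguousarray(np.broadcast_to(
                v[:, None, None, None, :], (n,) + (MASK_SIZE,) * 3 + (1,)
            ))
            feeds.append(vol_channel)
        x = self.concat.forward(feeds, train=train)
        x = self.fuse.forward(x, train=train)
        return x[..., 0]

    def backward(self, dmask: np.ndarray) -> None:
        """Backprop a gradient w.r.t. the output masks (N, 11, 11, 11)."""
        dy = self.fuse.backward(np.asarray(dmask, dtype=self.dtype)[..., None])
        dx = self.concat.backward(dy)[0]
        dx = self.tower.backward(dx)
        self.head.backward(dx.reshape(dx.shape[0], -1))

    def state_dict(self):
        return {"head": self.head.state_dict(), "tower": self.tower.state_dict(),
                "fuse": self.fuse.state_dict()}

    def load_state_dict(self, d):
        self.head.load_state_dict(d["head"])
        self.tower.load_state_dict(d["tower"])
        self.fuse.load_state_dict(d["fuse"])


class Discriminator:
    """11^3 patch -> probability that the patch holds a real microbleed."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(spawn_seed(cfg.seed, "gan.discriminator"))
        self.cfg = cfg
        self.dtype = dtype
        ch1, _, ch3 = cfg.channels
        self.conv = nn.Sequential(
            nn.Conv3d(1, ch1, 3, 2, 1, rng=rng, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Conv3d(ch1, ch3, 3, 2, 1, rng=rng, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Flatten(),
        )
        fc_in = ch3 * 27 + (1 if cfg.d_sees_volume else 0)
        self.fc = nn.Sequential(
            nn.Linear(fc_in, 32, rng=rng, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Linear(32, 1, rng=rng, dtype=dtype),
            nn.Sigmoid(),
        )

    def parameters(self):
        return self.conv.parameters() + self.fc.parameters()

    def forward(self, patches: np.ndarray, vol_norm: np.ndarray | None = None,
                train: bool = True) -> np.ndarray:
        p = np.asarray(patches, dtype=self.dtype)
        if p.ndim != 4 or p.shape[1:] != (MASK_SIZE,) * 3:
            raise ValueError(f"patches must be (N, 11, 11, 11), got {p.shape}")
        h = self.conv.forward(p[..., None], train=train)
        if self.cfg.d_sees_volume:
            if vol_norm is None:
                raise ValueError("d_sees_volume=True requires vol_norm")
            h = np.concatenate([h, np.asarray(vol_norm, dtype=self.dtype).reshape(-1, 1)], axis=1)
        return self.fc.forward(h, train=train)[:, 0]

    def backward(self, dscore: np.ndarray) -> np.ndarray:
        """Backprop; returns gradient w.r.t. the input patches."""
        dh = self.fc.backward(np.asarray(dscore, dtype=self.dtype)[:, None])
        if self.cfg.d_sees_volume:
            dh = dh[:, :-1]
        dx = self.conv.backward(dh)
        return dx[..., 0]

    def state_dict(self):
        return {"conv": self.conv.state_dict(), "fc": self.fc.state_dict()}

    def load_state_dict(self, d):
        self.conv.load_state_dict(d["conv"])
        self.fc.load_state_dict(d["fc"])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_lesion_gan(
    real_patches,
    neg_patches,
    dist: VolumeDistribution,
    cfg: GanConfig,
    spacing=DEFAULT_SPACING,
    real_volumes_mm3=None,
    callback=None,
) -> tuple[Generator, pd.DataFrame]:
    """Adversarial training of the lesion generator.

    `callback(epoch, gen)`, when given, runs at the end of each epoch
    (monitoring / checkpointing hook).

    `real_patches` are normalized [0, 1] 11^3 patches containing lesions;
    `neg_patches` are lesion-free patches the generator conditions on and
    multiplies into.  Per generator step, z ~ N(0, I), target volumes are
    drawn from `dist` and a random background is attached.  With
    cfg.d_sees_volume the discriminator receives the volume condition
    alongside each patch (fakes: the generator's target; reals: their
    measured volumes via `real_volumes_mm3`), so it can judge whether the
    apparent lesion size is consistent with the condition.  Returns the
    trained generator and a per-epoch log of all four loss components
    (loss_d, loss_g_adv, loss_border, loss_volume).  Fully reproducible
    from cfg.seed.
    """
    cfg.validate()
    reals = np.asarray(real_patches, dtype=np.float64)
    negs = np.asarray(neg_patches, dtype=np.float64)
    if reals.size == 0 or negs.size == 0:
        raise ValueError("real_patches and neg_patches must be nonempty")
    _check_normalized(reals, "real_patches")
    _check_normalized(negs, "neg_patches")
    if cfg.d_sees_volume:
        if real_volumes_mm3 is None:
            raise ValueError("cfg.d_sees_volume=True requires real_volumes_mm3 "
                             "(one measured lesion volume per real patch)")
        real_v_norm = (np.asarray(real_volumes_mm3, dtype=np.float64)
                       / cfg.volume_cap).astype(np.float32)
        if real_v_norm.shape[0] != reals.shape[0]:
            raise ValueError("real_volumes_mm3 must align with real_patches")
    else:
        real_v_norm = None

    gen = Generator(cfg)
    disc = Discriminator(cfg)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)

    rng_z = np.random.default_rng(spawn_seed(cfg.seed, "gan.z"))
    rng_vol = np.random.default_rng(spawn_seed(cfg.seed, "gan.volumes"))
    rng_shuf = np.random.default_rng(spawn_seed(cfg.seed, "gan.shuffle"))

    vv = voxel_volume(spacing)
    cap = cfg.volume_cap
    shell = border_shell(MASK_SIZE)
    k_shell = int(shell.sum())
    n_real = reals.shape[0]
    reals32 = reals.astype(np.float32)
    negs32 = negs.astype(np.float32)

    log_rows = []
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            lr_t = cfg.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / cfg.epochs))
            opt_g.lr = opt_d.lr = lr_t
        if cfg.adv_schedule == "anneal":
            frac = epoch / max(cfg.epochs - 1, 1)
            s0 = cfg.adv_anneal_start
            w_adv = 1.0 if frac < s0 else max(0.0, 1.0 - (frac - s0) / max(1 - s0, 1e-9))
        else:
            w_adv = 1.0
        order = rng_shuf.permutation(n_real)
        ep = {"loss_d": 0.0, "loss_g_adv": 0.0, "loss_border": 0.0, "loss_volume": 0.0}
        n_batches = 0
        for start in range(0, n_real, cfg.batch):
            idx = order[start:start + cfg.batch]
            nb = idx.size
            real_b = reals32[idx]
            neg_idx = rng_shuf.integers(0, negs32.shape[0], size=nb)
            neg_b = negs32[neg_idx]
            z = rng_z.standard_normal((nb, cfg.latent_dim)).astype(np.float32)
            targets = np.maximum(
                sample_volumes(dist, nb, seed=int(rng_vol.integers(0, 2**31 - 1))),
                cfg.min_target_volume,
            )
            v_norm = (targets / cap).astype(np.float32)

            # ---- generator forward (graph cached for the G step below)
            masks = gen.forward(z, v_norm, neg_b, train=True)
            fakes = neg_b * masks

            # ---- discriminator step on reals and detached fakes (one batch)
            v_real_b = real_v_norm[idx] if real_v_norm is not None else v_norm
            d_both = disc.forward(np.concatenate([real_b, fakes]),
                                  np.concatenate([v_real_b, v_norm]), train=True)
            d_real, d_fake = d_both[:nb], d_both[nb:]
            g_both = np.concatenate([
                -1.0 / np.clip(d_real, _EPS, 1 - _EPS) / nb,
                1.0 / np.clip(1.0 - d_fake, _EPS, 1 - _EPS) / nb,
            ])
            disc.backward(g_both)
            opt_d.step()
            loss_d, _ = adversarial_losses(d_real, d_fake)

            # ---- generator step: adversarial + border + volume
            d_fake2 = disc.forward(fakes, v_norm, train=True)
            if cfg.non_saturating:
                dscore = -1.0 / np.clip(d_fake2, _EPS, 1 - _EPS) / nb
                loss_g_adv = float(-np.mean(np.log(np.clip(d_fake2, _EPS, 1 - _EPS))))
            else:
                dscore = -1.0 / np.clip(1.0 - d_fake2, _EPS, 1 - _EPS) / nb
                loss_g_adv = float(np.mean(np.log(np.clip(1.0 - d_fake2, _EPS, 1 - _EPS))))
            dfake = disc.backward(dscore)
            dmask = w_adv * dfake * neg_b  # chain through fake = neg * mask

            # volume term, computed in normalized units (scale-invariant ratio)
            v_fake_n = (1.0 - masks.reshape(nb, -1)).sum(axis=1) * vv / cap
            lv = float(np.mean(np.abs(v_fake_n - v_norm) / v_norm))
            sign_v = np.sign(v_fake_n - v_norm) / v_norm
            dmask += cfg.volume_weight * (-(vv / cap) * sign_v / nb)[:, None, None, None]

            # border term
            shell_vals = masks[:, shell]
            lb = float(np.abs(1.0 - shell_vals).mean())
            dshell = cfg.border_weight * (np.sign(shell_vals - 1.0) / (nb * k_shell))
            dmask_b = np.zeros_like(masks)
            dmask_b[:, shell] = dshell
            dmask += dmask_b

            opt_g.zero_grad()
            gen.backward(dmask)
            opt_g.step()

            comps = {"loss_d": loss_d, "loss_g_adv": loss_g_adv,
                     "loss_border": lb, "loss_volume": lv}
            for k, val in comps.items():
                if not np.isfinite(val):
                    raise FloatingPointError(
                        f"non-finite {k} at epoch {epoch}, batch {n_batches}"
                    )
                ep[k] += val
            n_batches += 1

        log_rows.append({"epoch": epoch, **{k: v / n_batches for k, v in ep.items()}})
        if callback is not None:
            callback(epoch, gen)

    return gen, pd.DataFrame(log_rows)


def _check_normalized(arr: np.ndarray, name: str) -> None:
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError(f"{name} must be normalized to [0, 1]")


def generate_masks(
    gen: Generator,
    targets_mm3: np.ndarray,
    neg_patches: np.ndarray | None = None,
    seed: int = 0,
    batch: int = 256,
    pair_negs: bool = False,
) -> np.ndarray:
    """Sample masks for the given target volumes (inference mode).

    With ``pair_negs=True``, neg_patches[i] conditions mask i (one patch
    per target); otherwise backgrounds are drawn at random from
    neg_patches.
    """
    targets = np.asarray(targets_mm3, dtype=np.float64)
    n = targets.size
    rng = np.random.default_rng(spawn_seed(seed, "gan.sample"))
    masks = np.empty((n,) + (MASK_SIZE,) * 3, dtype=np.float64)
    mode = gen.cfg.conditioning_mode
    if pair_negs and (neg_patches is None or len(neg_patches) != n):
        raise ValueError("pair_negs=True requires exactly one neg patch per target")
    for start in range(0, n, batch):
        sl = slice(start, min(start + batch, n))
        nb = sl.stop - sl.start
        z = rng.standard_normal((nb, gen.cfg.latent_dim))
        neg = None
        if mode == "volume+background":
            if neg_patches is None:
                raise ValueError("generator is background-conditioned: neg_patches required")
            if pair_negs:
                neg = np.asarray(neg_patches)[sl]
            else:
                neg = np.asarray(neg_patches)[rng.integers(0, len(neg_patches), size=nb)]
        v = targets[sl] / gen.cfg.volume_cap if mode != "none" else None
        masks[sl] = gen.forward(z, v, neg, train=False)
    return masks


def volume_fidelity_regression(
    gen: Generator,
    dist: VolumeDistribution,
    n: int = 1000,
    spacing=DEFAULT_SPACING,
    neg_patches: np.ndarray | None = None,
    seed: int = 0,
):
    """OLS of realized mask volume on the requested target volume.

    Draws n (z, volume) pairs with volumes from `dist`, generates masks,
    measures each realized attenuated volume, and fits
    realized = slope * target + intercept.  Returns (slope, intercept,
    r_squared); this is the generator's volume-conditioning fidelity check.
    """
    if n < 3:
        raise ValueError("n must be >= 3 for a regression")
    targets = np.maximum(sample_volumes(dist, n, seed=spawn_seed(seed, "fidelity.volumes")),
                         gen.cfg.min_target_volume)
    masks = generate_masks(gen, targets, neg_patches, seed=spawn_seed(seed, "fidelity.z"))
    realized = mask_volume_batch(masks, spacing)
    fit = stats.linregress(targets, realized)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
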