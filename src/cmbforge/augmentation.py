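"""Training-set construction: mask insertion, classical augmentation, SMOTE.

Five augmentation strategies are supported for building balanced
positive/negative patch sets:

* M1 — analytical: randomized Gaussian partial-volume masks multiplied
  into sampled negative patches;
* M2 — unconditional GAN masks (no conditioning);
* M3 — volume-conditioned GAN (CGAN) masks;
* M4 — the full lesion GAN (volume + background conditioning);
* M5 — SMOTE: convex combinations of real positive patches.

All synthetic positives are products neg_patch * mask, so intensities
outside the mask's sub-unity support are bit-identical to the background —
the blending guarantee that keeps the classifier from keying on insertion
artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._rng import spawn_seed
from .types import (
    DEFAULT_SPACING,
    MASK_SIZE,
    LabeledPatch,
    LocationSample,
    SWIVolume,
    VolumeDistribution,
    check_lesion_mask,
    mask_volume,
)

__all__ = [
    "apply_mask",
    "implant_lesions",
    "classic_augment",
    "smote_augment",
    "build_training_set",
    "STRATEGIES",
]

STRATEGIES = ("M1", "M2", "M3", "M4", "M5")

_STRATEGY_PROVENANCE = {
    "M1": "analytical",
    "M2": "gan",
    "M3": "cgan",
    "M4": "lesiongan",
    "M5": "smote",
}


def apply_mask(neg_patch: np.ndarray, mask: np.ndarray,
               provenance: str = "lesiongan", subject_id: str | None = None) -> LabeledPatch:
    """Implant a lesion into a normalized background patch: out = neg * mask."""
    neg_patch = np.asarray(neg_patch, dtype=np.float64)
    mask = check_lesion_mask(mask)
    if neg_patch.shape != mask.shape:
        raise ValueError(f"shape mismatch: {neg_patch.shape} vs {mask.shape}")
    if neg_patch.min() < 0 or neg_patch.max() > 1:
        raise ValueError("neg_patch must be normalized to [0, 1]")
    return LabeledPatch(neg_patch * mask, 1, provenance, subject_id)


def implant_lesions(
    vol: SWIVolume,
    locations: list[LocationSample],
    masks: list[np.ndarray],
    spacing=None,
) -> tuple[SWIVolume, pd.DataFrame]:
    """Multiply lesion masks into a whole scan at the given locations.

    Each 11^3 neighborhood is normalized by the volume's global intensity
    maximum, multiplied by the mask, and rescaled — exactly the patch-level
    mask semantics, so patch and whole-volume insertion agree.  Returns the
    lesioned copy plus a ground-truth table (scan_id, x, y, z, volume_mm3).
    Locations whose 11^3 extents overlap are rejected.
    """
    if len(locations) != len(masks):
        raise ValueError("one mask per location required")
    spacing = spacing or vol.spacing
    centers = np.array([loc.center for loc in locations], dtype=int).reshape(-1, 3)
    bad = [
        (i, j)
        for i in range(len(centers))
        for j in range(i + 1, len(centers))
        if np.max(np.abs(centers[i] - centers[j])) < MASK_SIZE
    ]
    if bad:
        raise ValueError(f"overlapping implants at location pairs {bad}")

    out = SWIVolume(vol.intensities.copy(), vol.spacing, vol.brain_mask.copy(),
                    scan_id=vol.scan_id)
    half = MASK_SIZE // 2
    rows = []
    for loc, mask in zip(locations, masks):
        mask = check_lesion_mask(mask)
        c = loc.center
        sl = tuple(slice(ci - half, ci + half + 1) for ci in c)
        region = out.intensities[sl]
        if region.shape != mask.shape:
            raise IndexError(f"implant at {c} exceeds volume bounds")
        out.intensities[sl] = region * mask  # global-max normalization cancels
        rows.append({
            "scan_id": vol.scan_id, "x": c[0], "y": c[1], "z": c[2],
            "volume_mm3": mask_volume(mask, spacing),
        })
    truth = pd.DataFrame(rows, columns=["scan_id", "x", "y", "z", "volume_mm3"])
    return out, truth


def _rot90_axial(patch: np.ndarray, n: int) -> np.ndarray:
    # axial = in-plane (first two axes); the through-plane axis is spacing-
    # anisotropic so only in-plane rotation preserves voxel geometry
    return np.rot90(patch, k=n, axes=(0, 1))


def classic_augment(patches: list[LabeledPatch]) -> list[LabeledPatch]:
    """Rotation (90/180/270 in-plane) and single-axis flips: 7 new per input."""
    out = []
    for lp in patches:
        p = lp.patch
        variants = [_rot90_axial(p, n) for n in (1, 2, 3)]
        variants += [np.flip(p, axis=ax) for ax in range(3)]
        # a 7th distinct variant: in-plane 90-degree rotation of the z-flip
        variants.append(_rot90_axial(np.flip(p, axis=2), 1))
        out.extend(
            LabeledPatch(v.copy(), lp.label, "classic_aug", lp.subject_id)
            for v in variants
        )
    return out


def smote_augment(minority: list[LabeledPatch], n_new: int, k: int = 5,
                  seed: int = 0) -> list[LabeledPatch]:
    """SMOTE oversampling: each new patch is x + u * (x_nn - x), u ~ U(0,1).

    x is a random minority patch, x_nn one of its k nearest neighbours in
    flattened-intensity space (Euclidean).  Outputs are convex combinations
    of real patches, deterministic per seed.
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if len(minority) <= k:
        raise ValueError(f"SMOTE needs more than k={k} minority samples, got {len(minority)}")
    if n_new == 0:
        return []
    shape = minority[0].patch.shape
    x = np.stack([lp.patch.ravel() for lp in minority])
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)  # first column is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(minority), size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.uniform(size=n_new)
    out = []
    for b, p, ui in zip(base, pick, u):
        xnn = x[idx[b, p]]
        new = x[b] + ui * (xnn - x[b])
        out.append(LabeledPatch(new.reshape(shape), minority[b].label, "smote",
                                minority[b].subject_id))
    return out


def build_training_set(
    strategy: str,
    sources: dict,
    target_pos: int = 10000,
    target_neg: int = 10000,
    seed: int = 0,
) -> list[LabeledPatch]:
    """Assemble a balanced labeled patch set under one augmentation strategy.

    `sources` supplies what the strategy needs:

    * ``neg_patches`` (always): normalized [0, 1] background patches;
    * ``dist`` (M1-M4): the VolumeDistribution for target volumes;
    * ``spacing`` (M1-M4, optional): voxel spacing;
    * ``generator`` (M2-M4): a trained Generator whose conditioning mode
      matches the strategy;
    * ``real_positives`` (M5): list of LabeledPatch to oversample.

    Negatives are sampled fresh from neg_patches for every strategy.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    negs = np.asarray(sources["neg_patches"], dtype=np.float64)
    if negs.ndim != 4:
        raise ValueError("neg_patches must be a (N, 11, 11, 11) array")
    rng = np.random.default_rng(spawn_seed(seed, f"buildset.{strategy}"))
    provenance = _STRATEGY_PROVENANCE[strategy]

    positives: list[LabeledPatch]
    if strategy == "M5":
        reals = sources.get("real_positives")
        if not reals:
            raise ValueError("M5 (SMOTE) requires sources['real_positives']")
        positives = smote_augment(reals, target_pos, k=min(5, len(reals) - 1),
                                  seed=spawn_seed(seed, "buildset.smote"))
    else:
        dist: VolumeDistribution = sources["dist"]
        spacing = sources.get("spacing", DEFAULT_SPACING)
        from .volume_model import sample_volumes

        volumes = np.maximum(
            sample_volumes(dist, target_pos, seed=spawn_seed(seed, "buildset.volumes")),
            1e-3,
        )
        pick = rng.integers(0, len(negs), size=target_pos)
        if strategy == "M1":
            from .analytical import AnalyticalLesionConfig, make_analytical_mask

            masks = [
                make_analytical_mask(
                    AnalyticalLesionConfig(target_volume=float(v),
                                           seed=spawn_seed(seed, f"buildset.m1.{i}")),
                    spacing,
                )
                for i, v in enumerate(volumes)
            ]
        else:
            from .lesion_gan import generate_masks

            gen = sources.get("generator")
            if gen is None:
                raise ValueError(f"{strategy} requires sources['generator']")
            expected_mode = {"M2": "none", "M3": "volume", "M4": "volume+background"}[strategy]
            if gen.cfg.conditioning_mode != expected_mode:
                raise ValueError(
                    f"{strategy} needs a generator with conditioning_mode="
                    f"{expected_mode!r}, got {gen.cfg.conditioning_mode!r}"
                )
            masks = generate_masks(gen, volumes, neg_patches=negs[pick],
                                   seed=spawn_seed(seed, "buildset.gan"),
                                   pair_negs=True)
        positives = [
            apply_mask(negs[p], m, provenance=provenance)
            for p, m in zip(pick, masks)
        ]

    neg_pick = rng.integers(0, len(negs), size=target_neg)
    negatives = [LabeledPatch(negs[i].copy(), 0, "real") for i in neg_pick]
    return positives + negatives
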