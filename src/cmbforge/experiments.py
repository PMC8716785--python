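"""Reproducible desk-scale studies used by the acceptance checks.

Real SWI cohorts are not shippable, so the package's quantitative claims
are established on the self-contained experiments below.  They run at a
scale a single CPU can handle in minutes, with every random choice derived
from one seed:

* `fidelity_study` — train the lesion GAN on analytical lesions implanted
  into phantom backgrounds and regress realized generated-mask volume on
  the requested target volume (the volume-conditioning fidelity check).
* `detection_study` — train the patch classifier purely on synthetic
  (strategy M4) positives, detect implanted lesions on held-out phantom
  scans with vessel mimics, and compare against a no-augmentation baseline
  trained on a handful of "real" positives.

The study conditions (patch counts, epochs, cohort volume distribution)
are fixed here and documented in the methods note; they are the package's
standing experimental setup, not tunables.
"""

from __future__ import annotations

import numpy as np

from ._rng import spawn_seed
from .analytical import batch_analytical_masks
from .augmentation import build_training_set
from .classifier import ClassifierConfig, train_classifier
from .evaluation import match_candidates_to_truth, roc_auc
from .lesion_gan import GanConfig, train_lesion_gan, volume_fidelity_regression
from .phantom import PhantomConfig, extract_patch, generate_phantom, sample_negative_locations
from .pipeline import RunConfig, make_lesioned_scans
from .screening import RstConfig, extract_candidates, radial_symmetry_3d
from .types import DEFAULT_SPACING, LabeledPatch, LocationSample, VolumeDistribution
from .volume_model import smooth_volume_distribution

__all__ = ["study_volume_distribution", "fidelity_study", "detection_study"]


def study_volume_distribution(seed: int) -> VolumeDistribution:
    """The smoothed lesion-volume distribution of the phantom cohort.

    Cohort volumes are drawn Gamma(shape 2, scale 6) mm^3 — mode 6 mm^3,
    between the principal modes reported for clinical SWI cohorts — capped
    at 80 mm^3, then kernel-smoothed with the 0.5% probability floor.
    """
    rng = np.random.default_rng(spawn_seed(seed, "study.cohort"))
    volumes = np.clip(rng.gamma(2.0, 6.0, size=300), 0.1, 79.0)
    return smooth_volume_distribution(volumes)


def _phantom_negatives(seed: int, n: int, n_scans: int = 8,
                       shape=(64, 64, 40), hard_fraction: float = 0.5) -> np.ndarray:
    """Negative patches pooled over phantom scans.

    A `hard_fraction` of the patches is taken at radial-symmetry candidate
    locations of the (lesion-free) scans rather than uniformly at random:
    real SWI backgrounds are full of vessels and other screening hits, and
    a classifier must see such mimics among its negatives to be usable
    behind the screening stage.
    """
    per_scan = int(np.ceil(n / n_scans))
    n_hard = int(round(per_scan * hard_fraction))
    rst = RstConfig(threshold_sd=1.0)
    out = []
    for s in range(n_scans):
        vol = generate_phantom(PhantomConfig(shape=shape, seed=spawn_seed(seed, f"study.scan.{s}")))
        locs = sample_negative_locations(vol, per_scan - n_hard,
                                         seed=spawn_seed(seed, f"study.negs.{s}"))
        patches = [np.clip(extract_patch(vol, loc, 11) / 255.0, 0, 1) for loc in locs]
        if n_hard:
            smap = radial_symmetry_3d(vol, rst)
            cands = extract_candidates(smap, vol.brain_mask, rst)
            half = 11 // 2
            ok = [c for c in cands
                  if all(half <= ci < sh - half for ci, sh in zip(c.center, vol.shape))]
            rng = np.random.default_rng(spawn_seed(seed, f"study.hard.{s}"))
            if ok:
                pick = rng.choice(len(ok), size=n_hard, replace=len(ok) < n_hard)
                patches += [np.clip(extract_patch(vol, ok[i].center, 11) / 255.0, 0, 1)
                            for i in pick]
            else:  # no candidates on this scan: fall back to uniform locations
                locs2 = sample_negative_locations(
                    vol, n_hard, seed=spawn_seed(seed, f"study.hardfallback.{s}"))
                patches += [np.clip(extract_patch(vol, loc, 11) / 255.0, 0, 1)
                            for loc in locs2]
        out.extend(patches)
    return np.array(out[:n])


def fidelity_study(
    seed: int,
    epochs: int = 400,
    n_patches: int = 2000,
    n_regression: int = 1000,
    conditioning_mode: str = "volume+background",
    spacing=DEFAULT_SPACING,
):
    """Train the lesion GAN at desk scale and measure volume fidelity.

    "Real" lesion patches are analytical-model lesions implanted into
    phantom backgrounds; the GAN trains on them with the full Adam recipe
    (lr 2e-4, beta1 0.5, beta2 0.999, batch 64).  Returns a dict with the
    regression (slope, intercept, r_squared over `n_regression` generated
    masks), the trained generator, training log and study inputs.

    Training uses the non-saturating generator objective: at desk scale
    the discriminator wins early, and the literal minimax term then
    passes gradients through the discriminator's saturated sigmoid,
    leaving the generator with no adversarial pressure (it converges to
    diffuse, barely-attenuating masks that satisfy the volume loss but
    look nothing like lesions).
    """
    dist = study_volume_distribution(seed)
    negs = _phantom_negatives(seed, n_patches)
    masks = batch_analytical_masks(dist, n_patches, spacing,
                                   seed=spawn_seed(seed, "study.realmasks"))
    pair = np.random.default_rng(spawn_seed(seed, "study.pairing")).permutation(n_patches)
    reals = negs[pair] * np.array(masks)

    cfg = GanConfig(epochs=epochs, conditioning_mode=conditioning_mode,
                    non_saturating=True, seed=seed)
    gen, log = train_lesion_gan(reals, negs, dist, cfg, spacing)
    slope, intercept, r2 = volume_fidelity_regression(
        gen, dist, n=n_regression, spacing=spacing, neg_patches=negs,
        seed=spawn_seed(seed, "study.fidelity"),
    )
    return {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "generator": gen,
        "log": log,
        "negs": negs,
        "dist": dist,
    }


def detection_study(
    seed: int,
    generator=None,
    negs: np.ndarray | None = None,
    dist: VolumeDistribution | None = None,
    target_pos: int = 600,
    target_neg: int = 600,
    n_test_scans: int = 3,
    lesions_per_scan: int = 6,
    clf_epochs: int = 60,
    clf_lr: float = 3e-4,
    ensemble_size: int = 2,
    n_baseline_reals: int = 50,
    gan_epochs: int = 150,
):
    """Whole-scan detection with synthetic-only training (strategy M4).

    Trains (a) a classifier on `target_pos` GAN positives and (b) a
    baseline on `n_baseline_reals` "real" positives with no augmentation,
    then screens held-out lesioned phantom scans (with vessel mimics) and
    scores the candidates.  Returns both AUCs plus the screening
    sensitivity.  A pre-trained generator (with its negs/dist) may be
    passed in to reuse a fidelity-study run.
    """
    if dist is None:
        dist = study_volume_distribution(seed)
    if negs is None:
        negs = _phantom_negatives(seed, max(target_neg, 800))
    if generator is None:
        out = fidelity_study(seed, epochs=gan_epochs, n_patches=len(negs))
        generator, negs, dist = out["generator"], out["negs"], out["dist"]

    sources = {"neg_patches": negs, "dist": dist, "generator": generator}
    train_set = build_training_set("M4", sources, target_pos, target_neg,
                                   seed=spawn_seed(seed, "study.m4set"))
    ccfg = ClassifierConfig(epochs=clf_epochs, lr=clf_lr,
                            ensemble_size=ensemble_size, seed=seed)
    model = train_classifier(train_set, ccfg)

    # no-augmentation baseline: a few dozen real positives, balanced negatives
    rng = np.random.default_rng(spawn_seed(seed, "study.baseline"))
    base_masks = batch_analytical_masks(dist, n_baseline_reals,
                                        seed=spawn_seed(seed, "study.basemasks"))
    base_idx = rng.integers(0, len(negs), n_baseline_reals)
    base_set = [
        LabeledPatch(negs[i] * m, 1, "real") for i, m in zip(base_idx, base_masks)
    ] + [
        LabeledPatch(negs[i].copy(), 0, "real")
        for i in rng.integers(0, len(negs), n_baseline_reals)
    ]
    base_model = train_classifier(base_set, ccfg)

    run_cfg = RunConfig(seed=seed, lesions_per_test_scan=lesions_per_scan)
    scans, truths = make_lesioned_scans(run_cfg, dist, 9000 + seed, n_test_scans)
    rst = RstConfig()
    records, base_records, sens = [], [], []
    for vol, truth in zip(scans, truths):
        smap = radial_symmetry_3d(vol, rst)
        cands = extract_candidates(smap, vol.brain_mask, rst, scan_id=vol.scan_id)
        truth_locs = [LocationSample((int(r.x), int(r.y), int(r.z)))
                      for r in truth.itertuples()]
        patches = np.stack([
            np.clip(extract_patch(vol, c.center, 11) / 255.0, 0, 1) for c in cands
        ]) if cands else np.zeros((0, 11, 11, 11))
        for mdl, sink in ((model, records), (base_model, base_records)):
            scores = mdl.predict(patches) if len(cands) else np.zeros(0)
            sink.extend(match_candidates_to_truth(
                cands, scores, truth_locs, vol.spacing, 3.0, vol.scan_id))
        from .screening import screening_sensitivity

        sens.append(screening_sensitivity(cands, truth_locs, vol.spacing, 3.0))

    def _auc(recs):
        return roc_auc([r.score for r in recs], [r.is_lesion for r in recs])

    return {
        "auc_m4": _auc(records),
        "auc_baseline": _auc(base_records),
        "screening_sensitivity": float(np.mean(sens)),
        "n_candidates": len(records),
        "records": records,
    }
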