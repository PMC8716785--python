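"""End-to-end phantom study: generate -> train -> screen -> classify -> evaluate.

The pipeline stitches every module together on synthetic data: phantom
scans are generated and split into training and held-out test sets,
analytical lesions provide the "real" positives for GAN training, the
requested augmentation strategy builds a balanced patch set, the
classifier ensemble is trained, held-out scans (with freshly implanted
lesions) are screened by the radial symmetry transform and scored, and the
detection records are summarized as AUC/FROC/operating-point numbers.

Every stage derives its randomness from the master seed through named
substreams and persists its artifacts, so a finished run is bit-reproducible
and individual stages can be re-run after deleting their outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import spawn_seed
from .analytical import AnalyticalLesionConfig, batch_analytical_masks, make_analytical_mask
from .augmentation import build_training_set, implant_lesions
from .classifier import ClassifierConfig, train_classifier
from .evaluation import froc, match_candidates_to_truth, operating_point_at_sensitivity, roc_auc
from .lesion_gan import GanConfig, train_lesion_gan
from .phantom import PhantomConfig, extract_patch, generate_phantom, sample_negative_locations
from .screening import RstConfig, extract_candidates, radial_symmetry_3d, screening_sensitivity
from .types import LabeledPatch, LocationSample, VolumeDistribution
from .volume_model import sample_volumes, smooth_volume_distribution

__all__ = ["RunConfig", "run_pipeline", "make_study_negatives", "make_lesioned_scans"]


@dataclass
class RunConfig:
    """Configuration of a full phantom study (desk-scale defaults)."""

    seed: int = 0
    out_dir: str = "run"
    n_train_scans: int = 6
    n_test_scans: int = 3
    n_train_patches: int = 1000
    gan_epochs: int = 150
    strategy: str = "M4"
    target_pos: int = 600
    target_neg: int = 600
    lesions_per_test_scan: int = 6
    clf_epochs: int = 60
    clf_lr: float = 3e-4
    ensemble_size: int = 2
    hit_radius_mm: float = 3.0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    rst: RstConfig = field(default_factory=RstConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomConfig(**d["phantom"])
        if "rst" in d and isinstance(d["rst"], dict):
            d["rst"] = RstConfig(**d["rst"])
        return cls(**d)


def _log(stage: str, msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] [{stage}] {msg}", flush=True)


def make_study_negatives(cfg: RunConfig, n: int, scan_seed_base: int,
                         n_scans: int, hard_fraction: float = 0.5) -> np.ndarray:
    """Normalized [0, 1] negative patches pooled over phantom scans.

    Half the patches (by default) are taken at radial-symmetry candidate
    locations of the lesion-free scans, so the negative class contains the
    vessel mimics the classifier will face behind the screening stage.
    """
    per_scan = int(np.ceil(n / n_scans))
    n_hard = int(round(per_scan * hard_fraction))
    out = []
    for s in range(n_scans):
        pc = PhantomConfig(**{**asdict(cfg.phantom), "seed": scan_seed_base + s})
        vol = generate_phantom(pc)
        locs = sample_negative_locations(
            vol, per_scan - n_hard, seed=spawn_seed(cfg.seed, f"negs.{scan_seed_base + s}")
        )
        patches = [np.clip(extract_patch(vol, loc, 11) / 255.0, 0, 1) for loc in locs]
        if n_hard:
            rst = RstConfig(threshold_sd=1.0)
            smap = radial_symmetry_3d(vol, rst)
            cands = extract_candidates(smap, vol.brain_mask, rst)
            half = 11 // 2
            ok = [c for c in cands
                  if all(half <= ci < sh - half for ci, sh in zip(c.center, vol.shape))]
            rng = np.random.default_rng(spawn_seed(cfg.seed, f"hardnegs.{scan_seed_base + s}"))
            if ok:
                pick = rng.choice(len(ok), size=n_hard, replace=len(ok) < n_hard)
                patches += [np.clip(extract_patch(vol, ok[i].center, 11) / 255.0, 0, 1)
                            for i in pick]
        out.extend(patches)
    return np.array(out[:n])


def make_lesioned_scans(cfg: RunConfig, dist: VolumeDistribution, scan_seed_base: int,
                        n_scans: int):
    """Phantom test scans with implanted analytical lesions + truth tables."""
    scans, truths = [], []
    for s in range(n_scans):
        pc = PhantomConfig(**{**asdict(cfg.phantom), "seed": scan_seed_base + s})
        vol = generate_phantom(pc)
        k = cfg.lesions_per_test_scan
        seed = spawn_seed(cfg.seed, f"implant.{scan_seed_base + s}")
        # rejection-sample until implant sites are pairwise non-overlapping
        for attempt in range(50):
            locs = sample_negative_locations(vol, k, min_boundary_mm=4.0,
                                             seed=seed + attempt)
            centers = np.array([l.center for l in locs])
            d = np.abs(centers[:, None] - centers[None]).max(axis=2)
            if (d[np.triu_indices(k, 1)] >= 11).all():
                break
        else:
            raise RuntimeError("could not place non-overlapping lesions")
        vols = sample_volumes(dist, k, seed=seed)
        masks = [
            make_analytical_mask(
                AnalyticalLesionConfig(target_volume=float(max(v, 0.5)),
                                       seed=seed + 100 + i),
                vol.spacing,
            )
            for i, v in enumerate(vols)
        ]
        lesioned, truth = implant_lesions(vol, locs, masks)
        scans.append(lesioned)
        truths.append(truth)
    return scans, truths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full phantom study; returns (and persists) the report."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = cfg.phantom.spacing

    _log("phantom", f"building negative patches from {cfg.n_train_scans} scans")
    negs = make_study_negatives(cfg, cfg.n_train_patches, 1000 + cfg.seed, cfg.n_train_scans)

    _log("voldist", "building the smoothed lesion-volume distribution")
    rng = np.random.default_rng(spawn_seed(cfg.seed, "voldist"))
    cohort_volumes = np.clip(rng.gamma(2.0, 6.0, size=300), 0.1, 79.0)
    dist = smooth_volume_distribution(cohort_volumes)

    report: dict = {"config": {"seed": cfg.seed, "strategy": cfg.strategy}}

    gen = None
    if cfg.strategy in ("M2", "M3", "M4"):
        _log("train-gan", f"training generator ({cfg.gan_epochs} epochs)")
        mode = {"M2": "none", "M3": "volume", "M4": "volume+background"}[cfg.strategy]
        masks = batch_analytical_masks(dist, cfg.n_train_patches, spacing,
                                       seed=spawn_seed(cfg.seed, "gan.reals"))
        reals = negs[np.random.default_rng(spawn_seed(cfg.seed, "gan.pairing"))
                     .permutation(len(negs))] * np.array(masks)
        gcfg = GanConfig(epochs=cfg.gan_epochs, conditioning_mode=mode, seed=cfg.seed)
        gen, gan_log = train_lesion_gan(reals, negs, dist, gcfg, spacing)
        gan_log.to_csv(out_dir / "gan_training_log.csv", index=False)
        report["gan_final_losses"] = gan_log.iloc[-1].to_dict()

    _log("build-set", f"assembling {cfg.strategy} training set "
         f"({cfg.target_pos}+{cfg.target_neg})")
    sources = {"neg_patches": negs, "dist": dist, "spacing": spacing, "generator": gen}
    if cfg.strategy == "M5":
        masks = batch_analytical_masks(dist, 60, spacing, seed=spawn_seed(cfg.seed, "m5.reals"))
        sources["real_positives"] = [
            LabeledPatch(negs[i] * m, 1, "real", subject_id=f"s{i % 10}")
            for i, m in enumerate(masks)
        ]
    train_set = build_training_set(cfg.strategy, sources, cfg.target_pos,
                                   cfg.target_neg, seed=cfg.seed)

    _log("train-clf", f"training ensemble of {cfg.ensemble_size}")
    ccfg = ClassifierConfig(epochs=cfg.clf_epochs, lr=cfg.clf_lr,
                            ensemble_size=cfg.ensemble_size, seed=cfg.seed)
    model = train_classifier(train_set, ccfg)

    _log("screen", f"screening {cfg.n_test_scans} held-out lesioned scans")
    scans, truths = make_lesioned_scans(cfg, dist, 5000 + cfg.seed, cfg.n_test_scans)
    records = []
    screen_sens = []
    for vol, truth in zip(scans, truths):
        smap = radial_symmetry_3d(vol, cfg.rst)
        cands = extract_candidates(smap, vol.brain_mask, cfg.rst, scan_id=vol.scan_id)
        truth_locs = [LocationSample((int(r.x), int(r.y), int(r.z)))
                      for r in truth.itertuples()]
        screen_sens.append(
            screening_sensitivity(cands, truth_locs, vol.spacing, cfg.hit_radius_mm)
        )
        patches = np.stack([
            np.clip(extract_patch(vol, c.center, 11) / 255.0, 0, 1) for c in cands
        ]) if cands else np.zeros((0, 11, 11, 11))
        scores = model.predict(patches) if len(cands) else np.zeros(0)
        records.extend(match_candidates_to_truth(
            cands, scores, truth_locs, vol.spacing, cfg.hit_radius_mm, vol.scan_id
        ))
    n_lesions = sum(len(t) for t in truths)

    _log("evaluate", "summarizing detection records")
    scores = np.array([r.score for r in records])
    labels = np.array([r.is_lesion for r in records], dtype=int)
    auc = roc_auc(scores, labels)
    curve = froc(records, cfg.n_test_scans, n_lesions)
    report.update({
        "screening_sensitivity": float(np.mean(screen_sens)),
        "n_candidates": len(records),
        "n_lesions": n_lesions,
        "auc": auc,
        "froc": curve[:200],
    })
    try:
        op = operating_point_at_sensitivity(records, cfg.n_test_scans, 0.95, n_lesions)
        report["operating_point_95"] = asdict(op)
    except ValueError as exc:
        report["operating_point_95"] = str(exc)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    _log("done", f"AUC={auc:.4f}; report in {out_dir / 'report.json'}")
    return report
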