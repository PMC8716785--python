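"""Analytical synthetic-microbleed baseline.

A microbleed on SWI is, to first order, a dark Gaussian-shaped blob.  The
analytical model renders a randomly rotated, anisotropic 3D Gaussian
attenuation profile on a supersampled grid, scales its spatial extent so the
attenuated volume hits a requested target, and block-averages down to
acquisition resolution so that sub-voxel lesion boundaries produce the
partial-volume intensity gradients seen in real scans.  The result is an
11x11x11 multiplicative mask in [0, 1] with a unit border — the same output
currency as the lesion GAN, so either generator can feed the downstream
augmentation, screening and classification stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import special_ortho_group

from ._rng import spawn_seed
from .types import (
    DEFAULT_SPACING,
    MASK_SIZE,
    VolumeDistribution,
    border_shell,
    mask_volume,
    voxel_volume,
)

__all__ = ["AnalyticalLesionConfig", "make_analytical_mask", "batch_analytical_masks"]


@dataclass
class AnalyticalLesionConfig:
    """Parameters of one analytical lesion draw.

    target_volume
        Attenuated volume sum(1 - mask) * voxel_volume to realize, in mm^3.
    supersample_factor
        Rendering grid refinement per axis (>= 2); higher is a better
        partial-volume approximation.
    sigma_ratio_range
        Per-axis spread multipliers are drawn uniformly from this interval,
        making the blob anisotropic before a uniform random 3D rotation.
    min_intensity
        Darkest value the mask core may take, in [0, 1).  0 allows a fully
        attenuating core.
    """

    target_volume: float
    supersample_factor: int = 4
    sigma_ratio_range: tuple[float, float] = (1.0, 2.0)
    min_intensity: float = 0.0
    intensity_jitter: float = 0.0  # optional uniform jitter on core darkness
    seed: int = 0

    def validate(self) -> None:
        if self.target_volume <= 0:
            raise ValueError("target_volume must be > 0")
        if self.supersample_factor < 2:
            raise ValueError("supersample_factor must be >= 2")
        if not 0.0 <= self.min_intensity < 1.0:
            raise ValueError("min_intensity must be in [0, 1)")


_GRID_CACHE: dict = {}


def _supersampled_grid(spacing, f: int) -> np.ndarray:
    key = (tuple(np.round(spacing, 6)), f)
    if key not in _GRID_CACHE:
        n = MASK_SIZE * f
        spacing = np.asarray(spacing, dtype=float)
        coords = [
            (np.arange(n) + 0.5) / f * spacing[ax] - MASK_SIZE * spacing[ax] / 2.0
            for ax in range(3)
        ]
        _GRID_CACHE[key] = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
    return _GRID_CACHE[key]


def _quadratic_form(cfg: AnalyticalLesionConfig, spacing, rot: np.ndarray,
                    ratios: np.ndarray) -> np.ndarray:
    """q(x) at unit scale on the supersampled grid; a = A exp(-q / (2 s^2))."""
    grid = _supersampled_grid(spacing, cfg.supersample_factor)
    local = grid @ rot  # rotate coordinates into the blob frame
    return np.sum((local / ratios) ** 2, axis=-1)


def _attenuation_from_q(q: np.ndarray, scale: float, amplitude: float, f: int) -> np.ndarray:
    """Block-averaged 11^3 attenuation a(x) in [0, 1]; mask = 1 - a."""
    a = amplitude * np.exp(q * (-0.5 / scale**2))
    return a.reshape(MASK_SIZE, f, MASK_SIZE, f, MASK_SIZE, f).mean(axis=(1, 3, 5))


def make_analytical_mask(cfg: AnalyticalLesionConfig, spacing=DEFAULT_SPACING) -> np.ndarray:
    """Render one analytical lesion mask calibrated to cfg.target_volume.

    The spatial scale of the Gaussian is found by 1D root-finding so that
    the realized attenuated volume of the final mask (unit border enforced)
    matches the target to 1% relative tolerance.  Targets below the smallest
    extent-reachable volume are met exactly by scaling the attenuation
    amplitude instead (volume is linear in amplitude), so the
    target -> 0 limit yields an all-ones mask.
    """
    cfg.validate()
    rng = np.random.default_rng(spawn_seed(cfg.seed, "analytical"))
    rot = special_ortho_group.rvs(3, random_state=rng)
    ratios = rng.uniform(*cfg.sigma_ratio_range, size=3)
    ratios /= ratios.prod() ** (1.0 / 3.0)  # unit geometric mean: scale sets size
    amplitude = 1.0 - cfg.min_intensity
    if cfg.intensity_jitter > 0:
        amplitude *= 1.0 - rng.uniform(0.0, cfg.intensity_jitter)

    shell = border_shell(MASK_SIZE)
    vv = voxel_volume(spacing)
    f = cfg.supersample_factor
    q = _quadratic_form(cfg, spacing, rot, ratios)

    def realized(scale: float) -> float:
        a = _attenuation_from_q(q, scale, amplitude, f)
        a[shell] = 0.0
        return float(a.sum() * vv)

    # feasibility: a fully attenuated 9^3 interior bounds what the patch can hold
    interior = (MASK_SIZE - 2) ** 3
    v_max = amplitude * interior * vv
    if cfg.target_volume > 0.9 * v_max:
        raise ValueError(
            f"target_volume {cfg.target_volume:.1f} mm^3 cannot fit an "
            f"{MASK_SIZE}^3 patch with unit border at spacing {tuple(spacing)} "
            f"(feasible maximum ~{0.9 * v_max:.1f} mm^3)"
        )

    lo = 1e-3
    # closed-form seed: integral of the Gaussian is (2 pi)^(3/2) A s^3
    s0 = (cfg.target_volume / (amplitude * (2 * np.pi) ** 1.5)) ** (1.0 / 3.0)
    hi = max(float(np.max(np.asarray(spacing)) * MASK_SIZE), 2 * s0)
    v_lo = realized(lo)
    if cfg.target_volume <= v_lo:
        # sub-resolution lesion: linear amplitude scaling hits the target exactly
        scale, amp = lo, amplitude * cfg.target_volume / v_lo if v_lo > 0 else 0.0
    else:
        while realized(hi) < cfg.target_volume:
            hi *= 1.5
            if hi > 1e3:  # pragma: no cover - guarded by feasibility check
                raise ValueError("volume calibration failed to bracket the target")
        scale = optimize.brentq(
            lambda s: realized(s) - cfg.target_volume, lo, hi, rtol=1e-4
        )
        amp = amplitude

    a = _attenuation_from_q(q, scale, amp, f)
    mask = np.clip(1.0 - a, 0.0, 1.0)
    mask[shell] = 1.0
    return mask


def batch_analytical_masks(
    dist: VolumeDistribution,
    n: int,
    spacing=DEFAULT_SPACING,
    seed: int = 0,
    **cfg_kwargs,
) -> list[np.ndarray]:
    """n analytical masks with target volumes drawn i.i.d. from `dist`."""
    from .volume_model import sample_volumes

    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    volumes = sample_volumes(dist, n, seed=spawn_seed(seed, "analytical.volumes"))
    masks = []
    for i, v in enumerate(volumes):
        cfg = AnalyticalLesionConfig(
            target_volume=float(max(v, 1e-6)),
            seed=spawn_seed(seed, f"analytical.mask.{i}"),
            **cfg_kwargs,
        )
        masks.append(make_analytical_mask(cfg, spacing))
    return masks


def realized_volume(mask: np.ndarray, spacing=DEFAULT_SPACING) -> float:
    """Convenience alias for the shared attenuated-volume bookkeeping."""
    return mask_volume(mask, spacing)
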