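"""Synthetic SWI-like phantom volumes.

Real susceptibility-weighted scans are large, rated by experts and not
shippable with a code package, so every experiment here runs on phantoms: an
ellipsoidal "brain" filled with Gaussian-textured tissue, a configurable
number of dark curvilinear tubes standing in for veins (the main source of
microbleed-mimicking false positives on SWI), and additive noise.  The
phantom is deliberately simple — it contains no susceptibility physics, no
phase information and no anatomy — but it reproduces the two properties the
detection pipeline actually exercises: hypointense quasi-spherical targets
on a textured background, and elongated hypointense distractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._rng import substream
from .types import DEFAULT_SPACING, LocationSample, SWIVolume

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "sample_negative_locations",
    "extract_patch",
    "insert_patch",
    "boundary_distance_mm",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic SWI phantom.

    Intensities live on a [0, 255] scale.  Defaults give a mid-grey tissue
    (mean 120) with mild texture and noise, and a handful of dark vessels.
    """

    shape: tuple[int, int, int] = (64, 64, 40)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_vessels: int = 4
    vessel_radius_range: tuple[float, float] = (0.9, 1.6)  # mm
    vessel_intensity: float = 40.0
    tissue_mean: float = 120.0
    tissue_sd: float = 8.0
    noise_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if any(int(s) < 16 for s in self.shape):
            raise ValueError(
                f"shape {self.shape} too small to contain a brain mask; every axis must be >= 16"
            )
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.tissue_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def _ellipsoid_mask(shape, semi_axes_frac=(0.42, 0.42, 0.42)) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    axes = [f * s for f, s in zip(semi_axes_frac, shape)]
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def _rasterize_tube(shape, spacing, points, radius_mm) -> np.ndarray:
    """Boolean raster of a polyline thickened to `radius_mm` (anisotropy-aware)."""
    tube = np.zeros(shape, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if len(points) == 1:
        points = np.vstack([points, points])
    for a, b in zip(points[:-1], points[1:]):
        seg_len = np.linalg.norm((b - a) * spacing)
        n_steps = max(int(np.ceil(seg_len / min(spacing) * 2)), 2)
        for t in np.linspace(0.0, 1.0, n_steps):
            p = a + t * (b - a)
            lo = np.maximum(np.floor(p - radius_mm / spacing - 1), 0).astype(int)
            hi = np.minimum(np.ceil(p + radius_mm / spacing + 1), np.array(shape) - 1).astype(int)
            if np.any(lo > hi):
                continue
            sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
            grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
            d2 = sum(((g - pc) * sc) ** 2 for g, pc, sc in zip(grids, p, spacing))
            tube[sl] |= d2 <= radius_mm**2
    return tube


def generate_phantom(config: PhantomConfig) -> SWIVolume:
    """Generate a synthetic SWI-like volume. Pure function of the config."""
    config.validate()
    shape = tuple(int(s) for s in config.shape)
    mask = _ellipsoid_mask(shape)
    if not mask.any():
        raise ValueError("shape too small to contain a brain mask")

    rng_tex = substream(config.seed, "phantom.texture")
    rng_ves = substream(config.seed, "phantom.vessels")
    rng_noise = substream(config.seed, "phantom.noise")

    vol = np.full(shape, float(config.tissue_mean))
    if config.tissue_sd > 0:
        # smooth texture: low-pass filtered Gaussian field, rescaled to tissue_sd
        tex = rng_tex.normal(size=shape)
        tex = ndimage.gaussian_filter(tex, sigma=2.0)
        sd = tex.std()
        if sd > 0:
            vol += tex / sd * config.tissue_sd

    spacing = np.asarray(config.spacing, dtype=float)
    inner = ndimage.binary_erosion(mask, iterations=2) if config.n_vessels else mask

    def _inside(p):
        q = np.round(p).astype(int)
        return np.all(q >= 0) and np.all(q < np.array(shape)) and inner[tuple(q)]

    occupied = np.zeros(shape, dtype=bool)
    for _ in range(config.n_vessels):
        # random smooth polyline kept inside the brain so each vessel stays
        # one connected tube, disjoint from previously placed vessels
        for _retry in range(25):
            start = _random_interior_point(inner, rng_ves)
            direction = rng_ves.normal(size=3)
            direction /= np.linalg.norm(direction)
            n_knots = 6
            step_mm = 5.0
            pts = [start.astype(float)]
            for _ in range(n_knots):
                for _attempt in range(20):
                    cand_dir = direction + 0.45 * rng_ves.normal(size=3)
                    cand_dir /= np.linalg.norm(cand_dir)
                    cand = pts[-1] + cand_dir * step_mm / spacing
                    if _inside(cand):
                        direction = cand_dir
                        pts.append(cand)
                        break
                else:
                    break  # boxed in: stop extending this vessel
            radius = rng_ves.uniform(*config.vessel_radius_range)
            tube = _rasterize_tube(shape, spacing, np.array(pts), radius) & mask
            grown = ndimage.binary_dilation(tube, structure=np.ones((3, 3, 3), dtype=bool))
            if tube.sum() >= 5 and not (grown & occupied).any():
                occupied |= grown
                vol[tube] = config.vessel_intensity
                break
        else:
            raise ValueError("could not place pairwise-disjoint vessels; "
                             "reduce n_vessels or enlarge the phantom")

    if config.noise_sd > 0:
        vol += rng_noise.normal(scale=config.noise_sd, size=shape)

    vol = np.clip(vol, 0.0, 255.0)
    vol[~mask] = 0.0
    return SWIVolume(vol, tuple(spacing), mask, scan_id=f"phantom-{config.seed}")


def _random_interior_point(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx[rng.integers(len(idx))]


def boundary_distance_mm(vol: SWIVolume) -> np.ndarray:
    """Distance (mm) from each in-mask voxel to the nearest mask edge."""
    return ndimage.distance_transform_edt(vol.brain_mask, sampling=vol.spacing)


def sample_negative_locations(
    vol: SWIVolume,
    n: int,
    patch_size: int = 11,
    min_boundary_mm: float = 2.0,
    exclusion: list[LocationSample] | None = None,
    exclusion_radius_mm: float = 6.0,
    depth_histogram: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> list[LocationSample]:
    """Sample lesion-free locations inside the brain.

    Eligible voxels are at least `min_boundary_mm` inside the brain mask,
    far enough from excluded points (known lesions), and leave room for a
    `patch_size` cube.  By default sampling is uniform over eligible voxels;
    `depth_histogram = (bin_edges_mm, weights)` reweights voxels by their
    depth so an empirical real-lesion depth profile can be matched.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd, got {patch_size}")
    if n == 0:
        return []

    dist = boundary_distance_mm(vol)
    eligible = dist >= min_boundary_mm

    half = patch_size // 2
    fits = np.zeros(vol.shape, dtype=bool)
    sl = tuple(slice(half, s - half) for s in vol.shape)
    fits[sl] = True
    eligible &= fits

    if exclusion:
        spacing = np.asarray(vol.spacing)
        grids = np.meshgrid(*[np.arange(s) for s in vol.shape], indexing="ij", sparse=True)
        for loc in exclusion:
            d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, loc.center, spacing))
            eligible &= d2 > exclusion_radius_mm**2

    idx = np.argwhere(eligible)
    if len(idx) == 0:
        raise ValueError(
            "no eligible voxels: constraints (min_boundary_mm="
            f"{min_boundary_mm}, patch_size={patch_size}, exclusions) exclude the whole mask"
        )

    rng = np.random.default_rng(seed)
    if depth_histogram is None:
        choice = rng.choice(len(idx), size=n, replace=True)
    else:
        edges, weights = depth_histogram
        edges = np.asarray(edges, dtype=float)
        weights = np.asarray(weights, dtype=float)
        depths = dist[tuple(idx.T)]
        bins = np.clip(np.searchsorted(edges, depths, side="right") - 1, 0, len(weights) - 1)
        w = weights[bins]
        if w.sum() <= 0:
            raise ValueError("depth_histogram puts zero weight on every eligible voxel")
        choice = rng.choice(len(idx), size=n, replace=True, p=w / w.sum())

    return [
        LocationSample(tuple(int(c) for c in idx[i]), float(dist[tuple(idx[i])]))
        for i in choice
    ]


def _patch_slices(shape, center, size: int):
    if size % 2 == 0:
        raise ValueError(f"patch size must be odd, got {size}")
    half = size // 2
    sls = []
    for c, s in zip(center, shape):
        lo, hi = int(c) - half, int(c) + half + 1
        if lo < 0 or hi > s:
            raise IndexError(
                f"patch of size {size} at center {tuple(center)} exceeds volume bounds {shape}"
            )
        sls.append(slice(lo, hi))
    return tuple(sls)


def extract_patch(vol: SWIVolume | np.ndarray, center, size: int) -> np.ndarray:
    """Cubic patch of odd side `size` centered exactly at `center`."""
    arr = vol.intensities if isinstance(vol, SWIVolume) else np.asarray(vol)
    if isinstance(center, LocationSample):
        center = center.center
    return arr[_patch_slices(arr.shape, center, size)].copy()


def insert_patch(vol: SWIVolume | np.ndarray, patch: np.ndarray, center) -> None:
    """Write a cubic patch back in place (exact inverse of extract_patch)."""
    arr = vol.intensities if isinstance(vol, SWIVolume) else vol
    if isinstance(center, LocationSample):
        center = center.center
    size = patch.shape[0]
    if patch.shape != (size,) * 3:
        raise ValueError("patch must be cubic")
    arr[_patch_slices(arr.shape, center, size)] = patch
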