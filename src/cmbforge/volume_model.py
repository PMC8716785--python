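"""Lesion-volume estimation and the lesion-volume sampling distribution.

A 7x7x7 patch around a marked microbleed contains mostly healthy tissue plus
a small dark lesion.  The patch's intensity histogram is modelled as a
two-component mixture: a Gaussian N(mu, sigma) for tissue and a uniform
density on [0, 255] for outliers (the lesion and any vessel passing
through).  The mixture is fitted by expectation-maximization; a
maximum-posterior rule then labels each voxel tissue or outlier, and the
lesion volume follows from a two-compartment partial-volume model summed
over the hypointense outlier voxels.

Volumes measured over a cohort are kernel-smoothed into a binned sampling
distribution on [0, 80] mm^3 with a configurable probability floor, which is
what the lesion generators draw their volume targets from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .types import DEFAULT_SPACING, VOLUME_CAP, VolumeDistribution, voxel_volume

__all__ = [
    "MixtureFit",
    "fit_intensity_mixture",
    "estimate_lesion_volume",
    "smooth_volume_distribution",
    "sample_volume",
    "sample_volumes",
]

_UNIFORM_DENSITY = 1.0 / 255.0
_SIGMA_FLOOR = 0.5  # intensity units; prevents EM collapse on near-constant patches


@dataclass
class MixtureFit:
    """EM fit of the Gaussian-tissue + uniform-outlier intensity mixture."""

    mu: float
    sigma: float
    w: float  # mixing weight of the Gaussian (tissue) component
    loglik: float
    n_iter: int
    loglik_trace: np.ndarray | None = None


def _gauss_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2) / (np.sqrt(2.0 * np.pi) * sigma)


def fit_intensity_mixture(patch: np.ndarray, max_iter: int = 200, tol: float = 1e-6) -> MixtureFit:
    """Fit N(mu, sigma)*w + U(0,255)*(1-w) to patch intensities by EM.

    Initialization uses the patch median and MAD (robust to the lesion
    voxels themselves) with w = 0.9; sigma is floored to keep the Gaussian
    proper on low-texture patches.  The log-likelihood trace is recorded and
    is nondecreasing, as EM guarantees.
    """
    x = np.asarray(patch, dtype=np.float64).ravel()
    if np.unique(x).size < 2:
        raise ValueError("degenerate patch: needs >= 2 distinct intensity values")
    if x.min() < 0 or x.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")

    mu = float(np.median(x))
    sigma = max(1.4826 * float(np.median(np.abs(x - mu))), _SIGMA_FLOOR)
    w = 0.9

    trace = []
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        pg = w * _gauss_pdf(x, mu, sigma)
        pu = (1.0 - w) * _UNIFORM_DENSITY
        total = pg + pu
        loglik = float(np.log(total).sum())
        trace.append(loglik)
        r = pg / total  # responsibility of the Gaussian component
        # M-step
        rs = r.sum()
        w = float(rs / x.size)
        if rs > 0:
            mu = float((r * x).sum() / rs)
            sigma = float(np.sqrt((r * (x - mu) ** 2).sum() / rs))
        sigma = max(sigma, _SIGMA_FLOOR)
        w = min(max(w, 1e-6), 1.0 - 1e-6)
        if abs(loglik - prev) < tol:
            break
        prev = loglik

    return MixtureFit(mu=mu, sigma=sigma, w=w, loglik=trace[-1], n_iter=n_iter,
                      loglik_trace=np.asarray(trace))


def map_outlier_mask(patch: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """Boolean mask of voxels classified outlier by the maximum-posterior rule."""
    x = np.asarray(patch, dtype=np.float64)
    pg = fit.w * _gauss_pdf(x, fit.mu, fit.sigma)
    pu = (1.0 - fit.w) * _UNIFORM_DENSITY
    return pu > pg


def estimate_lesion_volume(patch: np.ndarray, fit: MixtureFit | None = None,
                           spacing=DEFAULT_SPACING, halo_sigmas: float = 1.5) -> float:
    """Lesion volume (mm^3) of a marked patch under the fitted mixture.

    Voxels MAP-classified as outliers *and* darker than the tissue mean
    form the lesion core; brighter outliers are ignored since microbleeds
    are hypointense by definition.  Because the partial-volume halo of a
    lesion darkens voxels too mildly for the MAP rule to flag them, the
    core is grown into its 26-connected hypointense halo (voxels below
    mu - halo_sigmas * sigma).  Each lesion voxel then contributes a
    partial-volume fraction f = (mu - I) / (mu - I_core), clamped to
    [0, 1], where I_core is the darkest core intensity — linear
    two-compartment intensity mixing between pure tissue and pure lesion
    core — and the fractions are summed and scaled by the voxel volume.
    """
    from scipy import ndimage

    if fit is None:
        fit = fit_intensity_mixture(patch)
    x = np.asarray(patch, dtype=np.float64)
    outlier = map_outlier_mask(x, fit)
    core = outlier & (x < fit.mu)
    if not core.any():
        return 0.0
    i_core = float(x[core].min())
    denom = fit.mu - i_core
    if denom <= 0:
        return 0.0
    halo = x < fit.mu - halo_sigmas * fit.sigma
    labels, _ = ndimage.label(halo | core, structure=np.ones((3, 3, 3), dtype=bool))
    lesion = np.isin(labels, np.unique(labels[core]))
    frac = np.clip((fit.mu - x[lesion]) / denom, 0.0, 1.0)
    return float(frac.sum() * voxel_volume(spacing))


def smooth_volume_distribution(
    volumes,
    cap: float = VOLUME_CAP,
    floor_prob: float = 0.005,
    bandwidth: float | str | None = None,
    n_bins: int = 80,
) -> VolumeDistribution:
    """Kernel-smoothed binned distribution of lesion volumes on [0, cap].

    A Gaussian KDE (Silverman bandwidth unless overridden) is evaluated on
    the bin grid, normalized, then floored at `floor_prob` per bin and
    renormalized.  The floor guarantees every volume in [0, cap] has
    nonzero sampling probability, so downstream generators are trained on
    the full volume range even when the cohort's volumes cluster tightly.
    """
    v = np.asarray(list(volumes), dtype=np.float64)
    if v.size == 0:
        raise ValueError("volumes is empty")
    if floor_prob * n_bins > 1.0:
        raise ValueError("floor_prob * n_bins must be <= 1")
    v = v[v <= cap]
    if v.size == 0:
        raise ValueError(f"all volumes exceed the cap of {cap} mm^3")

    edges = np.linspace(0.0, cap, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.std(v) == 0 or v.size < 2:
        probs = np.histogram(v, bins=edges)[0].astype(float)
    else:
        kde = gaussian_kde(v, bw_method=bandwidth)
        probs = kde(centers)
    total = probs.sum()
    probs = probs / total if total > 0 else np.full(n_bins, 1.0 / n_bins)
    probs = np.maximum(probs, floor_prob)
    probs /= probs.sum()
    return VolumeDistribution(edges, probs)


def sample_volumes(dist: VolumeDistribution, n: int, seed: int = 0) -> np.ndarray:
    """n inverse-CDF samples from a binned volume distribution.

    A bin is chosen by its probability; the volume is uniform within the
    chosen bin. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    bins = rng.choice(dist.probs.size, size=n, p=dist.probs)
    lo = dist.bin_edges[bins]
    hi = dist.bin_edges[bins + 1]
    return lo + rng.uniform(size=n) * (hi - lo)


def sample_volume(dist: VolumeDistribution, seed: int = 0) -> float:
    """One volume sample (see sample_volumes)."""
    return float(sample_volumes(dist, 1, seed=seed)[0])
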