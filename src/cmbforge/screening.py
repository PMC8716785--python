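"""Candidate screening by the 3D fast radial symmetry transform (RST).

A whole SWI scan has hundreds of thousands of brain voxels; classifying a
patch at each one is wasteful and drowns the classifier in trivial
negatives.  The RST is a gradient-voting filter that lights up centers of
radially symmetric blobs: every voxel with appreciable intensity gradient
casts a vote at the location a blob center would occupy if that voxel lay
on its rim.  Microbleeds are dark, so only dark-polarity votes are
accumulated (votes against the gradient direction, which points away from
a hypointense center).  Per radius n the orientation count O_n and
magnitude sum M_n maps combine into F_n = (M_n/k_n) * (|O_n|/k_n)^alpha,
which is Gaussian-smoothed and averaged over radii.  Local maxima of the
result above an adaptive threshold become the candidate locations passed
to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Candidate, LocationSample, SWIVolume

__all__ = [
    "RstConfig",
    "radial_symmetry_3d",
    "extract_candidates",
    "screening_sensitivity",
]


@dataclass
class RstConfig:
    """RST screening parameters.

    radii are in voxel units; alpha is the radial strictness exponent;
    kernel_sigma the post-vote Gaussian smoothing (voxels); threshold_sd
    the candidate cut in standard deviations of the in-mask map.
    """

    radii: tuple[int, ...] = (1, 2, 3, 4)
    alpha: float = 2.0
    kernel_sigma: float = 0.8
    polarity: str = "dark"
    threshold_sd: float = 2.0
    grad_threshold: float = 1e-6  # |g| below this casts no vote

    def validate(self) -> None:
        if any(int(r) <= 0 for r in self.radii):
            raise ValueError("radii must be positive integers")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.polarity not in ("dark", "bright"):
            raise ValueError("polarity must be 'dark' or 'bright'")


def _central_gradient(arr: np.ndarray) -> list[np.ndarray]:
    """Central differences in the interior; zero at the borders."""
    grads = []
    for ax in range(3):
        g = np.zeros_like(arr)
        sl_c = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_c[ax] = slice(1, -1)
        sl_p[ax] = slice(2, None)
        sl_m[ax] = slice(None, -2)
        g[tuple(sl_c)] = 0.5 * (arr[tuple(sl_p)] - arr[tuple(sl_m)])
        grads.append(g)
    return grads


def radial_symmetry_3d(vol: SWIVolume | np.ndarray, cfg: RstConfig | None = None) -> np.ndarray:
    """Radial-symmetry map of a volume (same shape as the input grid)."""
    cfg = cfg or RstConfig()
    cfg.validate()
    arr = vol.intensities if isinstance(vol, SWIVolume) else np.asarray(vol, dtype=np.float64)
    arr = np.asarray(arr, dtype=np.float64)
    shape = arr.shape

    g = _central_gradient(arr)
    mag = np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)
    voting = mag > cfg.grad_threshold
    vi = np.nonzero(voting)
    if vi[0].size == 0:
        return np.zeros(shape)
    gm = mag[vi]
    unit = [gc[vi] / gm for gc in g]
    base = np.stack(vi, axis=1)  # (V, 3)

    out = np.zeros(shape)
    sign = -1.0 if cfg.polarity == "dark" else 1.0
    for n in cfg.radii:
        # the (negatively) affected voxel this rim voxel votes for
        offs = np.stack([np.round(sign * n * u) for u in unit], axis=1)
        tgt = (base + offs).astype(np.int64)
        ok = np.all((tgt >= 0) & (tgt < np.array(shape)), axis=1)
        flat = np.ravel_multi_index(tuple(tgt[ok].T), shape)
        o_map = np.zeros(shape)
        m_map = np.zeros(shape)
        np.add.at(o_map.ravel(), flat, 1.0)
        np.add.at(m_map.ravel(), flat, gm[ok])
        k_n = o_map.max()
        if k_n <= 0:
            continue
        o_clamped = np.minimum(o_map, k_n)
        f_n = (m_map / k_n) * (np.abs(o_clamped) / k_n) ** cfg.alpha
        out += ndimage.gaussian_filter(f_n, sigma=cfg.kernel_sigma)
    return out / len(cfg.radii)


def extract_candidates(
    sym_map: np.ndarray,
    mask: np.ndarray,
    cfg: RstConfig | None = None,
    scan_id: str = "scan",
) -> list[Candidate]:
    """Local maxima (26-connectivity) of the map above an adaptive cut.

    The threshold is mean + threshold_sd * sd of the in-mask map values;
    candidates are returned sorted by score, highest first.
    """
    cfg = cfg or RstConfig()
    sym_map = np.asarray(sym_map, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if sym_map.shape != mask.shape:
        raise ValueError("map and mask shapes must match")
    vals = sym_map[mask]
    if vals.size == 0 or not np.any(sym_map != 0):
        return []
    thr = vals.mean() + cfg.threshold_sd * vals.std()
    local_max = sym_map == ndimage.maximum_filter(sym_map, size=3, mode="constant")
    hits = local_max & mask & (sym_map > thr) & (sym_map > 0)
    coords = np.argwhere(hits)
    scores = sym_map[tuple(coords.T)]
    order = np.argsort(-scores)
    return [
        Candidate(tuple(int(c) for c in coords[i]), float(scores[i]), scan_id)
        for i in order
    ]


def screening_sensitivity(
    candidates: list[Candidate],
    truth: list[LocationSample],
    spacing,
    hit_radius_mm: float = 3.0,
) -> float:
    """Fraction of truth lesions with a candidate within hit_radius_mm.

    Matching is greedy nearest-first and one-to-one, the same rule the
    evaluation stage uses.
    """
    from .evaluation import greedy_match

    if hit_radius_mm <= 0:
        raise ValueError("hit_radius_mm must be > 0")
    if not truth:
        raise ValueError("sensitivity undefined for empty truth")
    cand_pts = np.array([c.center for c in candidates], dtype=float).reshape(-1, 3)
    truth_pts = np.array([t.center for t in truth], dtype=float).reshape(-1, 3)
    matches = greedy_match(cand_pts, truth_pts, spacing, hit_radius_mm)
    return len(matches) / len(truth)
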