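"""Shared domain containers.

Conventions used throughout the package:

* Coordinates are 0-based voxel indices in array order ``(i, j, k)``;
  physical positions are ``index * spacing`` in mm.
* Intensity volumes live on a [0, 255] scale (the scale the intensity
  mixture model assumes); patches fed to networks are normalized to [0, 1].
* A lesion mask is an 11x11x11 array of values in [0, 1] that implants a
  hypointense lesion when multiplied voxel-wise into a background patch;
  mask value 1 leaves the background untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default voxel spacing in mm (dx, dy, dz).
DEFAULT_SPACING: tuple[float, float, float] = (0.93, 0.93, 1.75)

#: Side length of lesion-mask patches (voxels).
MASK_SIZE: int = 11

#: Side length of the patches used for lesion-volume estimation (voxels).
VOLUME_PATCH_SIZE: int = 7

#: Upper cap on lesion volume (mm^3) used by the sampling distribution.
VOLUME_CAP: float = 80.0


def voxel_volume(spacing) -> float:
    """Volume of one voxel in mm^3."""
    dx, dy, dz = spacing
    return float(dx) * float(dy) * float(dz)


@dataclass
class SWIVolume:
    """A susceptibility-weighted image: intensities, spacing and brain mask."""

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    scan_id: str = "scan"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise ValueError(f"intensities must be 3D, got {self.intensities.ndim}D")
        if self.brain_mask.shape != self.intensities.shape:
            raise ValueError("brain_mask shape must match intensities")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.brain_mask.any():
            raise ValueError("brain_mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        return voxel_volume(self.spacing)


@dataclass(frozen=True)
class LocationSample:
    """A voxel location inside the brain mask, with its depth from the edge."""

    center: tuple[int, int, int]
    distance_to_boundary: float = float("nan")


def check_lesion_mask(mask: np.ndarray, *, name: str = "mask") -> np.ndarray:
    """Validate the hard lesion-mask contract (shape and [0, 1] range)."""
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != (MASK_SIZE,) * 3:
        raise ValueError(f"{name} must be {MASK_SIZE}^3, got {mask.shape}")
    if mask.min() < 0.0 or mask.max() > 1.0:
        raise ValueError(f"{name} values must lie in [0, 1]")
    return mask


def border_shell(size: int) -> np.ndarray:
    """Boolean mask of the outermost one-voxel shell of a cubic patch."""
    shell = np.ones((size,) * 3, dtype=bool)
    if size > 2:
        shell[1:-1, 1:-1, 1:-1] = False
    return shell


def mask_volume(mask: np.ndarray, spacing=DEFAULT_SPACING) -> float:
    """Attenuated volume of a multiplicative mask: sum(1 - mask) * voxel volume.

    This is the one volume currency used everywhere: by the GAN's volume
    loss, by the analytical lesion calibration, and by the fidelity
    regression.
    """
    mask = np.asarray(mask, dtype=np.float64)
    return float(np.sum(1.0 - mask) * voxel_volume(spacing))


@dataclass
class VolumeDistribution:
    """Binned probability distribution over lesion volume on [0, cap] mm^3."""

    bin_edges: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must be a 1D array with >= 2 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if self.probs.shape != (self.bin_edges.size - 1,):
            raise ValueError("probs must have one entry per bin")
        if np.any(self.probs < 0):
            raise ValueError("probs must be nonnegative")
        total = self.probs.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"probs must sum to 1, got {total}")

    @property
    def cap(self) -> float:
        return float(self.bin_edges[-1])

    def to_dict(self) -> dict:
        return {"bin_edges": self.bin_edges.tolist(), "probs": self.probs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeDistribution":
        return cls(np.asarray(d["bin_edges"]), np.asarray(d["probs"]))

    @classmethod
    def point_mass(cls, volume: float, cap: float = VOLUME_CAP, n_bins: int = 160) -> "VolumeDistribution":
        """Degenerate distribution concentrated in the bin containing `volume`."""
        edges = np.linspace(0.0, cap, n_bins + 1)
        probs = np.zeros(n_bins)
        idx = min(int(np.searchsorted(edges, volume, side="right")) - 1, n_bins - 1)
        probs[max(idx, 0)] = 1.0
        return cls(edges, probs)


@dataclass
class LabeledPatch:
    """A cubic intensity patch with a class label and provenance tag."""

    patch: np.ndarray
    label: int  # 1 = lesion present, 0 = negative
    provenance: str = "real"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.float64)
        if self.patch.ndim != 3:
            raise ValueError("patch must be 3D")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class Candidate:
    """A screening hit: location plus radial-symmetry score."""

    center: tuple[int, int, int]
    symmetry_score: float
    scan_id: str = "scan"


@dataclass(frozen=True)
class DetectionRecord:
    """One scored candidate with its matched truth label."""

    scan_id: str
    center: tuple[int, int, int]
    score: float
    is_lesion: bool


@dataclass(frozen=True)
class OperatingPoint:
    """Detection statistics at one score threshold."""

    sensitivity: float
    specificity: float
    fp_per_scan: float
    threshold: float
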