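"""Shared I/O: NIfTI volumes, marker/candidate CSVs, config and reports.

Conventions (documented once, used everywhere):

* Marker and candidate CSVs use 0-based voxel indices in image array
  order, columns ``scan_id,x,y,z`` (plus ``score`` for candidates).
* NIfTI voxel spacing is carried in the header zooms; the affine is a
  diagonal scaling unless the input provided one.
* Volume distributions serialize as JSON {"bin_edges": [...], "probs": [...]}.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import LocationSample, SWIVolume, VolumeDistribution

__all__ = [
    "read_volume",
    "write_volume",
    "read_markers",
    "write_markers",
    "read_distribution",
    "write_distribution",
    "histogram_match",
]


def read_volume(path, mask_path=None, scan_id: str | None = None) -> SWIVolume:
    """Load a 3D NIfTI scan (and optional brain-mask NIfTI)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D from {path}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path}")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape:
            raise ValueError("brain mask shape does not match the scan")
    else:
        mask = np.ones(data.shape, dtype=bool)
    return SWIVolume(data, tuple(float(z) for z in zooms), mask,
                     scan_id=scan_id or Path(str(path)).stem.replace(".nii", ""))


def write_volume(vol: SWIVolume, path, mask_path=None) -> None:
    """Write a scan (and optionally its brain mask) as NIfTI with spacing."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.intensities, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    if mask_path is not None:
        mimg = nib.Nifti1Image(vol.brain_mask.astype(np.uint8), affine)
        mimg.header.set_zooms(vol.spacing)
        nib.save(mimg, str(mask_path))


def read_markers(path) -> pd.DataFrame:
    """Lesion point markers: columns scan_id, x, y, z (0-based voxel indices)."""
    df = pd.read_csv(path)
    required = {"scan_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"marker CSV missing columns: {sorted(missing)}")
    return df


def write_markers(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def markers_to_locations(df: pd.DataFrame, scan_id: str) -> list[LocationSample]:
    sub = df[df["scan_id"] == scan_id]
    return [LocationSample((int(r.x), int(r.y), int(r.z))) for r in sub.itertuples()]


def write_distribution(dist: VolumeDistribution, path) -> None:
    Path(path).write_text(json.dumps(dist.to_dict()))


def read_distribution(path) -> VolumeDistribution:
    return VolumeDistribution.from_dict(json.loads(Path(path).read_text()))


def histogram_match(vol: SWIVolume, reference: SWIVolume) -> SWIVolume:
    """Monotone intensity mapping equalizing in-mask quantiles to a reference.

    A light-weight stand-in for full histogram-matching preprocessing
    pipelines: in-mask intensities are mapped through the piecewise-linear
    function sending source percentiles (0-100) to the corresponding
    reference percentiles.
    """
    src = vol.intensities[vol.brain_mask]
    ref = reference.intensities[reference.brain_mask]
    qs = np.linspace(0, 100, 101)
    src_q = np.percentile(src, qs)
    ref_q = np.percentile(ref, qs)
    # make the source quantiles strictly increasing for interpolation
    src_q, keep = np.unique(src_q, return_index=True)
    ref_q = ref_q[keep]
    out = vol.intensities.copy()
    out[vol.brain_mask] = np.interp(vol.intensities[vol.brain_mask], src_q, ref_q)
    return SWIVolume(out, vol.spacing, vol.brain_mask.copy(), scan_id=vol.scan_id)
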