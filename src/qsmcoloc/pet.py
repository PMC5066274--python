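"""Amyloid-PET quantification: SUVR maps and the cortical composite score.

Late-frame activity is averaged voxelwise and standardized by the
cerebellar-gray mean, giving a standardized uptake value ratio (SUVR)
volume; the single-number summary of cortical amyloid burden is the
voxel-weighted mean SUVR over the merged cortical lobes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CORTICAL_LOBES, LabelMap, VolumeGrid

__all__ = ["SUVRMap", "compute_suvr", "cortical_composite", "validate_suvr_anchor"]


@dataclass
class SUVRMap:
    """Dimensionless SUVR volume; mean over the normalization region is 1."""

    volume: VolumeGrid
    normalization_region: str = "cerebellar_gray"


def compute_suvr(late_frames: list[VolumeGrid], labels: LabelMap,
                 normalization_region: str = "cerebellar_gray") -> SUVRMap:
    """Mean of the late frames divided by its cerebellar-gray average.

    Invariant to global rescaling of the activity. With a single frame that
    is already an SUVR volume this validates/re-establishes the anchor.
    """
    if len(late_frames) < 1:
        raise ValueError("need at least one late frame")
    ref = late_frames[0]
    for f in late_frames[1:]:
        ref.require_same_grid(f, "late frame")
    ref.require_same_grid(labels, "labels")
    avg = np.mean([f.data for f in late_frames], axis=0)
    norm_mask = labels.mask_of(normalization_region).data
    if not norm_mask.any():
        raise ValueError(f"empty normalization region {normalization_region!r}")
    denom = float(avg[norm_mask].mean())
    if denom == 0:
        raise ValueError("zero cerebellar mean; cannot normalize")
    out = avg / denom
    np.clip(out, 0.0, None, out=out)
    return SUVRMap(ref.with_data(out), normalization_region)


def validate_suvr_anchor(suvr: SUVRMap, labels: LabelMap, tol: float = 1e-6) -> None:
    """Check that the normalization-region mean is 1 within tolerance."""
    m = labels.mask_of(suvr.normalization_region).data
    mean = float(suvr.volume.data[m].mean())
    if abs(mean - 1.0) > tol:
        raise ValueError(
            f"SUVR anchor violated: {suvr.normalization_region} mean is {mean:.6g}, not 1")


def cortical_composite(suvr: SUVRMap, labels: LabelMap,
                       cortical: tuple[str, ...] = CORTICAL_LOBES) -> float:
    """Composite cortical retention: voxel-weighted mean SUVR over the union
    of the cortical-lobe labels ("merged" voxels, not a mean of ROI means)."""
    suvr.volume.require_same_grid(labels, "labels")
    lab = labels.data
    sel = np.zeros(lab.shape, bool)
    for name in cortical:
        m = lab == labels.label_of(name)
        if not m.any():
            raise ValueError(f"cortical label {name!r} empty")
        sel |= m
    return float(suvr.volume.data[sel].mean())
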