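"""Shared spatial data model.

All volumes live on a fixed, 0-based voxel-indexed grid; physical units
enter only through the voxel size in mm. Orientation is assumed consistent
across a subject's modalities (data are generated / provided co-registered);
a shape or voxel-size mismatch is a hard error, never a resampling trigger.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "LabelMap",
    "MultiEchoPhase",
    "SubjectRecord",
    "GridMismatchError",
    "STRUCTURE_LABELS",
    "STRUCTURE_NAMES",
    "TABLE_STRUCTURES",
    "CORTICAL_LOBES",
    "SUBCORTICAL_STRUCTURES",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


# Canonical integer labels for every structure the pipeline knows about.
# 0 is reserved for background.
STRUCTURE_LABELS: dict[str, int] = {
    "amygdala": 1,
    "nucleus_accumbens": 2,
    "hippocampus": 3,
    "entorhinal_cortex": 4,
    "thalamus": 5,
    "caudate_nucleus": 6,
    "putamen": 7,
    "globus_pallidus": 8,
    "frontal_cortex": 9,
    "temporal_cortex": 10,
    "parietal_cortex": 11,
    "occipital_cortex": 12,
    "cerebellar_gray": 13,
    "csf_ventricles": 14,
    "white_matter": 15,
    "mpfc_seed": 16,
}
STRUCTURE_NAMES: dict[int, str] = {v: k for k, v in STRUCTURE_LABELS.items()}

#: the 12 gray-matter structures quantified in the group tables
TABLE_STRUCTURES: tuple[str, ...] = (
    "amygdala",
    "nucleus_accumbens",
    "hippocampus",
    "entorhinal_cortex",
    "thalamus",
    "caudate_nucleus",
    "putamen",
    "globus_pallidus",
    "frontal_cortex",
    "temporal_cortex",
    "parietal_cortex",
    "occipital_cortex",
)
CORTICAL_LOBES: tuple[str, ...] = (
    "frontal_cortex",
    "temporal_cortex",
    "parietal_cortex",
    "occipital_cortex",
)
SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "amygdala",
    "nucleus_accumbens",
    "hippocampus",
    "entorhinal_cortex",
    "thalamus",
    "caudate_nucleus",
    "putamen",
    "globus_pallidus",
)


def _as_voxel_size(voxel_size_mm) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size_mm)
    if len(vs) != 3:
        raise ValueError(f"voxel_size_mm must have 3 entries, got {len(vs)}")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing (mm) and an origin offset.

    ``data`` may contain NaN only where an explicit validity mask
    accompanies it (e.g. susceptibility outside the SHARP validity mask).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeGrid needs 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ValueError(f"grid too small: shape {self.data.shape} (need >= 8 per axis)")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)
        self.origin_mm = tuple(float(v) for v in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0

    def same_grid(self, other: "VolumeGrid | BinaryMask | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
        )

    def require_same_grid(self, other, what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what}: shape/voxel-size mismatch "
                f"({self.shape}@{self.voxel_size_mm} vs {other.shape}@{other.voxel_size_mm})"
            )

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(np.asarray(data), self.voxel_size_mm, self.origin_mm)


@dataclass
class BinaryMask:
    """Boolean field on the grid of an associated :class:`VolumeGrid`."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("BinaryMask needs 3D data")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.data & np.asarray(other.data, bool), self.voxel_size_mm)


@dataclass
class LabelMap:
    """Non-negative integer field plus a label -> structure-name table.

    0 is reserved for background; labels are mutually exclusive by
    construction (one integer per voxel).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    names: Mapping[int, str] = field(default_factory=lambda: dict(STRUCTURE_NAMES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap needs 3D data")
        if np.any(self.data < 0):
            raise ValueError("labels must be non-negative")
        self.voxel_size_mm = _as_voxel_size(self.voxel_size_mm)
        self.names = dict(self.names)
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")

    @property
    def shape(self):
        return self.data.shape

    def label_of(self, name: str) -> int:
        for lab, nm in self.names.items():
            if nm == name:
                return lab
        raise KeyError(f"unknown structure name: {name!r}")

    def mask_of(self, name: str) -> BinaryMask:
        return BinaryMask(self.data == self.label_of(name), self.voxel_size_mm)

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.data) if v != 0)

    def validate_complete(self) -> None:
        """Every label in the table must occur in the field."""
        present = set(self.present_labels())
        missing = [nm for lab, nm in self.names.items() if lab not in present]
        if missing:
            raise ValueError(f"labels absent from field: {missing}")


@dataclass
class MultiEchoPhase:
    """Wrapped multi-echo GRE phase (radians, in (-pi, pi]) plus magnitude."""

    phase: list[VolumeGrid]            # one per echo, radians
    echo_times_s: tuple[float, ...]    # strictly increasing, seconds
    field_strength_t: float            # Tesla
    magnitude: list[VolumeGrid]        # one per echo, arbitrary units

    def __post_init__(self) -> None:
        if len(self.phase) < 2:
            raise ValueError("need at least 2 echoes")
        self.echo_times_s = tuple(float(t) for t in self.echo_times_s)
        if len(self.echo_times_s) != len(self.phase):
            raise ValueError("one echo time per phase volume required")
        if any(t2 <= t1 for t1, t2 in zip(self.echo_times_s, self.echo_times_s[1:])):
            raise ValueError("echo times must be strictly increasing")
        if self.field_strength_t <= 0:
            raise ValueError("field strength must be positive")
        if len(self.magnitude) != len(self.phase):
            raise ValueError("one magnitude volume per echo required")
        ref = self.phase[0]
        for vol in self.phase[1:] + self.magnitude:
            ref.require_same_grid(vol, "multi-echo data")
        for vol in self.phase:
            d = vol.data
            if np.any(d <= -np.pi) or np.any(d > np.pi):
                raise ValueError("wrapped phase must lie strictly in (-pi, pi]")

    @property
    def n_echoes(self) -> int:
        return len(self.phase)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str          # "control" | "mci"
    apoe_e4: bool
    age: float          # years
    gender: str         # "F" | "M"

    def __post_init__(self) -> None:
        if self.group not in ("control", "mci"):
            raise ValueError(f"unknown group value: {self.group!r} (expected control|mci)")
        if self.gender not in ("F", "M"):
            raise ValueError(f"unknown gender value: {self.gender!r} (expected F|M)")
        if not (40.0 <= self.age <= 110.0):
            raise ValueError(f"age {self.age} outside plausible range [40, 110]")
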