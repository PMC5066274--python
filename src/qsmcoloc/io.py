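"""File I/O: NIfTI-1 volumes, subject metadata TSV, config, provenance.

NIfTI-1 is the single volume format. Volumes are written in float32 (or the
integer dtype of a label map) with a diagonal affine built from the voxel
size, so a write/read round trip is bit-compatible at stored precision.
"""
from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BinaryMask, LabelMap, SubjectRecord, VolumeGrid

log = logging.getLogger("qsmcoloc")

__all__ = [
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "read_label_map",
    "write_label_map",
    "read_mask",
    "write_mask",
    "read_subject_table",
    "write_subject_table",
    "load_config",
    "write_provenance",
    "sha256_of",
]


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters with their standard defaults.

    QSM: variable-kernel SHARP background removal with a 4 mm maximum
    spherical radius and a k-space truncation threshold of 0.05; the brain
    mask uses a fractional intensity threshold of 0.3; ROI masks are eroded
    by 2 voxels before susceptibility averaging. Connectivity: 0.01-0.1 Hz
    band-pass and a voxelwise FDR threshold of 0.001 for the group mask.
    Table statistics use FDR 0.05.
    """

    sharp_max_radius_mm: float = 4.0
    sharp_regularization: float = 0.05
    bet_fractional_threshold: float = 0.3
    erosion_voxels: int = 2
    echoes_used: tuple[int, ...] = (1, 2)     # 0-based; the 12 and 18 ms echoes
    lsqr_tol: float = 1e-6
    lsqr_max_iter: int = 40   # iteration cap doubles as LSQR's regularization
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    mask_fdr: float = 0.001
    stats_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.band_low_hz < self.band_high_hz):
            raise ValueError(
                f"need 0 < band_low < band_high, got {self.band_low_hz}, {self.band_high_hz}"
            )
        if self.sharp_max_radius_mm <= 0:
            raise ValueError("SHARP max radius must be positive")
        if not (0.0 < self.sharp_regularization < 1.0):
            raise ValueError("SHARP regularization must lie in (0, 1)")
        if not (0.0 < self.mask_fdr < 1.0) or not (0.0 < self.stats_fdr < 1.0):
            raise ValueError("FDR levels must lie in (0, 1)")
        if self.erosion_voxels < 0:
            raise ValueError("erosion must be >= 0 voxels")
        self.echoes_used = tuple(int(e) for e in self.echoes_used)
        if len(self.echoes_used) < 1:
            raise ValueError("at least one echo must be used")


def _affine(voxel_size_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    aff[:3, 3] = origin_mm
    return aff


def write_volume(vol: VolumeGrid, path, description: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(vol.data)
    if not np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.voxel_size_mm, vol.origin_mm))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))
    return path


def read_volume(path) -> VolumeGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel size in header: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeGrid(data, tuple(float(z) for z in zooms), origin)


def read_series(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 4D NIfTI (x, y, z, t); returns (data, voxel_size_mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_series(data: np.ndarray, voxel_size_mm, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, np.float32), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def write_label_map(labels: LabelMap, path) -> Path:
    vol = VolumeGrid(labels.data.astype(np.int16), labels.voxel_size_mm)
    return write_volume(vol, path, "structure labels")


def read_label_map(path, names=None) -> LabelMap:
    vol = read_volume(path)
    from .core import STRUCTURE_NAMES

    return LabelMap(np.rint(vol.data).astype(np.int32), vol.voxel_size_mm,
                    names if names is not None else dict(STRUCTURE_NAMES))


def write_mask(mask: BinaryMask, path) -> Path:
    vol = VolumeGrid(mask.data.astype(np.int16), mask.voxel_size_mm)
    return write_volume(vol, path, "binary mask")


def read_mask(path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.voxel_size_mm)


_SUBJECT_COLUMNS = ["subject_id", "group", "apoe_e4", "age", "gender"]
_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def read_subject_table(path) -> list[SubjectRecord]:
    """Parse the participants TSV into subject records.

    group / apoe_e4 / gender are parsed case-insensitively; duplicate
    subject ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    records = []
    for _, row in df.iterrows():
        apoe_raw = str(row["apoe_e4"]).strip().lower()
        if apoe_raw in _TRUE:
            apoe = True
        elif apoe_raw in _FALSE:
            apoe = False
        else:
            raise ValueError(f"cannot parse apoe_e4 value: {row['apoe_e4']!r}")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]).strip(),
                group=str(row["group"]).strip().lower(),
                apoe_e4=apoe,
                age=float(row["age"]),
                gender=str(row["gender"]).strip().upper(),
            )
        )
    return records


def write_subject_table(records: list[SubjectRecord], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([asdict(r) for r in records], columns=_SUBJECT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


_FLOAT_KEYS = {
    "sharp_max_radius_mm", "sharp_regularization", "bet_fractional_threshold",
    "lsqr_tol", "band_low_hz", "band_high_hz", "mask_fdr", "stats_fdr",
}
_INT_KEYS = {"erosion_voxels", "lsqr_max_iter", "seed"}


def load_config(path=None) -> PipelineConfig:
    """Load a flat key=value config with [sections]; unspecified keys take
    the standard defaults. The fully resolved config is logged."""
    values: dict = {}
    if path is not None:
        parser = configparser.ConfigParser()
        text = Path(path).read_text()
        if not text.lstrip().startswith("["):
            text = "[default]\n" + text
        parser.read_string(text)
        for section in parser.sections():
            for key, raw in parser.items(section):
                key = key.lower()
                if key in _FLOAT_KEYS:
                    values[key] = float(raw)
                elif key in _INT_KEYS:
                    values[key] = int(raw)
                elif key == "echoes_used":
                    values[key] = tuple(int(x) for x in raw.replace(",", " ").split())
                else:
                    raise ValueError(f"unknown config key: {key}")
    cfg = PipelineConfig(**values)
    log.info("resolved config: %s", asdict(cfg))
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_path, *, inputs: dict, config: PipelineConfig, seed: int,
                     extra: dict | None = None) -> Path:
    """Record input hashes, the resolved config and the seed for a run.

    Deliberately excludes wall-clock time so that re-runs with identical
    inputs produce byte-identical provenance.
    """
    import nibabel
    import numpy
    import scipy

    record = {
        "inputs": {k: (sha256_of(v) if Path(str(v)).is_file() else str(v))
                   for k, v in inputs.items()},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": int(seed),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    if extra:
        record.update(extra)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return out_path
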