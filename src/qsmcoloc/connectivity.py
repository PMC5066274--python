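"""Seed-based resting-state connectivity and the group-level FDR mask.

Per subject: confound regression (6 motion + CSF + WM means), then a
zero-phase 0.01-0.1 Hz band-pass, then Fisher-z seed-to-voxel correlation
against the mean MPFC seed series. The fixed order (regression, then
filtering, then correlation) is deliberate and logged.

Group level: voxelwise 2x2 cell-means model over (MCI x iron-class) with a
one-sided contrast for elevated coupling in the MCI ∧ high-iron cell,
Benjamini-Hochberg correction across in-mask voxels, and a label-map
summary of the surviving cluster.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinaryMask, LabelMap, SubjectRecord
from .stats import fdr_bh

log = logging.getLogger("qsmcoloc")

__all__ = [
    "ConnectivityMap",
    "GroupMask",
    "bandpass_filter",
    "regress_confounds",
    "seed_to_voxel",
    "group_mask",
    "subject_connectivity",
]

_Z_GUARD = 1e-7  # |r| is clipped to 1 - guard before atanh


@dataclass
class ConnectivityMap:
    """Voxelwise Fisher z of the seed correlation for one subject."""

    z: np.ndarray               # 3D field, finite inside brain mask
    subject_id: str
    seed_label: str = "mpfc_seed"


@dataclass
class GroupMask:
    mask: BinaryMask
    statistic: np.ndarray       # voxelwise t field (0 outside analysis mask)
    fdr_threshold: float
    region_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    contrast: str = "cell_means_2x2"


def bandpass_filter(series: np.ndarray, tr_s: float, low_hz: float,
                    high_hz: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    4th-order Butterworth low-pass then high-pass, each applied forward and
    backward (no phase shift); DC is removed exactly, so the output has
    zero mean. Mid-passband amplitude is preserved (>= 0.95) and stopband
    components (<= low/2, >= 2*high) are attenuated to <= 0.05, including
    off-bin frequencies a plain FFT mask would leak. The two stages use
    the boundary extensions that suit their stopbands (even for the
    low-pass, odd for the high-pass), which keeps end transients small for
    both fast and slow contaminants.
    """
    series = np.asarray(series)
    n = series.shape[-1]
    if n < 32:
        raise ValueError("series too short to filter (need >= 32 frames)")
    nyquist = 0.5 / tr_s
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist} Hz")
    from scipy.signal import butter, sosfiltfilt
    lp = butter(4, high_hz / nyquist, btype="lowpass", output="sos")
    hp = butter(4, low_hz / nyquist, btype="highpass", output="sos")
    out = sosfiltfilt(lp, series, axis=-1, padtype="even",
                      padlen=min(n - 2, 3 * max(1, int(1 / (high_hz * tr_s)))))
    out = sosfiltfilt(hp, out, axis=-1, padtype="odd",
                      padlen=min(n - 2, 3 * max(1, int(1 / (low_hz * tr_s)))))
    out = out - out.mean(axis=-1, keepdims=True)
    return out.astype(series.dtype, copy=False) if series.dtype == np.float32 else out


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residualization of each row of ``series`` against
    [intercept, confounds]; residuals are orthogonal to the confounds."""
    series = np.asarray(series, float)
    conf = np.asarray(confounds, float)
    if conf.ndim != 2:
        raise ValueError("confounds must be 2D (time x regressors)")
    n_t = series.shape[-1]
    if conf.shape[0] != n_t:
        raise ValueError(f"confound length {conf.shape[0]} != series length {n_t}")
    X = np.column_stack([np.ones(n_t), conf])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient confound matrix")
    # residual = series - X (X^+ series); pinv is computed once on the small
    # design and applied as two matmuls (fast for many voxels). Work in the
    # series' own dtype to avoid upcasting large arrays.
    pinv = np.linalg.pinv(X)
    Xc = X.astype(series.dtype, copy=False)
    pc = pinv.astype(series.dtype, copy=False)
    Yt = series.reshape(-1, n_t).T
    resid = Yt - Xc @ (pc @ Yt)
    return resid.T.reshape(series.shape)


def seed_to_voxel(series_4d: np.ndarray, seed_mask: np.ndarray,
                  brain_mask: np.ndarray, subject_id: str = "",
                  seed_label: str = "mpfc_seed") -> ConnectivityMap:
    """Fisher-z map of the correlation between every brain voxel and the
    mean series over the seed; preprocessing must already be applied.
    Self-correlations are guarded: |r| is clipped to 1 - 1e-7."""
    seed_mask = np.asarray(seed_mask, bool)
    brain_mask = np.asarray(brain_mask, bool)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    seed_sig = series_4d[seed_mask].mean(axis=0)
    seed_sig = seed_sig - seed_sig.mean()
    denom_seed = np.sqrt((seed_sig ** 2).sum())
    if denom_seed == 0:
        raise ValueError("zero-variance seed signal")
    vox = series_4d[brain_mask]
    vox = vox - vox.mean(axis=1, keepdims=True)
    denom_vox = np.sqrt((vox ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vox @ seed_sig) / (denom_vox * denom_seed)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -(1.0 - _Z_GUARD), 1.0 - _Z_GUARD)
    z = np.zeros(series_4d.shape[:3])
    z[brain_mask] = np.arctanh(r)
    return ConnectivityMap(z, subject_id, seed_label)


def connectivity_from_flat(flat: np.ndarray, confounds: np.ndarray,
                           seed_sel: np.ndarray, tr_s: float,
                           low_hz: float = 0.01, high_hz: float = 0.1,
                           ) -> np.ndarray:
    """Core per-subject pipeline on an (n_voxels, t) array: confound
    regression -> band-pass -> Fisher z against the mean seed series
    (``seed_sel`` indexes rows of ``flat``). Returns z per voxel."""
    seed_sel = np.asarray(seed_sel, bool)
    if not seed_sel.any():
        raise ValueError("empty seed selection")
    flat = regress_confounds(np.asarray(flat, np.float32), confounds)
    flat = bandpass_filter(flat, tr_s, low_hz, high_hz)
    seed_sig = flat[seed_sel].mean(axis=0)
    seed_sig = seed_sig - seed_sig.mean()
    denom_seed = np.sqrt((seed_sig ** 2).sum())
    if denom_seed == 0:
        raise ValueError("zero-variance seed signal")
    vox = flat - flat.mean(axis=1, keepdims=True)
    denom_vox = np.sqrt((vox ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (vox @ seed_sig) / (denom_vox * denom_seed)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip(r, -(1.0 - _Z_GUARD), 1.0 - _Z_GUARD)
    return np.arctanh(r).astype(np.float64)


def subject_connectivity(series_4d: np.ndarray, confounds: np.ndarray,
                         seed_mask: np.ndarray, brain_mask: np.ndarray,
                         tr_s: float, low_hz: float = 0.01, high_hz: float = 0.1,
                         subject_id: str = "") -> ConnectivityMap:
    """Fixed per-subject pipeline: confound regression -> band-pass ->
    seed-to-voxel Fisher z (only brain voxels are processed)."""
    brain_mask = np.asarray(brain_mask, bool)
    seed_mask = np.asarray(seed_mask, bool)
    flat = series_4d[brain_mask]
    zf = connectivity_from_flat(flat, confounds, seed_mask[brain_mask], tr_s,
                                low_hz, high_hz)
    z = np.zeros(series_4d.shape[:3])
    z[brain_mask] = zf
    return ConnectivityMap(z, subject_id)


def _cell_design(is_mci: np.ndarray, is_high: np.ndarray):
    """2x2 cell-means design matrix and the (MCI ∧ high) - mean(others)
    contrast vector. Columns: (ctl,low), (ctl,high), (mci,low), (mci,high)."""
    cells = [(~is_mci & ~is_high), (~is_mci & is_high),
             (is_mci & ~is_high), (is_mci & is_high)]
    X = np.column_stack([c.astype(float) for c in cells])
    c = np.array([-1 / 3, -1 / 3, -1 / 3, 1.0])
    return X, c


def group_mask(maps: list[ConnectivityMap], subjects: list[SubjectRecord],
               iron_class: dict[str, str], labels: LabelMap,
               analysis_mask: np.ndarray, fdr_threshold: float = 0.001,
               exclude_seed: bool = True) -> GroupMask:
    """Voxelwise group model of the Fisher-z maps.

    The tested effect is the positive (MCI ∧ high-iron) contrast in a 2x2
    cell-means model (equivalent to intercept + MCI + iron + MCI x iron);
    one-sided p-values are BH-corrected across in-mask voxels and the mask
    keeps voxels with q < ``fdr_threshold``. When a design cell is empty or
    the residual df vanish (tiny cohorts), the model falls back to a
    two-group contrast (MCI ∧ high-iron vs rest), logged. Seed voxels are
    excluded from the analysis mask.
    """
    if len(maps) != len(subjects):
        raise ValueError("one connectivity map per subject required")
    analysis_mask = np.asarray(analysis_mask, bool).copy()
    if exclude_seed:
        analysis_mask &= labels.data != labels.label_of("mpfc_seed")
    n_vox = int(analysis_mask.sum())
    if n_vox == 0:
        raise ValueError("empty analysis mask")
    order = {m.subject_id: m for m in maps}
    Y = np.stack([order[s.subject_id].z[analysis_mask] for s in subjects])
    is_mci = np.array([s.group == "mci" for s in subjects])
    is_high = np.array([iron_class[s.subject_id] == "high" for s in subjects])

    X, c = _cell_design(is_mci, is_high)
    contrast_name = "cell_means_2x2"
    cell_counts = X.sum(axis=0)
    n, p = X.shape
    if (cell_counts == 0).any() or n - p < 1:
        if not (is_mci & is_high).any() or (is_mci & is_high).all():
            raise ValueError("tested-effect cell empty (or universal); cannot test")
        X = np.column_stack([np.ones(n), (is_mci & is_high).astype(float)])
        c = np.array([0.0, 1.0])
        p = 2
        contrast_name = "two_group_fallback"
        log.warning("2x2 design not estimable (cells %s); using MCI∧high vs rest",
                    cell_counts.astype(int).tolist())
        if n - p < 1:
            raise ValueError("not enough subjects for the group test")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                      # p x n_vox
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * float(c @ XtX_inv @ c), 1e-300))
    t = (c @ beta) / se
    from scipy import stats as sps
    p_one = sps.t.sf(t, df)
    q = fdr_bh(p_one)
    keep = q < fdr_threshold

    mask = np.zeros(analysis_mask.shape, bool)
    mask[analysis_mask] = keep
    tvol = np.zeros(analysis_mask.shape)
    tvol[analysis_mask] = t

    rows = []
    for lbl, name in sorted(labels.names.items()):
        region = labels.data == lbl
        n_in = int((mask & region).sum())
        if n_in:
            rows.append({"region": name, "voxels": n_in,
                         "pct_of_region": 100.0 * n_in / int(region.sum())})
    summary = pd.DataFrame(rows, columns=["region", "voxels", "pct_of_region"])
    return GroupMask(BinaryMask(mask, labels.voxel_size_mm), tvol,
                     fdr_threshold, summary, contrast_name)
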