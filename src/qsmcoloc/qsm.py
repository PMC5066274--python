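"""Quantitative susceptibility mapping from wrapped multi-echo phase.

Chain: Laplacian phase unwrapping -> brain masking -> phase-to-frequency
conversion -> variable-kernel SHARP background-field removal (per echo) ->
echo averaging -> masked dipole inversion by LSQR -> referencing to the
reference region selected by the lowest-across-subject-variance rule.

Numerical conventions
---------------------
* The unwrapping Poisson solve uses the cosine (DCT-II) basis, i.e. a
  mirror extension to a 2x grid per axis; this diagonalizes the Neumann
  discrete Laplacian exactly and avoids wrap-around bias. The
  zero-frequency component is set to 0, so output is zero-sum.
* The SHARP "regularization parameter" (default 0.05) is the truncation
  threshold on the k-space deconvolution filter (TSVD convention); the
  variable-kernel schedule runs over integer voxel radii from
  ceil(max_radius / voxel) down to 1, the largest valid radius winning
  per voxel.
* The dipole inversion is plain masked least squares solved with LSQR
  (tolerance 1e-6, max 300 iterations, zero start, no extra
  regularization term); D(0) = 0 makes constants unobservable, which is
  harmless because referencing removes them.
* The brain mask is a quantile-threshold + largest-connected-component +
  hole-fill stand-in for an external brain-extraction tool.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy import ndimage
from scipy.sparse.linalg import LinearOperator, lsqr

from .cohort import GYROMAGNETIC_RATIO_HZ_PER_T, dipole_kernel
from .core import BinaryMask, LabelMap, MultiEchoPhase, VolumeGrid
from .io import PipelineConfig

log = logging.getLogger("qsmcoloc")

__all__ = [
    "SusceptibilityMap",
    "InversionResult",
    "unwrap_phase_laplacian",
    "compute_brain_mask",
    "phase_to_frequency",
    "sharp_remove_background",
    "average_echo_fields",
    "invert_dipole_lsqr",
    "select_reference_region",
    "reference_susceptibility",
    "reconstruct_qsm",
]


@dataclass
class SusceptibilityMap:
    """Referenced susceptibility: chi (ppb) valid inside ``validity``; the
    mean over the reference region is ~0 after referencing."""

    chi: VolumeGrid                 # ppb
    validity: BinaryMask            # post-SHARP validity mask
    reference_region: str
    reference_mean_removed_ppb: float


@dataclass
class InversionResult:
    chi: VolumeGrid                 # ppb, unreferenced
    converged: bool
    iterations: int


# ---------------------------------------------------------------------------
# Laplacian phase unwrapping
# ---------------------------------------------------------------------------

def _neumann_laplacian(f: np.ndarray, voxel_size_mm) -> np.ndarray:
    """6-neighbour discrete Laplacian with mirrored (Neumann) boundaries."""
    out = np.zeros_like(f)
    for ax, h in enumerate(voxel_size_mm):
        fwd = np.concatenate([np.take(f, range(1, f.shape[ax]), axis=ax),
                              np.take(f, [-1], axis=ax)], axis=ax)
        bwd = np.concatenate([np.take(f, [0], axis=ax),
                              np.take(f, range(0, f.shape[ax] - 1), axis=ax)], axis=ax)
        out += (fwd + bwd - 2.0 * f) / h ** 2
    return out


def _poisson_solve_neumann(rhs: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Solve lap(phi) = rhs in the DCT-II basis (which diagonalizes the
    mirrored-boundary Laplacian); zero-frequency component set to 0."""
    lam = np.zeros(rhs.shape)
    for ax, (n, h) in enumerate(zip(rhs.shape, voxel_size_mm)):
        k = np.arange(n)
        ev = (2.0 * np.cos(np.pi * k / n) - 2.0) / h ** 2
        shape = [1, 1, 1]
        shape[ax] = n
        lam = lam + ev.reshape(shape)
    coeff = scipy.fft.dctn(rhs, type=2, norm="ortho")
    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = coeff / lam
    coeff[0, 0, 0] = 0.0
    return scipy.fft.idctn(coeff, type=2, norm="ortho")


def unwrap_phase_laplacian(wrapped: VolumeGrid) -> VolumeGrid:
    """Laplacian-based discrete phase unwrapping.

    Solves lap(phi_u) = cos(phi_w) lap(sin phi_w) - sin(phi_w) lap(cos phi_w)
    spectrally; the smooth true phase is recovered up to an additive
    constant (output is zero-sum) and a harmonic residual.
    """
    pw = np.asarray(wrapped.data, np.float64)
    if np.any(pw <= -np.pi) or np.any(pw > np.pi):
        raise ValueError("wrapped phase must lie in (-pi, pi]")
    if min(pw.shape) < 16:
        raise ValueError("grid too small for spectral unwrapping (need >= 16 per axis)")
    s, c = np.sin(pw), np.cos(pw)
    rhs = c * _neumann_laplacian(s, wrapped.voxel_size_mm) \
        - s * _neumann_laplacian(c, wrapped.voxel_size_mm)
    return wrapped.with_data(_poisson_solve_neumann(rhs, wrapped.voxel_size_mm))


# ---------------------------------------------------------------------------
# Masking and frequency conversion
# ---------------------------------------------------------------------------

def compute_brain_mask(magnitude: VolumeGrid, fractional_threshold: float = 0.3) -> BinaryMask:
    """Brain mask from a magnitude image: threshold at
    ``fractional_threshold`` x the 98th percentile of nonzero intensities,
    keep the largest connected component, fill holes. Deterministic."""
    mag = np.asarray(magnitude.data, np.float64)
    if np.any(mag < 0):
        raise ValueError("magnitude must be non-negative")
    nz = mag[mag > 0]
    if nz.size == 0:
        raise ValueError("all-zero magnitude image")
    thr = fractional_threshold * np.percentile(nz, 98)
    raw = mag >= thr
    labeled, n = ndimage.label(raw)
    if n == 0:
        raise ValueError("no voxels above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(labeled == keep)
    return BinaryMask(mask, magnitude.voxel_size_mm)


def phase_to_frequency(unwrapped: VolumeGrid, echo_time_s: float) -> VolumeGrid:
    """Frequency shift in Hz: phi / (2*pi*TE)."""
    if echo_time_s <= 0:
        raise ValueError("echo time must be positive")
    return unwrapped.with_data(unwrapped.data / (2.0 * np.pi * echo_time_s))


# ---------------------------------------------------------------------------
# SHARP background-field removal (variable kernel)
# ---------------------------------------------------------------------------

def _sphere_kernel_fft(padded_shape, voxel_size_mm, radius_mm) -> np.ndarray:
    """FFT of a normalized sphere of given physical radius, centred at the
    origin of a padded grid (linear antialiasing at the shell)."""
    coords = []
    for n, h in zip(padded_shape, voxel_size_mm):
        c = (np.arange(n) + n // 2) % n - n // 2
        coords.append(c * h)
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    dist = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    h_min = min(voxel_size_mm)
    ker = np.clip((radius_mm + 0.5 * h_min - dist) / h_min, 0.0, 1.0)
    ker /= ker.sum()
    return np.fft.fftn(ker)


def sharp_remove_background(freq: VolumeGrid, mask: BinaryMask,
                            max_radius_mm: float = 4.0,
                            regularization: float = 0.05,
                            n_completion: int = 0,
                            ) -> tuple[VolumeGrid, BinaryMask]:
    """V-SHARP: spherical-mean-value filtering with kernels shrinking from
    ``max_radius_mm`` down to 1 voxel near the mask edge, followed by
    per-radius k-space deconvolution with TSVD truncation at
    ``regularization``. Returns (local field, validity mask).

    The SMV convolutions run on a 2x zero-padded grid; the deconvolution
    filter lives on the original grid, where — at the default 4 mm kernel
    and 0.5 mm voxels — the truncation threshold leaves every resolvable
    wavelength intact for the largest kernel. ``n_completion`` > 0 enables
    an optional Gerchberg-style data-completion iteration that
    re-synthesises the filtered field outside each validity region before
    inverse filtering instead of treating it as zero.
    """
    m = np.asarray(mask.data, bool)
    if not m.any():
        raise ValueError("empty brain mask")
    h_min = min(freq.voxel_size_mm)
    r_max_vox = max(1, int(np.ceil(max_radius_mm / h_min)))
    shape = freq.data.shape
    pshape = tuple(2 * n for n in shape)
    sl = tuple(slice(0, n) for n in shape)

    fpad = np.zeros(pshape)
    fpad[sl] = np.where(m, freq.data, 0.0)
    mpad = np.zeros(pshape)
    mpad[sl] = m
    F = np.fft.fftn(fpad)
    M = np.fft.fftn(mpad)

    local = np.zeros(shape)
    assigned = np.zeros(shape, bool)
    for r_vox in range(r_max_vox, 0, -1):
        K = _sphere_kernel_fft(pshape, freq.voxel_size_mm, r_vox * h_min)
        cover = np.fft.ifftn(K * M).real[sl]
        valid = m & (cover >= 1.0 - 1e-6)
        if not valid.any():
            continue
        new = valid & ~assigned
        if not new.any():
            assigned |= valid
            continue
        smv = (fpad - np.fft.ifftn(K * F).real)[sl]
        Ku = _sphere_kernel_fft(shape, freq.voxel_size_mm, r_vox * h_min)
        C = 1.0 - Ku
        inv = np.where(np.abs(C) >= regularization,
                       1.0 / np.where(C == 0, 1.0, C), 0.0)
        data = np.where(valid, smv, 0.0)
        g = np.fft.ifftn(inv * np.fft.fftn(data)).real
        for _ in range(n_completion):
            cg = np.fft.ifftn(C * np.fft.fftn(g)).real
            g = np.fft.ifftn(inv * np.fft.fftn(np.where(valid, smv, cg))).real
        local[new] = g[new]
        assigned |= valid
    if not assigned.any():
        raise ValueError("mask smaller than the smallest SHARP kernel")
    local = np.where(assigned, local, 0.0)
    return freq.with_data(local), BinaryMask(assigned, freq.voxel_size_mm)


def average_echo_fields(fields: list[VolumeGrid]) -> VolumeGrid:
    """Voxelwise arithmetic mean of per-echo frequency maps."""
    if len(fields) < 1:
        raise ValueError("need at least one field")
    ref = fields[0]
    for f in fields[1:]:
        ref.require_same_grid(f, "echo field")
    return ref.with_data(np.mean([f.data for f in fields], axis=0))


# ---------------------------------------------------------------------------
# Dipole inversion
# ---------------------------------------------------------------------------

def invert_dipole_lsqr(local_field: VolumeGrid, validity: BinaryMask,
                       field_strength_t: float,
                       config: PipelineConfig | None = None) -> InversionResult:
    """Masked dipole inversion: argmin_chi || M (F^-1 D F chi - b) ||_2
    solved with LSQR. Input field in Hz, output chi in ppb."""
    cfg = config if config is not None else PipelineConfig()
    m = np.asarray(validity.data, bool)
    if not m.any():
        raise ValueError("empty validity mask")
    shape = local_field.data.shape
    D = dipole_kernel(shape, local_field.voxel_size_mm)
    f_larmor = GYROMAGNETIC_RATIO_HZ_PER_T * field_strength_t
    b = (np.asarray(local_field.data, np.float64)[m] / (f_larmor * 1e-9))
    n_mask = int(m.sum())

    # chi is supported on the validity mask (sources outside it were removed
    # as background); this keeps the system square and well determined
    def matvec(x):
        vol = np.zeros(shape)
        vol[m] = x
        f = np.fft.ifftn(D * np.fft.fftn(vol)).real
        return f[m]

    A = LinearOperator((n_mask, n_mask), matvec=matvec, rmatvec=matvec,
                       dtype=np.float64)
    x, istop, itn, *_ = lsqr(A, b, atol=cfg.lsqr_tol, btol=cfg.lsqr_tol,
                             iter_lim=cfg.lsqr_max_iter)
    # istop 7 = iteration cap: expected, the cap is the regularizer for this
    # semiconvergent problem (documented in the methods note)
    converged = istop in (0, 1, 2, 7)
    if istop == 7:
        log.info("LSQR stopped at the %d-iteration cap (early-stopping "
                 "regularization)", itn)
    elif not converged:
        log.warning("LSQR aborted (istop=%d after %d iterations); "
                    "returning partial result", istop, itn)
    vol = np.zeros(shape)
    vol[m] = x
    chi = local_field.with_data(vol)
    return InversionResult(chi, converged, int(itn))


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------

def select_reference_region(roi_means: pd.DataFrame) -> str:
    """Pick the reference region: the candidate (column) with the lowest
    across-subject standard deviation of region-mean susceptibility.
    Ties break deterministically to the first label in sorted order."""
    if roi_means.shape[0] < 2 or roi_means.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 candidate regions")
    if roi_means.isna().any().any():
        raise ValueError("missing cells in the candidate-region table")
    sds = roi_means.std(axis=0, ddof=1)
    best = min(sorted(sds.index), key=lambda c: (sds[c], c))
    tied = [c for c in sds.index if sds[c] == sds[best] and c != best]
    if tied:
        log.info("reference-region tie between %s and %s; chose %s by label order",
                 best, tied, best)
    return str(best)


def reference_susceptibility(chi: VolumeGrid, labels: LabelMap, reference: str,
                             validity: BinaryMask | None = None,
                             erode_reference: int = 1) -> SusceptibilityMap:
    """Subtract the reference-region mean everywhere; the removed offset is
    recorded. Idempotent up to numerical tolerance.

    The reference mean is taken over the region eroded by
    ``erode_reference`` voxels (same partial-volume guard as the ROI
    means); if erosion empties it, the uneroded region is used.
    """
    chi.require_same_grid(labels, "labels")
    full_ref = labels.mask_of(reference).data
    if erode_reference > 0:
        eroded = ndimage.binary_erosion(
            full_ref, ndimage.generate_binary_structure(3, 1), erode_reference)
        ref_mask = eroded if eroded.any() else full_ref
    else:
        ref_mask = full_ref
    if validity is not None:
        ref_mask = ref_mask & validity.data
        if not ref_mask.any():
            ref_mask = full_ref & validity.data
    else:
        validity = BinaryMask(np.ones(chi.shape, bool), chi.voxel_size_mm)
    if not ref_mask.any():
        raise ValueError(f"reference region {reference!r} empty within validity mask")
    offset = float(chi.data[ref_mask].mean())
    out = np.where(validity.data, chi.data - offset, 0.0)
    return SusceptibilityMap(chi.with_data(out), validity, reference, offset)


# ---------------------------------------------------------------------------
# Full per-subject chain
# ---------------------------------------------------------------------------

@dataclass
class QsmIntermediates:
    unwrapped: list[VolumeGrid]
    brain_mask: BinaryMask
    local_fields: list[VolumeGrid]
    averaged_field: VolumeGrid


def reconstruct_qsm(me: MultiEchoPhase, config: PipelineConfig | None = None,
                    return_intermediates: bool = False):
    """Run unwrap -> mask -> frequency -> SHARP (per echo) -> average ->
    LSQR inversion on the configured echoes. Returns (chi ppb unreferenced,
    validity mask[, intermediates])."""
    cfg = config if config is not None else PipelineConfig()
    echoes = [e for e in cfg.echoes_used if e < me.n_echoes]
    if not echoes:
        raise ValueError("no configured echo available in the data")
    mask = compute_brain_mask(me.magnitude[echoes[0]], cfg.bet_fractional_threshold)
    unwrapped, locals_ = [], []
    validity = None
    for e in echoes:
        uw = unwrap_phase_laplacian(me.phase[e])
        unwrapped.append(uw)
        freq = phase_to_frequency(uw, me.echo_times_s[e])
        loc, val = sharp_remove_background(freq, mask, cfg.sharp_max_radius_mm,
                                           cfg.sharp_regularization)
        locals_.append(loc)
        validity = val if validity is None else BinaryMask(
            validity.data & val.data, val.voxel_size_mm)
    avg = average_echo_fields(locals_)
    inv = invert_dipole_lsqr(avg, validity, me.field_strength_t, cfg)
    if return_intermediates:
        return inv.chi, validity, QsmIntermediates(unwrapped, mask, locals_, avg)
    return inv.chi, validity
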