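"""Synthetic multi-modal cohort generator.

Builds a fully synthetic study population — susceptibility phantoms,
forward-simulated wrapped multi-echo GRE phase, amyloid-PET SUVR maps,
seed-coupled BOLD series and subject metadata — with the statistical
structure the downstream analysis assumes:

* regional susceptibility (ppb) and SUVR distributions parameterised per
  (group x APOE-e4) cell, subject-level means drawn from
  Normal(cell mean, cell STE * sqrt(n_cell));
* a Gaussian-copula coupling between each subject's susceptibility and
  SUVR deviations inside a designated frontomedial "colocalization"
  region, so the population Spearman correlation equals a requested value;
* BOLD seed coupling between an MPFC seed patch and the same frontomedial
  region, with amplitude largest in the (MCI ∧ high-iron) cell;
* a ventricular-CSF region simulated at zero offset from the global
  susceptibility baseline with the lowest between-subject variance among
  reference candidates, so the reference-selection rule picks it.

All generators are pure functions of (spec, seed): identical outputs on
repeat. Ground truth (latent regional means, true volumes, the coupled
region) is stored alongside the generated data and is only ever consumed
by tests, never by pipeline stages.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CORTICAL_LOBES,
    STRUCTURE_LABELS,
    STRUCTURE_NAMES,
    BinaryMask,
    LabelMap,
    MultiEchoPhase,
    SubjectRecord,
    VolumeGrid,
)
from . import io as qio

__all__ = [
    "CohortSpec",
    "Cohort",
    "GroundTruth",
    "PhantomLayout",
    "make_phantom_labels",
    "assign_susceptibility",
    "forward_dipole_field",
    "simulate_multiecho_phase",
    "simulate_pet",
    "simulate_bold",
    "simulate_bold_flat",
    "make_cohort",
    "sample_coupled_pairs",
    "spearman_to_pearson",
    "GYROMAGNETIC_RATIO_HZ_PER_T",
]

#: proton gyromagnetic ratio, Hz per Tesla
GYROMAGNETIC_RATIO_HZ_PER_T = 42.577e6

# ---------------------------------------------------------------------------
# Cell parameters: per-structure mean +/- standard error of the mean for
# susceptibility (ppb, referenced to ventricular CSF) and PiB SUVR, in the
# four (group x APOE-e4) cells of the emulated study population.
# Cell order: (control, e4-), (control, e4+), (mci, e4-), (mci, e4+).
# ---------------------------------------------------------------------------

CELLS = (("control", False), ("control", True), ("mci", False), ("mci", True))
CELL_N = {("control", False): 15, ("control", True): 7,
          ("mci", False): 9, ("mci", True): 6}

_CHI = {  # ppb, (mean, ste) per cell
    "amygdala":          ((-17.2, 2.5), (-15.3, 2.2), (-17.5, 1.8), (-17.2, 2.6)),
    "nucleus_accumbens": ((12.1, 4.1), (11.2, 3.2), (8.2, 4.9), (17.3, 4.7)),
    "hippocampus":       ((-1.4, 1.7), (-1.2, 2.1), (-2.0, 2.0), (1.5, 3.5)),
    "entorhinal_cortex": ((22.6, 5.1), (25.0, 2.6), (23.1, 3.4), (30.0, 2.5)),
    "thalamus":          ((-6.5, 1.9), (-10.5, 1.4), (-9.1, 1.4), (-8.5, 2.1)),
    "caudate_nucleus":   ((46.0, 3.7), (31.5, 5.5), (32.7, 2.0), (46.3, 4.5)),
    "putamen":           ((67.2, 4.3), (55.9, 5.3), (58.6, 3.7), (65.2, 4.0)),
    "globus_pallidus":   ((106.4, 5.0), (100.4, 5.7), (96.4, 3.3), (103.5, 6.3)),
    "frontal_cortex":    ((2.6, 1.9), (1.1, 2.0), (0.1, 1.6), (6.3, 2.2)),
    "temporal_cortex":   ((0.7, 1.6), (-0.6, 2.0), (0.0, 1.8), (5.2, 1.8)),
    "parietal_cortex":   ((4.1, 1.6), (2.7, 1.8), (1.3, 1.2), (8.1, 1.8)),
    "occipital_cortex":  ((4.0, 1.9), (2.9, 1.8), (1.5, 1.4), (7.2, 2.4)),
}

_SUVR = {  # dimensionless, (mean, ste) per cell
    "amygdala":          ((1.19, 0.02), (1.19, 0.02), (1.07, 0.02), (1.54, 0.03)),
    "nucleus_accumbens": ((1.17, 0.02), (1.23, 0.03), (1.16, 0.02), (2.41, 0.07)),
    "hippocampus":       ((1.25, 0.02), (1.31, 0.02), (1.14, 0.03), (1.42, 0.03)),
    "entorhinal_cortex": ((1.08, 0.02), (1.14, 0.01), (1.02, 0.03), (1.31, 0.03)),
    "thalamus":          ((1.48, 0.04), (1.48, 0.04), (1.46, 0.02), (1.80, 0.06)),
    "caudate_nucleus":   ((1.26, 0.03), (1.28, 0.03), (1.24, 0.04), (2.13, 0.09)),
    "putamen":           ((1.33, 0.02), (1.36, 0.01), (1.29, 0.01), (2.23, 0.05)),
    "globus_pallidus":   ((1.45, 0.02), (1.50, 0.04), (1.41, 0.03), (1.92, 0.06)),
    "frontal_cortex":    ((1.02, 0.03), (1.13, 0.04), (0.98, 0.05), (1.95, 0.10)),
    "temporal_cortex":   ((1.04, 0.02), (1.10, 0.04), (1.03, 0.02), (1.73, 0.07)),
    "parietal_cortex":   ((0.99, 0.02), (1.15, 0.05), (1.00, 0.03), (1.87, 0.09)),
    "occipital_cortex":  ((1.14, 0.03), (1.19, 0.04), (1.13, 0.02), (1.59, 0.08)),
}

# Structures outside the group tables: (mean, between-subject SD), same in
# every cell. Ventricular CSF gets the lowest between-subject SD so the
# reference-selection rule picks it; white matter is a small negative
# constant (myelin), with no anisotropy.
_CHI_FIXED = {
    "cerebellar_gray": (10.0, 3.0),
    "csf_ventricles": (0.0, 0.3),
    "white_matter": (-25.0, 2.0),
}
_SUVR_FIXED = {
    "cerebellar_gray": (1.0, 0.0),   # SUVR anchor
    "csf_ventricles": (0.4, 0.05),
    "white_matter": (1.3, 0.10),     # non-specific white-matter retention
}


def _cell_tables():
    chi, suvr = {}, {}
    for s in _CHI:
        chi[s] = {c: (m, e * math.sqrt(CELL_N[c]))
                  for c, (m, e) in zip(CELLS, _CHI[s])}
        suvr[s] = {c: (m, e * math.sqrt(CELL_N[c]))
                   for c, (m, e) in zip(CELLS, _SUVR[s])}
    for s, ms in _CHI_FIXED.items():
        chi[s] = {c: ms for c in CELLS}
    for s, ms in _SUVR_FIXED.items():
        suvr[s] = {c: ms for c in CELLS}
    # the MPFC seed patch is frontomedial cortex: reuse the frontal cell values
    chi["mpfc_seed"] = dict(chi["frontal_cortex"])
    suvr["mpfc_seed"] = dict(suvr["frontal_cortex"])
    return chi, suvr


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman rank
    correlation equals ``rho_s`` (rho_s = (6/pi) asin(r/2))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@dataclass
class CohortSpec:
    """All knobs of the synthetic cohort; defaults are the emulated study
    conditions (37 subjects, 3-echo GRE at 6/12/18 ms and 7 T, cell means
    and standard errors of the group tables, frontomedial chi-SUVR rank
    coupling 0.86 in MCI)."""

    n_control: int = 22
    n_mci: int = 15
    apoe_rate_control: float = 7 / 22
    apoe_rate_mci: float = 6 / 15
    #: per-structure (mean, between-subject SD) per (group, apoe) cell
    chi_params: dict = field(default_factory=lambda: _cell_tables()[0])
    suvr_params: dict = field(default_factory=lambda: _cell_tables()[1])
    #: target Spearman rank coupling of chi and SUVR deviations in the
    #: colocalization region, per group
    coupling: dict = field(default_factory=lambda: {"control": 0.0, "mci": 0.86})
    coupled_structures: tuple[str, ...] = ("frontal_cortex", "mpfc_seed")
    # susceptibility volume composition
    baseline_chi_ppb: float = 5.8        # global offset; CSF sits on it
    baseline_sd_ppb: float = 1.0         # between-subject baseline variation
    chi_texture_sd_ppb: float = 1.0      # within-structure voxel texture
    background_chi_ppb: float = 9000.0   # air-like source outside the brain
    # acquisition
    echo_times_s: tuple[float, ...] = (0.006, 0.012, 0.018)
    field_strength_t: float = 7.0
    phase_snr: float = 50.0
    # PET
    pet_texture_sd: float = 0.03
    # BOLD
    tr_s: float = 2.0
    n_frames: int = 210
    bold_noise_sd: float = 1.0
    #: coupling amplitude of the frontomedial target onto the seed latent,
    #: per (group, iron-class) cell; 0.75 gives a pre-filter voxel r ~ 0.6
    bold_alpha: dict = field(default_factory=lambda: {
        ("control", "low"): 0.0, ("control", "high"): 0.0,
        ("mci", "low"): 0.0, ("mci", "high"): 0.75,
    })
    seed_voxel_noise_sd: float = 0.3
    confound_leak: float = 0.2
    # geometry
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_mci <= 0:
            raise ValueError("group sizes must be positive")
        for r in (self.apoe_rate_control, self.apoe_rate_mci):
            if not (0.0 <= r <= 1.0):
                raise ValueError("APOE rates must lie in [0, 1]")
        for g, c in self.coupling.items():
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling for {g} must lie in [0, 1]")
        if self.n_frames <= 0:
            raise ValueError("BOLD series length must be positive")
        if self.phase_snr <= 0:
            raise ValueError("phase snr must be positive")

    @classmethod
    def smoke(cls, seed: int = 0) -> "CohortSpec":
        """Tiny 2+2-subject 16^3 cohort that runs in seconds."""
        return cls(n_control=2, n_mci=2, shape=(16, 16, 16),
                   voxel_size_mm=(1.0, 1.0, 1.0), n_frames=64, seed=seed)


@dataclass
class GroundTruth:
    """Latent truth for one subject; consumed only by tests."""

    subject_id: str
    chi_means_ppb: dict          # referenced to the true CSF mean
    chi_abs_means_ppb: dict      # including the global baseline
    suvr_means: dict
    baseline_ppb: float
    iron_latent: float           # the copula latent u driving coupled chi
    cortical_chi_ppb: float      # voxel-weighted mean over the 4 lobes
    cortical_suvr: float
    iron_class: str = ""         # filled after the cohort-wide median split


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

# Structure placement in normalized brain coordinates u = (x - c) / brain_radii:
# center u, radii as fractions of the brain semi-axes. Bilateral structures
# are mirrored in +/- x.
# Quantified nuclei keep semi-axes >= ~3 voxels on the default 64-grid so a
# 2-voxel ROI erosion leaves a usable core, and sit clear of the maximum
# SHARP kernel's rim (resolvability rule; see the methods note).
_BILATERAL = {
    "thalamus": ((0.22, -0.08, 0.05), (0.16, 0.18, 0.16)),
    "caudate_nucleus": ((0.23, 0.22, 0.20), (0.13, 0.18, 0.14)),
    "putamen": ((0.42, 0.10, 0.02), (0.13, 0.19, 0.15)),
    "globus_pallidus": ((0.26, 0.03, -0.05), (0.12, 0.14, 0.13)),
    "nucleus_accumbens": ((0.16, 0.40, -0.14), (0.12, 0.13, 0.12)),
    "amygdala": ((0.38, 0.26, -0.30), (0.14, 0.14, 0.13)),
    "hippocampus": ((0.44, -0.15, -0.26), (0.11, 0.22, 0.11)),
    "entorhinal_cortex": ((0.40, 0.10, -0.42), (0.13, 0.13, 0.12)),
    "csf_ventricles": ((0.08, 0.02, 0.14), (0.08, 0.26, 0.11)),
}
_MPFC = ((0.0, 0.72, 0.10), (0.16, 0.22, 0.18))
_BRAIN_FRAC = (0.40, 0.44, 0.38)      # brain semi-axes as fraction of shape
_SHELL_INNER = 0.82                   # cortical shell: SHELL_INNER < |u| <= 1
_SINUS = ((0.0, 0.85, -1.10), (0.22, 0.18, 0.18))  # background source, brain coords


@dataclass
class PhantomLayout:
    labels: LabelMap
    brain_mask: BinaryMask        # the "intracranial" ellipsoid
    background_mask: BinaryMask   # air-like source outside the brain


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return ((x - center[0]) ** 2 / radii[0] ** 2
            + (y - center[1]) ** 2 / radii[1] ** 2
            + (z - center[2]) ** 2 / radii[2] ** 2) <= 1.0


def make_phantom_labels(shape, voxel_size_mm=(0.5, 0.5, 0.5), seed: int = 0) -> PhantomLayout:
    """Deterministic geometric phantom containing every known structure.

    Ellipsoidal nuclei, a 4-lobe cortical shell, ventricular CSF, a
    cerebellar patch, an MPFC seed patch and white-matter filler inside an
    ellipsoidal intracranial mask, plus an air-like background source
    outside it. Structures are mutually exclusive; for grids of at least
    48 voxels per axis every structure occupies >= 50 voxels, and on any
    admissible grid every label is present.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError(f"grid {shape} too small to place all structures (need >= 16 per axis)")
    rng = np.random.default_rng(seed)
    center = np.array([(s - 1) / 2.0 for s in shape])
    brain_r = np.array([f * s for f, s in zip(_BRAIN_FRAC, shape)])
    idx = np.indices(shape, dtype=np.float64)
    # normalized brain coordinates
    u = [(idx[a] - center[a]) / brain_r[a] for a in range(3)]
    rho = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    brain = rho <= 1.0

    lab = np.zeros(shape, np.int32)
    L = STRUCTURE_LABELS
    lab[brain] = L["white_matter"]

    # cortical shell split into lobes; cerebellum carved first
    shell = brain & (rho > _SHELL_INNER)
    cereb = brain & (rho > 0.55) & (u[1] < -0.45) & (u[2] < -0.35)
    lab[cereb] = L["cerebellar_gray"]
    lobes = shell & ~cereb
    lab[lobes & (u[1] > 0.30)] = L["frontal_cortex"]
    lab[lobes & (u[1] < -0.45)] = L["occipital_cortex"]
    mid = lobes & (u[1] >= -0.45) & (u[1] <= 0.30)
    lab[mid & (u[2] > 0.10)] = L["parietal_cortex"]
    lab[mid & (u[2] <= 0.10)] = L["temporal_cortex"]

    def jitter(vec, scale):
        return tuple(v + rng.uniform(-scale, scale) for v in vec)

    # bilateral deep structures and ventricles (painted over WM / each other
    # in a fixed order; the later paint wins, keeping labels exclusive).
    # Ventricles go last so the CSF reference region stays compact instead
    # of being carved into thin sheets by the surrounding nuclei.
    order = ["thalamus", "caudate_nucleus", "putamen",
             "globus_pallidus", "nucleus_accumbens", "amygdala",
             "hippocampus", "entorhinal_cortex", "csf_ventricles"]
    for name in order:
        c0, r0 = _BILATERAL[name]
        for sx in (+1.0, -1.0):
            c = jitter((sx * c0[0], c0[1], c0[2]), 0.02)
            r = tuple(rv * rng.uniform(0.97, 1.03) for rv in r0)
            body = _ellipsoid(u, c, r) & brain
            lab[body] = L[name]

    # MPFC seed patch, painted last
    c = jitter(_MPFC[0], 0.02)
    lab[_ellipsoid(u, c, _MPFC[1]) & brain] = L["mpfc_seed"]

    # guarantee presence of every label (centers may fall between voxels on
    # very small grids)
    for name, lbl in L.items():
        if not np.any(lab == lbl):
            if name in _BILATERAL:
                c0 = _BILATERAL[name][0]
            elif name == "mpfc_seed":
                c0 = _MPFC[0]
            else:
                c0 = (0.0, 0.0, 0.0)
            vox = np.clip(np.rint(center + np.array(c0) * brain_r * 0.8).astype(int),
                          0, np.array(shape) - 1)
            lab[tuple(vox)] = lbl

    labels = LabelMap(lab, voxel_size_mm, dict(STRUCTURE_NAMES))
    if min(shape) >= 48:
        counts = {nm: int((lab == lb).sum()) for nm, lb in L.items()}
        small = {nm: c for nm, c in counts.items() if c < 50}
        if small:  # pragma: no cover - geometry is tuned to avoid this
            raise ValueError(f"structures below 50 voxels on a >=48 grid: {small}")

    background = _ellipsoid(u, _SINUS[0], _SINUS[1]) & ~brain
    # keep it inside the grid; on tiny grids it may be empty, which is fine
    return PhantomLayout(labels, BinaryMask(brain, voxel_size_mm),
                         BinaryMask(background, voxel_size_mm))


# ---------------------------------------------------------------------------
# Latent subject means (the Gaussian-copula core)
# ---------------------------------------------------------------------------

def _sample_subject_means(subject: SubjectRecord, spec: CohortSpec,
                          rng: np.random.Generator) -> tuple[dict, dict, float, float]:
    """Draw per-structure chi (referenced, ppb) and SUVR means for one
    subject. Coupled structures share a single iron latent u; their SUVR
    deviations use v = r*u + sqrt(1-r^2)*eps with r chosen so the
    population Spearman correlation equals the group's coupling."""
    cell = (subject.group, subject.apoe_e4)
    for table, what in ((spec.chi_params, "chi"), (spec.suvr_params, "SUVR")):
        missing = [s for s in STRUCTURE_LABELS if cell not in table.get(s, {})]
        if missing:
            raise ValueError(f"missing {what} cell parameters for {cell}: {missing}")
    rho_s = spec.coupling[subject.group]
    r = spearman_to_pearson(rho_s)
    u = rng.standard_normal()
    v = r * u + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal()
    chi, suvr = {}, {}
    for name in STRUCTURE_LABELS:
        cm, cs = spec.chi_params[name][cell]
        z = u if name in spec.coupled_structures else rng.standard_normal()
        chi[name] = cm + cs * z
        sm, ss = spec.suvr_params[name][cell]
        z2 = v if name in spec.coupled_structures else rng.standard_normal()
        suvr[name] = sm + ss * z2
    return chi, suvr, u, rho_s


def sample_coupled_pairs(n: int, coupling: float, group: str = "mci",
                         apoe: bool = False, spec: CohortSpec | None = None,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Latent (chi, SUVR) frontomedial means for ``n`` subjects drawn from a
    single (group, APOE) cell with the given rank coupling; used to verify
    the copula calibration without building any volumes."""
    spec = spec if spec is not None else CohortSpec()
    spec = replace(spec, coupling={**spec.coupling, group: coupling})
    rng = np.random.default_rng(seed)
    subj = SubjectRecord("latent", group, apoe, 70.0, "F")
    chis = np.empty(n)
    suvrs = np.empty(n)
    for i in range(n):
        chi, suvr, _, _ = _sample_subject_means(subj, spec, rng)
        chis[i] = chi["frontal_cortex"]
        suvrs[i] = suvr["frontal_cortex"]
    return chis, suvrs


# ---------------------------------------------------------------------------
# Volume synthesis
# ---------------------------------------------------------------------------

def assign_susceptibility(layout: PhantomLayout, chi_means: dict, baseline: float,
                          spec: CohortSpec, rng: np.random.Generator) -> VolumeGrid:
    """Paint the absolute susceptibility volume (ppb): per-structure mean +
    baseline + small voxel texture inside the brain; the air-like
    background source outside it; 0 elsewhere."""
    lab = layout.labels.data
    chi = np.zeros(lab.shape, np.float64)
    for name, lbl in STRUCTURE_LABELS.items():
        m = lab == lbl
        if not m.any():
            continue
        chi[m] = baseline + chi_means[name]
        if spec.chi_texture_sd_ppb > 0:
            chi[m] += spec.chi_texture_sd_ppb * rng.standard_normal(int(m.sum()))
    chi[layout.background_mask.data] = spec.background_chi_ppb
    return VolumeGrid(chi, layout.labels.voxel_size_mm)


def dipole_kernel(shape, voxel_size_mm) -> np.ndarray:
    """k-space dipole kernel D(k) = 1/3 - kz^2/|k|^2, with D(0) = 0.

    B0 is along the third (z) axis; k in cycles/mm from the grid spacing.
    """
    ks = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, voxel_size_mm)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij", sparse=True)
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kz ** 2 / k2
    d[0, 0, 0] = 0.0
    return d


def forward_dipole_field(chi: VolumeGrid, field_strength_t: float) -> VolumeGrid:
    """Frequency shift (Hz) induced by a susceptibility distribution (ppb):
    df = f_larmor * IFFT[ D(k) * FFT(chi * 1e-9) ]."""
    data = np.asarray(chi.data, np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("susceptibility volume contains non-finite values")
    d = dipole_kernel(data.shape, chi.voxel_size_mm)
    f_larmor = GYROMAGNETIC_RATIO_HZ_PER_T * field_strength_t
    shift = np.fft.ifftn(d * np.fft.fftn(data * 1e-9)).real * f_larmor
    return chi.with_data(shift)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.angle(np.exp(1j * phi))
    w[w <= -np.pi] += 2 * np.pi
    return w


def simulate_multiecho_phase(delta_f: VolumeGrid, echo_times_s, snr: float,
                             seed: int = 0, field_strength_t: float = 7.0,
                             envelope: np.ndarray | None = None) -> MultiEchoPhase:
    """Wrapped multi-echo phase from a frequency-shift map.

    The complex signal has magnitude ``envelope`` (1 by default) with
    circular Gaussian noise of sd 1/snr per channel; phase(TE) =
    wrap(2*pi*df*TE). ``snr=inf`` gives noiseless data.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    env = np.ones(delta_f.shape) if envelope is None else np.asarray(envelope, np.float64)
    phases, mags = [], []
    for te in echo_times_s:
        phi = 2 * np.pi * delta_f.data * te
        signal = env * np.exp(1j * phi)
        if np.isfinite(snr):
            noise_sd = 1.0 / snr
            signal = signal + noise_sd * (
                rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
            )
        p = np.angle(signal)
        p[p <= -np.pi] += 2 * np.pi
        phases.append(delta_f.with_data(p))
        mags.append(delta_f.with_data(np.abs(signal)))
    return MultiEchoPhase(phases, tuple(echo_times_s), field_strength_t, mags)


def simulate_pet(layout: PhantomLayout, suvr_means: dict, spec: CohortSpec,
                 rng: np.random.Generator) -> VolumeGrid:
    """SUVR volume: per-structure latent mean plus voxel texture, then
    anchored so the cerebellar-gray mean is exactly 1."""
    lab = layout.labels.data
    cereb = lab == STRUCTURE_LABELS["cerebellar_gray"]
    if not cereb.any():
        raise ValueError("cerebellar gray label missing: cannot anchor SUVR")
    vol = np.zeros(lab.shape, np.float64)
    for name, lbl in STRUCTURE_LABELS.items():
        m = lab == lbl
        if not m.any():
            continue
        vol[m] = suvr_means[name]
        if spec.pet_texture_sd > 0:
            vol[m] += spec.pet_texture_sd * rng.standard_normal(int(m.sum()))
    cereb_mean = vol[cereb].mean()
    if cereb_mean == 0:
        raise ValueError("cerebellar mean is zero; cannot normalize")
    vol[lab > 0] /= cereb_mean
    np.clip(vol, 0.0, None, out=vol)
    return VolumeGrid(vol, layout.labels.voxel_size_mm)


def bandlimited_series(n_frames: int, tr_s: float, low_hz: float, high_hz: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance series with power confined to [low, high] Hz."""
    freqs = np.fft.rfftfreq(n_frames, d=tr_s)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    spec_c = np.zeros(freqs.size, np.complex128)
    spec_c[band] = rng.standard_normal(int(band.sum())) + 1j * rng.standard_normal(int(band.sum()))
    s = np.fft.irfft(spec_c, n=n_frames)
    s -= s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def simulate_bold_flat(layout: PhantomLayout, group: str, iron_class: str,
                       spec: CohortSpec, seed: int = 0,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Brain-voxel BOLD series as an (n_brain, t) float32 array plus the
    confound table; rows follow ``layout.labels.data[brain]`` order. The
    memory-light core behind :func:`simulate_bold`."""
    if spec.n_frames <= 0:
        raise ValueError("series length must be positive")
    if iron_class not in ("high", "low"):
        raise ValueError(f"iron_class must be high|low, got {iron_class!r}")
    rng = np.random.default_rng(seed)
    lab = layout.labels.data
    seed_mask = lab == STRUCTURE_LABELS["mpfc_seed"]
    if not seed_mask.any():
        raise ValueError("MPFC seed label missing")
    brain = lab > 0
    n_t = spec.n_frames

    latent = bandlimited_series(n_t, spec.tr_s, 0.01, 0.1, rng)
    motion = np.cumsum(0.2 * rng.standard_normal((6, n_t)), axis=1)
    motion -= motion.mean(axis=1, keepdims=True)
    msd = motion.std(axis=1, keepdims=True)
    msd[msd == 0] = 1.0
    motion /= msd

    n_brain = int(brain.sum())
    series = rng.standard_normal((n_brain, n_t)).astype(np.float32)
    series *= np.float32(spec.bold_noise_sd)
    leak_w = spec.confound_leak * rng.standard_normal((n_brain, 6))
    series += (leak_w @ motion).astype(np.float32)

    flat_lab = lab[brain]
    target_names = [s for s in spec.coupled_structures if s != "mpfc_seed"]
    target_sel = np.isin(flat_lab, [STRUCTURE_LABELS[s] for s in target_names])
    alpha = spec.bold_alpha[(group, iron_class)]
    if alpha:
        series[target_sel] += np.float32(alpha) * latent.astype(np.float32)
    seed_sel = flat_lab == STRUCTURE_LABELS["mpfc_seed"]
    series[seed_sel] = (latent.astype(np.float32)
                        + np.float32(spec.seed_voxel_noise_sd)
                        * rng.standard_normal((int(seed_sel.sum()), n_t)).astype(np.float32))

    conf = {f"motion_{i + 1}": motion[i] for i in range(6)}
    csf_sel = flat_lab == STRUCTURE_LABELS["csf_ventricles"]
    wm_sel = flat_lab == STRUCTURE_LABELS["white_matter"]
    conf["csf"] = series[csf_sel].mean(axis=0) if csf_sel.any() else np.zeros(n_t)
    conf["wm"] = series[wm_sel].mean(axis=0) if wm_sel.any() else np.zeros(n_t)
    return series, pd.DataFrame(conf)


def simulate_bold(layout: PhantomLayout, group: str, iron_class: str,
                  spec: CohortSpec, seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """4D BOLD series (x, y, z, t, float32) plus a confound table.

    The MPFC seed carries a 0.01-0.1 Hz band-limited latent; frontomedial
    target voxels carry alpha * latent + noise with alpha from the
    (group x iron-class) cell; every brain voxel leaks a little of the
    synthetic motion confounds. Outside the brain the series is zero.
    """
    series, conf = simulate_bold_flat(layout, group, iron_class, spec, seed)
    brain = layout.labels.data > 0
    data = np.zeros(layout.labels.data.shape + (series.shape[1],), np.float32)
    data[brain] = series
    return data, conf


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """In-memory cohort handle: metadata plus deterministic per-subject
    volume generators (volumes are re-created on demand from stored seeds,
    so large modalities never need to be held simultaneously)."""

    spec: CohortSpec
    layout: PhantomLayout
    subjects: list[SubjectRecord]
    truth: dict[str, GroundTruth]
    _subject_seeds: dict[str, dict[str, int]]

    @property
    def labels(self) -> LabelMap:
        return self.layout.labels

    def record(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def chi_volume(self, subject_id: str) -> VolumeGrid:
        t = self.truth[subject_id]
        rng = np.random.default_rng(self._subject_seeds[subject_id]["chi"])
        return assign_susceptibility(self.layout, t.chi_means_ppb, t.baseline_ppb,
                                     self.spec, rng)

    def chi_referenced_truth(self, subject_id: str) -> VolumeGrid:
        """True susceptibility volume referenced to the CSF structure mean."""
        vol = self.chi_volume(subject_id)
        csf = self.layout.labels.data == STRUCTURE_LABELS["csf_ventricles"]
        out = vol.data - vol.data[csf].mean()
        out[~self.layout.brain_mask.data] = 0.0
        return vol.with_data(out)

    def suvr_volume(self, subject_id: str) -> VolumeGrid:
        t = self.truth[subject_id]
        rng = np.random.default_rng(self._subject_seeds[subject_id]["pet"])
        return simulate_pet(self.layout, t.suvr_means, self.spec, rng)

    def phase(self, subject_id: str) -> MultiEchoPhase:
        chi = self.chi_volume(subject_id)
        field = forward_dipole_field(chi, self.spec.field_strength_t)
        return simulate_multiecho_phase(
            field, self.spec.echo_times_s, self.spec.phase_snr,
            seed=self._subject_seeds[subject_id]["phase"],
            field_strength_t=self.spec.field_strength_t,
            envelope=self.layout.brain_mask.data.astype(np.float64),
        )

    def bold(self, subject_id: str) -> tuple[np.ndarray, pd.DataFrame]:
        rec = self.record(subject_id)
        t = self.truth[subject_id]
        return simulate_bold(self.layout, rec.group, t.iron_class, self.spec,
                             seed=self._subject_seeds[subject_id]["bold"])

    def bold_flat(self, subject_id: str) -> tuple[np.ndarray, pd.DataFrame]:
        """(n_brain, t) series + confounds, rows in brain-mask order."""
        rec = self.record(subject_id)
        t = self.truth[subject_id]
        return simulate_bold_flat(self.layout, rec.group, t.iron_class, self.spec,
                                  seed=self._subject_seeds[subject_id]["bold"])

    def coupled_region_mask(self) -> BinaryMask:
        lab = self.layout.labels.data
        sel = np.isin(lab, [STRUCTURE_LABELS[s] for s in self.spec.coupled_structures])
        return BinaryMask(sel, self.layout.labels.voxel_size_mm)


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def make_cohort(spec: CohortSpec, out_dir=None, write_bold: bool = True) -> Cohort:
    """Generate the cohort; optionally write the full tree to ``out_dir``:
    ``sub-XXX/{phase_e*,mag_e*,pet_suvr,bold,labels}.nii.gz + confounds.tsv``
    plus ``participants.tsv`` and ``ground_truth/``.
    """
    root = np.random.SeedSequence(spec.seed)
    meta_ss, phantom_ss, *rest = root.spawn(2 + spec.n_control + spec.n_mci)
    meta_rng = np.random.default_rng(meta_ss)
    layout = make_phantom_labels(spec.shape, spec.voxel_size_mm,
                                 seed=int(phantom_ss.generate_state(1)[0] % (2 ** 31)))

    # subject metadata: exact APOE-carrier and gender counts, shuffled
    subjects: list[SubjectRecord] = []
    for group, n, apoe_rate, f_frac, age_m, age_sd in (
        ("control", spec.n_control, spec.apoe_rate_control, 8 / 22, 72.0, 5.0),
        ("mci", spec.n_mci, spec.apoe_rate_mci, 5 / 15, 75.0, 8.0),
    ):
        n_apoe = int(round(apoe_rate * n))
        n_f = int(round(f_frac * n))
        apoe_flags = np.zeros(n, bool)
        apoe_flags[meta_rng.permutation(n)[:n_apoe]] = True
        genders = np.array(["M"] * n)
        genders[meta_rng.permutation(n)[:n_f]] = "F"
        for i in range(n):
            sid = f"sub-{len(subjects) + 1:03d}"
            age = _truncated_normal(meta_rng, age_m, age_sd, 62.0, 89.0)
            subjects.append(SubjectRecord(sid, group, bool(apoe_flags[i]),
                                          round(age, 1), str(genders[i])))

    # latent regional means per subject
    lab = layout.labels.data
    counts = {nm: int((lab == lb).sum()) for nm, lb in STRUCTURE_LABELS.items()}
    truth: dict[str, GroundTruth] = {}
    subject_seeds: dict[str, dict[str, int]] = {}
    for rec, ss in zip(subjects, rest):
        means_ss, chi_ss, phase_ss, pet_ss, bold_ss = ss.spawn(5)
        rng = np.random.default_rng(means_ss)
        chi_means, suvr_means, u, _ = _sample_subject_means(rec, spec, rng)
        baseline = spec.baseline_chi_ppb + spec.baseline_sd_ppb * rng.standard_normal()
        csf = chi_means["csf_ventricles"]
        chi_ref = {k: v - csf for k, v in chi_means.items()}
        w = np.array([counts[s] for s in CORTICAL_LOBES], float)
        cort_chi = float(np.average([chi_ref[s] for s in CORTICAL_LOBES], weights=w))
        cort_suvr = float(np.average([suvr_means[s] for s in CORTICAL_LOBES], weights=w))
        truth[rec.subject_id] = GroundTruth(
            rec.subject_id, chi_ref,
            {k: baseline + v for k, v in chi_means.items()},
            suvr_means, baseline, u, cort_chi, cort_suvr)
        subject_seeds[rec.subject_id] = {
            name: int(s.generate_state(1)[0] % (2 ** 31))
            for name, s in zip(("chi", "phase", "pet", "bold"),
                               (chi_ss, phase_ss, pet_ss, bold_ss))
        }

    # cohort-wide median split of true cortical susceptibility -> iron class
    vals = np.array([truth[s.subject_id].cortical_chi_ppb for s in subjects])
    thr = float(np.median(vals))
    for s in subjects:
        t = truth[s.subject_id]
        t.iron_class = "high" if t.cortical_chi_ppb > thr else "low"

    cohort = Cohort(spec, layout, subjects, truth, subject_seeds)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qio.write_subject_table(subjects, out / "participants.tsv")
        gt_dir = out / "ground_truth"
        gt_dir.mkdir(exist_ok=True)
        for rec in subjects:
            sdir = out / rec.subject_id
            sdir.mkdir(exist_ok=True)
            qio.write_label_map(layout.labels, sdir / "labels.nii.gz")
            phase = cohort.phase(rec.subject_id)
            for e in range(phase.n_echoes):
                qio.write_volume(phase.phase[e], sdir / f"phase_e{e + 1}.nii.gz", "wrapped phase, rad")
                qio.write_volume(phase.magnitude[e], sdir / f"mag_e{e + 1}.nii.gz", "magnitude, a.u.")
            qio.write_volume(cohort.suvr_volume(rec.subject_id),
                             sdir / "pet_suvr.nii.gz", "PiB SUVR")
            if write_bold:
                bold, conf = cohort.bold(rec.subject_id)
                qio.write_series(bold, spec.voxel_size_mm, sdir / "bold.nii.gz")
                conf.to_csv(sdir / "confounds.tsv", sep="\t", index=False,
                            float_format="%.6f")
            qio.write_volume(cohort.chi_referenced_truth(rec.subject_id),
                             gt_dir / f"{rec.subject_id}_chi_true.nii.gz",
                             "true chi (ppb, CSF-referenced)")
        qio.write_mask(cohort.coupled_region_mask(), gt_dir / "coupled_region.nii.gz")
        latents = {
            sid: {"chi_means_ppb": t.chi_means_ppb, "suvr_means": t.suvr_means,
                  "baseline_ppb": t.baseline_ppb, "iron_latent": t.iron_latent,
                  "cortical_chi_ppb": t.cortical_chi_ppb,
                  "cortical_suvr": t.cortical_suvr, "iron_class": t.iron_class}
            for sid, t in truth.items()
        }
        (gt_dir / "latents.json").write_text(json.dumps(latents, indent=1, sort_keys=True))
    return cohort
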