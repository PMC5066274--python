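# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. It states only behaviour that the
test suite or `scripts/acceptance.py` actually compute.

## The analysis in one paragraph

Tissue magnetic susceptibility χ (in ppb, a proxy for gray-matter iron) is
reconstructed per subject from wrapped multi-echo GRE phase; amyloid-β
plaque load is quantified as PiB-PET SUVR normalized to cerebellar gray;
resting-state BOLD gives a seed-to-voxel coupling map of the medial
prefrontal cortex (MPFC). A voxelwise group model over the
(MCI × iron-class) design defines an FDR-thresholded mask of elevated
coupling; mean χ and mean SUVR inside that mask are then correlated across
MCI subjects (Spearman ρ, adjusted R²) and stratified by APOE-ε4 status.
Iron class is the cohort-wide median split of mean cortical gray-matter χ.

## Synthetic cohort: what it emulates, and what it does not

The generator (`qsmcoloc.cohort`) replaces unavailable subject data. Its
defaults are the emulated study conditions:

* 22 controls and 15 MCI subjects; APOE-ε4 carriers 7/22 and 6/15
  (assigned exactly, shuffled); genders 8F/14M and 5F/10M; ages
  Normal(72, 5) / Normal(75, 8) truncated to [62, 89].
* Per-structure regional means of χ and SUVR are drawn per
  (group × APOE-ε4) cell as Normal(cell mean, cell STE × √n_cell), with
  n_cell = 15/7/9/6 — the tables the analysis is meant to reproduce print
  standard errors, so the SD is reconstituted from them.
* χ–SUVR coupling: within a designated frontomedial colocalization region
  (frontal cortical shell + MPFC patch), each subject's χ deviation is a
  latent u ~ N(0,1) and the SUVR deviation uses
  v = r·u + √(1−r²)·ε with r = 2 sin(π ρ*/6), so the population Spearman
  correlation equals the target ρ* (0.86 in MCI, 0 in controls). The
  calibration is exact within one cell; the acceptance script verifies
  ρ̂ at n = 2000. Across a mixed cohort the APOE main effect adds to the
  rank correlation, as in the real data.
* Acquisition: 3 echoes at TE = 6/12/18 ms, 7 T, complex signal of unit
  magnitude inside the brain with circular Gaussian noise of SD 1/SNR per
  channel (default SNR 50); phase wrapped to (−π, π].
* Geometry: a 64³ grid at 0.5 mm voxels holds an ellipsoidal "brain" with
  a 4-lobe cortical shell, ellipsoidal nuclei, ventricular CSF, a
  cerebellar patch, an MPFC patch and white-matter filler, plus an
  air-like background source (χ = 9 ppm) outside the brain that produces
  phase wraps and a background field ~20× the internal fields.
  Quantified nuclei have semi-axes of at least ~3 voxels so that a
  2-voxel ROI erosion leaves a usable core (resolvability rule), and the
  ventricles are painted last so the CSF reference region is compact.
  Wrap gradients stay below π per voxel (verified during design).
* Ventricular CSF is simulated at zero offset from the global χ baseline
  (5.8 ppb) with the smallest between-subject SD (0.3 ppb) among the
  reference candidates, so the reference-selection rule picks it; white
  matter is a constant −25 ppb (myelin treated as isotropic and, for the
  gray-matter questions asked here, negligible).
* BOLD: 210 frames at TR = 2 s. The MPFC seed carries a band-limited
  (0.01–0.1 Hz) latent; frontomedial target voxels add α·latent with
  α = 0.75 (pre-filter voxel correlation ≈ 0.6) only in the
  MCI ∧ high-iron cell; all brain voxels receive unit-SD noise and a small
  leak of the six synthetic motion confounds; CSF/WM mean series complete
  the confound table.

Not emulated: realistic anatomy, registration/motion/distortion artifacts,
PET kinetics, scanner reconstruction. Passing tests therefore demonstrate
the correctness and calibration of the *algorithms* under controlled
conditions, not robustness to real-data nuisances.

## QSM chain: numerical choices

* **Unwrapping.** ∇²φᵤ = cos φ·∇²sin φ − sin φ·∇²cos φ, with the discrete
  6-neighbour Laplacian and its exact spectral inverse in the DCT-II
  (mirrored-boundary) basis; the zero-frequency coefficient is set to 0.
  Mirroring, rather than zero-padding, avoids boundary jumps in the sin/cos
  fields; a 6π ramp is recovered with interior error < 0.1 rad.
* **Brain mask.** Threshold at 0.3 × the 98th percentile of nonzero
  magnitude, largest connected component, hole filling — a deterministic
  stand-in for an external brain-extraction tool.
* **SHARP.** Variable spherical kernels with integer voxel radii from
  ⌈4 mm / voxel⌉ down to 1; a voxel uses the largest sphere that fits in
  the mask. Each radius is deconvolved by its own (δ − ρ_r) filter with
  TSVD truncation at 0.05 (the truncation-threshold reading of the
  "regularization parameter"; a Tikhonov variant was considered and
  rejected — see limitations). SMV convolutions run on a 2× zero-padded
  grid; the deconvolution filter is built on the original grid, where at
  0.5 mm voxels every nonzero spatial frequency of the 8-voxel kernel
  stays above the truncation threshold, so no resolvable content is
  zeroed for interior voxels. The validity mask is the set of voxels where
  at least the 1-voxel sphere fits.
* **Echo combination.** The 12 and 18 ms echoes are SHARP-processed
  separately and their local fields averaged (higher SNR than either
  echo alone), in that order.
* **Dipole inversion.** Plain masked least squares with the unknowns
  restricted to the validity mask, solved by LSQR with tolerance 1e-6 and
  an iteration cap of 40. Two deliberate choices: (i) restricting the
  unknown support is required — enlarging it makes the system
  underdetermined and the minimum-norm solution systematically shrinks
  compact structures; (ii) the iteration cap acts as the regularizer of
  this semiconvergent problem: running the solver to convergence fits the
  residual imperfections of the SHARP field and degrades ROI accuracy.
  D(0) = 0 leaves the global offset unobservable; referencing removes it.
* **Referencing.** Candidates are white-matter tracts and ventricular CSF;
  the candidate with the lowest across-subject SD of region-mean χ wins
  (ties break to the first label in sorted order, logged). The reference
  mean is computed on the region eroded by 1 voxel — the same
  partial-volume guard as the ROI means — because bleed from neighbouring
  structures into a thin CSF region would shift every referenced value.

## Connectivity and statistics

* Per-subject order is fixed: confound regression (OLS against intercept +
  6 motion + CSF + WM), then band-pass, then correlation. The band-pass is
  a zero-phase forward-backward 4th-order Butterworth (low-pass then
  high-pass, with even/odd boundary extensions respectively); mid-passband
  gain ≥ 0.95 and stopband (≤ low/2, ≥ 2·high) ≤ 0.05 — bounds a brick-wall
  FFT mask does not meet for off-bin contaminants.
* The group model is a 2×2 cell-means OLS per voxel with the one-sided
  contrast μ(MCI, high) − ⅓[μ(ctl, low) + μ(ctl, high) + μ(MCI, low)],
  equivalent to a positive (main effects + interaction) combination;
  voxelwise t statistics match a brute-force OLS oracle to 1e-8. BH
  correction is shared with the table statistics (`fdr_bh`). Analysis is
  restricted to gray matter (the seed is gray matter; WM and CSF inform
  the confounds). On cohorts too small to estimate four cells the model
  falls back to MCI ∧ high-iron vs rest, logged.
* Group tables use per-structure ANCOVA (value ~ group + age + gender) with
  BH across structures; the multivariate reading of the original analysis
  is deliberately not implemented because per-structure effects are what
  the reported tables contain. Cohen's d is computed on raw values.
  Type-I error of the ANCOVA under a permutation null is 3.9% at α = 0.05
  (1000 replicates, computed by the acceptance script).
* Median splits use the mid-value convention; "high" is strictly greater
  than the threshold, ties go low (logged).
* Odds ratios apply the Haldane–Anscombe +0.5 only when a zero cell is
  present, with a Wald log-scale 95% CI and Fisher's exact p on the raw
  counts. Spearman p-values are exact-permutation for n ≤ 10 (untied),
  t-approximate otherwise; adjusted R² comes from the OLS fit of y on x.
* The colocalization correlation is computed over MCI subjects only;
  "high/low" classifications reuse the cohort-wide (all-subject) medians.

## Problem sizes used by the tests and acceptance script

Phantom reconstructions run on the default 64³ grid (one subject for the
round-trip check); the copula calibration uses 2000 latent subjects; the
connectivity-recovery check runs full 37-subject cohorts over 10 seeds in
the test suite and 5 seeds in the acceptance script; the determinism check
uses a 2+2-subject 16³ cohort with ROI erosion 0 (at 16³ every eroded ROI
would be empty). These sizes are the package's chosen desk-scale
conditions.

## Known limitations

* **SHARP fidelity at desk scale.** The 64³ phantom brain is ~50 voxels
  across against an 8-voxel maximum kernel, a far harsher ratio than real
  acquisitions. The background-removal residual this leaves is the
  dominant error of the chain: the acceptance script's round-trip reports
  most deep nuclei within max(15%, 3 ppb) of truth but small
  ventricle-adjacent structures (nucleus accumbens, thalamus) can exceed
  the 3 ppb floor by several ppb. A control experiment in the test suite
  (inverting the exact field of the validity-supported sources with the
  same solver settings) recovers every deep nucleus within 4 ppb,
  isolating the residual to the background-removal stage. SHARP-family
  methods are known to bias susceptibility estimates when the mask is
  small relative to the kernel.
* The TSVD-vs-Tikhonov reading of the SHARP regularization parameter is
  genuinely ambiguous; TSVD was chosen (and the Tikhonov variant measured
  to be no better on the recovery fixtures).
* Cortical χ near the mask edge is intrinsically less reliable (partial
  validity coverage); at 16³ smoke scale the cortical shell leaves the
  validity mask entirely and the iron summary falls back to all gray
  matter, logged.
* The BOLD coupling amplitudes are free parameters of the generator (the
  source analysis reports no effect size for them); α = 0.75 gives an
  unambiguous recovery target rather than a borderline one.
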