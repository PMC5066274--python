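"""Synthetic cohort generator: phantom geometry, forward physics, latents."""
import numpy as np
import pytest

from qsmcoloc.cohort import (CELL_N, CohortSpec, assign_susceptibility,
                             forward_dipole_field, make_cohort,
                             make_phantom_labels, sample_coupled_pairs,
                             simulate_bold_flat, simulate_multiecho_phase,
                             simulate_pet, wrap_phase)
from qsmcoloc.core import (CORTICAL_LOBES, STRUCTURE_LABELS, SubjectRecord,
                           VolumeGrid)


class TestPhantom:
    def test_all_structures_present_and_sized(self, layout48):
        lab = layout48.labels.data
        for name, lbl in STRUCTURE_LABELS.items():
            assert (lab == lbl).sum() >= 50, name
        layout48.labels.validate_complete()

    def test_structures_mutually_exclusive_by_construction(self, layout48):
        # one integer per voxel guarantees exclusivity; background is 0
        assert layout48.labels.data.min() == 0

    def test_deterministic_given_seed(self):
        a = make_phantom_labels((32, 32, 32), seed=3)
        b = make_phantom_labels((32, 32, 32), seed=3)
        assert np.array_equal(a.labels.data, b.labels.data)
        c = make_phantom_labels((32, 32, 32), seed=4)
        assert not np.array_equal(a.labels.data, c.labels.data)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_phantom_labels((8, 8, 8))

    def test_background_source_outside_brain(self, layout48):
        assert not (layout48.background_mask.data & layout48.brain_mask.data).any()


class TestSusceptibilityAssignment:
    def test_zero_variance_spec_reproduces_cell_means_exactly(self, layout48, rng):
        spec = CohortSpec(chi_texture_sd_ppb=0.0, baseline_sd_ppb=0.0)
        zero_sd = {s: {c: (m, 0.0) for c, (m, _) in cells.items()}
                   for s, cells in spec.chi_params.items()}
        from dataclasses import replace
        spec = replace(spec, chi_params=zero_sd)
        from qsmcoloc.cohort import _sample_subject_means
        subj = SubjectRecord("s", "mci", True, 75, "M")
        chi, _, _, _ = _sample_subject_means(subj, spec, rng)
        assert chi["frontal_cortex"] == pytest.approx(6.3)
        assert chi["globus_pallidus"] == pytest.approx(103.5)
        vol = assign_susceptibility(layout48, chi, baseline=0.0, spec=spec,
                                    rng=np.random.default_rng(0))
        gp = vol.data[layout48.labels.data == STRUCTURE_LABELS["globus_pallidus"]]
        assert gp.mean() == pytest.approx(103.5)

    def test_control_pallidus_grand_mean_matches_group_value(self):
        # the (e4-, e4+) control cells weighted 15:7 give the whole-group mean
        spec = CohortSpec()
        rng = np.random.default_rng(7)
        from qsmcoloc.cohort import _sample_subject_means
        vals = []
        for i in range(200):
            apoe = i % 22 < 7
            subj = SubjectRecord(f"s{i}", "control", apoe, 72, "F")
            chi, _, _, _ = _sample_subject_means(subj, spec, rng)
            vals.append(chi["globus_pallidus"])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 104.5) < 3 * se + 0.7  # 104.5 = 15:7 mixture

    def test_two_seeds_differ_but_share_expectation(self):
        a, _ = sample_coupled_pairs(300, 0.5, seed=1)
        b, _ = sample_coupled_pairs(300, 0.5, seed=2)
        assert not np.array_equal(a, b)
        pooled_se = np.sqrt(np.var(a) / 300 + np.var(b) / 300)
        assert abs(a.mean() - b.mean()) < 4 * pooled_se

    def test_missing_cell_parameters_rejected(self, rng):
        from dataclasses import replace
        from qsmcoloc.cohort import _sample_subject_means
        spec = CohortSpec()
        broken = dict(spec.chi_params)
        broken["thalamus"] = {k: v for k, v in broken["thalamus"].items()
                              if k != ("mci", True)}
        spec = replace(spec, chi_params=broken)
        with pytest.raises(ValueError, match="cell"):
            _sample_subject_means(SubjectRecord("s", "mci", True, 75, "M"), spec, rng)


class TestForwardDipole:
    def test_uniform_susceptibility_gives_zero_shift(self):
        vol = VolumeGrid(np.full((24, 24, 24), 123.0), (1, 1, 1))
        f = forward_dipole_field(vol, 7.0)
        assert np.abs(f.data).max() < 1e-9

    def test_sphere_internal_shift_near_zero(self):
        # Lorentz-sphere result: the demeaned internal field of a uniform
        # sphere vanishes
        n = 64
        c = (n - 1) / 2
        idx = np.indices((n, n, n), dtype=float)
        r2 = sum((idx[a] - c) ** 2 for a in range(3))
        chi = np.where(r2 <= 8 ** 2, 100.0, 0.0)
        f = forward_dipole_field(VolumeGrid(chi, (1, 1, 1)), 7.0)
        inner = f.data[r2 <= 5 ** 2]
        scale = np.abs(f.data).max()
        assert abs(inner.mean()) < 0.05 * scale

    def test_nonfinite_susceptibility_rejected(self):
        bad = np.zeros((16, 16, 16))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            forward_dipole_field(VolumeGrid(bad), 7.0)


class TestPhaseSimulation:
    def test_wrap_formula_below_pi(self):
        # 10 Hz at TE = 12 ms: phase 0.24*pi, no wrap
        f = VolumeGrid(np.full((8, 8, 8), 10.0))
        me = simulate_multiecho_phase(f, (0.012, 0.024), np.inf)
        assert me.phase[0].data[0, 0, 0] == pytest.approx(0.7540, abs=1e-4)

    def test_wrap_formula_above_pi(self):
        # 50 Hz at TE = 18 ms: 5.655 rad wraps to -0.628
        f = VolumeGrid(np.full((8, 8, 8), 50.0))
        me = simulate_multiecho_phase(f, (0.009, 0.018), np.inf)
        assert me.phase[1].data[0, 0, 0] == pytest.approx(-0.6283, abs=1e-4)

    def test_noiseless_echoes_scale_with_te(self, rng):
        f = VolumeGrid(rng.uniform(-5, 5, (12, 12, 12)))
        me = simulate_multiecho_phase(f, (0.006, 0.012, 0.018), np.inf)
        unwrapped = [2 * np.pi * f.data * te for te in (0.006, 0.012, 0.018)]
        for ph, true in zip(me.phase, unwrapped):
            assert np.allclose(ph.data, wrap_phase(true), atol=1e-12)

    def test_same_seed_reproduces(self):
        f = VolumeGrid(np.full((8, 8, 8), 3.0))
        a = simulate_multiecho_phase(f, (0.006, 0.012), 50.0, seed=9)
        b = simulate_multiecho_phase(f, (0.006, 0.012), 50.0, seed=9)
        assert np.array_equal(a.phase[0].data, b.phase[0].data)

    def test_nonpositive_snr_rejected(self):
        f = VolumeGrid(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError, match="snr"):
            simulate_multiecho_phase(f, (0.006, 0.012), 0.0)

    def test_phase_strictly_in_half_open_interval(self, rng):
        f = VolumeGrid(rng.uniform(-100, 100, (16, 16, 16)))
        me = simulate_multiecho_phase(f, (0.006, 0.012), 5.0, seed=0)
        for ph in me.phase:
            assert ph.data.max() <= np.pi and ph.data.min() > -np.pi


class TestPet:
    def test_cerebellar_anchor_exact(self, layout48, default_cohort):
        sid = default_cohort.subjects[0].subject_id
        suvr = default_cohort.suvr_volume(sid)
        cereb = default_cohort.labels.data == STRUCTURE_LABELS["cerebellar_gray"]
        assert suvr.data[cereb].mean() == pytest.approx(1.0, abs=1e-9)

    def test_full_coupling_without_noise_gives_rank_one(self):
        chi, suvr = sample_coupled_pairs(60, 1.0, seed=4)
        from scipy.stats import spearmanr
        assert spearmanr(chi, suvr).statistic == pytest.approx(1.0)

    def test_missing_cerebellum_rejected(self, layout48, rng):
        import copy
        broken = copy.deepcopy(layout48)
        broken.labels.data[broken.labels.data ==
                           STRUCTURE_LABELS["cerebellar_gray"]] = 0
        with pytest.raises(ValueError, match="cerebellar"):
            simulate_pet(broken, {s: 1.0 for s in STRUCTURE_LABELS}, CohortSpec(), rng)


class TestBold:
    def test_null_coupling_gives_near_zero_seed_correlation(self, layout48):
        spec = CohortSpec(bold_alpha={(g, c): 0.0 for g in ("control", "mci")
                                      for c in ("low", "high")},
                          shape=(48, 48, 48))
        lab_flat = layout48.labels.data[layout48.labels.data > 0]
        target = np.isin(lab_flat, [STRUCTURE_LABELS["frontal_cortex"]])
        seed_sel = lab_flat == STRUCTURE_LABELS["mpfc_seed"]
        for seed in (0, 1, 2):
            series, _ = simulate_bold_flat(layout48, "mci", "high", spec, seed=seed)
            s = series[seed_sel].mean(axis=0)
            v = series[target]
            s = s - s.mean()
            v = v - v.mean(axis=1, keepdims=True)
            r = (v @ s) / (np.linalg.norm(v, axis=1) * np.linalg.norm(s))
            assert abs(r.mean()) < 0.15

    def test_same_seed_identical_series(self, layout48):
        spec = CohortSpec(shape=(48, 48, 48))
        a, ca = simulate_bold_flat(layout48, "mci", "high", spec, seed=11)
        b, cb = simulate_bold_flat(layout48, "mci", "high", spec, seed=11)
        assert np.array_equal(a, b)
        assert ca.equals(cb)

    def test_nonpositive_series_length_rejected(self, layout48):
        from dataclasses import replace
        with pytest.raises(ValueError):
            simulate_bold_flat(layout48, "mci", "high",
                               replace(CohortSpec(), n_frames=0), seed=0)


class TestCohortAssembly:
    def test_default_cohort_composition(self, default_cohort):
        subs = default_cohort.subjects
        assert len(subs) == 37
        mci = [s for s in subs if s.group == "mci"]
        ctl = [s for s in subs if s.group == "control"]
        assert (len(ctl), len(mci)) == (22, 15)
        assert sum(s.apoe_e4 for s in ctl) == 7
        assert sum(s.apoe_e4 for s in mci) == 6
        assert sum(s.gender == "F" for s in ctl) == 8
        assert sum(s.gender == "F" for s in mci) == 5
        assert all(62 <= s.age <= 89 for s in subs)

    def test_smoke_cohort_files_on_disk(self, smoke_cohort):
        cohort, out = smoke_cohort
        for rec in cohort.subjects:
            sdir = out / rec.subject_id
            for f in ("phase_e1.nii.gz", "phase_e2.nii.gz", "phase_e3.nii.gz",
                      "mag_e1.nii.gz", "pet_suvr.nii.gz", "bold.nii.gz",
                      "labels.nii.gz", "confounds.tsv"):
                assert (sdir / f).exists(), f
        assert (out / "participants.tsv").exists()
        assert (out / "ground_truth" / "coupled_region.nii.gz").exists()

    def test_generators_are_pure_functions_of_seed(self):
        a = make_cohort(CohortSpec.smoke(seed=3))
        b = make_cohort(CohortSpec.smoke(seed=3))
        sid = a.subjects[0].subject_id
        assert np.array_equal(a.chi_volume(sid).data, b.chi_volume(sid).data)
        assert np.array_equal(a.phase(sid).phase[0].data, b.phase(sid).phase[0].data)
        assert a.truth[sid].chi_means_ppb == b.truth[sid].chi_means_ppb

    def test_iron_class_is_cohort_median_split(self, default_cohort):
        vals = {sid: t.cortical_chi_ppb for sid, t in default_cohort.truth.items()}
        thr = np.median(list(vals.values()))
        for sid, t in default_cohort.truth.items():
            assert t.iron_class == ("high" if vals[sid] > thr else "low")
        n_high = sum(t.iron_class == "high" for t in default_cohort.truth.values())
        assert n_high == 18  # 37 distinct values
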