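"""End-to-end orchestration over a cohort directory.

Per subject: QSM reconstruction from wrapped multi-echo phase, SUVR
validation, ROI quantification. Cohort level: reference-region selection,
median-split iron/amyloid classification, the seed-connectivity group
mask, group statistics tables and the colocalization report.

All report files are written with fixed numeric formatting and no
timestamps, so a re-run with the same seed is byte-identical.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .coloc import ColocalizationReport, colocalization_analysis, extract_mask_means
from .connectivity import GroupMask, group_mask, subject_connectivity
from .core import CORTICAL_LOBES, LabelMap, SubjectRecord
from .io import PipelineConfig
from .pet import SUVRMap, compute_suvr, cortical_composite
from .qsm import (SusceptibilityMap, reconstruct_qsm, reference_susceptibility,
                  select_reference_region)
from .stats import ClassificationResult, group_table, median_split, roi_means

log = logging.getLogger("qsmcoloc")

__all__ = ["PipelineResult", "run_pipeline", "load_cohort_dir"]

#: candidate reference regions: white-matter tracts and central CSF
REFERENCE_CANDIDATES = ("csf_ventricles", "white_matter")


@dataclass
class SubjectData:
    """Everything the pipeline needs for one subject, already in memory."""

    record: SubjectRecord
    phase: "object"                  # MultiEchoPhase
    suvr: "object"                   # VolumeGrid (SUVR)
    bold: np.ndarray | None          # (x, y, z, t) or None
    confounds: pd.DataFrame | None


@dataclass
class PipelineResult:
    reference_region: str
    roi_table: pd.DataFrame
    chi_maps: dict[str, SusceptibilityMap]
    suvr_maps: dict[str, SUVRMap]
    composites: pd.DataFrame           # subject_id, cortical_suvr, cortical_chi_ppb
    classifications: dict[str, ClassificationResult]
    group_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    connectivity_mask: GroupMask | None = None
    coloc: ColocalizationReport | None = None


def load_cohort_dir(cohort_dir) -> tuple[list[SubjectRecord], LabelMap,
                                         dict[str, SubjectData]]:
    """Read a generated cohort tree (participants.tsv + per-subject files)."""
    from .core import MultiEchoPhase

    cohort_dir = Path(cohort_dir)
    subjects = qio.read_subject_table(cohort_dir / "participants.tsv")
    labels = None
    data: dict[str, SubjectData] = {}
    for rec in subjects:
        sdir = cohort_dir / rec.subject_id
        if labels is None:
            labels = qio.read_label_map(sdir / "labels.nii.gz")
        phases, mags, tes = [], [], []
        e = 1
        while (sdir / f"phase_e{e}.nii.gz").exists():
            phases.append(qio.read_volume(sdir / f"phase_e{e}.nii.gz"))
            mags.append(qio.read_volume(sdir / f"mag_e{e}.nii.gz"))
            tes.append(0.006 * e)
            e += 1
        me = MultiEchoPhase(phases, tuple(tes), 7.0, mags)
        suvr = qio.read_volume(sdir / "pet_suvr.nii.gz")
        bold = conf = None
        if (sdir / "bold.nii.gz").exists():
            bold, _ = qio.read_series(sdir / "bold.nii.gz")
            conf = pd.read_csv(sdir / "confounds.tsv", sep="\t")
        data[rec.subject_id] = SubjectData(rec, me, suvr, bold, conf)
    return subjects, labels, data


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(subjects: list[SubjectRecord], labels: LabelMap,
                 data: dict[str, SubjectData], config: PipelineConfig | None = None,
                 out_dir=None, tr_s: float = 2.0) -> PipelineResult:
    """Run the full analysis on in-memory subject data.

    Stages: QSM per subject -> reference selection and referencing -> ROI
    table + cortical summaries -> median splits -> seed connectivity and
    the (MCI x iron) group mask -> colocalization report -> group tables.
    """
    cfg = config if config is not None else PipelineConfig()

    # --- QSM per subject (unreferenced), reference-candidate means
    unref, validities = {}, {}
    cand_rows = {}
    for sid, sd in sorted(data.items()):
        chi, val = reconstruct_qsm(sd.phase, cfg)
        unref[sid] = chi
        validities[sid] = val
        row = {}
        for cand in REFERENCE_CANDIDATES:
            m = labels.mask_of(cand).data & val.data
            row[cand] = float(chi.data[m].mean()) if m.any() else np.nan
        cand_rows[sid] = row
    cand_table = pd.DataFrame.from_dict(cand_rows, orient="index")
    reference = select_reference_region(cand_table)
    log.info("selected reference region: %s", reference)

    chi_maps = {sid: reference_susceptibility(unref[sid], labels, reference,
                                              validities[sid])
                for sid in sorted(unref)}

    # --- PET anchors + ROI table + cortical summaries
    suvr_maps = {}
    roi_frames = []
    comp_rows = []
    cort_sel = np.isin(labels.data, [labels.label_of(s) for s in CORTICAL_LOBES])
    for sid, sd in sorted(data.items()):
        suvr_maps[sid] = compute_suvr([sd.suvr], labels)
        smap = chi_maps[sid]
        roi_frames.append(roi_means(smap.chi.data, smap.validity.data,
                                    suvr_maps[sid].volume.data, labels,
                                    cfg.erosion_voxels, sid))
        sel = cort_sel & smap.validity.data
        comp_rows.append({
            "subject_id": sid,
            "cortical_suvr": cortical_composite(suvr_maps[sid], labels),
            "cortical_chi_ppb": float(smap.chi.data[sel].mean()) if sel.any() else np.nan,
        })
    roi_table = pd.concat(roi_frames, ignore_index=True)
    composites = pd.DataFrame(comp_rows)
    if composites["cortical_chi_ppb"].isna().any():
        # tiny grids can leave no cortical voxels inside the SHARP validity
        # mask; fall back to all gray matter within validity for everyone
        from .coloc import GRAY_MATTER_STRUCTURES
        gm_sel = np.isin(labels.data,
                         [labels.label_of(s) for s in GRAY_MATTER_STRUCTURES])
        log.warning("cortex outside chi validity for some subjects; iron "
                    "summary falls back to all gray matter within validity")
        fallback = []
        for sid in composites["subject_id"]:
            smap = chi_maps[sid]
            sel = gm_sel & smap.validity.data
            fallback.append(float(smap.chi.data[sel].mean()) if sel.any() else np.nan)
        composites["cortical_chi_ppb"] = fallback

    # --- median-split classifications (all subjects, cohort-wide medians)
    classifications = {
        "suvr_cortical": median_split(
            dict(zip(composites["subject_id"], composites["cortical_suvr"])),
            "suvr_cortical"),
        "chi_cortical": median_split(
            dict(zip(composites["subject_id"], composites["cortical_chi_ppb"])),
            "chi_cortical"),
    }
    iron_class = classifications["chi_cortical"].labels

    # --- seed connectivity group mask
    result_mask = None
    coloc_report = None
    have_bold = all(data[s.subject_id].bold is not None for s in subjects)
    if have_bold:
        from .coloc import GRAY_MATTER_STRUCTURES

        # analyse gray matter only (the seed is gray matter, so its signal
        # is available; white matter and CSF enter via the confounds)
        gm = np.isin(labels.data,
                     [labels.label_of(s) for s in GRAY_MATTER_STRUCTURES])
        maps = []
        seed = labels.mask_of("mpfc_seed").data
        for sid, sd in sorted(data.items()):
            conf = sd.confounds[[c for c in sd.confounds.columns]].values
            maps.append(subject_connectivity(sd.bold, conf, seed, gm, tr_s,
                                             cfg.band_low_hz, cfg.band_high_hz, sid))
        try:
            result_mask = group_mask(maps, subjects, iron_class, labels, gm,
                                     cfg.mask_fdr)
        except ValueError as exc:
            log.warning("group connectivity mask not computed: %s", exc)

    # --- colocalization
    if result_mask is not None and result_mask.mask.data.any():
        try:
            pairs, excluded = extract_mask_means(
                result_mask.mask.data,
                {sid: chi_maps[sid].chi.data for sid in chi_maps},
                {sid: suvr_maps[sid].volume.data for sid in suvr_maps},
                labels,
                {sid: chi_maps[sid].validity.data for sid in chi_maps})
            coloc_report = colocalization_analysis(pairs, subjects, classifications)
            coloc_report.excluded = excluded
        except ValueError as exc:
            log.warning("colocalization skipped: %s", exc)
    else:
        log.warning("connectivity mask empty or unavailable; colocalization skipped")

    # --- group statistics tables
    mci = [s for s in subjects if s.group == "mci"]
    controls = [s for s in subjects if s.group == "control"]
    group_stats = {}
    group_stats["chi_by_group"] = group_table(roi_table, subjects,
                                              "mean_chi_ppb", cfg.stats_fdr, "group")
    group_stats["volume_by_group"] = group_table(roi_table, subjects,
                                                 "volume_ml", cfg.stats_fdr, "group")
    if len(mci) >= 6:
        group_stats["chi_by_apoe_mci"] = group_table(roi_table, mci,
                                                     "mean_chi_ppb", cfg.stats_fdr, "apoe")
        group_stats["suvr_by_apoe_mci"] = group_table(roi_table, mci,
                                                      "mean_suvr", cfg.stats_fdr, "apoe")
    if len(controls) >= 6:
        group_stats["suvr_by_apoe_control"] = group_table(
            roi_table, controls, "mean_suvr", cfg.stats_fdr, "apoe")

    result = PipelineResult(reference, roi_table, chi_maps, suvr_maps,
                            composites, classifications, group_stats,
                            result_mask, coloc_report)
    if out_dir is not None:
        _write_reports(result, out_dir, cfg)
    return result


def _write_reports(res: PipelineResult, out_dir, cfg: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _fmt(res.roi_table, out / "roi_table.tsv")
    _fmt(res.composites, out / "cortical_summaries.tsv")
    cls_rows = []
    for measure, cls in sorted(res.classifications.items()):
        for sid, lab_ in sorted(cls.labels.items()):
            cls_rows.append({"measure": measure, "subject_id": sid,
                             "class": lab_, "threshold": cls.threshold})
    _fmt(pd.DataFrame(cls_rows), out / "classifications.tsv")
    for name, df in sorted(res.group_stats.items()):
        _fmt(df, out / f"stats_{name}.tsv")
    if res.connectivity_mask is not None:
        _fmt(res.connectivity_mask.region_summary, out / "mask_regions.tsv")
        qio.write_mask(res.connectivity_mask.mask, out / "connectivity_mask.nii.gz")
    if res.coloc is not None:
        _fmt(res.coloc.per_subject, out / "coloc_subjects.tsv")
        _fmt(res.coloc.strata, out / "coloc_strata.tsv")
        _fmt(res.coloc.odds_ratios, out / "coloc_odds_ratios.tsv")
        summary = pd.DataFrame([{
            "rho_mci": res.coloc.rho_mci, "p_mci": res.coloc.p_mci,
            "adj_r2_mci": res.coloc.adj_r2_mci,
            "reference_region": res.reference_region,
            "n_excluded": len(res.coloc.excluded),
        }])
        _fmt(summary, out / "coloc_summary.tsv")
    meta = pd.DataFrame([{"reference_region": res.reference_region,
                          "stats_fdr": cfg.stats_fdr, "mask_fdr": cfg.mask_fdr}])
    _fmt(meta, out / "pipeline_meta.tsv")
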