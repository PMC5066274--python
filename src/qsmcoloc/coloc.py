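"""Colocalization of brain iron and amyloid load inside the
connectivity-derived mask.

Per subject, mean susceptibility and mean SUVR are extracted over
(mask ∩ gray matter ∩ chi validity); the association is quantified with
Spearman's rho (+ adjusted R^2) over MCI subjects, APOE-e4-stratified
comparisons within each group, and odds ratios for APOE-e4 carriage vs
"high" amyloid / "high" iron classification.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CORTICAL_LOBES, LabelMap, SubjectRecord
from .stats import ClassificationResult, odds_ratio, spearman_coloc

log = logging.getLogger("qsmcoloc")

__all__ = ["ColocalizationReport", "extract_mask_means", "colocalization_analysis"]

GRAY_MATTER_STRUCTURES = CORTICAL_LOBES + (
    "amygdala", "nucleus_accumbens", "hippocampus", "entorhinal_cortex",
    "thalamus", "caudate_nucleus", "putamen", "globus_pallidus",
    "cerebellar_gray", "mpfc_seed",
)


@dataclass
class ColocalizationReport:
    per_subject: pd.DataFrame          # subject_id, mask_mean_chi_ppb, mask_mean_suvr
    rho_mci: float = np.nan
    p_mci: float = np.nan
    adj_r2_mci: float = np.nan
    strata: pd.DataFrame = field(default_factory=pd.DataFrame)
    odds_ratios: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded: list[str] = field(default_factory=list)


def extract_mask_means(mask: np.ndarray, chi_by_subject: dict[str, np.ndarray],
                       suvr_by_subject: dict[str, np.ndarray],
                       labels: LabelMap,
                       validity_by_subject: dict[str, np.ndarray] | None = None,
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject (mean chi, mean SUVR) over mask ∩ gray matter ∩ validity.

    Subjects with an empty intersection are excluded and reported; if the
    intersection is empty for everyone this is an error.
    """
    mask = np.asarray(mask, bool)
    gm = np.isin(labels.data, [labels.label_of(s) for s in GRAY_MATTER_STRUCTURES])
    base = mask & gm
    rows, excluded = [], []
    for sid in sorted(chi_by_subject):
        sel = base
        if validity_by_subject is not None:
            sel = sel & np.asarray(validity_by_subject[sid], bool)
        if not sel.any():
            excluded.append(sid)
            log.warning("subject %s: empty mask ∩ gray-matter ∩ validity; excluded", sid)
            continue
        rows.append({
            "subject_id": sid,
            "mask_mean_chi_ppb": float(chi_by_subject[sid][sel].mean()),
            "mask_mean_suvr": float(suvr_by_subject[sid][sel].mean()),
        })
    if not rows:
        raise ValueError("mask ∩ gray matter ∩ validity empty for every subject")
    return pd.DataFrame(rows), excluded


def _two_by_two(flags_a, flags_b) -> np.ndarray:
    a = np.asarray(flags_a, bool)
    b = np.asarray(flags_b, bool)
    return np.array([[int((a & b).sum()), int((a & ~b).sum())],
                     [int((~a & b).sum()), int((~a & ~b).sum())]], float)


def colocalization_analysis(pairs: pd.DataFrame, subjects: list[SubjectRecord],
                            classifications: dict[str, ClassificationResult],
                            ) -> ColocalizationReport:
    """Headline analysis on the extracted per-subject pairs.

    Spearman rho / adjusted R^2 over MCI subjects only (matching the way the
    scatter analysis is defined); APOE-stratified two-sample comparisons of
    both measures within each group; odds ratios (APOE -> high amyloid,
    APOE -> high iron) within MCI using the cohort-wide median thresholds.
    Strata with fewer than 2 subjects are skipped and logged.
    """
    meta = {s.subject_id: s for s in subjects}
    df = pairs[pairs["subject_id"].isin(meta)].copy()
    df["group"] = [meta[s].group for s in df["subject_id"]]
    df["apoe_e4"] = [meta[s].apoe_e4 for s in df["subject_id"]]

    report = ColocalizationReport(per_subject=df.reset_index(drop=True))

    mci = df[df["group"] == "mci"]
    if len(mci) >= 4:
        try:
            rho, p, adj = spearman_coloc(mci["mask_mean_chi_ppb"], mci["mask_mean_suvr"])
            report.rho_mci, report.p_mci, report.adj_r2_mci = rho, p, adj
        except ValueError as exc:
            log.warning("MCI colocalization correlation skipped: %s", exc)
    else:
        log.warning("fewer than 4 MCI subjects with pairs; rho not computed")

    strata_rows = []
    for grp in ("control", "mci"):
        sub = df[df["group"] == grp]
        for col, measure in (("mask_mean_chi_ppb", "chi"), ("mask_mean_suvr", "suvr")):
            neg = sub.loc[~sub["apoe_e4"], col].values
            pos = sub.loc[sub["apoe_e4"], col].values
            if neg.size < 2 or pos.size < 2:
                log.warning("stratum %s/%s too small; skipped", grp, measure)
                continue
            from scipy import stats as sps
            t, p = sps.ttest_ind(pos, neg, equal_var=True)
            strata_rows.append({
                "group": grp, "measure": measure,
                "mean_apoe_neg": neg.mean(),
                "ste_apoe_neg": neg.std(ddof=1) / np.sqrt(neg.size),
                "mean_apoe_pos": pos.mean(),
                "ste_apoe_pos": pos.std(ddof=1) / np.sqrt(pos.size),
                "p_value": float(p),
            })
    report.strata = pd.DataFrame(strata_rows)

    or_rows = []
    mci_ids = [s.subject_id for s in subjects if s.group == "mci"
               and s.subject_id in set(df["subject_id"])]
    apoe = [meta[s].apoe_e4 for s in mci_ids]
    for measure, cls in sorted(classifications.items()):
        if not mci_ids:
            break
        high = [cls.labels.get(s) == "high" for s in mci_ids]
        table = _two_by_two(apoe, high)
        try:
            or_, (lo, hi), p = odds_ratio(table)
        except ValueError as exc:
            log.warning("odds ratio for %s undefined: %s", measure, exc)
            continue
        or_rows.append({"measure": measure, "odds_ratio": or_,
                        "ci_low": lo, "ci_high": hi, "p_value": p})
    report.odds_ratios = pd.DataFrame(or_rows)
    return report
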