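"""ROI quantification and group statistics.

Covers mask erosion and per-structure means, intracranial-volume-corrected
structure volumes, covariate-adjusted (age, gender) group comparisons with
Benjamini-Hochberg correction, Cohen's d effect sizes, median-split
classification into "high"/"low", odds ratios with Haldane-Anscombe
correction, and the Spearman colocalization statistic with adjusted R^2.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .core import BinaryMask, LabelMap, SubjectRecord

log = logging.getLogger("qsmcoloc")

__all__ = [
    "ROITable",
    "GroupTestResult",
    "ClassificationResult",
    "erode_mask",
    "roi_means",
    "correct_volume",
    "ancova_group_test",
    "fdr_bh",
    "cohens_d",
    "median_split",
    "odds_ratio",
    "spearman_coloc",
    "group_table",
]

ROITable = pd.DataFrame  # rows: subject_id, structure, mean_chi_ppb,
#                                volume_ml, corrected_volume_ml, mean_suvr

_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connected


@dataclass
class GroupTestResult:
    structure: str
    effect: float          # adjusted group-effect estimate
    p_value: float
    q_value: float
    cohens_d: float
    mean_a: float
    ste_a: float
    mean_b: float
    ste_b: float


@dataclass
class ClassificationResult:
    measure: str
    threshold: float                 # the sample median
    labels: dict[str, str]           # subject_id -> "high" | "low"

    @property
    def n_high(self) -> int:
        return sum(1 for v in self.labels.values() if v == "high")

    @property
    def n_low(self) -> int:
        return sum(1 for v in self.labels.values() if v == "low")


def erode_mask(mask: BinaryMask, n_voxels: int) -> BinaryMask:
    """n iterations of 6-connected morphological erosion (n=0 is identity).
    The result may be empty; callers drop such structures with a warning."""
    if n_voxels < 0:
        raise ValueError("erosion count must be >= 0")
    data = np.asarray(mask.data, bool)
    if n_voxels > 0:
        data = ndimage.binary_erosion(data, _STRUCT6, iterations=n_voxels)
    return BinaryMask(data, mask.voxel_size_mm)


def roi_means(chi_data: np.ndarray, validity: np.ndarray | None,
              suvr_data: np.ndarray | None, labels: LabelMap,
              erosion_voxels: int = 2, subject_id: str = "") -> ROITable:
    """Per-structure rows for one subject.

    chi is averaged over the eroded label intersected with the validity
    mask; SUVR over the uneroded label; volume is the uneroded voxel count
    times the voxel volume in ml. Structures whose eroded mask is empty are
    dropped with a warning.
    """
    vx = labels.voxel_size_mm
    voxel_ml = vx[0] * vx[1] * vx[2] / 1000.0
    rows = []
    for lbl, name in sorted(labels.names.items()):
        full = labels.data == lbl
        if not full.any():
            log.warning("structure %s absent from label map; skipped", name)
            continue
        eroded = erode_mask(BinaryMask(full, vx), erosion_voxels).data
        if validity is not None:
            eroded = eroded & validity
        if not eroded.any():
            log.warning("structure %s empty after erosion; row dropped", name)
            continue
        rows.append({
            "subject_id": subject_id,
            "structure": name,
            "mean_chi_ppb": float(chi_data[eroded].mean()),
            "volume_ml": float(full.sum()) * voxel_ml,
            "mean_suvr": float(suvr_data[full].mean()) if suvr_data is not None
                         else np.nan,
        })
    return pd.DataFrame(rows)


def correct_volume(volume_ml: float, subject_icv_ml: float,
                   group_mean_icv_ml: float) -> float:
    """Corrected volume = volume x (group mean ICV / subject ICV)."""
    if volume_ml <= 0 or subject_icv_ml <= 0 or group_mean_icv_ml <= 0:
        raise ValueError("volumes must be positive")
    return volume_ml * (group_mean_icv_ml / subject_icv_ml)


def ancova_group_test(values, groups, age, gender) -> tuple[float, float]:
    """Group effect adjusted for age and gender.

    Linear model value ~ intercept + group + age + gender; returns the
    group coefficient (second-listed group minus first) and its two-sided
    p-value.
    """
    import statsmodels.api as sm

    values = np.asarray(values, float)
    g = pd.Categorical(groups)
    if len(g.categories) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(g.categories)}")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 3:
        raise ValueError("need >= 3 subjects per group")
    gender_num = np.asarray([{"F": 0.0, "M": 1.0}[x] for x in gender])
    # explicit intercept: add_constant would silently skip it if any
    # covariate happened to be constant, shifting every coefficient index
    X = np.column_stack([
        np.ones(values.size), (g.codes == 1).astype(float),
        np.asarray(age, float), gender_num])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(values, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values:
    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1, original order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohens_d(group_a, group_b) -> float:
    """d = (mean_b - mean_a) / pooled SD."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    na, nb = a.size, b.size
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if s2 == 0:
        raise ValueError("zero pooled variance")
    return float((b.mean() - a.mean()) / math.sqrt(s2))


def median_split(values: dict[str, float], measure: str = "") -> ClassificationResult:
    """Dichotomize at the sample median (mid-value convention for even n);
    strictly greater than the threshold is "high", ties go "low"."""
    if len(values) < 2:
        raise ValueError("need >= 2 subjects")
    arr = np.array(list(values.values()), float)
    thr = float(np.median(arr))
    labels = {sid: ("high" if v > thr else "low") for sid, v in values.items()}
    n_ties = int(np.sum(arr == thr))
    if n_ties:
        log.info("median_split(%s): %d value(s) at the median assigned 'low'",
                 measure, n_ties)
    return ClassificationResult(measure, thr, labels)


def odds_ratio(table) -> tuple[float, tuple[float, float], float]:
    """Odds ratio of a 2x2 count table [[a, b], [c, d]].

    Haldane-Anscombe +0.5 on all cells when any cell is 0; Wald log-scale
    95% CI (on the corrected counts when corrected); Fisher exact p on the
    raw counts. Returns (OR, (lo, hi), p).
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum(axis=1).min() == 0 or t.sum(axis=0).min() == 0:
        raise ValueError("a row or column of the 2x2 table is entirely zero")
    _, p = sps.fisher_exact(np.rint(t).astype(int))
    tc = t + 0.5 if (t == 0).any() else t
    a, b = tc[0]
    c, d = tc[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.959963984540054 * se)
    hi = math.exp(math.log(or_) + 1.959963984540054 * se)
    return float(or_), (float(lo), float(hi)), float(p)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_coloc(x, y) -> tuple[float, float, float]:
    """Spearman rho (mid-ranks), its p-value, and the adjusted R^2 of the
    OLS fit of y on x.

    p is exact-permutation for n <= 10 (untied data), else the t
    approximation. adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) with
    R^2 = squared Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input")
    n = x.size
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tied = (np.unique(x).size < n) or (np.unique(y).size < n)
    if n <= 10 and not tied:
        # exact permutation distribution of rho; for untied ranks rho is a
        # linear function of sum(rank_x * perm(rank_y)), so all n!
        # correlations reduce to one chunked integer matmul
        obs = abs(rho)
        rx0 = np.arange(1, n + 1, dtype=np.float64)
        mu = rx0.mean()
        denom = ((rx0 - mu) ** 2).sum()
        count = 0
        total = 0
        perm_iter = itertools.permutations(range(n))
        while True:
            chunk = list(itertools.islice(perm_iter, 200_000))
            if not chunk:
                break
            P = np.asarray(chunk, dtype=np.int8) + 1
            s = P.astype(np.float64) @ rx0
            rho_perm = (s - n * mu * mu) / denom
            count += int(np.sum(np.abs(rho_perm) >= obs - 1e-12))
            total += len(chunk)
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
    r_pearson = float(np.corrcoef(x, y)[0, 1])
    r2 = r_pearson ** 2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return rho, float(p), float(adj_r2)


def group_table(roi: ROITable, subjects: list[SubjectRecord],
                value_col: str = "mean_chi_ppb", fdr_level: float = 0.05,
                split_by: str = "group") -> pd.DataFrame:
    """Per-structure covariate-adjusted comparisons with BH correction.

    ``split_by`` is "group" (control vs MCI) or "apoe" (within a single
    group; pass pre-filtered subjects). Cohen's d is computed on raw
    (unadjusted) values.
    """
    meta = {s.subject_id: s for s in subjects}
    roi = roi[roi["subject_id"].isin(meta)]
    rows = []
    for structure, sub in roi.groupby("structure", sort=True):
        vals = sub.set_index("subject_id")[value_col].dropna()
        recs = [meta[sid] for sid in vals.index]
        if split_by == "group":
            flags = [r.group == "mci" for r in recs]
            names = ("control", "mci")
        else:
            flags = [r.apoe_e4 for r in recs]
            names = ("apoe_neg", "apoe_pos")
        a = vals.values[~np.asarray(flags)]
        b = vals.values[np.asarray(flags)]
        if a.size < 3 or b.size < 3:
            log.warning("%s: too few subjects per stratum; skipped", structure)
            continue
        try:
            eff, p = ancova_group_test(
                vals.values, [names[1] if f else names[0] for f in flags],
                [r.age for r in recs], [r.gender for r in recs])
        except ValueError as exc:
            log.warning("%s: %s; skipped", structure, exc)
            continue
        rows.append({
            "structure": structure, "effect": eff, "p_value": p,
            "cohens_d": cohens_d(a, b),
            f"mean_{names[0]}": a.mean(), f"ste_{names[0]}": a.std(ddof=1) / math.sqrt(a.size),
            f"mean_{names[1]}": b.mean(), f"ste_{names[1]}": b.std(ddof=1) / math.sqrt(b.size),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = fdr_bh(out["p_value"].values)
        out["significant"] = out["q_value"] < fdr_level
    return out
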