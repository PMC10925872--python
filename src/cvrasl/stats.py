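"""Comparative statistics between perfusion (CBF, AAT) and reactivity
(CVR, hemodynamic lag) maps.

Three analyses mirror the study design:

1. tissue-ROI group statistics: per-subject means per tissue (GM, WM,
   edema, metastasis) split by steal status, compared with Kruskal-Wallis
   H-tests under Benjamini-Hochberg FDR control, plus Spearman
   correlations of the per-subject means within tissue;
2. 5%-bin ROIs: the AAT (or CBF) map is sorted and cut into 20 bins of 5%
   of the voxels each; per-bin means of every map feed a repeated-measures
   correlation (common within-subject slope with subject-specific
   intercepts);
3. voxelwise Pearson correlation per subject, with a group-level Wilcoxon
   signed-rank test against zero.

CSF and previously treated (resected/irradiated) lesions never contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import ANALYZED_TISSUES, LabelMap, Tissue
from .cvr_lag import StealMasks

__all__ = [
    "exclude_nonanalyzed",
    "tissue_roi_summary",
    "kruskal_wallis",
    "benjamini_hochberg",
    "spearman",
    "bin_rois",
    "rmcorr",
    "RmcorrResult",
    "GroupTestResult",
    "voxelwise_correlation",
    "wilcoxon_signed_rank",
    "cohort_summary",
    "load_table1",
]


@dataclass
class GroupTestResult:
    """Statistic + p-value of a nonparametric group test."""

    statistic: float
    p: float
    groups: tuple[str, ...] = ()
    p_adjusted: float | None = None
    flagged: bool = False


@dataclass
class RmcorrResult:
    """Repeated-measures correlation (common slope, subject intercepts)."""

    r_rm: float
    common_slope: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


# ---------------------------------------------------------------------------
# masks and ROI summaries

def exclude_nonanalyzed(labels: LabelMap,
                        tnsr_retained: np.ndarray | None = None) -> np.ndarray:
    """Analyzed mask = brain minus CSF, treated lesions and tNSR-removed voxels."""
    excluded = labels.mask(Tissue.CSF, Tissue.TREATED_LESION)
    mask = labels.brain_mask & ~excluded
    if tnsr_retained is not None:
        mask &= np.asarray(tnsr_retained, dtype=bool)
    if not mask.any():
        raise ValueError("exclusion left no analyzable voxels")
    return mask


def tissue_roi_summary(maps: dict[str, np.ndarray],
                       labels: LabelMap,
                       steal: StealMasks,
                       subject: str = "s01",
                       analyzed_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Mean/sd of every metric per tissue x steal-status cell.

    Returns a tidy frame with columns subject, tissue, steal_status,
    metric, mean, sd, n_voxels.  Empty cells are omitted (logged via
    warnings).
    """
    rows = []
    status_masks = {"steal": steal.steal, "non_steal": steal.non_steal}
    for tissue in ANALYZED_TISSUES:
        t_mask = labels.mask(tissue)
        if analyzed_mask is not None:
            t_mask = t_mask & analyzed_mask
        for status, s_mask in status_masks.items():
            cell = t_mask & s_mask
            n = int(cell.sum())
            if n == 0:
                warnings.warn(f"empty ROI cell: {tissue.name}/{status}")
                continue
            for metric, arr in maps.items():
                vals = np.asarray(arr, dtype=float)[cell]
                rows.append({
                    "subject": subject, "tissue": tissue.name,
                    "steal_status": status, "metric": metric,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
                    "n_voxels": n,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary tests (library-backed, with the study's error semantics)

def kruskal_wallis(groups: list[np.ndarray],
                   labels: tuple[str, ...] = ()) -> GroupTestResult:
    """Kruskal-Wallis H-test across >= 2 nonempty samples.

    All-identical observations yield H = 0, p = 1 rather than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return GroupTestResult(statistic=0.0, p=1.0, groups=tuple(labels))
    h, p = sps.kruskal(*groups)
    return GroupTestResult(statistic=float(h), p=float(p), groups=tuple(labels))


def benjamini_hochberg(pvals, q: float = 0.05):
    """Step-up FDR control; returns (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def spearman(x, y) -> GroupTestResult:
    """Spearman rank correlation (tie-averaged ranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    rho, p = sps.spearmanr(x, y)
    return GroupTestResult(statistic=float(rho), p=float(p))


def wilcoxon_signed_rank(values, mu: float = 0.0,
                         alternative: str = "two-sided") -> GroupTestResult:
    """Wilcoxon signed-rank test of the location against ``mu``.

    Zero differences are excluded; if none remain the result is flagged
    (statistic and p are NaN).  Exact p for small n without ties, normal
    approximation otherwise (scipy's policy).
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        return GroupTestResult(statistic=np.nan, p=np.nan, flagged=True)
    w, p = sps.wilcoxon(d, alternative=alternative)
    return GroupTestResult(statistic=float(w), p=float(p))


# ---------------------------------------------------------------------------
# 5%-bin ROIs and repeated-measures correlation

def bin_rois(sort_map: np.ndarray,
             other_maps: dict[str, np.ndarray],
             mask: np.ndarray,
             n_bins: int = 20,
             sort_name: str = "sort",
             subject: str = "s01") -> pd.DataFrame:
    """Quantile-bin ROIs on ``sort_map`` and per-bin means of every map.

    In-mask voxels are sorted ascending on the sorting map and split into
    ``n_bins`` contiguous bins whose sizes differ by at most one; voxels
    whose value ties the last value of the previous bin are pulled down
    into it, keeping equal values together.  A constant sorting map is
    degenerate (single tie group) and raises.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(sort_map, dtype=float)[mask]
    n = vals.size
    if n < n_bins:
        raise ValueError("fewer in-mask voxels than bins")
    if np.all(vals == vals[0]):
        raise ValueError("constant sorting map: bins are degenerate")
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]

    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    bin_of = np.empty(n, dtype=int)
    for b in range(n_bins):
        bin_of[edges[b]:edges[b + 1]] = b
    # ties across a boundary fall to the lower bin
    for b in range(1, n_bins):
        i = edges[b]
        while i < n and sorted_vals[i] == sorted_vals[edges[b] - 1]:
            bin_of[i] = bin_of[edges[b] - 1]
            i += 1

    others = {name: np.asarray(arr, dtype=float)[mask][order]
              for name, arr in other_maps.items()}
    rows = []
    for b in range(n_bins):
        sel = bin_of == b
        if not sel.any():
            continue
        row = {"subject": subject, "bin_index": b + 1,
               "n_voxels": int(sel.sum()),
               f"mean_{sort_name}": float(sorted_vals[sel].mean())}
        for name, arr in others.items():
            row[f"mean_{name}"] = float(arr[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def rmcorr(table: pd.DataFrame,
           x: str = "x", y: str = "y",
           subject: str = "subject") -> RmcorrResult:
    """Repeated-measures correlation via within-subject residualization.

    Fits y = subject intercepts + common slope * x by least squares; the
    correlation is sign(slope) * sqrt(SS_x / (SS_x + SS_err)) where SS_x is
    the sum of squares explained by x after subject effects, with
    df = N - n_subjects - 1 and p from F(1, df).  Subjects with fewer than
    two observations are dropped with a warning.
    """
    df_in = table[[subject, x, y]].dropna()
    counts = df_in.groupby(subject)[x].count()
    bad = counts[counts < 2].index
    if len(bad) > 0:
        warnings.warn(f"dropping subjects with < 2 observations: {list(bad)}")
        df_in = df_in[~df_in[subject].isin(bad)]
    n_subj = df_in[subject].nunique()
    if n_subj < 2:
        raise ValueError("repeated-measures correlation needs >= 2 subjects")

    g = df_in.groupby(subject)
    xc = (df_in[x] - g[x].transform("mean")).to_numpy(dtype=float)
    yc = (df_in[y] - g[y].transform("mean")).to_numpy(dtype=float)
    ssx = float(xc @ xc)
    if ssx == 0:
        raise ValueError("x has no within-subject variance")
    slope = float(xc @ yc) / ssx
    ss_model = slope ** 2 * ssx
    ss_err = float(yc @ yc) - ss_model
    n_obs = len(df_in)
    dof = n_obs - n_subj - 1
    if dof < 1:
        raise ValueError("not enough observations for the residual df")
    denom = ss_model + ss_err
    r_rm = 0.0 if denom == 0 else np.sign(slope) * np.sqrt(ss_model / denom)
    if ss_err <= 0:  # perfect fit
        p = 0.0
    else:
        f_stat = ss_model / (ss_err / dof)
        p = float(sps.f.sf(f_stat, 1, dof))
    return RmcorrResult(r_rm=float(r_rm), common_slope=slope, df=dof, p=p,
                        n_subjects=n_subj, n_obs=n_obs)


# ---------------------------------------------------------------------------
# voxelwise association

def voxelwise_correlation(map_a: np.ndarray,
                          map_b: np.ndarray,
                          masks: dict[str, np.ndarray]) -> dict[str, float]:
    """Pearson r over in-mask voxels, per named mask (e.g. steal/non-steal)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    out: dict[str, float] = {}
    for name, m in masks.items():
        m = np.asarray(m, dtype=bool)
        if m.sum() < 3:
            raise ValueError(f"mask '{name}' has fewer than 3 voxels")
        r, _ = sps.pearsonr(a[m], b[m])
        out[name] = float(r)
    return out


# ---------------------------------------------------------------------------
# cohort summaries

MISSING = "-"


def load_table1() -> pd.DataFrame:
    """Packaged per-patient cohort table (volumes in cc, '-' = missing)."""
    with resources.files("cvrasl.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def cohort_summary(table: pd.DataFrame | None = None) -> dict:
    """Column means (non-missing denominator) and categorical counts.

    Numeric columns may carry '-' for missing entries; those entries are
    excluded from the mean and counted separately.  An all-missing column
    is flagged with mean None.
    """
    df = load_table1() if table is None else table.copy()
    numeric_cols = [c for c in df.columns
                    if c not in ("patient", "sex", "primary_tumor",
                                 "previous_resection", "previous_rt")]
    summary: dict = {"n_subjects": int(len(df)), "means": {}, "counts": {}}
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")  # '-' becomes NaN
        n = int(vals.notna().sum())
        summary["means"][col] = {
            "mean": float(vals.mean()) if n else None,
            "n": n,
            "flagged_empty": n == 0,
        }
    for col in ("sex", "primary_tumor", "previous_resection", "previous_rt"):
        if col in df.columns:
            summary["counts"][col] = df[col].value_counts().to_dict()
    return summary
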