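"""Group-comparison and correlation statistics for ROI INT analyses.

Covers the full battery used in case-control INT studies: Welch two-sample
t tests (one- or two-tailed) with Hedges g from summary statistics or raw
samples, one-way ANOVA from group summaries, Pearson chi-square for sex
distributions, ANCOVA of ROI INT on group with age/sex/IQ/FD covariates
(model-comparison F with partial eta squared), Benjamini-Hochberg FDR,
Spearman correlation grids against clinical measures, a Shapiro-Wilk
normality gate, and simplified mass-univariate voxelwise group maps with
26-connectivity cluster tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .int_core import IntMap

__all__ = [
    "GroupTestResult",
    "VoxelwiseResults",
    "ancova_group_effect",
    "anova_oneway_summary",
    "bh_fdr",
    "chi_square_contingency",
    "eta_squared_partial",
    "hedges_g",
    "hedges_g_from_samples",
    "normality_gate",
    "spearman_grid",
    "voxelwise_group_maps",
    "welch_t",
    "welch_t_from_samples",
]

TAILS = ("two_sided", "one_sided_first_larger", "one_sided_observed")


@dataclass
class GroupTestResult:
    """One statistical comparison: statistic, df, p values, effect size."""

    label: str
    statistic: float
    df: Union[float, tuple]
    p_unc: float
    p_fdr: Optional[float] = None
    effect: Optional[float] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_unc <= 1.0):
            raise ValueError(f"p_unc out of [0, 1]: {self.p_unc}")
        if self.p_fdr is not None and self.p_fdr < self.p_unc - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


def _check_group_summary(s: float, n: int, which: str) -> None:
    if n < 2:
        raise ValueError(f"{which}: need n >= 2, got {n}")
    if not (s > 0) or not np.isfinite(s):
        raise ValueError(f"{which}: sd must be positive and finite, got {s}")


def welch_t(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    tail: str = "two_sided",
) -> tuple:
    """Welch's two-sample t test from group summary statistics.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    ``tail`` is ``"two_sided"``, ``"one_sided_first_larger"`` (alternative:
    group 1 mean exceeds group 2), or ``"one_sided_observed"`` (tail taken
    in the direction of the observed difference).
    """
    _check_group_summary(s1, n1, "group 1")
    _check_group_summary(s2, n2, "group 2")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}, got {tail!r}")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    if v1 + v2 == 0:
        raise ValueError("zero variance in both groups: t undefined")
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    if tail == "two_sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tail == "one_sided_first_larger":
        p = stats.t.sf(t, df)
    else:  # one_sided_observed
        p = stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_from_samples(
    x1: Sequence[float], x2: Sequence[float], tail: str = "two_sided"
) -> tuple:
    """Raw-sample overload of :func:`welch_t` (reduces to mean/sd/n)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return welch_t(
        x1.mean(), x1.std(ddof=1), x1.size,
        x2.mean(), x2.std(ddof=1), x2.size,
        tail=tail,
    )


def hedges_g(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Hedges g: pooled-SD standardized mean difference with the
    small-sample correction J = 1 - 3 / (4(n1 + n2) - 9).

    Positive when the first group's mean is larger.
    """
    _check_group_summary(s1, n1, "group 1")
    _check_group_summary(s2, n2, "group 2")
    sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("pooled variance is zero: effect size undefined")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float((m1 - m2) / np.sqrt(sp2) * J)


def hedges_g_from_samples(x1: Sequence[float], x2: Sequence[float]) -> float:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return hedges_g(
        x1.mean(), x1.std(ddof=1), x1.size,
        x2.mean(), x2.std(ddof=1), x2.size,
    )


def anova_oneway_summary(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> tuple:
    """One-way ANOVA from per-group summary statistics.

    Returns ``(F, df1, df2, p)`` from the between/within sum-of-squares
    decomposition: df1 = k - 1, df2 = N - k.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ValueError("need matching summaries for at least 2 groups")
    for i, (s, n) in enumerate(zip(sds, ns)):
        _check_group_summary(s, n, f"group {i}")
    N = int(ns.sum())
    k = means.size
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, N - k
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def chi_square_contingency(counts: Sequence[Sequence[float]]) -> tuple:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction.  Returns ``(chi2, df, p)`` with df = (r-1)(c-1)."""
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or np.any(table < 0) or table.sum() <= 0:
        raise ValueError("counts must be a non-negative 2-D table with total > 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def eta_squared_partial(F: float, df1: float, df2: float) -> float:
    """Partial eta squared recovered from an F statistic:
    F*df1 / (F*df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("need F >= 0 and positive degrees of freedom")
    return float(F * df1 / (F * df1 + df2))


_DEFAULT_COVARIATES = ("age", "sex", "iq", "fd_mean")


def _design_columns(records: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} not in records")
        col = records[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.dropna().unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov!r}: only binary categoricals supported")
            col = (col == levels[-1]).astype(float)  # e.g. sex F=0, M=1
        cols[cov] = np.asarray(col, dtype=float)
    return pd.DataFrame(cols, index=records.index)


def ancova_group_effect(
    values: Sequence[float],
    records: pd.DataFrame,
    covariates: Sequence[str] = _DEFAULT_COVARIATES,
    label: str = "group",
) -> GroupTestResult:
    """F test for a multi-level group factor adjusting for covariates.

    Fits the linear model ``value ~ group + covariates`` by least squares
    with treatment-coded group and compares it against the covariates-only
    model; the group F is the model-comparison (Type II-style) statistic
    and the effect size is partial eta squared
    SS_group / (SS_group + SS_residual).

    ``records`` must hold a ``group`` column plus the covariate columns;
    binary string covariates (e.g. sex) are coded 0/1.
    """
    y = np.asarray(values, dtype=float)
    if y.size != len(records):
        raise ValueError("values and records must align")
    groups = records["group"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = groups.value_counts()
    if counts.min() < 3:
        raise ValueError(f"need >= 3 subjects per group, got {dict(counts)}")
    cov = _design_columns(records, covariates) if len(covariates) else pd.DataFrame(index=records.index)

    n = y.size
    intercept = np.ones((n, 1))
    dummies = np.column_stack(
        [(groups == lev).to_numpy(float) for lev in levels[1:]]
    )
    X_reduced = np.hstack([intercept, cov.to_numpy()]) if len(cov.columns) else intercept
    X_full = np.hstack([X_reduced, dummies])

    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        bad = _collinear_columns(X_full, ["intercept", *cov.columns, *levels[1:]])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    rss_reduced = _ols_rss(X_reduced, y)
    rss_full = _ols_rss(X_full, y)
    df_group = len(levels) - 1
    df_resid = n - X_full.shape[1]
    ss_group = max(rss_reduced - rss_full, 0.0)
    F = (ss_group / df_group) / (rss_full / df_resid)
    p = float(stats.f.sf(F, df_group, df_resid))
    eta = ss_group / (ss_group + rss_full)
    return GroupTestResult(
        label=label, statistic=float(F), df=(df_group, df_resid),
        p_unc=p, effect=float(eta),
    )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (order-preserving,
    each >= its raw p, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a nonempty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_grid(
    roi_values: pd.DataFrame,
    clinical: pd.DataFrame,
    groups: Optional[pd.Series] = None,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman rank correlations between every ROI column and every
    clinical column, with BH-FDR applied across all cells of each group's
    grid.

    Rows of ``roi_values`` and ``clinical`` are subjects (aligned on
    index).  Cells use pairwise-complete observations and average ranks on
    ties; cells with fewer than ``min_pairs`` complete pairs are marked
    missing and excluded from the FDR family.  Returns a tidy frame with
    columns group, roi, measure, n, rho, p_unc, p_fdr.
    """
    if not roi_values.index.equals(clinical.index):
        raise ValueError("roi_values and clinical must share their subject index")
    if groups is None:
        groups = pd.Series("all", index=roi_values.index)
    rows = []
    for grp in pd.unique(groups):
        sel = groups == grp
        rv, cl = roi_values[sel], clinical[sel]
        for roi in roi_values.columns:
            for measure in clinical.columns:
                pair = pd.concat([rv[roi], cl[measure]], axis=1).dropna()
                n = len(pair)
                if n < min_pairs:
                    rows.append((grp, roi, measure, n, np.nan, np.nan))
                    continue
                rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
                rows.append((grp, roi, measure, n, float(rho), float(p)))
    out = pd.DataFrame(
        rows, columns=["group", "roi", "measure", "n", "rho", "p_unc"]
    )
    out["p_fdr"] = np.nan
    for grp in out["group"].unique():
        ok = (out["group"] == grp) & out["p_unc"].notna()
        if ok.any():
            out.loc[ok, "p_fdr"] = bh_fdr(out.loc[ok, "p_unc"].to_numpy())
    return out


def normality_gate(values: Sequence[float], alpha: float = 0.05) -> tuple:
    """Shapiro-Wilk test; returns ``(W, p, normal)`` with ``normal`` true
    iff p > alpha.  Used to choose between Pearson and Spearman reporting
    (the pipeline reports Spearman when the gate fails)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant input: normality test undefined")
    W, p = stats.shapiro(x)
    return float(W), float(p), bool(p > alpha)


@dataclass
class VoxelwiseResults:
    """Mass-univariate group maps on a common grid."""

    f_map: np.ndarray
    f_threshold: float
    t_maps: dict
    t_thresholds: dict
    mask: np.ndarray
    affine: np.ndarray
    clusters: pd.DataFrame
    threshold_p: float


def _label_clusters(
    stat_map: np.ndarray,
    supra: np.ndarray,
    affine: np.ndarray,
    map_label: str,
) -> list:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n = ndimage.label(supra, structure=structure)
    rows = []
    for cid in range(1, n + 1):
        sel = labels == cid
        vals = np.where(sel, stat_map, -np.inf)
        peak_idx = np.unravel_index(np.argmax(vals), vals.shape)
        peak_mm = (affine @ np.array([*peak_idx, 1.0]))[:3]
        rows.append(
            {
                "map": map_label,
                "cluster_id": cid,
                "size_voxels": int(sel.sum()),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "peak_stat": float(stat_map[peak_idx]),
            }
        )
    return rows


def voxelwise_group_maps(
    int_maps: Sequence[IntMap],
    groups: Sequence[str],
    threshold_p: float = 0.001,
) -> VoxelwiseResults:
    """Simplified mass-univariate group comparison of INT maps.

    Per voxel: a one-way ANOVA F across groups plus, for every ordered
    group pair, a pooled-variance two-sample t map tested one-tailed
    (first group larger).  Maps are thresholded at uncorrected
    ``p < threshold_p`` and suprathreshold voxels are grouped into
    26-connectivity clusters with peak world coordinates.
    """
    if len(int_maps) != len(groups):
        raise ValueError("one group label per map required")
    shape = int_maps[0].grid.shape
    affine = int_maps[0].affine
    for m in int_maps:
        if m.grid.shape != shape or not np.allclose(m.affine, affine):
            raise ValueError("all INT maps must share grid and affine")
    groups = np.asarray([str(g) for g in groups])
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    per_group = {g: np.stack([m.grid for m, lab in zip(int_maps, groups) if lab == g])
                 for g in levels}
    for g, arr in per_group.items():
        if arr.shape[0] < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
    data = np.stack([m.grid for m in int_maps])
    mask = np.all(np.isfinite(data), axis=0)
    for m in int_maps:
        mask &= m.mask

    ns = {g: per_group[g].shape[0] for g in levels}
    means = {g: per_group[g].mean(axis=0) for g in levels}
    # within-group sums of squares
    ssw = sum(((per_group[g] - means[g]) ** 2).sum(axis=0) for g in levels)
    grand = data.mean(axis=0)
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in levels)
    k = len(levels)
    N = data.shape[0]
    df1, df2 = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f_map = (ssb / df1) / (ssw / df2)
    f_map = np.where(mask & np.isfinite(f_map), f_map, np.nan)
    f_crit = float(stats.f.isf(threshold_p, df1, df2))

    t_maps, t_thresholds = {}, {}
    cluster_rows = _label_clusters(f_map, mask & (f_map > f_crit), affine, "F")
    for i, g1 in enumerate(levels):
        for g2 in levels[i + 1:]:
            n1, n2 = ns[g1], ns[g2]
            sp2 = (
                ((per_group[g1] - means[g1]) ** 2).sum(axis=0)
                + ((per_group[g2] - means[g2]) ** 2).sum(axis=0)
            ) / (n1 + n2 - 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (means[g1] - means[g2]) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            t = np.where(mask & np.isfinite(t), t, np.nan)
            t_crit = float(stats.t.isf(threshold_p, n1 + n2 - 2))
            for a, b, tm in ((g1, g2, t), (g2, g1, -t)):
                label = f"{a}>{b}"
                t_maps[label] = tm
                t_thresholds[label] = t_crit
                cluster_rows += _label_clusters(tm, mask & (tm > t_crit), affine, label)

    clusters = pd.DataFrame(
        cluster_rows,
        columns=["map", "cluster_id", "size_voxels", "peak_x_mm", "peak_y_mm",
                 "peak_z_mm", "peak_stat"],
    )
    return VoxelwiseResults(
        f_map=f_map, f_threshold=f_crit, t_maps=t_maps,
        t_thresholds=t_thresholds, mask=mask, affine=affine,
        clusters=clusters, threshold_p=threshold_p,
    )
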