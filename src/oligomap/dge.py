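"""Two-part hurdle differential expression with marker and contrast filters.

The test follows the MAST model class: a logistic regression of detection
(count > 0) on group membership plus covariates, and a Gaussian regression
of log-normalised expression among detected cells on the same design.  The
likelihood-ratio statistics of the group term are summed across the two
parts and referred to a chi-square whose degrees of freedom are the summed
per-part degrees; a part with no usable information (constant detection,
fewer than three detected cells, or a rank-deficient continuous design)
contributes zero degrees of freedom.

Marker screening applies the pre-filter (positive log2FC > 0.25, detected in
>= 20% of the cluster of interest and < 60% outside) before testing; the
condition contrast applies |log2FC| >= 0.25 with max(pct) >= 20% (two-sided
analogue), then the survivor thresholds |log2FC| >= 0.5 and BH-adjusted
p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix
from .errors import ValidationError


@dataclass
class MarkerFilter:
    min_log2fc: float = 0.25
    min_pct_in: float = 0.20
    max_pct_out: float = 0.60


@dataclass
class DGEThresholds:
    min_abs_log2fc: float = 0.5
    max_adj_p: float = 0.05


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def detection_fractions(nm: NormalizedMatrix, gene, in_group, out_group) -> tuple[float, float]:
    """Fraction of cells with detected expression (value > 0) in each group."""
    in_group = np.asarray(in_group)
    out_group = np.asarray(out_group)
    if in_group.sum() == 0 or out_group.sum() == 0:
        raise ValidationError("groups must be non-empty")
    if np.any(in_group & out_group):
        raise ValidationError("groups must be disjoint")
    row = nm.values[nm.gene_index()[gene]]
    det = row > 0
    return float(det[in_group].mean()), float(det[out_group].mean())


def log2_fold_change(
    nm: NormalizedMatrix, gene, in_group, out_group, pseudocount: float = 1.0
) -> float:
    """log2 ratio of back-transformed (expm1) group means plus a pseudocount."""
    row = nm.values[nm.gene_index()[gene]]
    in_group = np.asarray(in_group)
    out_group = np.asarray(out_group)
    mean_in = np.expm1(row[in_group]).mean()
    mean_out = np.expm1(row[out_group]).mean()
    return float(np.log2(mean_in + pseudocount) - np.log2(mean_out + pseudocount))


def _logistic_ll(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 1e-8, max_iter: int = 100
) -> tuple[np.ndarray, bool]:
    """Newton-Raphson logistic MLE with a small ridge stabiliser.

    Returns (beta, separated): when coefficients diverge, the fit is redone
    with a stronger ridge and flagged.
    """
    beta = np.zeros(X.shape[1])
    separated = False
    lam = ridge
    for attempt in range(2):
        beta = np.zeros(X.shape[1])
        ok = True
        for _ in range(max_iter):
            eta = np.clip(X @ beta, -30, 30)
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            grad = X.T @ (y - p) - lam * beta
            H = (X * w[:, None]).T @ X + lam * np.eye(X.shape[1])
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                ok = False
                break
            beta = beta + step
            if np.max(np.abs(step)) < 1e-10:
                break
        if ok and np.max(np.abs(beta)) < 15.0:
            return beta, separated
        separated = True
        lam = 1e-4
    return beta, separated


def _design(groups: np.ndarray, covariates: pd.DataFrame | None) -> tuple[np.ndarray, np.ndarray]:
    """(null design, alt design): intercept + covariate dummies, + group dummy."""
    n = len(groups)
    levels = sorted(pd.unique(groups), key=str)
    if len(levels) != 2:
        raise ValidationError("hurdle test requires exactly two groups")
    g = (np.asarray(groups, dtype=object) == levels[1]).astype(float)
    cols = [np.ones(n)]
    if covariates is not None and len(covariates.columns):
        dummies = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
        for j in range(dummies.shape[1]):
            col = dummies[:, j]
            if col.std() > 0:
                cols.append(col)
    X0 = np.column_stack(cols)
    X1 = np.column_stack(cols + [g])
    return X0, X1


def hurdle_test(
    nm: NormalizedMatrix,
    gene,
    groups,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Combined hurdle LRT of the group term for one gene.

    Returns statistic, degrees of freedom, p-value and a separation flag.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != nm.n_cells:
        raise ValidationError("groups must cover all cells")
    for lev in pd.unique(groups):
        if (groups == lev).sum() < 2:
            raise ValidationError(f"group {lev!r} has fewer than 2 cells")
    row = nm.values[nm.gene_index()[gene]]
    det = (row > 0).astype(float)
    X0, X1 = _design(groups, covariates)

    stat = 0.0
    df = 0
    separated = False
    # discrete part: detection ~ design
    if 0.0 < det.mean() < 1.0:
        b0, s0 = _fit_logistic(X0, det)
        b1, s1 = _fit_logistic(X1, det)
        separated = s0 or s1
        lr_d = 2.0 * (_logistic_ll(b1, X1, det) - _logistic_ll(b0, X0, det))
        stat += max(lr_d, 0.0)
        df += 1
    # continuous part: expression among detected cells ~ design
    mask = det > 0
    if mask.sum() >= 3:
        y = row[mask]
        Xc0, Xc1 = X0[mask], X1[mask]
        if np.linalg.matrix_rank(Xc1) > np.linalg.matrix_rank(Xc0):
            rss0 = _rss(Xc0, y)
            rss1 = _rss(Xc1, y)
            if rss1 > 0:
                lr_c = mask.sum() * np.log(rss0 / rss1)
                stat += max(lr_c, 0.0)
                df += 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return {"statistic": float(stat), "df": int(df), "p_value": p, "separated": separated}


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _gene_stats(
    nm: NormalizedMatrix, in_mask: np.ndarray, out_mask: np.ndarray, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Vectorised pct_in / pct_out / log2fc for all genes at once."""
    det = nm.values > 0
    pct_in = det[:, in_mask].mean(axis=1)
    pct_out = det[:, out_mask].mean(axis=1)
    bt = np.expm1(nm.values)
    lfc = np.log2(bt[:, in_mask].mean(axis=1) + pseudocount) - np.log2(
        bt[:, out_mask].mean(axis=1) + pseudocount
    )
    return pd.DataFrame(
        {"gene": nm.gene_ids, "pct_in": pct_in, "pct_out": pct_out, "log2fc": lfc}
    )


def _finalise(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down") if len(table) else []
    return table


def marker_screen(
    nm: NormalizedMatrix,
    labels,
    marker_filter: MarkerFilter | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Per-cluster marker tables (cluster vs rest), pre-filtered then hurdle-tested.

    BH adjustment is applied within each cluster's tested gene set.
    """
    marker_filter = marker_filter or MarkerFilter()
    labels = np.asarray(labels, dtype=object)
    clusters = sorted(set(labels), key=str)
    if len(clusters) < 2:
        raise ValidationError("marker screen requires at least two clusters")
    results = {}
    for cl in clusters:
        in_mask = labels == cl
        out_mask = ~in_mask
        table = _gene_stats(nm, in_mask, out_mask)
        keep = (
            (table["log2fc"] > marker_filter.min_log2fc)
            & (table["pct_in"] >= marker_filter.min_pct_in)
            & (table["pct_out"] < marker_filter.max_pct_out)
        )
        table = table[keep].reset_index(drop=True)
        groups = np.where(in_mask, "in", "out")
        pvals = []
        for gene in table["gene"]:
            pvals.append(hurdle_test(nm, gene, groups, covariates)["p_value"])
        table["p_value"] = pvals
        results[cl] = _finalise(table)
    return results


def condition_contrast(
    nm: NormalizedMatrix,
    condition,
    covariates: pd.DataFrame | None = None,
    thresholds: DGEThresholds | None = None,
    prefilter: MarkerFilter | None = None,
) -> tuple[list, list, pd.DataFrame]:
    """Two-condition contrast: pre-filter, hurdle test, BH, survivor thresholds.

    Returns (upregulated genes, downregulated genes, full tested table); the
    sign of log2fc is condition[1] relative to condition[0] in sorted order.
    """
    thresholds = thresholds or DGEThresholds()
    prefilter = prefilter or MarkerFilter()
    condition = np.asarray(condition, dtype=object)
    levels = sorted(pd.unique(condition), key=str)
    if len(levels) != 2:
        raise ValidationError("condition contrast requires exactly two conditions")
    in_mask = condition == levels[1]
    out_mask = ~in_mask
    table = _gene_stats(nm, in_mask, out_mask)
    keep = (np.abs(table["log2fc"]) > prefilter.min_log2fc) & (
        np.maximum(table["pct_in"], table["pct_out"]) >= prefilter.min_pct_in
    )
    table = table[keep].reset_index(drop=True)
    pvals = []
    for gene in table["gene"]:
        pvals.append(hurdle_test(nm, gene, condition, covariates)["p_value"])
    table["p_value"] = pvals
    table = _finalise(table)
    surv = table[
        (np.abs(table["log2fc"]) >= thresholds.min_abs_log2fc)
        & (table["adj_p"] < thresholds.max_adj_p)
    ]
    up = sorted(surv.loc[surv["log2fc"] > 0, "gene"])
    down = sorted(surv.loc[surv["log2fc"] < 0, "gene"])
    return up, down, table
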