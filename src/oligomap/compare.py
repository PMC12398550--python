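"""Cluster-profile cosine similarity and cluster-composition comparison.

Profiles are per-cluster mean log-normalised expression restricted to a
shared feature space (a detection-frequency alternative is available); the
similarity between a target and a source cluster is the cosine of their
profile vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .containers import CellTable, NormalizedMatrix
from .dge import bh_adjust
from .errors import ValidationError


def cluster_centroids(
    nm: NormalizedMatrix,
    labels,
    feature_space: list,
    min_cluster_size: int = 3,
    profile: str = "mean_expression",
) -> pd.DataFrame:
    """Clusters x features centroid matrix (rows indexed by cluster label).

    ``profile`` chooses mean log-normalised expression (default) or the
    fraction of cells detecting each feature.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != nm.n_cells:
        raise ValidationError("labels must cover all cells")
    idx_map = nm.gene_index()
    cols = [idx_map.get(g) for g in feature_space]
    rows = {}
    for lab in sorted(set(labels), key=str):
        mask = labels == lab
        if mask.sum() == 0:
            raise ValidationError(f"empty cluster {lab!r}")
        if mask.sum() < min_cluster_size:
            warnings.warn(f"cluster {lab!r} has fewer than {min_cluster_size} cells")
        sub = nm.values[:, mask]
        if profile == "mean_expression":
            vec = sub.mean(axis=1)
        elif profile == "detection_frequency":
            vec = (sub > 0).mean(axis=1)
        else:
            raise ValidationError(f"unknown profile kind: {profile}")
        rows[lab] = [vec[c] if c is not None else 0.0 for c in cols]
    return pd.DataFrame.from_dict(rows, orient="index", columns=feature_space)


def cosine_similarity(A: pd.DataFrame, B: pd.DataFrame) -> pd.DataFrame:
    """S[i, j] = a_i . b_j / (|a_i| |b_j|); zero-norm profiles give NaN."""
    if A.shape[1] != B.shape[1]:
        raise ValidationError("profile matrices must share the feature dimension")
    a = A.to_numpy(dtype=float)
    b = B.to_numpy(dtype=float)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        warnings.warn("zero-norm profile; similarity undefined (NaN) for those rows")
    with np.errstate(invalid="ignore", divide="ignore"):
        S = (a @ b.T) / np.outer(na, nb)
    S[np.outer(na == 0, np.ones(len(nb), dtype=bool))] = np.nan
    S[np.outer(np.ones(len(na), dtype=bool), nb == 0)] = np.nan
    return pd.DataFrame(S, index=A.index, columns=B.index)


def composition_compare(cells: CellTable, cluster_col: str = "label", condition_col: str = "condition") -> pd.DataFrame:
    """Cluster x condition fractions plus per-cluster two-proportion z tests.

    For each cluster, the fraction of cells belonging to it is compared
    between the two conditions; p-values are BH-adjusted across clusters.
    """
    df = cells.df
    conditions = sorted(df[condition_col].dropna().unique(), key=str)
    if len(conditions) < 2:
        raise ValidationError("composition comparison needs at least two conditions")
    if len(conditions) > 2:
        raise ValidationError("composition comparison supports exactly two conditions")
    counts = pd.crosstab(df[cluster_col], df[condition_col])
    for c in conditions:
        if c not in counts.columns or counts[c].sum() == 0:
            raise ValidationError(f"condition {c!r} has no cells")
    totals = counts.sum(axis=0)
    fractions = counts / totals
    pvals = []
    for cluster in counts.index:
        k = counts.loc[cluster, conditions].to_numpy()
        n = totals[conditions].to_numpy()
        if k.sum() in (0, n.sum()):
            pvals.append(1.0)
            continue
        _, p = proportions_ztest(k, n)
        pvals.append(float(p) if np.isfinite(p) else 1.0)
    out = pd.DataFrame(
        {
            "cluster": counts.index,
            **{f"n_{c}": counts[c].to_numpy() for c in conditions},
            **{f"frac_{c}": fractions[c].to_numpy() for c in conditions},
            "delta_fraction": fractions[conditions[1]].to_numpy()
            - fractions[conditions[0]].to_numpy(),
            "p_value": pvals,
        }
    ).reset_index(drop=True)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out
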