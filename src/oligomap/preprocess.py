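"""QC filtering, normalisation, variable genes, PCA and Louvain clustering.

Gene QC removes genes detected in at most ``min_cells_per_gene_exclusive``
cells (default 10, i.e. a gene must be seen in strictly more than 10 cells to
survive).  Cell QC is a median +/- k*MAD outlier rule on log-scale library
size and detected-gene count, plus a one-sided mitochondrial-fraction cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .containers import CountMatrix, NormalizedMatrix
from .errors import EmptyResultError, ValidationError


@dataclass
class QCConfig:
    min_cells_per_gene_exclusive: int = 10
    mad_multiplier: float = 3.0
    max_mito_fraction: float = 1.0
    mito_gene_prefix: str = "MT-"


@dataclass
class Embedding:
    """PCA scores (cells x components) with per-component explained variance."""

    coords: np.ndarray
    explained_variance: np.ndarray
    loadings: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    n_pcs_selected: int = 0


def filter_genes(m: CountMatrix, qc: QCConfig | None = None) -> CountMatrix:
    """Drop genes detected (count > 0) in at most the threshold number of cells."""
    qc = qc or QCConfig()
    detected_in = np.asarray((m.values > 0).sum(axis=1)).ravel()
    keep = detected_in > qc.min_cells_per_gene_exclusive
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene")
    return m.subset_genes(keep)


def _mad_bounds(x: np.ndarray, k: float) -> tuple[float, float]:
    """median +/- k * scaled MAD (x1.4826, consistent for normal data).

    A zero MAD (more than half the cells identical on the metric) carries no
    scale information, so the bounds are left open.
    """
    med = np.median(x)
    mad = 1.4826 * np.median(np.abs(x - med))
    if mad == 0:
        return -np.inf, np.inf
    return med - k * mad, med + k * mad


def filter_cells(
    m: CountMatrix, qc: QCConfig | None = None, force: bool = False
) -> tuple[CountMatrix, pd.DataFrame]:
    """Two-sided MAD filter on log totals / log gene counts, one-sided mito cut.

    Returns the filtered matrix and a per-cell report with the criterion each
    removal is attributed to.
    """
    qc = qc or QCConfig()
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    n_detected = np.asarray((m.values > 0).sum(axis=0)).ravel()
    log_totals = np.log1p(totals)
    log_genes = np.log1p(n_detected)
    mito_mask = np.array(
        [g.split("_", 1)[-1].startswith(qc.mito_gene_prefix) or g.startswith(qc.mito_gene_prefix)
         for g in m.gene_ids]
    )
    mito_counts = (
        np.asarray(m.values[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros_like(totals)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    lo_t, hi_t = _mad_bounds(log_totals, qc.mad_multiplier)
    lo_g, hi_g = _mad_bounds(log_genes, qc.mad_multiplier)
    fail_umi = (log_totals < lo_t) | (log_totals > hi_t)
    fail_genes = (log_genes < lo_g) | (log_genes > hi_g)
    fail_mito = mito_frac > qc.max_mito_fraction
    removed = fail_umi | fail_genes | fail_mito

    report = pd.DataFrame(
        {
            "barcode": m.barcodes,
            "total_umis": totals,
            "n_genes": n_detected,
            "mito_fraction": mito_frac,
            "fail_umi": fail_umi,
            "fail_gene_count": fail_genes,
            "fail_mito": fail_mito,
            "removed": removed,
        }
    )
    frac_removed = removed.mean() if len(removed) else 0.0
    if frac_removed > 0.9 and not force:
        raise EmptyResultError(
            f"cell QC would remove {frac_removed:.0%} of cells; pass force=True to override"
        )
    return m.subset_cells(~removed), report


def size_factors(m: CountMatrix, basis: str = "median_ratio") -> np.ndarray:
    """Per-cell size factors rescaled to geometric mean 1.

    ``median_ratio`` uses the median count ratio to a geometric-mean
    reference over genes detected in every cell (DESeq convention); when
    fewer than 20 such genes exist — typical for sparse droplet data — it
    falls back to library-size factors.  Both are monotone per-cell scalings,
    which is all downstream stages require.
    """
    totals = np.asarray(m.values.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValidationError("zero-count cell present; run cell QC first")
    sf = None
    if basis == "median_ratio":
        dense_ok = np.asarray((m.values > 0).sum(axis=1)).ravel() == m.n_cells
        if dense_ok.sum() >= 20:
            sub = np.asarray(m.values[dense_ok].todense(), dtype=float)
            log_ref = np.mean(np.log(sub), axis=1)
            sf = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
        else:
            sf = totals
    elif basis == "library_size":
        sf = totals
    else:
        raise ValidationError(f"unknown size-factor basis: {basis}")
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def normalize(m: CountMatrix, basis: str = "median_ratio") -> NormalizedMatrix:
    """ln(count / size_factor + 1) expression matrix."""
    sf = size_factors(m, basis=basis)
    dense = np.asarray(m.values.todense(), dtype=float)
    values = np.log1p(dense / sf[None, :])
    return NormalizedMatrix(
        values=values, size_factors=sf, gene_ids=m.gene_ids, barcodes=m.barcodes
    )


def select_variable_genes(nm: NormalizedMatrix, n_top: int = 2000) -> list:
    """Top genes by standardized variance against a parametric mean-variance trend.

    Works on depth-corrected counts (expm1 of the log values).  The trend is
    the one-parameter quasi-negative-binomial law var = mu + phi * mu^2 with
    phi estimated as a robust median over expressed genes, so genes whose
    variance exceeds what a homogeneous count model allows at their mean —
    bimodal markers in particular — rank highest.  A flexible local fit is
    deliberately avoided: it would adapt to any cluster of high-variance
    genes and erase exactly the signal being sought.
    """
    if n_top > nm.n_genes:
        n_top = nm.n_genes
    counts = np.expm1(nm.values)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    if np.allclose(var, 0):
        raise ValidationError("constant expression matrix; no variable genes")
    expressed = mean > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_per_gene = (var - mean) / np.square(mean)
    phi = max(float(np.median(phi_per_gene[expressed])), 0.0)
    trend = mean + phi * np.square(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = np.where(trend > 0, var / trend, 0.0)
    standardized[~expressed] = 0.0
    standardized[var == 0] = 0.0  # constant genes are never selected
    order = np.argsort(-standardized, kind="stable")
    return [nm.gene_ids[i] for i in order[:n_top]]


def run_pca(
    nm: NormalizedMatrix, genes: list, max_pcs: int = 30, scale: bool = True
) -> Embedding:
    """PCA of cells on the selected genes; deterministic sign convention.

    Each component's sign is fixed so its largest-magnitude gene loading is
    positive.
    """
    idx_map = nm.gene_index()
    missing = [g for g in genes if g not in idx_map]
    if missing:
        raise ValidationError(f"{len(missing)} requested genes absent from matrix")
    idx = [idx_map[g] for g in genes]
    X = nm.values[idx, :].T.astype(float)  # cells x genes
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    k = min(max_pcs, X.shape[1], X.shape[0] - 1 if X.shape[0] > 1 else 1)
    if k < max_pcs:
        warnings.warn(f"max_pcs clipped to {k} by data dimensions")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # sign convention: largest-|loading| gene positive per component
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    denom = max(X.shape[0] - 1, 1)
    ev = S**2 / denom
    return Embedding(
        coords=U * S,
        explained_variance=ev,
        loadings=Vt.T,
        gene_ids=np.asarray(genes, dtype=object),
        barcodes=nm.barcodes,
    )


def choose_elbow(
    explained_variance: np.ndarray,
    drop_fraction: float = 0.1,
    floor: int = 5,
    cap: int | None = None,
) -> int:
    """Elbow heuristic on the variance spectrum.

    Returns the smallest k at which the drop between successive components
    first falls below ``drop_fraction`` of total variance after at least one
    large drop has been seen; a spectrum with no large drop at all has no
    elbow and yields the cap (or full length).  A floor and cap bound the
    answer, and vectors shorter than the floor return their full length.
    """
    ev = np.asarray(explained_variance, dtype=float)
    n = len(ev)
    if n == 0:
        raise ValidationError("empty variance vector")
    if n < floor:
        warnings.warn("variance vector shorter than elbow floor; using full length")
        return n
    threshold = drop_fraction * ev.sum()
    k = n
    seen_large = False
    for i in range(1, n):
        drop = ev[i - 1] - ev[i]
        if drop >= threshold and threshold > 0:
            seen_large = True
        elif seen_large:
            k = i
            break
    k = max(k, min(floor, n))
    if cap is not None:
        k = min(k, cap)
    return k


def _snn_graph(coords: np.ndarray, k_neighbors: int) -> nx.Graph:
    n = coords.shape[0]
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            if g.has_edge(i, j):
                continue
            shared = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = shared / union
            if w > 0:
                g.add_edge(i, j, weight=w)
    return g


def cluster_cells(
    emb: Embedding,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int | None = None,
) -> pd.DataFrame:
    """Shared-nearest-neighbour graph + Louvain modularity clustering.

    Labels are contiguous integers ordered by decreasing cluster size;
    determinism follows from the seed.
    """
    coords = emb.coords if n_pcs is None else emb.coords[:, :n_pcs]
    if k_neighbors >= coords.shape[0]:
        raise ValidationError("k_neighbors must be smaller than the number of cells")
    g = _snn_graph(coords, k_neighbors)
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    if isolated:
        warnings.warn(f"{len(isolated)} cells are disconnected; assigned singleton clusters")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=int(seed)
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(coords.shape[0], dtype=int)
    for lab, comm in enumerate(communities):
        for v in comm:
            labels[v] = lab
    return pd.DataFrame({"barcode": emb.barcodes, "cluster": labels})


def modularity(emb: Embedding, labels: np.ndarray, k_neighbors: int = 20) -> float:
    """Modularity of a partition on the same SNN graph used for clustering."""
    g = _snn_graph(emb.coords, k_neighbors)
    groups: dict = {}
    for v, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(v)
    return nx.community.modularity(g, list(groups.values()), weight="weight")
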