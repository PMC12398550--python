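"""Synthetic data with known ground truth for every pipeline stage.

The count model is a negative binomial (gamma-Poisson) with class-specific
means and logistic dropout on the log mean: classes are distinguished by
blocks of marker genes whose mean is ``base_mean * marker_fold``, and each
gene/cell entry is zeroed with probability ``1 - sigmoid(slope * (ln mu -
midpoint))``.  This is the minimal model that reproduces the detect /
non-detect structure the binarized classifier exploits.  Domain shift between
a labelled "atlas" source and an unlabelled target is a per-gene log-normal
scaling of the means — the simplest shift that breaks naive centroid
transfer while preserving marker detection ranks.

All generators are pure functions of their configuration, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    HUMAN_PREFIX,
    MOUSE_PREFIX,
    CellTable,
    CountMatrix,
)
from .errors import ConfigError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic single-cell generators.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2 / dispersion); ``dropout_midpoint``/``dropout_slope`` set the
    logistic detection curve on ln(mean).
    """

    n_classes: int = 8
    n_genes: int = 500
    cells_per_class: int = 200
    markers_per_class: int = 10
    base_mean: float = 0.5
    marker_fold: float = 8.0
    dispersion: float = 2.0
    dropout_midpoint: float = -2.3
    dropout_slope: float = 1.0
    domain_shift_sd: float = 0.3
    contamination_fraction: float = 0.05
    effect_log2fc: float = 1.0
    frac_de_genes: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_genes < 1 or self.cells_per_class < 1:
            raise ConfigError("counts of classes/genes/cells must be positive")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ConfigError("markers_per_class * n_classes exceeds n_genes")
        if self.base_mean <= 0 or self.marker_fold <= 0 or self.dispersion <= 0:
            raise ConfigError("base_mean, marker_fold and dispersion must be positive")
        if self.domain_shift_sd < 0:
            raise ConfigError("domain_shift_sd must be non-negative")
        if not 0.0 <= self.contamination_fraction < 0.3:
            raise ConfigError("contamination_fraction must be in [0, 0.3)")
        if not 0.0 <= self.frac_de_genes <= 1.0:
            raise ConfigError("frac_de_genes must be in [0, 1]")


@dataclass
class GroundTruth:
    """Truth records aligned one-to-one with generated cells/genes/axons."""

    cells: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    axons: pd.DataFrame | None = None
    class_means: np.ndarray | None = None  # classes x genes
    class_names: list = field(default_factory=list)
    gene_ids: np.ndarray | None = None


def _class_mean_matrix(cfg: SimulationConfig) -> tuple[np.ndarray, list]:
    means = np.full((cfg.n_classes, cfg.n_genes), cfg.base_mean)
    for c in range(cfg.n_classes):
        lo = c * cfg.markers_per_class
        means[c, lo : lo + cfg.markers_per_class] = cfg.base_mean * cfg.marker_fold
    names = [f"class_{c}" for c in range(cfg.n_classes)]
    return means, names


def _nb_dropout_counts(
    means: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draws thinned by logistic dropout on ln(mean).

    *means* is cells x genes; returns an integer matrix of the same shape.
    """
    lam = rng.gamma(shape=cfg.dispersion, scale=means / cfg.dispersion)
    counts = rng.poisson(lam)
    p_keep = 1.0 / (1.0 + np.exp(-cfg.dropout_slope * (np.log(means) - cfg.dropout_midpoint)))
    counts[rng.random(counts.shape) >= p_keep] = 0
    return counts


def _to_count_matrix(counts_cells_by_genes, gene_ids, barcodes) -> CountMatrix:
    return CountMatrix(
        values=sp.csr_matrix(counts_cells_by_genes.T),
        gene_ids=np.asarray(gene_ids, dtype=object),
        barcodes=np.asarray(barcodes, dtype=object),
    )


def simulate_reference(cfg: SimulationConfig) -> tuple[CountMatrix, CellTable, GroundTruth]:
    """Labelled source "atlas": balanced classes, marker-block means."""
    rng = np.random.default_rng(cfg.seed)
    means, class_names = _class_mean_matrix(cfg)
    labels = np.repeat(np.arange(cfg.n_classes), cfg.cells_per_class)
    counts = _nb_dropout_counts(means[labels], cfg, rng)
    n_cells = len(labels)
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    barcodes = [f"ref_{i:05d}" for i in range(n_cells)]
    label_names = [class_names[c] for c in labels]
    table = CellTable(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "label": label_names,
                "sample": "reference",
                "condition": "reference",
            }
        )
    )
    truth = GroundTruth(
        cells=pd.DataFrame({"barcode": barcodes, "label": label_names}),
        class_means=means,
        class_names=class_names,
        gene_ids=np.asarray(gene_ids, dtype=object),
    )
    return _to_count_matrix(counts, gene_ids, barcodes), table, truth


def simulate_target(
    cfg: SimulationConfig, reference_truth: GroundTruth
) -> tuple[CountMatrix, GroundTruth]:
    """Domain-shifted target sharing the reference's classes and genes.

    Gene-wise means are multiplied by log-normal(0, domain_shift_sd) factors
    fixed per gene; true labels are retained only in the returned truth.
    """
    if reference_truth.class_means is None or reference_truth.gene_ids is None:
        raise ConfigError("reference ground truth must carry class means and gene ids")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 1]))
    n_genes = reference_truth.class_means.shape[1]
    if n_genes != cfg.n_genes:
        raise ConfigError("gene set mismatch between config and reference truth")
    factors = np.exp(rng.normal(0.0, cfg.domain_shift_sd, size=n_genes))
    means = reference_truth.class_means * factors[None, :]
    labels = np.repeat(np.arange(cfg.n_classes), cfg.cells_per_class)
    rng.shuffle(labels)
    counts = _nb_dropout_counts(means[labels], cfg, rng)
    barcodes = [f"tgt_{i:05d}" for i in range(len(labels))]
    label_names = [reference_truth.class_names[c] for c in labels]
    truth = GroundTruth(
        cells=pd.DataFrame({"barcode": barcodes, "label": label_names}),
        class_means=means,
        class_names=reference_truth.class_names,
        gene_ids=reference_truth.gene_ids,
        genes=pd.DataFrame(
            {"gene": reference_truth.gene_ids, "shift_factor": factors}
        ),
    )
    return _to_count_matrix(counts, reference_truth.gene_ids, barcodes), truth


def simulate_chimera(cfg: SimulationConfig, n_cells: int | None = None) -> tuple[CountMatrix, GroundTruth]:
    """Mixed human/mouse counts with cross-species contamination.

    Each cell draws counts over its own species' genes; a binomial fraction
    of every count is then reassigned uniformly to the other species' genes,
    emulating ambient cross-mapping in a dissociated chimera sample.
    """
    if not cfg.contamination_fraction < 0.3:
        raise ConfigError("contamination_fraction must be < 0.3")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 2]))
    if n_cells is None:
        n_cells = cfg.n_classes * cfg.cells_per_class
    n_genes = cfg.n_genes
    gene_ids = [f"{HUMAN_PREFIX}G{i:05d}" for i in range(n_genes)] + [
        f"{MOUSE_PREFIX}G{i:05d}" for i in range(n_genes)
    ]
    species = np.array(["human"] * (n_cells // 2) + ["mouse"] * (n_cells - n_cells // 2))
    rng.shuffle(species)
    means = np.full(n_genes, cfg.base_mean * 2.0)  # flat profile; composition is the signal
    counts = np.zeros((n_cells, 2 * n_genes), dtype=np.int64)
    own = _nb_dropout_counts(np.tile(means, (n_cells, 1)), cfg, rng)
    leak = rng.binomial(own, cfg.contamination_fraction)
    kept = own - leak
    leak_totals = leak.sum(axis=1)
    for i in range(n_cells):
        block = slice(0, n_genes) if species[i] == "human" else slice(n_genes, 2 * n_genes)
        other = slice(n_genes, 2 * n_genes) if species[i] == "human" else slice(0, n_genes)
        counts[i, block] = kept[i]
        if leak_totals[i] > 0:
            counts[i, other] = rng.multinomial(leak_totals[i], np.full(n_genes, 1.0 / n_genes))
    barcodes = [f"chi_{i:05d}" for i in range(n_cells)]
    truth = GroundTruth(cells=pd.DataFrame({"barcode": barcodes, "species": species}))
    return _to_count_matrix(counts, gene_ids, barcodes), truth


def simulate_two_group(cfg: SimulationConfig) -> tuple[CountMatrix, CellTable, GroundTruth]:
    """Two equal groups for DGE calibration: DE genes shifted by effect_log2fc."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 3]))
    n_de = int(round(cfg.frac_de_genes * cfg.n_genes))
    base = np.full(cfg.n_genes, cfg.base_mean * 4.0)
    mean_a = base.copy()
    mean_b = base.copy()
    true_lfc = np.zeros(cfg.n_genes)
    if n_de:
        signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
        mean_b[:n_de] = base[:n_de] * 2.0 ** (cfg.effect_log2fc * signs)
        true_lfc[:n_de] = cfg.effect_log2fc * signs
    n = cfg.cells_per_class
    counts_a = _nb_dropout_counts(np.tile(mean_a, (n, 1)), cfg, rng)
    counts_b = _nb_dropout_counts(np.tile(mean_b, (n, 1)), cfg, rng)
    counts = np.vstack([counts_a, counts_b])
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    barcodes = [f"grp_{i:05d}" for i in range(2 * n)]
    condition = ["vehicle"] * n + ["metformin"] * n
    table = CellTable(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "label": "oligo",
                "sample": ["s1"] * n + ["s2"] * n,
                "condition": condition,
            }
        )
    )
    truth = GroundTruth(
        cells=pd.DataFrame({"barcode": barcodes, "condition": condition}),
        genes=pd.DataFrame(
            {
                "gene": gene_ids,
                "is_de": true_lfc != 0.0,
                "true_log2fc": true_lfc,
            }
        ),
    )
    return _to_count_matrix(counts, gene_ids, barcodes), table, truth


def simulate_morphometry(
    n_axons: int,
    g_mean: float,
    g_sd: float,
    mito_fraction: float,
    seed: int,
    diameter_log_mean: float = -0.2,
    diameter_log_sd: float = 0.35,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Axon geometry table with known g-ratios.

    Axon diameters are log-normal; areas are derived assuming circular cross
    sections, so the true g-ratio is recovered exactly as
    sqrt(axon_area / outer_area).  Mitochondrial areas are gamma-distributed
    fractions of the axon area with mean ``mito_fraction``.
    """
    if not (0 < g_mean - 3 * g_sd and g_mean + 3 * g_sd < 1):
        raise ConfigError("require 0 < g_mean +/- 3*g_sd < 1")
    rng = np.random.default_rng(seed)
    d = np.exp(rng.normal(diameter_log_mean, diameter_log_sd, size=n_axons))
    g = np.clip(rng.normal(g_mean, g_sd, size=n_axons), 1e-3, 1.0) if g_sd > 0 else np.full(n_axons, g_mean)
    axon_area = np.pi * (d / 2.0) ** 2
    outer_area = axon_area / g**2
    if mito_fraction > 0:
        frac = rng.gamma(shape=20.0, scale=mito_fraction / 20.0, size=n_axons)
    else:
        frac = np.zeros(n_axons)
    total_mito = frac * axon_area
    n_mito = 1 + rng.poisson(1.0, size=n_axons)
    rows = []
    for i in range(n_axons):
        if total_mito[i] > 0:
            w = rng.dirichlet(np.ones(n_mito[i]))
            mitos = list(total_mito[i] * w)
        else:
            mitos = []
        rows.append(
            {
                "axon_id": f"ax_{i:05d}",
                "animal_id": f"animal_{i % 6}",
                "condition": "vehicle" if i % 2 == 0 else "metformin",
                "axon_area": axon_area[i],
                "outer_area": outer_area[i],
                "mito_areas": mitos,
                "myelinated": True,
                "compartment": "axon",
            }
        )
    profiles = pd.DataFrame(rows)
    truth = GroundTruth(
        axons=pd.DataFrame(
            {
                "axon_id": profiles["axon_id"],
                "true_g_ratio": g,
                "true_diameter": d,
                "true_mito_fraction": frac,
            }
        )
    )
    return profiles, truth


def simulate_puncta(
    n_animals: int,
    rois_per_animal: int,
    cells_per_roi: int,
    olig2_fraction: float,
    puncta_mean: float,
    seed: int,
    condition: str = "vehicle",
    probe: str = "EIF1",
) -> pd.DataFrame:
    """Synthetic RNAscope ROI table: per-cell puncta counts and OLIG2 status."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for r in range(rois_per_animal):
            olig2 = rng.random(cells_per_roi) < olig2_fraction
            puncta = rng.poisson(puncta_mean, size=cells_per_roi)
            for c in range(cells_per_roi):
                rows.append(
                    {
                        "roi_id": f"{condition}_a{a}_roi{r}",
                        "animal_id": f"{condition}_a{a}",
                        "condition": condition,
                        "probe": probe,
                        "cell_id": f"{condition}_a{a}_roi{r}_c{c}",
                        "olig2_positive": bool(olig2[c]),
                        "puncta": int(puncta[c]),
                    }
                )
    return pd.DataFrame(rows)


def shuffled_labels(labels, seed: int) -> np.ndarray:
    """Permutation-null labels (used to check chance-level transfer)."""
    rng = np.random.default_rng(seed)
    out = np.asarray(labels, dtype=object).copy()
    rng.shuffle(out)
    return out
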