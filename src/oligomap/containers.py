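"""Core in-memory containers: sparse count matrices and cell annotations.

Counts are stored genes x cells (rows are genes), mirroring the on-disk
Matrix Market triplet convention of droplet pipelines.  Gene ids from a
concatenated two-species ("barnyard") reference carry a genome prefix
(``GRCh38_`` / ``mm10_``) which is parsed into a per-gene species tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ValidationError

HUMAN_PREFIX = "GRCh38_"
MOUSE_PREFIX = "mm10_"

SPECIES_HUMAN = "human"
SPECIES_MOUSE = "mouse"
SPECIES_NONE = "none"


def species_from_gene_id(gene_id: str) -> str:
    """Species tag from the concatenated-genome gene-id prefix convention."""
    if gene_id.startswith(HUMAN_PREFIX):
        return SPECIES_HUMAN
    if gene_id.startswith(MOUSE_PREFIX):
        return SPECIES_MOUSE
    return SPECIES_NONE


@dataclass
class CountMatrix:
    """Sparse UMI count matrix (genes x cells) with species-tagged gene ids.

    Invariants: counts are non-negative integers; ``gene_ids`` and
    ``barcodes`` are unique and match the matrix dimensions.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    gene_species: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.gene_species is None:
            self.gene_species = np.array(
                [species_from_gene_id(g) for g in self.gene_ids], dtype=object
            )
        else:
            self.gene_species = np.asarray(self.gene_species, dtype=object)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise ValidationError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(self.gene_species) != n_genes:
            raise ValidationError("gene_species length mismatch")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("duplicate gene ids")
        if len(set(self.barcodes)) != n_cells:
            raise ValidationError("duplicate barcodes")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.all(np.equal(np.mod(data, 1), 0)):
                raise ValidationError("non-integral counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            values=self.values[mask],
            gene_ids=self.gene_ids[mask],
            barcodes=self.barcodes,
            gene_species=self.gene_species[mask],
        )

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(
            values=self.values[:, mask],
            gene_ids=self.gene_ids,
            barcodes=self.barcodes[mask],
            gene_species=self.gene_species,
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.values.shape == other.values.shape
            and (self.values != other.values).nnz == 0
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.gene_species, other.gene_species)
        )


@dataclass
class CellTable:
    """Per-cell annotations keyed by barcode (label, sample, condition, species)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "barcode" not in self.df.columns:
            raise ValidationError("CellTable requires a 'barcode' column")
        if self.df["barcode"].duplicated().any():
            raise ValidationError("duplicate barcodes in CellTable")
        self.df = self.df.reset_index(drop=True)

    def check_matches(self, m: CountMatrix) -> None:
        missing = set(self.df["barcode"]) - set(m.barcodes)
        if missing:
            raise ValidationError(
                f"{len(missing)} CellTable barcodes absent from CountMatrix"
            )

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class NormalizedMatrix:
    """Natural-log, size-factor-scaled expression: ln(count / sf + 1).

    Dense genes x cells; size factors are positive with geometric mean 1 so
    that the overall count scale is preserved.
    """

    values: np.ndarray
    size_factors: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if np.any(self.size_factors <= 0):
            raise ValidationError("size factors must be positive")
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValidationError("NormalizedMatrix shape mismatch")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.gene_ids)}
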