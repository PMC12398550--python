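"""Readers and writers for the triplet count-matrix format and TSV tables.

The on-disk layout follows the 10x convention: ``matrix.mtx`` (Matrix Market
coordinate, integer, 1-based indices), ``genes.tsv`` (gene id and species tag)
and ``barcodes.tsv``.  Reading and writing are exact inverses on valid
matrices.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CellTable, CountMatrix
from .errors import FormatError, ValidationError

MATRIX_FILE = "matrix.mtx"
GENES_FILE = "genes.tsv"
BARCODES_FILE = "barcodes.tsv"


def read_count_matrix(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style MTX triplet into a :class:`CountMatrix`.

    Species tags are parsed from the gene-id prefix convention
    (``GRCh38_``/``mm10_``) unless the gene table carries an explicit
    ``species`` column.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.stat().st_size == 0:
        raise FormatError(f"empty matrix file: {matrix_path}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)

    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    gene_ids = genes.iloc[:, 0].to_numpy(dtype=object)
    barcode_ids = barcodes.iloc[:, 0].to_numpy(dtype=object)

    if mat.shape[0] != len(gene_ids) or mat.shape[1] != len(barcode_ids):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but tables list "
            f"{len(gene_ids)} genes and {len(barcode_ids)} barcodes"
        )
    species = None
    if genes.shape[1] >= 2:
        species = genes.iloc[:, 1].to_numpy(dtype=object)
    try:
        return CountMatrix(
            values=mat, gene_ids=gene_ids, barcodes=barcode_ids, gene_species=species
        )
    except ValidationError:
        raise


def write_count_matrix(m: CountMatrix, out_dir) -> dict:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` under *out_dir*.

    Round-trip identity: ``read(write(m)) == m`` exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / MATRIX_FILE,
        "genes": out_dir / GENES_FILE,
        "barcodes": out_dir / BARCODES_FILE,
    }
    coo = m.values.tocoo()
    buf = _io.BytesIO()
    scipy.io.mmwrite(
        buf, sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=m.values.shape),
        field="integer",
    )
    paths["matrix"].write_bytes(buf.getvalue())
    pd.DataFrame({"gene": m.gene_ids, "species": m.gene_species}).to_csv(
        paths["genes"], sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": m.barcodes}).to_csv(
        paths["barcodes"], sep="\t", header=False, index=False
    )
    return paths


def read_count_dir(dir_path) -> CountMatrix:
    """Read a directory produced by :func:`write_count_matrix`."""
    dir_path = Path(dir_path)
    return read_count_matrix(
        dir_path / MATRIX_FILE, dir_path / GENES_FILE, dir_path / BARCODES_FILE
    )


def read_cell_table(path) -> CellTable:
    """Read a headered TSV of per-cell annotations."""
    return CellTable(pd.read_csv(path, sep="\t", dtype={"barcode": str}))


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a results table as headered TSV (the pipeline's exchange format)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
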