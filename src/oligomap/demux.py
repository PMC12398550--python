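"""Species demultiplexing of chimera cells from per-species count composition.

A cell is allocated to a species when at least ``min_fraction`` (default
70%, boundary inclusive) of its species-assignable signal maps to that
genome; the fraction can be computed over UMI counts (default) or over
distinct detected genes.  Because ``min_fraction > 0.5``, at most one
species can pass, and everything else is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SPECIES_HUMAN, SPECIES_MOUSE, CountMatrix
from .errors import ValidationError


@dataclass
class DemuxConfig:
    min_fraction: float = 0.70
    basis: str = "umi_counts"  # or "detected_genes"

    def __post_init__(self) -> None:
        if not 0.5 < self.min_fraction <= 1.0:
            raise ValidationError("min_fraction must be in (0.5, 1]")
        if self.basis not in ("umi_counts", "detected_genes"):
            raise ValidationError("basis must be 'umi_counts' or 'detected_genes'")


def assign_species(m: CountMatrix, cfg: DemuxConfig | None = None) -> pd.DataFrame:
    """Per-cell species call table: barcode, human_fraction, call, zero_signal."""
    cfg = cfg or DemuxConfig()
    human_mask = m.gene_species == SPECIES_HUMAN
    mouse_mask = m.gene_species == SPECIES_MOUSE
    if not human_mask.any() or not mouse_mask.any():
        raise ValidationError("matrix must contain genes tagged for both species")
    if cfg.basis == "umi_counts":
        h = np.asarray(m.values[human_mask].sum(axis=0)).ravel().astype(float)
        mu = np.asarray(m.values[mouse_mask].sum(axis=0)).ravel().astype(float)
    else:
        h = np.asarray((m.values[human_mask] > 0).sum(axis=0)).ravel().astype(float)
        mu = np.asarray((m.values[mouse_mask] > 0).sum(axis=0)).ravel().astype(float)
    total = h + mu
    zero = total == 0
    with np.errstate(invalid="ignore"):
        frac = np.where(zero, np.nan, h / np.maximum(total, 1e-300))
    call = np.full(m.n_cells, "ambiguous", dtype=object)
    call[~zero & (frac >= cfg.min_fraction)] = "human"
    call[~zero & (1.0 - frac >= cfg.min_fraction)] = "mouse"
    return pd.DataFrame(
        {
            "barcode": m.barcodes,
            "human_fraction": frac,
            "call": call,
            "zero_signal": zero,
        }
    )


def split_by_species(
    m: CountMatrix, calls: pd.DataFrame
) -> tuple[CountMatrix, CountMatrix, list]:
    """Split into (human matrix over human genes, mouse matrix over mouse genes,
    ambiguous barcode list).  Ambiguous cells appear in neither matrix."""
    if set(calls["barcode"]) != set(m.barcodes):
        raise ValidationError("species calls must cover exactly the matrix barcodes")
    call_of = dict(zip(calls["barcode"], calls["call"]))
    cell_calls = np.array([call_of[b] for b in m.barcodes], dtype=object)
    human_cells = cell_calls == "human"
    mouse_cells = cell_calls == "mouse"
    human_genes = m.gene_species == SPECIES_HUMAN
    mouse_genes = m.gene_species == SPECIES_MOUSE
    human = m.subset_genes(human_genes).subset_cells(human_cells)
    mouse = m.subset_genes(mouse_genes).subset_cells(mouse_cells)
    if human.n_cells == 0:
        warnings.warn("no cells called human")
    if mouse.n_cells == 0:
        warnings.warn("no cells called mouse")
    ambiguous = [b for b, c in zip(m.barcodes, cell_calls) if c == "ambiguous"]
    return human, mouse, ambiguous
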