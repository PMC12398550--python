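"""Demultiplex a mixed human/mouse chimera sample by count composition.

Simulates 600 chimera cells with 5% cross-species count leakage, calls each
cell's species (a cell needs >= 70% of its species-assignable UMIs on one
genome), splits the matrix, and reports accuracy against the known truth.
"""

import numpy as np

from oligomap.demux import DemuxConfig, assign_species, split_by_species
from oligomap.simulate import SimulationConfig, simulate_chimera

cfg = SimulationConfig(contamination_fraction=0.05, seed=7)
matrix, truth = simulate_chimera(cfg, n_cells=600)

calls = assign_species(matrix, DemuxConfig(min_fraction=0.70, basis="umi_counts"))
human, mouse, ambiguous = split_by_species(matrix, calls)

truth_of = dict(zip(truth.cells["barcode"], truth.cells["species"]))
correct = np.mean([truth_of[b] == c for b, c in zip(calls["barcode"], calls["call"])])

print(f"cells: {matrix.n_cells}, human called: {human.n_cells}, "
      f"mouse called: {mouse.n_cells}, ambiguous: {len(ambiguous)}")
print(f"accuracy vs ground truth: {correct:.4f}")
# Accuracy near 1.0 shows that 5% ambient leakage leaves the per-cell
# species composition far from the 70% decision boundary.
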