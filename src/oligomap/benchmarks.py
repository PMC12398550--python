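"""Self-contained validation experiments on synthetic ground truth.

Each function builds its own fixture through :mod:`oligomap.simulate`, runs
the corresponding pipeline stage, and measures recovery against the known
truth.  They are used by the acceptance script and the test suite; all
randomness flows from the ``seed`` argument.

Problem sizes are chosen to finish in minutes on a single CPU: the transfer
fixture uses 8 classes x 200 cells over 500 genes with a 100-epoch x
64-step ensemble schedule, and the hurdle calibration uses 2000 null genes
at 100 cells per group.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import ann, demux, preprocess
from .config import RunConfig
from .dge import hurdle_test
from .simulate import (
    SimulationConfig,
    shuffled_labels,
    simulate_chimera,
    simulate_reference,
    simulate_target,
    simulate_two_group,
)


def standard_transfer_fixture(seed: int) -> SimulationConfig:
    """The standard label-transfer fixture: 8 classes, 500 genes, 200 cells/class."""
    return SimulationConfig(
        n_classes=8,
        n_genes=500,
        cells_per_class=200,
        markers_per_class=10,
        domain_shift_sd=0.3,
        seed=seed,
    )


def _transfer_setup(seed: int, n_top: int = 300):
    cfg = standard_transfer_fixture(seed)
    ref_m, ref_cells, ref_truth = simulate_reference(cfg)
    tgt_m, tgt_truth = simulate_target(cfg, ref_truth)
    src_nm = preprocess.normalize(preprocess.filter_genes(ref_m))
    tgt_nm = preprocess.normalize(preprocess.filter_genes(tgt_m))
    fs = ann.build_feature_space(
        preprocess.select_variable_genes(src_nm, n_top),
        preprocess.select_variable_genes(tgt_nm, n_top),
    )
    Xs = ann.binarize(ref_m, fs)
    Xt = ann.binarize(tgt_m, fs)
    labels = ref_cells.df["label"].to_numpy(dtype=object)
    return Xs, labels, Xt, tgt_truth.cells["label"].to_numpy(dtype=object), fs


def transfer_recovery(
    seed: int, epochs: int = 100, steps_per_epoch: int = 64, n_folds: int = 5
) -> dict:
    """Ensemble label transfer on the standard fixture vs ground truth."""
    Xs, labels, Xt, true_labels, fs = _transfer_setup(seed)
    train_cfg = ann.TrainingConfig(
        n_folds=n_folds, epochs=epochs, steps_per_epoch=steps_per_epoch, seed=seed
    )
    models, fold_metrics = ann.train_ensemble(Xs, labels, ann.ANNConfig(), train_cfg)
    pred = ann.ensemble_predict(models, Xt)
    metrics = ann.evaluate(pred["final_label"], true_labels)
    return {
        "balanced_accuracy": metrics["balanced_accuracy"],
        "macro_precision": metrics["macro_precision"],
        "macro_recall": metrics["macro_recall"],
        "mean_fold_accuracy": float(fold_metrics["balanced_accuracy"].mean()),
        "n_target_cells": int(Xt.shape[0]),
        "n_classes": len(set(labels)),
        "feature_space_size": len(fs),
    }


def permutation_null(
    seed: int, epochs: int = 30, steps_per_epoch: int = 32, n_folds: int = 3
) -> dict:
    """Chance-level check: transfer after shuffling source labels."""
    Xs, labels, Xt, true_labels, _ = _transfer_setup(seed)
    perm = shuffled_labels(labels, seed + 1)
    train_cfg = ann.TrainingConfig(
        n_folds=n_folds, epochs=epochs, steps_per_epoch=steps_per_epoch, seed=seed
    )
    models, _ = ann.train_ensemble(Xs, perm, ann.ANNConfig(), train_cfg)
    pred = ann.ensemble_predict(models, Xt)
    metrics = ann.evaluate(pred["final_label"], true_labels)
    k = len(set(labels))
    return {
        "balanced_accuracy": metrics["balanced_accuracy"],
        "chance_level": 1.0 / k,
        "n_classes": k,
        "n_target_cells": int(Xt.shape[0]),
    }


def gradient_check(seed: int, n_features: int = 50, n_classes: int = 4) -> dict:
    """Max |analytic - central finite difference| of the loss gradient."""
    rng = np.random.default_rng(seed)
    model = ann.init_model(
        n_features, ann.ANNConfig(hidden1=8, hidden2=6), list(range(n_classes)), rng
    )
    model.b1 = rng.normal(0, 0.3, size=model.b1.shape)
    model.b2 = rng.normal(0, 0.3, size=model.b2.shape)
    model.b3 = rng.normal(0, 0.3, size=model.b3.shape)
    X = (rng.random((16, n_features)) > 0.5).astype(float)
    Y = ann.one_hot(rng.integers(0, n_classes, size=16).tolist(), list(range(n_classes)))
    grads = ann.gradients(model, X, Y)
    eps = 1e-6
    worst = 0.0
    checked = 0
    for p, g in zip(model.params(), grads):
        flat = p.ravel()
        for idx in rng.choice(flat.size, size=min(30, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = ann.loss(model, X, Y)
            flat[idx] = orig - eps
            dn = ann.loss(model, X, Y)
            flat[idx] = orig
            worst = max(worst, abs(g.ravel()[idx] - (up - dn) / (2 * eps)))
            checked += 1
    return {"max_abs_difference": float(worst), "n_coordinates": checked}


def demux_recovery(seed: int, n_cells: int = 1000, contamination: float = 0.05) -> dict:
    """Species-call accuracy on a contaminated chimera plus partition check."""
    cfg = SimulationConfig(seed=seed, contamination_fraction=contamination)
    m, truth = simulate_chimera(cfg, n_cells=n_cells)
    calls = demux.assign_species(m)
    human, mouse, ambiguous = demux.split_by_species(m, calls)
    groups = [set(human.barcodes), set(mouse.barcodes), set(ambiguous)]
    partition_ok = set().union(*groups) == set(m.barcodes) and sum(
        len(g) for g in groups
    ) == m.n_cells
    truth_of = dict(zip(truth.cells["barcode"], truth.cells["species"]))
    called = calls[calls["call"] != "ambiguous"]
    correct = np.mean(
        [truth_of[b] == c for b, c in zip(called["barcode"], called["call"])]
    )
    overall = np.sum(
        [truth_of[b] == c for b, c in zip(calls["barcode"], calls["call"])]
    ) / len(calls)
    return {
        "accuracy": float(overall),
        "called_accuracy": float(correct) if len(called) else float("nan"),
        "n_ambiguous": int(len(ambiguous)),
        "partition_exact": bool(partition_ok),
        "n_cells": int(n_cells),
    }


def hurdle_null_calibration(
    seed: int, n_genes: int = 2000, n_per_group: int = 100, alpha: float = 0.05
) -> dict:
    """Type-I error of the hurdle LRT on a fully null two-group fixture."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        cells_per_class=n_per_group,
        markers_per_class=0,
        frac_de_genes=0.0,
        seed=seed,
    )
    m, cells, _ = simulate_two_group(cfg)
    nm = preprocess.normalize(m)
    cond = cells.df["condition"].to_numpy(dtype=object)
    pvals = np.array(
        [hurdle_test(nm, g, cond)["p_value"] for g in nm.gene_ids]
    )
    informative = pvals < 1.0  # genes with at least one testable part
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "n_genes": int(n_genes),
        "n_informative": int(informative.sum()),
        "alpha": alpha,
    }


def clustering_recovery(seed: int, n_per_blob: int = 60, separation: float = 10.0) -> dict:
    """Planted two-blob partition: ARI and modularity against singletons."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n_per_blob, 5))
    b = rng.normal(0, 1, size=(n_per_blob, 5))
    b[:, 0] += separation
    coords = np.vstack([a, b])
    emb = preprocess.Embedding(
        coords=coords,
        explained_variance=np.ones(5),
        loadings=np.eye(5),
        gene_ids=np.arange(5).astype(object),
        barcodes=np.array([f"C{i}" for i in range(2 * n_per_blob)], dtype=object),
    )
    truth = np.array([0] * n_per_blob + [1] * n_per_blob)
    labels = preprocess.cluster_cells(emb, k_neighbors=20, seed=seed)["cluster"].to_numpy()
    q = preprocess.modularity(emb, labels)
    q_singletons = preprocess.modularity(emb, np.arange(len(labels)))
    return {
        "ari": float(adjusted_rand_score(truth, labels)),
        "n_clusters": int(len(set(labels))),
        "modularity": float(q),
        "modularity_singletons": float(q_singletons),
        "n_cells": int(2 * n_per_blob),
    }


def _tree_hashes(root: Path) -> dict:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def pipeline_stability(seed: int, out_dir, chimera_cells: int = 2000) -> dict:
    """Run the full pipeline twice at one seed and compare output hashes."""
    from .pipeline import run_all

    cfg = RunConfig(seed=seed)
    cfg.simulate.chimera_cells = chimera_cells
    cfg.simulate.cells_per_class = 100
    cfg.morphometry.lilliefors_sims = 500
    out_dir = Path(out_dir)
    summaries = []
    hashes = []
    for name in ("run_a", "run_b"):
        summaries.append(run_all(cfg, out_dir / name))
        hashes.append(_tree_hashes(out_dir / name))
    return {
        "hash_stable": bool(hashes[0] == hashes[1]),
        "n_output_files": len(hashes[0]),
        "chimera_cells": chimera_cells,
        "summary": summaries[0],
    }
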