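"""End-to-end orchestration of the synthetic-fixture pipeline.

``run_all`` generates every synthetic input, then runs demultiplexing,
preprocessing/clustering, ANN label transfer, cluster comparison, hurdle
differential expression and morphometry, writing all declared outputs under
one directory.  Given the same configuration (seed included) the written
files are byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ann, compare, demux, dge, io, morphometry, preprocess, simulate
from .config import RunConfig, stage_seed


def _sim_config(cfg: RunConfig, stage: str) -> simulate.SimulationConfig:
    s = cfg.simulate
    return simulate.SimulationConfig(
        n_classes=s.n_classes,
        n_genes=s.n_genes,
        cells_per_class=s.cells_per_class,
        markers_per_class=s.markers_per_class,
        base_mean=s.base_mean,
        marker_fold=s.marker_fold,
        dispersion=s.dispersion,
        dropout_midpoint=s.dropout_midpoint,
        dropout_slope=s.dropout_slope,
        domain_shift_sd=s.domain_shift_sd,
        contamination_fraction=s.contamination_fraction,
        effect_log2fc=s.effect_log2fc,
        frac_de_genes=s.frac_de_genes,
        seed=stage_seed(cfg.seed, stage),
    )


def run_all(cfg: RunConfig, out_dir=None) -> dict:
    """Run every stage on synthetic fixtures; returns a summary dictionary."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log: list[str] = [
        f"oligomap {__version__} run-all (numpy {np.__version__}, pandas {pd.__version__})",
        f"seed={cfg.seed}",
        "config=" + json.dumps(cfg.to_dict(), sort_keys=True),
    ]
    summary: dict = {"seed": cfg.seed}

    # --- simulate ---------------------------------------------------------
    sim_cfg = _sim_config(cfg, "simulate")
    chimera, chi_truth = simulate.simulate_chimera(sim_cfg, n_cells=cfg.simulate.chimera_cells)
    io.write_count_matrix(chimera, out / "sim" / "chimera")
    io.write_table(chi_truth.cells, out / "sim" / "chimera_truth.tsv")

    ref_m, ref_cells, ref_truth = simulate.simulate_reference(sim_cfg)
    tgt_m, tgt_truth = simulate.simulate_target(sim_cfg, ref_truth)
    io.write_count_matrix(ref_m, out / "sim" / "reference")
    io.write_count_matrix(tgt_m, out / "sim" / "target")
    io.write_table(ref_cells.df, out / "sim" / "reference_cells.tsv")
    io.write_table(tgt_truth.cells, out / "sim" / "target_truth.tsv")

    two_m, two_cells, two_truth = simulate.simulate_two_group(sim_cfg)
    io.write_count_matrix(two_m, out / "sim" / "two_group")
    io.write_table(two_cells.df, out / "sim" / "two_group_cells.tsv")
    io.write_table(two_truth.genes, out / "sim" / "two_group_truth.tsv")

    axons, axon_truth = simulate.simulate_morphometry(
        n_axons=cfg.simulate.n_axons,
        g_mean=cfg.simulate.g_mean,
        g_sd=cfg.simulate.g_sd,
        mito_fraction=cfg.simulate.mito_fraction,
        seed=stage_seed(cfg.seed, "morphometry_sim"),
    )
    axons_disk = axons.assign(mito_areas=axons["mito_areas"].map(lambda m: ";".join(f"{x:.9g}" for x in m)))
    io.write_table(axons_disk, out / "sim" / "axons.tsv")
    io.write_table(axon_truth.axons, out / "sim" / "axons_truth.tsv")
    puncta = pd.concat(
        [
            simulate.simulate_puncta(3, 2, 40, 0.6, 3.0, stage_seed(cfg.seed, "puncta_v"), "vehicle"),
            simulate.simulate_puncta(3, 2, 40, 0.6, 4.0, stage_seed(cfg.seed, "puncta_m"), "metformin"),
        ],
        ignore_index=True,
    )
    io.write_table(puncta, out / "sim" / "puncta.tsv")
    log.append("simulate: wrote chimera, reference, target, two_group, axons, puncta")

    # --- demux ------------------------------------------------------------
    dmx_cfg = demux.DemuxConfig(min_fraction=cfg.demux.min_fraction, basis=cfg.demux.basis)
    calls = demux.assign_species(chimera, dmx_cfg)
    io.write_table(calls, out / "demux" / "species_calls.tsv")
    human_m, mouse_m, ambiguous = demux.split_by_species(chimera, calls)
    io.write_count_matrix(human_m, out / "demux" / "human")
    io.write_count_matrix(mouse_m, out / "demux" / "mouse")
    io.write_table(pd.DataFrame({"barcode": ambiguous}), out / "demux" / "ambiguous.tsv")
    truth_species = dict(zip(chi_truth.cells["barcode"], chi_truth.cells["species"]))
    called = calls[calls["call"] != "ambiguous"]
    demux_acc = float(
        np.mean([truth_species[b] == c for b, c in zip(called["barcode"], called["call"])])
    )
    summary["demux_accuracy"] = demux_acc
    summary["demux_ambiguous"] = int(len(ambiguous))
    log.append(f"demux: accuracy={demux_acc:.4f} ambiguous={len(ambiguous)}")

    # --- preprocess + cluster the reference -------------------------------
    qc = preprocess.QCConfig(
        min_cells_per_gene_exclusive=cfg.preprocess.min_cells_per_gene_exclusive,
        mad_multiplier=cfg.preprocess.mad_multiplier,
        max_mito_fraction=cfg.preprocess.max_mito_fraction,
        mito_gene_prefix=cfg.preprocess.mito_gene_prefix,
    )
    ref_f = preprocess.filter_genes(ref_m, qc)
    ref_f, qc_report = preprocess.filter_cells(ref_f, qc)
    io.write_table(qc_report, out / "preprocess" / "qc_report.tsv")
    ref_nm = preprocess.normalize(ref_f)
    hvg = preprocess.select_variable_genes(ref_nm, cfg.preprocess.n_top_genes)
    emb = preprocess.run_pca(ref_nm, hvg, max_pcs=cfg.preprocess.max_pcs)
    n_pcs = preprocess.choose_elbow(
        emb.explained_variance,
        drop_fraction=cfg.preprocess.elbow_drop_fraction,
        floor=cfg.preprocess.elbow_floor,
        cap=cfg.preprocess.max_pcs,
    )
    emb.n_pcs_selected = n_pcs
    clusters = preprocess.cluster_cells(
        emb,
        k_neighbors=cfg.preprocess.k_neighbors,
        resolution=cfg.preprocess.resolution,
        seed=stage_seed(cfg.seed, "cluster"),
        n_pcs=n_pcs,
    )
    io.write_table(clusters, out / "preprocess" / "clusters.tsv")
    summary["n_pcs_selected"] = int(n_pcs)
    summary["n_clusters"] = int(clusters["cluster"].nunique())
    log.append(f"preprocess: {ref_f.n_genes} genes, {ref_f.n_cells} cells, "
               f"{n_pcs} PCs, {summary['n_clusters']} clusters")

    # --- ANN transfer ------------------------------------------------------
    tgt_f = preprocess.filter_genes(tgt_m, qc)
    tgt_nm = preprocess.normalize(tgt_f)
    tgt_hvg = preprocess.select_variable_genes(tgt_nm, cfg.preprocess.n_top_genes)
    fs = ann.build_feature_space(hvg, tgt_hvg)
    Xs = ann.binarize(ref_m, fs)
    Xt = ann.binarize(tgt_m, fs)
    labels = ref_cells.df["label"].to_numpy(dtype=object)
    a = cfg.ann
    ann_cfg = ann.ANNConfig(hidden1=a.hidden1, hidden2=a.hidden2, l1_lambda=a.l1_lambda)
    train_cfg = ann.TrainingConfig(
        n_folds=a.n_folds,
        epochs=a.epochs,
        steps_per_epoch=a.steps_per_epoch,
        per_class_per_step=a.per_class_per_step,
        learning_rate=a.learning_rate,
        rho=a.rho,
        epsilon=a.epsilon,
        seed=stage_seed(cfg.seed, "ann"),
    )
    models, fold_metrics = ann.train_ensemble(Xs, labels, ann_cfg, train_cfg)
    io.write_table(fold_metrics, out / "transfer" / "fold_metrics.tsv")
    pred = ann.ensemble_predict(models, Xt, confidence_threshold=a.confidence_threshold)
    pred.insert(0, "barcode", tgt_m.barcodes)
    io.write_table(pred, out / "transfer" / "predictions.tsv")
    metrics = ann.evaluate(pred["final_label"], tgt_truth.cells["label"])
    summary["transfer_balanced_accuracy"] = metrics["balanced_accuracy"]
    summary["feature_space_size"] = len(fs)
    log.append(
        f"transfer: F={len(fs)} balanced_accuracy={metrics['balanced_accuracy']:.4f}"
    )

    # --- comparative -------------------------------------------------------
    ref_cent = compare.cluster_centroids(ref_nm,
        ref_cells.df.set_index("barcode").loc[list(ref_nm.barcodes), "label"].to_numpy(dtype=object),
        fs)
    pred_of = dict(zip(pred["barcode"], pred["final_label"]))
    tgt_labels = np.asarray([pred_of[b] for b in tgt_nm.barcodes], dtype=object)
    tgt_cent = compare.cluster_centroids(tgt_nm, tgt_labels, fs)
    sim_mat = compare.cosine_similarity(tgt_cent, ref_cent)
    io.write_table(sim_mat.reset_index(names="target_cluster"), out / "compare" / "cosine_similarity.tsv")
    diag = float(np.mean([sim_mat.loc[c, c] for c in sim_mat.index if c in sim_mat.columns]))
    summary["matched_cluster_cosine"] = diag
    comp = compare.composition_compare(two_cells, cluster_col="label")
    io.write_table(comp, out / "compare" / "composition.tsv")
    log.append(f"compare: mean matched-cluster cosine={diag:.4f}")

    # --- hurdle DGE --------------------------------------------------------
    two_f = preprocess.filter_genes(two_m, qc)
    two_nm = preprocess.normalize(two_f)
    cond = two_cells.df.set_index("barcode").loc[list(two_nm.barcodes), "condition"].to_numpy(dtype=object)
    thresholds = dge.DGEThresholds(
        min_abs_log2fc=cfg.dge.min_abs_log2fc, max_adj_p=cfg.dge.max_adj_p
    )
    prefilter = dge.MarkerFilter(
        min_log2fc=cfg.dge.min_log2fc,
        min_pct_in=cfg.dge.min_pct_in,
        max_pct_out=cfg.dge.max_pct_out,
    )
    up, down, table = dge.condition_contrast(two_nm, cond, thresholds=thresholds, prefilter=prefilter)
    io.write_table(table, out / "dge" / "contrast.tsv")
    io.write_table(pd.DataFrame({"gene": up}), out / "dge" / "upregulated.tsv")
    io.write_table(pd.DataFrame({"gene": down}), out / "dge" / "downregulated.tsv")
    truth_de = set(two_truth.genes.loc[two_truth.genes["is_de"], "gene"])
    found = set(up) | set(down)
    jacc = len(found & truth_de) / len(found | truth_de) if (found or truth_de) else 1.0
    summary["dge_up"] = len(up)
    summary["dge_down"] = len(down)
    summary["dge_jaccard_vs_truth"] = jacc
    log.append(f"dge: up={len(up)} down={len(down)} jaccard={jacc:.3f}")

    # --- morphometry -------------------------------------------------------
    mcfg = morphometry.MorphometryConfig(
        min_axon_diameter=cfg.morphometry.min_axon_diameter,
        normality_alpha=cfg.morphometry.normality_alpha,
        lilliefors_sims=cfg.morphometry.lilliefors_sims,
        lilliefors_seed=stage_seed(cfg.seed, "lilliefors"),
    )
    kept, excluded = morphometry.exclude_small_axons(axons, mcfg)
    kept = kept.assign(g_ratio=morphometry.g_ratio(kept["axon_area"], kept["outer_area"]))
    io.write_table(kept.drop(columns=["mito_areas"]), out / "morphometry" / "g_ratios.tsv")
    per_animal, myel_summary = morphometry.myelinated_fraction(kept)
    io.write_table(per_animal, out / "morphometry" / "myelinated_per_animal.tsv")
    io.write_table(myel_summary, out / "morphometry" / "myelinated_summary.tsv")
    per_obj, mito_per_animal = morphometry.mito_area_fraction(kept)
    io.write_table(per_obj, out / "morphometry" / "mito_per_object.tsv")
    io.write_table(mito_per_animal, out / "morphometry" / "mito_per_animal.tsv")
    mito_test = morphometry.group_compare(mito_per_animal, "mito_fraction", cfg=mcfg)
    per_roi, score_summary = morphometry.composite_score(puncta)
    io.write_table(per_roi, out / "morphometry" / "composite_per_roi.tsv")
    io.write_table(score_summary, out / "morphometry" / "composite_summary.tsv")
    summary["n_axons_kept"] = int(len(kept))
    summary["n_axons_excluded"] = int(len(excluded))
    summary["mean_g_ratio"] = float(kept["g_ratio"].mean())
    summary["mito_test"] = mito_test["test"]
    summary["mito_test_p"] = mito_test["p_value"]
    log.append(
        f"morphometry: kept={len(kept)} excluded={len(excluded)} "
        f"mean_g={summary['mean_g_ratio']:.4f} mito_test={mito_test['test']}"
    )

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary
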