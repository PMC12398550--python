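"""Transfer atlas cell-type labels to a domain-shifted dataset with the ANN ensemble.

Builds a labelled 8-class source "atlas" and an unlabelled target whose
gene-wise means are perturbed by log-normal domain-shift factors, binarizes
expression over the union of variable genes, trains a stratified 5-fold
ensemble (scaled-down schedule), and scores the plurality-vote labels
against the hidden truth.
"""

from oligomap import ann, preprocess
from oligomap.simulate import SimulationConfig, simulate_reference, simulate_target

cfg = SimulationConfig(n_classes=8, n_genes=500, cells_per_class=100,
                       domain_shift_sd=0.3, seed=3)
source, source_cells, truth = simulate_reference(cfg)
target, target_truth = simulate_target(cfg, truth)

src_nm = preprocess.normalize(preprocess.filter_genes(source))
tgt_nm = preprocess.normalize(preprocess.filter_genes(target))
feature_space = ann.build_feature_space(
    preprocess.select_variable_genes(src_nm, 300),
    preprocess.select_variable_genes(tgt_nm, 300),
)
print(f"binarized feature space: {len(feature_space)} genes")

X_source = ann.binarize(source, feature_space)
X_target = ann.binarize(target, feature_space)
labels = source_cells.df["label"].to_numpy(dtype=object)

models, fold_metrics = ann.train_ensemble(
    X_source, labels, ann.ANNConfig(),
    ann.TrainingConfig(n_folds=5, epochs=30, steps_per_epoch=32, seed=0),
)
print("per-fold validation balanced accuracy:")
print(fold_metrics.to_string(index=False))

pred = ann.ensemble_predict(models, X_target)
metrics = ann.evaluate(pred["final_label"], target_truth.cells["label"])
print(f"target balanced accuracy: {metrics['balanced_accuracy']:.3f}, "
      f"macro precision: {metrics['macro_precision']:.3f}, "
      f"ties broken: {int(pred['tie_broken'].sum())}")
# Balanced accuracy well above 1/8 = 0.125 chance shows the detection
# pattern survives the domain shift that breaks naive centroid matching.
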