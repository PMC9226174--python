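# cgsig — cell-graph survival signatures from multiplexed IHC

`cgsig` turns per-cell feature tables exported from multiplexed
immunohistochemistry (mIHC) images into a patient-level prognostic signature
("digital grade") for survival-interval classification, and evaluates its
prognostic value with standard survival statistics.

It is aimed at computational-pathology researchers who have HALO-style cell
segmentation tables (pixel coordinates plus per-cell marker/morphology
features at 0.5 µm/pixel) and right-censored overall-survival (OS) follow-up,
and who want a reproducible spatial-graph deep-learning baseline without
starting from raw images.

## The method

1. **Cell-graphs.** Each image is partitioned into non-overlapping regions of
   at most 100 cells (density-adaptive grid with recursive bisection). Within
   a region, cells *i*, *j* at Euclidean pixel distance *d(i,j)* are joined by
   an edge with reciprocal-distance weight

       w_ij = 40 / d(i,j)   if d(i,j) ≤ 40 px (20 µm),   else no edge,

   so interaction strength decays with distance and vanishes beyond the
   20 µm effective cell-interaction range. Nodes carry 35 attributes —
   5 optical features for each of 6 biomarkers (DAPI, PD-L1, CD68, Foxp3,
   CD8, Pan-CK) plus 5 morphology features — min-max normalized to [0, 1]
   on the training split.

2. **Labels.** OS is binned into classes: binary (short-term < 24 mo,
   long-term > 48 mo, 24–48 mo *uncategorized*) or ternary (thresholds 12
   and 60 months). Every cell-graph inherits its patient's label; all splits
   and cross-validation folds are at the patient level.

3. **GNN classifier.** Four blocks of two graph convolutions (GIN,
   `X' = MLP((A + (1+ε)I) X)`, or GCN, `X' = ReLU(D̃^-1/2 (A+I) D̃^-1/2 X W)`)
   followed by TopK or SAG pooling at ratio 0.5; per-block mean‖max summary
   layers are summed and fed to a three-layer fully connected head with
   softmax. Training: Adam, lr 5·10⁻⁴, weight decay 10⁻⁴, batch 256, up to
   200 epochs with early stopping; the Table-style hyperparameter grid
   (3 learning rates × 3 decays × 2 widths × 3 ratios = 54 points) is
   searched exhaustively.

4. **Digital grade.** Per-graph predicted classes are aggregated per patient
   by largest vote proportion; the resulting grade is evaluated with
   Kaplan–Meier curves, log-rank tests, Cox proportional-hazards models
   (hazard ratio, Harrell's C) and compared against TNM stage regroupings
   (TNM-2/3/6) and the combined grade×TNM-2 variable.

5. **Interpretability.** A tight Haar-type graph-framelet transform
   decomposes each node-feature channel into low-pass and per-scale
   high-pass energies, separating smooth from spatially oscillatory signal.

Because clinical mIHC cohorts are rarely public, the package ships a
synthetic tumor-microenvironment generator (`cgsig.synthetic`): Pan-CK⁺
tumor cells in Gaussian nests, immune cells at class-dependent distances
from the nests, class-shifted morphology/intensity distributions, and OS
times drawn inside class-consistent windows with censoring. Every stage of
the pipeline is tested end-to-end on these cohorts.

## Worked example

```python
from cgsig.synthetic import acceptance_cohort_config, generate_cohort
from cgsig.labels import BinningRule, SplitSpec, label_cohort, split_patients
from cgsig.cell_table_io import fit_normalizer, apply_normalizer
from cgsig.graphs import build_all
from cgsig.nn.layers import GNNConfig
from cgsig.train import TrainConfig, train_model, predict_dataset, evaluate

cohort = generate_cohort(acceptance_cohort_config(seed=1, n_patients=20))
labels = label_cohort(cohort.patients, BinningRule("binary"))
classed = {p: l for p, l in labels.items() if isinstance(l, int)}
parts = split_patients(sorted(classed), SplitSpec(seed=0), classed)
train_p = [p for p, s in parts.items() if s == "train"]
norm = fit_normalizer([t for t in cohort.tables if t.patient_id in train_p])
ds = build_all([apply_normalizer(norm, t) for t in cohort.tables], labels)

gnn = GNNConfig(conv_type="gin", pool_type="topk", hidden_units=32)
params, _ = train_model(
    ds.subset(train_p),
    ds.subset([p for p, s in parts.items() if s == "val"]),
    gnn, TrainConfig(max_epochs=40, patience=15, seed=0))
probs, _, y = predict_dataset(
    params, ds.subset([p for p, s in parts.items() if s == "test"]).labeled(), gnn)
rep = evaluate(probs, y, 2)
print(f"test accuracy {rep.accuracy:.3f}  AUROC {rep.mean_auroc:.3f}")
```

Output:

```
test accuracy 0.979  AUROC 1.000
```

i.e. on held-out patients of this strongly class-separated synthetic cohort,
97.9 % of the ~50-node cell-graphs are classified into the correct survival
interval and the graph-level ROC is essentially perfect; majority voting then
grades every test patient correctly.

The same workflow runs from the shell:

```bash
cgsig simulate --config sim.yaml --out cohort/ --seed 17
cgsig run --config experiment.yaml --out run/
cgsig report --run run/
```

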