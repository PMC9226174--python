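# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `cgsig`, in the order the pipeline runs.

## Cell tables and normalization

A cell table holds one row per segmented cell: pixel coordinates (0.5 µm per
pixel, origin top-left, 0-based) and 35 node attributes — for each of six
biomarkers (DAPI, PD-L1, CD68, Foxp3, CD8, Pan-CK) the five optical features
*positive*, *positive nucleus*, *positive cytoplasm* (Booleans stored as
0/1), *nucleus intensity*, *cytoplasm intensity*, plus five morphology
features (cell area, cytoplasm area, nucleus area, nucleus perimeter,
nucleus roundness). Canonical snake-case column names are used; a
`header_map` on `FeatureSchema` adapts raw exports whose headers differ.

Features are min-max scaled to [0, 1]. The scaler is fitted on the training
patients only and applied to validation/test data with clamping into [0, 1],
avoiding information leakage through the feature range. A constant feature
maps to 0 (rather than dividing by zero); the column is flagged so the
caller can drop it.

## Survival binning

Binary: OS < 24 months → short-term (0); OS > 48 months → long-term (1);
the 24–48 month band is *uncategorized* — excluded from classifier data but
retained for survival analysis. Ternary thresholds default to 12 and 60
months; 50 months is selectable where the older convention is wanted.
Boundary values fall into the middle band (the definitions are strict
inequalities on both sides). Censored patients are classifiable only when
their follow-up already exceeds the upper threshold (they are then known to
be long-term); censored below it, their class is unknowable and they are
excluded from classifier data while remaining in the survival analyses.
These censoring rules are this package's own convention; alternatives can
be composed from `bin_survival`'s outputs.

Splits are 64/16/20 train/validation/test at the patient level, stratified
by class (largest-remainder rounding per stratum); cross-validation uses
k = 5 patient-disjoint folds, stratified the same way. Graphs always follow
their patient, so no cell of a test patient is ever seen in training.

## Cell-graph construction

Each image is partitioned into non-overlapping regions of at most
`max_cells = 100` cells: a square grid with tile side
`ceil(sqrt(max_cells · A / n))` (A the bounding-box area, n the cell count)
is laid over the image, and any tile exceeding the cap is bisected along its
longer axis recursively. Tiles with fewer than `min_cells = 10` cells are
discarded — such fragments carry almost no neighborhood structure; the
threshold is configurable. The procedure is deterministic.

Within a region, edges join all cell pairs within 40 px (20 µm — the assumed
maximum effective interaction distance between immune and tumor cells) with
weight w = 40/d. Coincident or near-duplicate cells (d < 1 px) are kept and
their weight capped at 40 via `d_min = 1`, since the reciprocal law is
singular at d = 0. Edges are stored once (i < j) and expanded symmetrically
when the adjacency is materialized. Neighbor search uses a k-d tree and is
tested against an all-pairs oracle.

## Network architecture and training

Four blocks of **two** graph convolutions followed by one pooling step
(ratio 0.5, keeping `ceil(ratio · n)` nodes per graph, ties broken toward
the lower node index; TopK scores are normalized feature projections, SAG
scores come from a one-layer graph convolution; kept features are gated by
tanh of their score). The convolutions consume the *weighted* adjacency, so
the reciprocal-distance weights of the edge rule actually shape message
passing. For GIN the adjacency is first rescaled by D^-1/2 A D^-1/2 on
weighted degrees (`message_norm="sym"`), which preserves relative edge
weights while bounding the propagation operator's norm — with eight stacked
convolutions the raw weighted adjacency (row sums up to ~100) makes
activations diverge. GIN's ε defaults to 0 (optionally learnable); the GIN
MLP is two ReLU layers.

The summary layer concatenates per-graph mean and max of node features
after every block and sums the four block summaries (jumping-knowledge
style). The readout head is three fully connected layers shrinking
2h → h → h/2 → classes with terminal softmax (the summary vector is 2h wide
because of the mean‖max concatenation). A graph emptied of nodes would
contribute a zero summary, though pooling with `ceil` can never fully empty
a graph.

Training minimizes cross-entropy with Adam (lr 5·10⁻⁴, L2 weight decay
10⁻⁴, batch 256, ≤ 200 epochs), early-stopping on validation loss with
patience 20 and restoring the best-epoch parameters. The loss is unweighted
by default; a class-weight option exists for imbalanced cohorts. All
randomness (initialization, batch order) flows from one integer seed;
single-threaded runs are exactly reproducible. Hyperparameter search is an
exhaustive 54-point grid (learning rate {1e-4, 5e-4, 1e-3} × weight decay
{1e-4, 5e-4, 1e-3} × hidden {256, 512} × ratio {0.5, 0.65, 0.75}), ranked
by validation AUROC with validation loss as tie-break.

The layers and optimizer run on a compact reverse-mode autodiff engine
(`cgsig.nn.tensor`) providing exactly the operator set the model needs
(dense/sparse matmul, broadcast arithmetic, ReLU/tanh, row gather,
per-graph segment mean/max, fused softmax cross-entropy). Sparse adjacency
matrices are constants — no gradient flows into graph structure; the
segment-max subgradient splits equally among tied rows. Analytic gradients
are verified against central finite differences in the test suite.

## Patient aggregation

Per-graph hard labels are counted per patient; the digital grade is the
class with the largest vote share. Ties break toward the shorter-survival
class — conservative for clinical triage — and a mean-probability soft vote
is available. Under independent per-graph errors at rate < 0.5, majority
voting over n graphs drives the patient-level error below the Hoeffding
bound exp(−2n(p−½)²), which the tests check empirically.

## Survival statistics

Kaplan–Meier estimation, the multi-group log-rank test, Harrell's C and Cox
proportional-hazards regression are computed with lifelines; the test suite
cross-checks them against hand-computed product limits, a permutation
reference, an exhaustive comparable-pair oracle and parameter-recovery
simulations. Cox models use Efron's tie correction (month-resolution times
guarantee ties); confidence intervals are Wald on the log hazard ratio. The
C-index treats risk scores in the Cox orientation (higher = shorter
survival); digital grades order the other way, so grade scores are negated
before concordance, making informative grades score above 0.5. In
`survival_report` the Cox fit carries a small ridge penalty (0.1), because a
perfectly separating grade otherwise sends the coefficient to −∞;
coefficients with |log HR| > 10 are flagged as separation. The median
survival is the first time the curve reaches ≤ 0.5.

TNM regroupings: TNM-2 (I+II vs III), TNM-3 (I vs II vs III), TNM-6
(I, IIA, IIB, IIIA, IIIB, IIIC, with bare I substages collapsed to I).
Stage-IV patients must be excluded before regrouping, and the functions
refuse them. The combined grade×TNM-2 variable is the 2×2 product coded 0–3
from best to worst expected prognosis.

## Graph framelets

The framelet transform diagonalizes the weighted graph Laplacian
(unnormalized by default; normalized selectable) and evaluates a Haar-type
filter bank — low-pass α̂(ξ) = cos(ξ/2), one high-pass β̂(ξ) = sin(ξ/2) —
at dyadically dilated arguments. Eigenvalues are rescaled to [0, π] so the
finest high-pass spans the whole spectrum. With J scale levels the filters

    high_j(ξ) = sin(ξ/2^(J−j+1)) · Π_{t<J−j+1} cos(ξ/2^t),
    low(ξ)    = Π_{t=1..J} cos(ξ/2^t)

square-sum to 1 identically by telescoping sin²+cos², so the frame is tight:
reconstruction is exact and coefficient energy equals signal energy
(Parseval), both enforced at 1e−8 in the tests. Larger j carries finer
detail; a constant signal has exactly zero high-pass content. Whole images
above 2,000 cells are tiled with the standard sub-sampling regions and
per-channel energies summed across tiles (full eigendecomposition at that
size is the cost ceiling, not a modeling choice); channel summaries report
per-feature low/high-pass ℓ² energies per scale.

## Synthetic cohorts

The generator emulates a TMA-core mIHC experiment: by default 7,000–13,000
cells on a 3,000 px (1.5 mm) field; 40 % Pan-CK⁺ tumor cells in five
Gaussian nests (σ = radius/2, radius 150 px), 25 % immune cells (CD8 12 %,
CD68 8 %, Foxp3 5 %) placed at an exponential radial offset beyond a nest
boundary, the rest uniform stroma. Class effects enter through three knobs:
the immune proximity scale (default 240 px for the short-survival class vs
30 px for the long-survival class — infiltrated tumors fare better), a
morphology mean shift (0.6 sd on the short class) and a DAPI
nucleus-intensity shift (0.35). Marker intensities are Gaussian
(positive ≈ 0.7, negative ≈ 0.15, sd 0.08) and Boolean positivity follows
cell type (PD-L1 is enriched on tumor and macrophages). OS times are
uniform inside class windows chosen strictly inside the binning bands
(binary: [0, 23.5] / [48.5, 88]), so generated labels are always consistent
with the thresholds; censoring flips the event indicator at the configured
rate without moving the time. A separate exponential two-group simulator
with known hazard ratio and calibrated censoring backs the Cox
parameter-recovery tests.

What the generator does **not** model: realistic marker correlation
structure, segmentation artifacts, staining batch effects, spatial
heterogeneity beyond isotropic nests, competing risks, or any faithful
PD-L1/CD163 biology. Passing tests therefore demonstrate that the pipeline
recovers planted spatial/morphological class structure and that its
statistics are correctly implemented — not clinical performance on real
cohorts.

## Problem sizes in tests and the acceptance script

End-to-end runs use a scaled-down preset (`acceptance_cohort_config`):
60 patients, 1,100–1,400 cells on a 1,200 px field (~23 graphs per
patient), GIN-TopK with 32 hidden units, ≤ 60 epochs. This keeps a full
simulate→train→evaluate→survival chain at a few minutes on one CPU while
preserving the default effect sizes; unit tests use still smaller
constructed datasets. The full-size TMA geometry (7,000–13,000 cells,
3,000 px) remains the generator's default for users who want realistic
cohort scale.

## Known limitations

- The training loop is CPU-bound numpy; at the full 512-hidden, 16,951-graph
  scale it is orders of magnitude slower than a GPU framework. The
  architecture is faithful but the package is sized for method study, not
  large-cohort production training.
- Sub-sampling geometry (grid + bisection) is one deterministic reading of
  "non-overlapping regions of ~100 cells"; sliding-window variants with
  other geometry are deliberately out of scope.
- The digital grade uses hard votes; learned aggregation is out of scope.
- Framelet analysis is interpretability-only; framelet-based convolution
  layers are not implemented.
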