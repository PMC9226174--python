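"""Training loop, metrics, cross-validation, grid search and feature ablation.

Graph-level classification metrics follow the study design: accuracy,
macro-F1, the generalized (multiclass) Matthews correlation coefficient and
per-class one-vs-rest AUROC, all computed on held-out cell-graphs whose
patients never appear in training (patient-level splits, enforced).
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import (
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)

from .graphs import GraphDataset
from .labels import make_cv_folds
from .nn.layers import (
    Adam,
    GNNConfig,
    init_params,
    make_batch,
    model_forward,
    predict_proba,
)
from .nn.tensor import softmax_cross_entropy
from .schema import DEFAULT_SCHEMA, FEATURE_GROUPS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self):
        for name in ("learning_rate", "weight_decay", "batch_size", "max_epochs",
                     "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MetricReport:
    accuracy: float
    macro_f1: float
    mcc: float
    auroc: dict[int, float | None]
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    n: int = 0

    @property
    def mean_auroc(self) -> float | None:
        vals = [v for v in self.auroc.values() if v is not None]
        return float(np.mean(vals)) if vals else None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
            "auroc": {str(k): v for k, v in self.auroc.items()},
            "mean_auroc": self.mean_auroc,
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }


def evaluate(probs: np.ndarray, labels: np.ndarray, n_classes: int | None = None) -> MetricReport:
    """Score per-graph probability vectors against integer labels."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(probs) != len(labels):
        raise ValueError("predictions and labels differ in length")
    n_classes = n_classes or probs.shape[1]
    pred = probs.argmax(axis=1)
    classes = np.arange(n_classes)
    cm = confusion_matrix(labels, pred, labels=classes)
    rowsum = cm.sum(axis=1, keepdims=True)
    cm_norm = np.divide(cm, np.maximum(rowsum, 1), dtype=float)
    auroc: dict[int, float | None] = {}
    for c in classes:
        pos = labels == c
        if pos.all() or not pos.any():
            logger.warning("AUROC undefined for class %d (single-class labels)", c)
            auroc[int(c)] = None
        else:
            auroc[int(c)] = float(roc_auc_score(pos, probs[:, c]))
    return MetricReport(
        accuracy=float((pred == labels).mean()),
        macro_f1=float(f1_score(labels, pred, labels=classes, average="macro",
                                zero_division=0)),
        mcc=float(matthews_corrcoef(labels, pred)),
        auroc=auroc,
        confusion=cm,
        confusion_normalized=cm_norm,
        n=len(labels),
    )


def _check_disjoint(train: GraphDataset, val: GraphDataset) -> None:
    overlap = set(train.patient_ids()) & set(val.patient_ids())
    if overlap:
        raise ValueError(f"patient-level leakage between splits: {sorted(overlap)}")


def _copy_params(params):
    return {k: copy.deepcopy(v.data) for k, v in params.items()}


def _batch_iter(graphs, batch_size, rng, feature_columns):
    order = rng.permutation(len(graphs))
    for start in range(0, len(order), batch_size):
        chunk = [graphs[i] for i in order[start:start + batch_size]]
        yield make_batch(chunk, feature_columns)


def train_model(
    train_set: GraphDataset,
    val_set: GraphDataset,
    gnn_config: GNNConfig,
    config: TrainConfig = TrainConfig(),
    feature_columns: np.ndarray | None = None,
):
    """Minimize cross-entropy with Adam; early-stop on validation loss.

    Returns (params, history); params are those of the best validation epoch.
    """
    _check_disjoint(train_set, val_set)
    train_graphs = train_set.labeled().graphs
    val_graphs = val_set.labeled().graphs
    if not train_graphs or not val_graphs:
        raise ValueError("empty labeled train or validation set")
    rng = np.random.default_rng(config.seed)
    params = init_params(gnn_config, rng)
    opt = Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    val_batch = make_batch(val_graphs, feature_columns)
    val_labels = val_batch.labels

    best_loss, best_params, best_epoch = np.inf, _copy_params(params), -1
    history = []
    for epoch in range(config.max_epochs):
        losses = []
        for batch in _batch_iter(train_graphs, config.batch_size, rng, feature_columns):
            opt.zero_grad()
            logits = model_forward(params, batch, gnn_config)
            loss, _ = softmax_cross_entropy(logits, batch.labels)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_logits = model_forward(params, val_batch, gnn_config)
        val_loss, val_probs = softmax_cross_entropy(val_logits, val_labels)
        val_loss = float(val_loss.data)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "val_accuracy": float((val_probs.argmax(1) == val_labels).mean()),
            }
        )
        if val_loss < best_loss - 1e-9:
            best_loss, best_epoch = val_loss, epoch
            best_params = _copy_params(params)
        elif epoch - best_epoch >= config.patience:
            break
    for k, v in best_params.items():
        params[k].data = v
    return params, history


def predict_dataset(
    params,
    dataset: GraphDataset,
    gnn_config: GNNConfig,
    feature_columns: np.ndarray | None = None,
    batch_size: int = 512,
):
    """Per-graph probability matrix plus aligned (patient_id, label) metadata."""
    graphs = dataset.graphs
    probs = []
    for start in range(0, len(graphs), batch_size):
        batch = make_batch(graphs[start:start + batch_size], feature_columns)
        probs.append(predict_proba(params, batch, gnn_config))
    probs = np.vstack(probs) if probs else np.empty((0, gnn_config.n_classes))
    pids = [g.patient_id for g in graphs]
    labels = np.array([-1 if g.label is None else g.label for g in graphs])
    return probs, pids, labels


def cross_validate(
    dataset: GraphDataset,
    gnn_config: GNNConfig,
    config: TrainConfig = TrainConfig(),
    k: int = 5,
    n_repeats: int = 1,
    val_fraction: float = 0.2,
):
    """Repeated k-fold CV with patient-level folds stratified by patient label.

    Within each training split a patient-level validation subset (for early
    stopping) is carved out.  Repeats change only the fold/seed randomness.
    Returns (list of per-fold MetricReports, aggregate dict with mean/sd).
    """
    labeled = dataset.labeled()
    patient_label = {g.patient_id: g.label for g in labeled.graphs}
    pids = sorted(patient_label)
    reports = []
    for rep in range(n_repeats):
        folds = make_cv_folds(pids, k=k, seed=config.seed + rep, labels=patient_label)
        for fold in range(k):
            test_pids = set(folds.fold_members(fold))
            rest = [p for p in pids if p not in test_pids]
            rng = np.random.default_rng(config.seed + 1000 * rep + fold)
            rest = list(rng.permutation(rest))
            n_val = max(1, int(round(val_fraction * len(rest))))
            val_pids, train_pids = set(rest[:n_val]), set(rest[n_val:])
            params, _ = train_model(
                labeled.subset(train_pids),
                labeled.subset(val_pids),
                gnn_config,
                replace(config, seed=config.seed + 1000 * rep + fold),
            )
            test_set = labeled.subset(test_pids)
            probs, _, labels = predict_dataset(params, test_set, gnn_config)
            reports.append(evaluate(probs, labels, gnn_config.n_classes))
    agg = {
        "accuracy": (float(np.mean([r.accuracy for r in reports])),
                     float(np.std([r.accuracy for r in reports]))),
        "macro_f1": (float(np.mean([r.macro_f1 for r in reports])),
                     float(np.std([r.macro_f1 for r in reports]))),
        "mcc": (float(np.mean([r.mcc for r in reports])),
                float(np.std([r.mcc for r in reports]))),
    }
    return reports, agg


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter grid: 3 learning rates x 3 decays x 2 widths x 3 ratios."""

    learning_rate: tuple[float, ...] = (1e-4, 5e-4, 1e-3)
    weight_decay: tuple[float, ...] = (1e-4, 5e-4, 1e-3)
    hidden_units: tuple[int, ...] = (256, 512)
    pooling_ratio: tuple[float, ...] = (0.5, 0.65, 0.75)

    def enumerate(self) -> list[dict]:
        if not all((self.learning_rate, self.weight_decay, self.hidden_units,
                    self.pooling_ratio)):
            raise ValueError("empty search space")
        return [
            {"learning_rate": lr, "weight_decay": wd,
             "hidden_units": h, "pooling_ratio": r}
            for lr, wd, h, r in itertools.product(
                self.learning_rate, self.weight_decay,
                self.hidden_units, self.pooling_ratio)
        ]


def grid_search(
    space: SearchSpace,
    train_set: GraphDataset | None,
    val_set: GraphDataset | None,
    gnn_config: GNNConfig,
    config: TrainConfig = TrainConfig(),
    dry_run: bool = False,
):
    """Exhaustive enumeration of the grid, ranked by validation AUROC.

    ``dry_run=True`` returns the enumerated configurations without training.
    Ties in AUROC break toward the lower validation loss.
    """
    combos = space.enumerate()
    if dry_run:
        return combos
    results = []
    for combo in combos:
        gc = replace(gnn_config, hidden_units=combo["hidden_units"],
                     pooling_ratio=combo["pooling_ratio"])
        tc = replace(config, learning_rate=combo["learning_rate"],
                     weight_decay=combo["weight_decay"])
        params, history = train_model(train_set, val_set, gc, tc)
        probs, _, labels = predict_dataset(params, val_set.labeled(), gc)
        report = evaluate(probs, labels, gc.n_classes)
        results.append(
            {**combo,
             "val_auroc": report.mean_auroc,
             "val_loss": min(h["val_loss"] for h in history)}
        )
    results.sort(key=lambda r: (-(r["val_auroc"] if r["val_auroc"] is not None else -1),
                                r["val_loss"]))
    return results


def ablate_features(
    train_set: GraphDataset,
    val_set: GraphDataset,
    test_set: GraphDataset,
    gnn_config: GNNConfig,
    config: TrainConfig = TrainConfig(),
    groups: tuple[str, ...] = FEATURE_GROUPS,
    n_repeats: int = 5,
):
    """Leave-one-feature-group-out ablation.

    Trains ``n_repeats`` models (fresh random initialization each) with all
    35 features and with each 5-column group removed; reports test accuracy
    mean, sd and delta versus the all-features baseline.
    """
    schema = DEFAULT_SCHEMA
    for g in groups:
        schema.group_columns(g)  # raises on unknown group names
    rows = []
    baseline_mean = None
    for name in ("all_features",) + tuple(groups):
        if name == "all_features":
            cols = np.arange(schema.n_features)
        else:
            drop = set(schema.group_columns(name))
            cols = np.array([i for i in range(schema.n_features) if i not in drop])
        gc = replace(gnn_config, in_features=len(cols))
        accs = []
        for rep in range(n_repeats):
            tc = replace(config, seed=config.seed + rep)
            params, _ = train_model(train_set, val_set, gc, tc, feature_columns=cols)
            probs, _, labels = predict_dataset(params, test_set.labeled(), gc,
                                               feature_columns=cols)
            accs.append(evaluate(probs, labels, gc.n_classes).accuracy)
        mean, sd = float(np.mean(accs)), float(np.std(accs))
        if name == "all_features":
            baseline_mean = mean
        rows.append(
            {"setting": name if name == "all_features" else f"no_{name}",
             "n_features": len(cols), "accuracy_mean": mean, "accuracy_sd": sd,
             "delta_vs_all": mean - baseline_mean}
        )
    return rows
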