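import numpy as np
import pytest

from cgsig.graphs import GraphDataset
from cgsig.nn.layers import GNNConfig
from cgsig.train import (
    SearchSpace,
    TrainConfig,
    ablate_features,
    cross_validate,
    evaluate,
    grid_search,
    predict_dataset,
    train_model,
)

from conftest import micro_dataset, random_graph


def probs_from_preds(preds, labels, n_classes=2):
    p = np.full((len(preds), n_classes), 0.0)
    p[np.arange(len(preds)), preds] = 1.0
    return p


def brute_force_metrics(probs, labels):
    """Definitional accuracy / macro-F1 / MCC / AUROC oracle."""
    pred = probs.argmax(1)
    labels = np.asarray(labels)
    k = probs.shape[1]
    acc = np.mean(pred == labels)
    f1s = []
    for c in range(k):
        tp = np.sum((pred == c) & (labels == c))
        fp = np.sum((pred == c) & (labels != c))
        fn = np.sum((pred != c) & (labels == c))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    # generalized (R_K) correlation
    c_mat = np.zeros((k, k))
    for t, p_ in zip(labels, pred):
        c_mat[t, p_] += 1
    n = c_mat.sum()
    tr = np.trace(c_mat)
    dot_tp = np.sum(c_mat.sum(0) * c_mat.sum(1))
    denom = np.sqrt(n**2 - np.sum(c_mat.sum(0) ** 2)) * np.sqrt(n**2 - np.sum(c_mat.sum(1) ** 2))
    mcc = (tr * n - dot_tp) / denom if denom else 0.0
    aurocs = {}
    for c in range(k):
        pos, neg = probs[labels == c, c], probs[labels != c, c]
        if len(pos) and len(neg):
            greater = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            aurocs[c] = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return acc, np.mean(f1s), mcc, aurocs


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 0, 1, 1])
        rep = evaluate(probs_from_preds(labels, labels), labels)
        assert rep.accuracy == rep.macro_f1 == rep.mcc == 1.0

    def test_known_confusion_matrix(self):
        # confusion [[8,2],[3,7]]: accuracy 0.75, MCC/F1 from the 2x2 formulas
        labels = np.array([0] * 10 + [1] * 10)
        preds = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        rep = evaluate(probs_from_preds(preds, labels), labels)
        assert rep.accuracy == 0.75
        tp, fp, fn, tn = 7, 2, 3, 8  # class 1 as positive
        mcc = (tp * tn - fp * fn) / np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        assert rep.mcc == pytest.approx(mcc)
        f1_pos = 2 * tp / (2 * tp + fp + fn)
        f1_neg = 2 * tn / (2 * tn + fn + fp)
        assert rep.macro_f1 == pytest.approx((f1_pos + f1_neg) / 2)
        assert rep.confusion.tolist() == [[8, 2], [3, 7]]
        np.testing.assert_allclose(rep.confusion_normalized.sum(axis=1), 1.0)

    def test_constant_predictor_has_zero_mcc(self):
        labels = np.array([0, 1] * 10)
        rep = evaluate(probs_from_preds(np.zeros(20, int), labels), labels)
        assert rep.mcc == 0.0

    def test_single_class_labels_yield_missing_auroc(self):
        labels = np.zeros(5, int)
        rep = evaluate(probs_from_preds(labels, labels), labels)
        assert rep.auroc[1] is None

    @pytest.mark.parametrize("k", [2, 3])
    def test_agrees_with_definitional_oracle(self, k):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, k, n)
            if len(np.unique(labels)) < k:
                continue
            probs = rng.dirichlet(np.ones(k), n)
            rep = evaluate(probs, labels, k)
            acc, f1, mcc, aurocs = brute_force_metrics(probs, labels)
            assert rep.accuracy == pytest.approx(acc, abs=1e-9)
            assert rep.macro_f1 == pytest.approx(f1, abs=1e-9)
            assert rep.mcc == pytest.approx(mcc, abs=1e-9)
            for c, v in aurocs.items():
                assert rep.auroc[c] == pytest.approx(v, abs=1e-9)


MICRO_GNN = GNNConfig(in_features=35, hidden_units=8, n_blocks=2)
FAST = dict(batch_size=64, patience=50, learning_rate=5e-3)


class TestTrainModel:
    def _split(self, ds, n_train_patients):
        pids = ds.patient_ids()
        return ds.subset(pids[:n_train_patients]), ds.subset(pids[n_train_patients:])

    def test_leakage_guard_refuses_overlapping_patients(self, rng):
        ds = micro_dataset(rng, n_patients=6)
        with pytest.raises(ValueError, match="leakage"):
            train_model(ds, ds, MICRO_GNN, TrainConfig(seed=0))

    def test_separable_classes_reach_high_training_accuracy(self, rng):
        ds = micro_dataset(rng, n_patients=16, shift=0.7)
        tr, va = self._split(ds, 12)
        params, hist = train_model(tr, va, MICRO_GNN,
                                   TrainConfig(max_epochs=80, seed=0, **FAST))
        probs, _, labels = predict_dataset(params, tr, MICRO_GNN)
        assert (probs.argmax(1) == labels).mean() >= 0.95
        assert len(hist) <= 80

    def test_permuted_labels_give_chance_auroc(self, rng):
        ds = micro_dataset(rng, n_patients=16, shift=0.7)
        perm_labels = {}
        for g in ds.graphs:  # permute labels at the patient level
            perm_labels.setdefault(g.patient_id, rng.integers(0, 2))
            g.label = int(perm_labels[g.patient_id])
        tr, va = self._split(ds, 12)
        params, _ = train_model(tr, va, MICRO_GNN,
                                TrainConfig(max_epochs=30, seed=1, **FAST))
        probs, _, labels = predict_dataset(params, va, MICRO_GNN)
        rep = evaluate(probs, labels, 2)
        assert 0.2 <= rep.mean_auroc <= 0.8

    def test_same_seed_identical_loss_curves(self, rng):
        ds = micro_dataset(rng, n_patients=10)
        tr, va = self._split(ds, 7)
        cfg = TrainConfig(max_epochs=5, seed=3, **FAST)
        _, h1 = train_model(tr, va, MICRO_GNN, cfg)
        _, h2 = train_model(tr, va, MICRO_GNN, cfg)
        assert h1 == h2

    def test_early_stopping_returns_best_validation_params(self, rng):
        from cgsig.nn.layers import make_batch
        from cgsig.nn.tensor import softmax_cross_entropy
        from cgsig.nn.layers import model_forward

        ds = micro_dataset(rng, n_patients=12)
        tr, va = self._split(ds, 8)
        params, hist = train_model(tr, va, MICRO_GNN,
                                   TrainConfig(max_epochs=15, seed=0, **FAST))
        batch = make_batch(va.labeled().graphs)
        loss, _ = softmax_cross_entropy(model_forward(params, batch, MICRO_GNN),
                                        batch.labels)
        best = min(h["val_loss"] for h in hist)
        assert float(loss.data) == pytest.approx(best, abs=1e-9)


class TestCrossValidate:
    def test_structure_and_repeat_count(self, rng):
        ds = micro_dataset(rng, n_patients=15, graphs_per_patient=2, n_nodes=6)
        cfg = GNNConfig(in_features=35, hidden_units=4, n_blocks=1)
        reports, agg = cross_validate(
            ds, cfg, TrainConfig(max_epochs=2, seed=0, **FAST), k=5, n_repeats=2
        )
        assert len(reports) == 10  # 2 repeats x 5 folds
        assert set(agg) == {"accuracy", "macro_f1", "mcc"}
        mean, sd = agg["accuracy"]
        assert 0.0 <= mean <= 1.0 and sd >= 0.0


class TestGridSearch:
    def test_full_grid_enumerates_54_configurations(self):
        combos = grid_search(SearchSpace(), None, None, MICRO_GNN, dry_run=True)
        assert len(combos) == 54  # 3 lr x 3 wd x 2 hidden x 3 ratio

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(learning_rate=()).enumerate()

    def test_singleton_space_trains_and_ranks(self, rng):
        ds = micro_dataset(rng, n_patients=10, graphs_per_patient=2, n_nodes=6)
        tr, va = ds.subset(ds.patient_ids()[:7]), ds.subset(ds.patient_ids()[7:])
        space = SearchSpace(learning_rate=(1e-3,), weight_decay=(1e-4,),
                            hidden_units=(4,), pooling_ratio=(0.5, 0.75))
        cfg = GNNConfig(in_features=35, hidden_units=4, n_blocks=1)
        results = grid_search(space, tr, va, cfg,
                              TrainConfig(max_epochs=2, seed=0, **FAST))
        assert len(results) == 2
        assert {r["pooling_ratio"] for r in results} == {0.5, 0.75}
        assert all("val_auroc" in r and "val_loss" in r for r in results)


class TestAblation:
    def test_unknown_group_rejected(self, rng):
        ds = micro_dataset(rng, n_patients=6)
        with pytest.raises(KeyError):
            ablate_features(ds, ds, ds, MICRO_GNN, groups=("nonexistent",))

    def test_morphology_only_signal_collapses_without_morphology(self, rng):
        """When the class signal lives solely in the morphology columns,
        removing that group drops accuracy to chance."""
        morph_cols = list(range(30, 35))
        ds = micro_dataset(rng, n_patients=20, graphs_per_patient=3, n_nodes=6,
                           shift=0.8, signal_columns=morph_cols)
        pids = ds.patient_ids()
        tr, va, te = ds.subset(pids[:12]), ds.subset(pids[12:16]), ds.subset(pids[16:])
        cfg = GNNConfig(in_features=35, hidden_units=8, n_blocks=1)
        rows = ablate_features(tr, va, te, cfg,
                               TrainConfig(max_epochs=60, seed=0, **FAST),
                               groups=("morphology",), n_repeats=2)
        assert [r["setting"] for r in rows] == ["all_features", "no_morphology"]
        assert rows[0]["n_features"] == 35 and rows[1]["n_features"] == 30
        assert rows[0]["accuracy_mean"] >= 0.9
        assert rows[1]["accuracy_mean"] <= 0.75
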