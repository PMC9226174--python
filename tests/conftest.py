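import numpy as np
import pytest

from cgsig.cell_table_io import CellTable
from cgsig.graphs import CellGraph, GraphDataset
from cgsig.schema import DEFAULT_SCHEMA


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cell_table(rng, n_cells=50, side=500.0, patient_id="P1"):
    """Schema-valid random cell table (uniform positions, mixed features)."""
    schema = DEFAULT_SCHEMA
    coords = rng.uniform(0, side, (n_cells, 2))
    feats = rng.uniform(0, 1, (n_cells, schema.n_features))
    bool_idx = [schema.feature_index(c) for c in schema.boolean_features]
    feats[:, bool_idx] = rng.integers(0, 2, (n_cells, len(bool_idx)))
    return CellTable(patient_id, coords, feats, schema)


def random_graph(rng, n_nodes=10, n_features=35, edge_p=0.4, label=0, patient_id="P1"):
    """Random weighted graph (not necessarily spatial) for model-level tests."""
    edges, weights = [], []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_p:
                edges.append((i, j))
                weights.append(rng.uniform(1.0, 40.0))
    edges = np.array(edges, int) if edges else np.empty((0, 2), int)
    return CellGraph(
        features=rng.uniform(0, 1, (n_nodes, n_features)),
        coords=rng.uniform(0, 100, (n_nodes, 2)),
        edges=edges,
        weights=np.array(weights),
        label=label,
        patient_id=patient_id,
    )


def micro_dataset(rng, n_patients=20, graphs_per_patient=4, n_nodes=8, shift=0.6,
                  signal_columns=None, n_classes=2):
    """Tiny separable dataset: class k's node features shift by k*shift.

    ``signal_columns`` restricts the class signal to those feature columns.
    """
    graphs = []
    for p in range(n_patients):
        label = p % n_classes
        pid = f"M{p:03d}"
        for _ in range(graphs_per_patient):
            g = random_graph(rng, n_nodes=n_nodes, label=label, patient_id=pid)
            cols = (slice(None) if signal_columns is None
                    else np.asarray(signal_columns))
            g.features[:, cols] = np.clip(
                g.features[:, cols] * 0.3 + label * shift, 0, 1
            )
            graphs.append(g)
    return GraphDataset(graphs)
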