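"""Graph neural network layers and the four cell-graph classifier variants.

Architecture: four blocks, each of two graph convolutions (GIN or GCN,
ReLU-activated) followed by one graph pooling step (TopK or SAG) that keeps
a fixed fraction of each graph's nodes.  After every block a summary layer
concatenates the per-graph mean and max of node features; the four block
summaries are summed (jumping-knowledge) and passed through a three-layer
fully connected head ending in a softmax.

Message passing consumes the *weighted* adjacency (reciprocal-distance
weights), so spatially closer cell pairs exchange stronger messages:

* GIN:  ``X' = MLP((A + (1 + eps) I) X)`` with a two-layer ReLU MLP;
* GCN:  ``X' = ReLU(D^-1/2 (A + I) D^-1/2 X W + b)`` with weighted degrees.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .tensor import Tensor, segment_max, segment_mean, softmax, spmm

CONV_TYPES = ("gin", "gcn")
POOL_TYPES = ("topk", "sag")


@dataclass(frozen=True)
class GNNConfig:
    conv_type: str = "gin"
    pool_type: str = "topk"
    in_features: int = 35
    hidden_units: int = 512
    pooling_ratio: float = 0.5
    n_blocks: int = 4
    convs_per_block: int = 2
    n_classes: int = 2
    epsilon: float = 0.0
    epsilon_learnable: bool = False
    #: "sym" rescales the weighted adjacency by D^-1/2 A D^-1/2 before GIN
    #: message passing (keeps relative reciprocal-distance weights, bounds the
    #: operator norm so 8 stacked convolutions stay numerically stable);
    #: "none" passes raw weights.
    message_norm: str = "sym"

    def __post_init__(self):
        if self.conv_type not in CONV_TYPES:
            raise ValueError(f"conv_type must be one of {CONV_TYPES}")
        if self.pool_type not in POOL_TYPES:
            raise ValueError(f"pool_type must be one of {POOL_TYPES}")
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if not 0.0 < self.pooling_ratio <= 1.0:
            raise ValueError("pooling_ratio must be in (0, 1]")

    @property
    def arch_name(self) -> str:
        return f"{self.conv_type}_{self.pool_type}"


ARCHITECTURES = {
    "gin_topk": ("gin", "topk"),
    "gin_sag": ("gin", "sag"),
    "gcn_topk": ("gcn", "topk"),
    "gcn_sag": ("gcn", "sag"),
}


@dataclass
class GraphBatch:
    """Concatenated node features, block-diagonal weighted adjacency, membership."""

    x: np.ndarray  # (N, d)
    adj: sp.csr_matrix  # (N, N) symmetric, weighted, no self-loops
    batch: np.ndarray  # (N,) graph index per node
    n_graphs: int
    labels: np.ndarray | None = None


def make_batch(graphs, feature_columns: np.ndarray | None = None) -> GraphBatch:
    """Assemble a batch from CellGraph objects, optionally selecting feature columns."""
    feats, rows, cols, vals, batch = [], [], [], [], []
    labels = []
    offset = 0
    for gi, g in enumerate(graphs):
        f = g.features if feature_columns is None else g.features[:, feature_columns]
        feats.append(f)
        if len(g.edges):
            i, j = g.edges[:, 0] + offset, g.edges[:, 1] + offset
            rows.extend([i, j])
            cols.extend([j, i])
            vals.extend([g.weights, g.weights])
        batch.append(np.full(g.n_nodes, gi))
        labels.append(-1 if g.label is None else g.label)
        offset += g.n_nodes
    x = np.vstack(feats)
    n = offset
    if rows:
        adj = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        adj = sp.csr_matrix((n, n))
    return GraphBatch(x, adj, np.concatenate(batch), len(graphs), np.array(labels))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


def init_params(config: GNNConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Glorot-uniform parameter initialization for the configured architecture."""
    p: dict[str, Tensor] = {}
    h = config.hidden_units
    din = config.in_features
    for b in range(config.n_blocks):
        for c in range(config.convs_per_block):
            d = din if (b == 0 and c == 0) else h
            if config.conv_type == "gin":
                p[f"b{b}c{c}_w1"] = Tensor(_glorot(rng, d, h), True)
                p[f"b{b}c{c}_b1"] = Tensor(np.zeros(h), True)
                p[f"b{b}c{c}_w2"] = Tensor(_glorot(rng, h, h), True)
                p[f"b{b}c{c}_b2"] = Tensor(np.zeros(h), True)
                if config.epsilon_learnable:
                    p[f"b{b}c{c}_eps"] = Tensor(np.array(config.epsilon), True)
            else:
                p[f"b{b}c{c}_w"] = Tensor(_glorot(rng, d, h), True)
                p[f"b{b}c{c}_b"] = Tensor(np.zeros(h), True)
        if config.pool_type == "topk":
            p[f"b{b}_pool_p"] = Tensor(_glorot(rng, h, 1), True)
        else:
            p[f"b{b}_pool_w"] = Tensor(_glorot(rng, h, 1), True)
            p[f"b{b}_pool_b"] = Tensor(np.zeros(1), True)
    p["fc1_w"] = Tensor(_glorot(rng, 2 * h, h), True)
    p["fc1_b"] = Tensor(np.zeros(h), True)
    p["fc2_w"] = Tensor(_glorot(rng, h, max(h // 2, 1)), True)
    p["fc2_b"] = Tensor(np.zeros(max(h // 2, 1)), True)
    p["fc3_w"] = Tensor(_glorot(rng, max(h // 2, 1), config.n_classes), True)
    p["fc3_b"] = Tensor(np.zeros(config.n_classes), True)
    return p


def gcn_normalize(adj: sp.csr_matrix) -> sp.csr_matrix:
    """Symmetric degree normalization with self-loops on the weighted adjacency."""
    n = adj.shape[0]
    a_tilde = adj + sp.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    d_mat = sp.diags(d_inv_sqrt)
    return (d_mat @ a_tilde @ d_mat).tocsr()


def _sym_scale(adj: sp.csr_matrix) -> sp.csr_matrix:
    """D^-1/2 A D^-1/2 on weighted degrees, without self-loops."""
    deg = np.asarray(adj.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1.0))
    d_mat = sp.diags(d_inv_sqrt)
    return (d_mat @ adj @ d_mat).tocsr()


def gin_conv(x: Tensor, adj: sp.csr_matrix, eps, w1, b1, w2, b2) -> Tensor:
    """GIN aggregation (A + (1+eps) I) X followed by a two-layer ReLU MLP."""
    agg = spmm(adj, x)
    if isinstance(eps, Tensor):
        agg = agg + x * (eps + Tensor(1.0))
    else:
        agg = agg + x * (1.0 + eps)
    hidden = (agg @ w1 + b1).relu()
    return (hidden @ w2 + b2).relu()


def gcn_conv(x: Tensor, norm_adj: sp.csr_matrix, w, b) -> Tensor:
    """Degree-normalized weighted propagation, linear map, ReLU."""
    return (spmm(norm_adj, x) @ w + b).relu()


def _topk_select(scores: np.ndarray, batch: np.ndarray, ratio: float) -> np.ndarray:
    """Indices (ascending) of the top ceil(ratio*n_g) scorers per graph.

    Ties are broken toward the lower node index.
    """
    n = len(scores)
    order = np.lexsort((np.arange(n), -scores, batch))
    sorted_batch = batch[order]
    # rank within each graph along the sorted order
    boundary = np.flatnonzero(np.diff(sorted_batch)) + 1
    starts = np.concatenate([[0], boundary])
    rank = np.arange(n) - np.repeat(starts, np.diff(np.concatenate([starts, [n]])))
    counts = np.bincount(batch)
    k_per = np.ceil(ratio * np.maximum(counts, 1)).astype(int)
    keep = rank < k_per[sorted_batch]
    return np.sort(order[keep])


def _apply_pool(x, adj, batch, scores: Tensor, ratio: float):
    perm = _topk_select(scores.data.ravel(), batch, ratio)
    gate = scores.gather_rows(perm).tanh()
    x_kept = x.gather_rows(perm) * gate
    adj_kept = adj[perm][:, perm].tocsr()
    return x_kept, adj_kept, batch[perm], perm


def topk_pool(x: Tensor, adj, batch, p_vec: Tensor, ratio: float):
    """Projection-score pooling: s = X p / ||p||, keep top fraction, gate by tanh(s)."""
    inv_norm = (p_vec * p_vec).sum().pow(-0.5)
    scores = (x @ p_vec) * inv_norm
    return _apply_pool(x, adj, batch, scores, ratio)


def sag_pool(x: Tensor, adj, batch, w: Tensor, b: Tensor, ratio: float):
    """Self-attention pooling: scores from a one-layer graph convolution."""
    scores = spmm(gcn_normalize(adj), x) @ w + b
    return _apply_pool(x, adj, batch, scores, ratio)


def readout(x: Tensor, batch: np.ndarray, n_graphs: int) -> Tensor:
    """Summary layer: per-graph mean concatenated with per-graph max."""
    return segment_mean(x, batch, n_graphs).concat_cols(segment_max(x, batch, n_graphs))


def model_forward(
    params: dict[str, Tensor], batch: GraphBatch, config: GNNConfig
) -> Tensor:
    """Class logits (n_graphs, n_classes) for a batch of cell-graphs."""
    x = Tensor(batch.x)
    adj = batch.adj
    bidx = batch.batch
    summary: Tensor | None = None
    for b in range(config.n_blocks):
        if config.conv_type == "gcn":
            norm_adj = gcn_normalize(adj)
        else:
            norm_adj = None
            gin_adj = _sym_scale(adj) if config.message_norm == "sym" else adj
        for c in range(config.convs_per_block):
            if config.conv_type == "gin":
                eps = params.get(f"b{b}c{c}_eps", config.epsilon)
                x = gin_conv(
                    x, gin_adj, eps,
                    params[f"b{b}c{c}_w1"], params[f"b{b}c{c}_b1"],
                    params[f"b{b}c{c}_w2"], params[f"b{b}c{c}_b2"],
                )
            else:
                x = gcn_conv(x, norm_adj, params[f"b{b}c{c}_w"], params[f"b{b}c{c}_b"])
        if config.pool_type == "topk":
            x, adj, bidx, _ = topk_pool(
                x, adj, bidx, params[f"b{b}_pool_p"], config.pooling_ratio
            )
        else:
            x, adj, bidx, _ = sag_pool(
                x, adj, bidx, params[f"b{b}_pool_w"], params[f"b{b}_pool_b"],
                config.pooling_ratio,
            )
        r = readout(x, bidx, batch.n_graphs)
        summary = r if summary is None else summary + r
    h1 = (summary @ params["fc1_w"] + params["fc1_b"]).relu()
    h2 = (h1 @ params["fc2_w"] + params["fc2_b"]).relu()
    logits = h2 @ params["fc3_w"] + params["fc3_b"]
    if not np.isfinite(logits.data).all():
        raise FloatingPointError("non-finite values in forward pass (readout head)")
    return logits


def predict_proba(
    params: dict[str, Tensor], batch: GraphBatch, config: GNNConfig
) -> np.ndarray:
    """Per-graph class probabilities (rows sum to 1)."""
    return softmax(model_forward(params, batch, config).data)


class Adam:
    """Adaptive-moment optimizer with coupled L2 weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 weight_decay: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(path: str | Path, params: dict[str, Tensor], config: GNNConfig) -> None:
    """Single-file archive: config JSON + parameter tensors."""
    buf = io.BytesIO()
    np.savez(buf, **{k: v.data for k, v in params.items()})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(asdict(config)))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[dict[str, Tensor], GNNConfig]:
    with zipfile.ZipFile(path) as zf:
        config = GNNConfig(**json.loads(zf.read("config.json")))
        z = np.load(io.BytesIO(zf.read("params.npz")))
        params = {k: Tensor(z[k], True) for k in z.files}
    return params, config
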