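"""Sub-sampling of cell tables into <=100-cell regions and weighted cell-graphs.

Edges join cell pairs within 20 µm (40 px at 0.5 µm/px) and carry the
reciprocal-distance weight w = 40/d, so w ranges from 1 at the cutoff up to
a cap of 40 for (near-)coincident cells.  Each image is tiled by a
density-adaptive square grid; any tile over the node cap is bisected along
its longer axis until compliant, and near-empty tiles are discarded.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

from .cell_table_io import CellTable

RADIUS_PX = 40.0  # 20 µm at 0.5 µm per pixel
D_MIN_PX = 1.0  # weight cap distance for coincident / duplicate cells


def compute_distance(a, b) -> float:
    """Euclidean distance in pixels between two (x, y) points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.hypot(*(a - b)))


def edge_weight(d: float, radius: float = RADIUS_PX, d_min: float = D_MIN_PX) -> float:
    """Reciprocal-distance edge weight: radius/d within the cutoff, else 0."""
    if d < 0:
        raise ValueError("negative distance")
    if d > radius:
        return 0.0
    return radius / max(d, d_min)


@dataclass(frozen=True)
class Region:
    """Half-open pixel rectangle [x0,x1) x [y0,y1) with its member cell indices."""

    x0: float
    x1: float
    y0: float
    y1: float
    members: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.members)


def subsample_regions(
    table: CellTable, max_cells: int = 100, min_cells: int = 10
) -> list[Region]:
    """Partition an image into disjoint regions of at most ``max_cells`` cells.

    The initial grid tile side is ceil(sqrt(max_cells * A / n)) with A the
    bounding-box area and n the cell count, so a uniform image fills tiles to
    about the cap; denser tiles are bisected along their longer axis until
    compliant.  Tiles with fewer than ``min_cells`` cells are dropped.  The
    procedure is deterministic in the input.
    """
    xy = table.coords
    n = len(xy)
    x0, y0 = xy.min(axis=0)
    x1, y1 = xy.max(axis=0)
    width, height = max(x1 - x0, 1.0), max(y1 - y0, 1.0)
    side = math.ceil(math.sqrt(max_cells * width * height / n))

    regions: list[Region] = []
    stack: list[tuple[float, float, float, float, np.ndarray]] = []
    nx = max(1, math.ceil(width / side))
    ny = max(1, math.ceil(height / side))
    ix = np.minimum(((xy[:, 0] - x0) // side).astype(int), nx - 1)
    iy = np.minimum(((xy[:, 1] - y0) // side).astype(int), ny - 1)
    for i in range(nx):
        for j in range(ny):
            idx = np.flatnonzero((ix == i) & (iy == j))
            if len(idx):
                stack.append(
                    (x0 + i * side, x0 + (i + 1) * side,
                     y0 + j * side, y0 + (j + 1) * side, idx)
                )
    while stack:
        bx0, bx1, by0, by1, idx = stack.pop()
        if len(idx) <= max_cells:
            if len(idx) >= min_cells:
                regions.append(Region(bx0, bx1, by0, by1, tuple(idx.tolist())))
            continue
        if bx1 - bx0 >= by1 - by0:  # bisect the longer axis
            mid = 0.5 * (bx0 + bx1)
            left = xy[idx, 0] < mid
            stack.append((bx0, mid, by0, by1, idx[left]))
            stack.append((mid, bx1, by0, by1, idx[~left]))
        else:
            mid = 0.5 * (by0 + by1)
            low = xy[idx, 1] < mid
            stack.append((bx0, bx1, by0, mid, idx[low]))
            stack.append((bx0, bx1, mid, by1, idx[~low]))
    regions.sort(key=lambda r: (r.x0, r.y0, r.x1, r.y1))
    return regions


@dataclass
class CellGraph:
    """One weighted cell-graph: node features, coordinates, and radius edges.

    Edges are stored once with i < j; ``adjacency()`` expands them to the
    symmetric sparse matrix used by the models.
    """

    features: np.ndarray  # (n, 35)
    coords: np.ndarray  # (n, 2)
    edges: np.ndarray  # (m, 2) int, i < j
    weights: np.ndarray  # (m,)
    label: int | None
    patient_id: str
    region_id: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def adjacency(self) -> csr_matrix:
        n = self.n_nodes
        if len(self.edges) == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        vals = np.concatenate([self.weights, self.weights])
        return csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_cell_graph(
    table: CellTable,
    region: Region,
    label: int | None,
    radius: float = RADIUS_PX,
    region_id: str = "",
) -> CellGraph:
    """Radius graph over the region's cells with w = radius/d weights."""
    idx = np.asarray(region.members, dtype=int)
    xy = table.coords[idx]
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    if len(pairs):
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        d = np.linalg.norm(xy[pairs[:, 0]] - xy[pairs[:, 1]], axis=1)
        w = radius / np.maximum(d, D_MIN_PX)
    else:
        pairs = np.empty((0, 2), dtype=int)
        w = np.empty(0)
    return CellGraph(
        features=table.features[idx].copy(),
        coords=xy.copy(),
        edges=pairs,
        weights=w,
        label=label,
        patient_id=table.patient_id,
        region_id=region_id,
    )


@dataclass
class GraphDataset:
    graphs: list[CellGraph]
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.graphs)

    def patient_ids(self) -> list[str]:
        return sorted({g.patient_id for g in self.graphs})

    def subset(self, patient_ids) -> "GraphDataset":
        keep = set(patient_ids)
        return GraphDataset([g for g in self.graphs if g.patient_id in keep], self.manifest)

    def labeled(self) -> "GraphDataset":
        return GraphDataset([g for g in self.graphs if g.label is not None], self.manifest)


def build_all(
    tables: list[CellTable],
    labels: dict[str, int | str],
    max_cells: int = 100,
    min_cells: int = 10,
    radius: float = RADIUS_PX,
) -> GraphDataset:
    """Build every patient's cell-graphs; graphs inherit the patient label.

    Patients whose label is not an integer class (uncategorized / excluded)
    get ``label=None`` graphs, usable for inference only.
    """
    graphs: list[CellGraph] = []
    per_patient = {}
    for table in tables:
        lab = labels.get(table.patient_id)
        lab = lab if isinstance(lab, (int, np.integer)) else None
        regions = subsample_regions(table, max_cells=max_cells, min_cells=min_cells)
        boxes = []
        for k, region in enumerate(regions):
            rid = f"{table.patient_id}:{k}"
            graphs.append(build_cell_graph(table, region, lab, radius, rid))
            boxes.append([region.x0, region.x1, region.y0, region.y1, len(region)])
        per_patient[table.patient_id] = {
            "label": None if lab is None else int(lab),
            "n_cells": len(table),
            "n_graphs": len(regions),
            "region_boxes": boxes,
        }
    manifest = {
        "radius_px": radius,
        "max_cells": max_cells,
        "min_cells": min_cells,
        "n_graphs": len(graphs),
        "patients": per_patient,
    }
    manifest["digest"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    return GraphDataset(graphs, manifest)


def save_dataset(dataset: GraphDataset, out_dir: str | Path) -> None:
    """Serialize to a directory: manifest.json + flat npz arrays."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(dataset.manifest, indent=1))
    node_off, edge_off = [0], [0]
    meta = []
    for g in dataset.graphs:
        node_off.append(node_off[-1] + g.n_nodes)
        edge_off.append(edge_off[-1] + len(g.edges))
        meta.append((g.patient_id, g.region_id, -1 if g.label is None else g.label))
    np.savez_compressed(
        out / "graphs.npz",
        features=np.vstack([g.features for g in dataset.graphs]),
        coords=np.vstack([g.coords for g in dataset.graphs]),
        edges=np.vstack([g.edges for g in dataset.graphs]) if edge_off[-1] else np.empty((0, 2), int),
        weights=np.concatenate([g.weights for g in dataset.graphs]) if edge_off[-1] else np.empty(0),
        node_offsets=np.array(node_off),
        edge_offsets=np.array(edge_off),
        patient=np.array([m[0] for m in meta]),
        region=np.array([m[1] for m in meta]),
        label=np.array([m[2] for m in meta]),
    )


def load_dataset(in_dir: str | Path) -> GraphDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    z = np.load(src / "graphs.npz", allow_pickle=False)
    graphs = []
    no, eo = z["node_offsets"], z["edge_offsets"]
    for k in range(len(no) - 1):
        lab = int(z["label"][k])
        graphs.append(
            CellGraph(
                features=z["features"][no[k]:no[k + 1]],
                coords=z["coords"][no[k]:no[k + 1]],
                edges=z["edges"][eo[k]:eo[k + 1]],
                weights=z["weights"][eo[k]:eo[k + 1]],
                label=None if lab < 0 else lab,
                patient_id=str(z["patient"][k]),
                region_id=str(z["region"][k]),
            )
        )
    return GraphDataset(graphs, manifest)
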