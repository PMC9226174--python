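"""Tight graph-framelet decomposition with Haar-type filters.

A node signal f is projected onto multi-scale framelets built from the graph
Laplacian's eigenpairs (lambda_l, u_l): low-pass framelets use the scaling
function alpha(xi) = cos(xi/2) and the single Haar high-pass uses
beta(xi) = sin(xi/2), evaluated at dyadically dilated arguments (dilation
base 2).  Eigenvalues are rescaled to [0, pi] so the finest high-pass spans
the full spectrum.  With J scale levels the filters

    high_j(xi)  = sin(xi / 2^(J-j+1)) * prod_{t<J-j+1} cos(xi / 2^t)
    low(xi)     = prod_{t=1..J} cos(xi / 2^t)

satisfy low^2 + sum_j high_j^2 = 1 identically (telescoping sin^2+cos^2), so
the frame is tight: decomposition preserves energy (Parseval) and the
adjoint reconstructs exactly.  Larger j means finer scale (more detail).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cell_table_io import CellTable
from .graphs import CellGraph, Region, build_cell_graph, subsample_regions
from .schema import DEFAULT_SCHEMA


@dataclass(frozen=True)
class FilterBank:
    """Scaling functions on [0, pi]: one low-pass and r >= 1 high-passes."""

    alpha: Callable[[np.ndarray], np.ndarray]
    betas: tuple[Callable[[np.ndarray], np.ndarray], ...]

    def partition_residual(self, xi: np.ndarray) -> np.ndarray:
        """alpha^2 + sum beta^2 - 1 (zero for a tight bank)."""
        total = self.alpha(xi) ** 2
        for b in self.betas:
            total = total + b(xi) ** 2
        return total - 1.0


HAAR_BANK = FilterBank(
    alpha=lambda xi: np.cos(xi / 2.0),
    betas=(lambda xi: np.sin(xi / 2.0),),
)


@dataclass
class GraphSpectrum:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns
    variant: str


@dataclass
class FrameletCoefficients:
    """Low-pass (coarsest) and per-scale high-pass projection coefficients.

    ``high[j-1][r]`` holds scale-level j (1 = coarsest, J = finest detail)
    for high-pass filter r.  Arrays share the signal's trailing shape.
    """

    low: np.ndarray
    high: list[list[np.ndarray]]
    n_scales: int

    def energy(self) -> dict[str, float]:
        out = {"low": float(np.sum(self.low**2))}
        for j, per_r in enumerate(self.high, start=1):
            out[f"high_{j}"] = float(sum(np.sum(w**2) for w in per_r))
        return out

    def total_count(self) -> int:
        n = self.low.shape[0]
        r = len(self.high[0]) if self.high else 0
        return n * (self.n_scales * r + 1)


def graph_laplacian(graph: CellGraph, variant: str = "unnormalized") -> np.ndarray:
    adj = graph.adjacency().toarray()
    deg = adj.sum(axis=1)
    if variant == "unnormalized":
        return np.diag(deg) - adj
    if variant == "normalized":
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
        lap = -adj * inv_sqrt[:, None] * inv_sqrt[None, :]
        np.fill_diagonal(lap, np.where(deg > 0, 1.0, 0.0))
        return lap
    raise ValueError(f"unknown Laplacian variant {variant!r}")


def graph_spectrum(
    graph: CellGraph, variant: str = "unnormalized", max_spectrum_nodes: int = 2000
) -> GraphSpectrum:
    """Full symmetric eigendecomposition of the weighted graph Laplacian."""
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if graph.n_nodes > max_spectrum_nodes:
        raise ValueError(
            f"graph has {graph.n_nodes} nodes (> {max_spectrum_nodes}); "
            "tile the image with subsample_regions before spectral analysis"
        )
    if len(graph.weights) and (graph.weights < 0).any():
        raise ValueError("negative edge weights")
    lam, u = np.linalg.eigh(graph_laplacian(graph, variant))
    lam = np.maximum(lam, 0.0)  # clip eigh round-off below zero
    return GraphSpectrum(lam, u, variant)


def _filter_matrix_diags(
    spectrum: GraphSpectrum, bank: FilterBank, n_scales: int
) -> tuple[np.ndarray, list[list[np.ndarray]]]:
    """Diagonal filter responses per eigenvalue for low and each (scale, r)."""
    lam_max = spectrum.eigenvalues.max()
    xi = (
        np.zeros_like(spectrum.eigenvalues)
        if lam_max <= 0
        else np.pi * spectrum.eigenvalues / lam_max
    )
    low = np.ones_like(xi)
    highs: list[list[np.ndarray]] = []
    # walk from the finest argument xi/2 down; scale level J-t+1 gets sin term
    for t in range(1, n_scales + 1):
        arg = xi / 2.0**t
        highs.append([low * beta(arg) for beta in bank.betas])
        low = low * bank.alpha(arg)
    highs.reverse()  # index 0 = coarsest scale level 1
    return low, highs


def framelet_decompose(
    signal: np.ndarray,
    spectrum: GraphSpectrum,
    bank: FilterBank = HAAR_BANK,
    n_scales: int = 2,
) -> FrameletCoefficients:
    """Project a node signal onto the framelet system (spectral evaluation)."""
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    signal = np.asarray(signal, dtype=float)
    n = spectrum.eigenvectors.shape[0]
    if signal.shape[0] != n:
        raise ValueError(f"signal length {signal.shape[0]} != {n} nodes")
    u = spectrum.eigenvectors
    fhat = u.T @ signal
    low_d, highs_d = _filter_matrix_diags(spectrum, bank, n_scales)
    expand = (lambda d: d[:, None]) if signal.ndim > 1 else (lambda d: d)
    low = u @ (expand(low_d) * fhat)
    high = [[u @ (expand(d) * fhat) for d in per_scale] for per_scale in highs_d]
    return FrameletCoefficients(low, high, n_scales)


def framelet_reconstruct(
    coeffs: FrameletCoefficients,
    spectrum: GraphSpectrum,
    bank: FilterBank = HAAR_BANK,
) -> np.ndarray:
    """Adjoint synthesis; exact inverse of decomposition for a tight bank."""
    u = spectrum.eigenvectors
    n = u.shape[0]
    if coeffs.low.shape[0] != n:
        raise ValueError("coefficients inconsistent with spectrum size")
    low_d, highs_d = _filter_matrix_diags(spectrum, bank, coeffs.n_scales)
    expand = (lambda d: d[:, None]) if coeffs.low.ndim > 1 else (lambda d: d)
    acc = u @ (expand(low_d) * (u.T @ coeffs.low))
    for per_scale_d, per_scale_w in zip(highs_d, coeffs.high):
        for d, w in zip(per_scale_d, per_scale_w):
            acc = acc + u @ (expand(d) * (u.T @ w))
    return acc


def channel_summary(
    table: CellTable,
    features: list[str],
    n_scales: int = 2,
    bank: FilterBank = HAAR_BANK,
    variant: str = "unnormalized",
    max_spectrum_nodes: int = 2000,
    max_cells_per_tile: int = 100,
) -> pd.DataFrame:
    """Per-feature low/high-pass framelet energies over a whole image.

    Images above ``max_spectrum_nodes`` cells are tiled with the standard
    sub-sampling regions and channel energies are summed across tiles.
    Returns one row per feature with columns ``low``, ``high_1..high_J`` and
    ``total`` (which equals the feature's squared norm over analyzed cells,
    by tightness).
    """
    if not features:
        raise ValueError("empty feature subset")
    schema = table.schema or DEFAULT_SCHEMA
    cols = [schema.feature_index(f) for f in features]
    if len(table) > max_spectrum_nodes:
        regions = subsample_regions(table, max_cells=max_cells_per_tile)
    else:
        regions = [None]
    energies = {f: {"low": 0.0, **{f"high_{j}": 0.0 for j in range(1, n_scales + 1)}}
                for f in features}
    for region in regions:
        if region is None:
            x0, y0 = table.coords.min(axis=0)
            x1, y1 = table.coords.max(axis=0)
            region = Region(x0, x1 + 1, y0, y1 + 1, tuple(range(len(table))))
        graph = build_cell_graph(table, region, None)
        spectrum = graph_spectrum(graph, variant, max_spectrum_nodes)
        signals = graph.features[:, cols]
        coeffs = framelet_decompose(signals, spectrum, bank, n_scales)
        for fi, f in enumerate(features):
            energies[f]["low"] += float(np.sum(coeffs.low[:, fi] ** 2))
            for j, per_r in enumerate(coeffs.high, start=1):
                energies[f][f"high_{j}"] += float(
                    sum(np.sum(w[:, fi] ** 2) for w in per_r)
                )
    rows = []
    for f in features:
        row = {"feature": f, **energies[f]}
        row["total"] = row["low"] + sum(row[f"high_{j}"] for j in range(1, n_scales + 1))
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
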