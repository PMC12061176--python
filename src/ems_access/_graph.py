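"""Shared 8-connected grid-graph shortest path machinery.

Both the travel-time oracle (rate = 1/speed, min/m) and the least
cumulative resistance allocation (rate = impedance/100, s/m) reduce to
shortest paths on the same graph: nodes are cell centers, an edge between
adjacent cells costs ``distance * (rate_a + rate_b) / 2`` — the time to
traverse half of each cell at that cell's own rate. Diagonal moves cost
sqrt(2) times the cell size.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

_OFFSETS = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]


def grid_graph(
    rate: np.ndarray,
    cell_size: float,
    valid: np.ndarray | None = None,
    connectivity: int = 8,
) -> coo_matrix:
    """Sparse symmetric cost graph over a raster of per-meter rates.

    Parameters
    ----------
    rate:
        (n_rows, n_cols) per-meter traversal cost (e.g. minutes per meter).
    valid:
        Optional boolean mask; edges only join valid cells.
    connectivity:
        4 or 8; 8 adds diagonal moves at sqrt(2) the distance.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    n_rows, n_cols = rate.shape
    if valid is None:
        valid = np.ones(rate.shape, dtype=bool)
    rows_i, cols_j, weights = [], [], []
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    offsets = _OFFSETS if connectivity == 8 else _OFFSETS[:2]
    for dr, dc, dist_factor in offsets:
        r0 = slice(max(0, -dr), n_rows - max(0, dr))
        r1 = slice(max(0, dr), n_rows - max(0, -dr))
        c0 = slice(max(0, -dc), n_cols - max(0, dc))
        c1 = slice(max(0, dc), n_cols - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = idx[r0, c0][ok]
        b = idx[r1, c1][ok]
        w = dist_factor * cell_size * 0.5 * (rate[r0, c0][ok] + rate[r1, c1][ok])
        rows_i.append(a)
        cols_j.append(b)
        weights.append(w)
    i = np.concatenate(rows_i) if rows_i else np.array([], dtype=int)
    j = np.concatenate(cols_j) if cols_j else np.array([], dtype=int)
    w = np.concatenate(weights) if weights else np.array([], dtype=float)
    n = n_rows * n_cols
    return coo_matrix((w, (i, j)), shape=(n, n))


def shortest_costs(
    rate: np.ndarray,
    cell_size: float,
    source_cells: np.ndarray,
    valid: np.ndarray | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Per-source least cumulative cost to every cell.

    Returns an array of shape (n_sources, n_cells) (row-major flat cell
    order); unreachable cells hold ``inf``.
    """
    graph = grid_graph(rate, cell_size, valid=valid, connectivity=connectivity)
    sources = np.atleast_1d(np.asarray(source_cells, dtype=int))
    dist = dijkstra(graph.tocsr(), directed=False, indices=sources)
    return np.atleast_2d(dist)
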