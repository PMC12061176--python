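"""Independent brute-force oracles used to validate the package.

These deliberately use a different shortest-path implementation
(networkx) and naive loops rather than the package's vectorized
scipy-based machinery, so the two routes cross-check each other.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

SQRT2 = float(np.sqrt(2.0))


def nx_shortest_costs(
    rate: np.ndarray,
    cell_size: float,
    source_cells: list[int],
    valid: np.ndarray | None = None,
    connectivity: int = 8,
) -> np.ndarray:
    """Per-source least cumulative cost over the grid graph, via networkx.

    Mirrors the edge definition used throughout: moving between adjacent
    cell centers costs distance * (rate_a + rate_b) / 2, diagonals at
    sqrt(2) the cell size.
    """
    n_rows, n_cols = rate.shape
    if valid is None:
        valid = np.ones(rate.shape, dtype=bool)
    g = nx.Graph()
    moves = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, SQRT2), (1, -1, SQRT2)]
    if connectivity == 4:
        moves = moves[:2]
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            for dr, dc, f in moves:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < n_rows and 0 <= c2 < n_cols and valid[r2, c2]:
                    w = f * cell_size * 0.5 * (rate[r, c] + rate[r2, c2])
                    g.add_edge(r * n_cols + c, r2 * n_cols + c2, weight=w)
    out = np.full((len(source_cells), n_rows * n_cols), np.inf)
    for i, s in enumerate(source_cells):
        if s not in g:
            g.add_node(s)
        lengths = nx.single_source_dijkstra_path_length(g, s)
        for node, d in lengths.items():
            out[i, node] = d
    return out


def octile_distance(dr: np.ndarray, dc: np.ndarray) -> np.ndarray:
    """Length of the shortest 8-connected grid path in cell units."""
    a, b = np.abs(dr), np.abs(dc)
    return np.maximum(a, b) + (SQRT2 - 1.0) * np.minimum(a, b)


def brute_force_knearest(dest_xy: np.ndarray, station_xy: np.ndarray, station_ids: np.ndarray, k: int):
    """All-pairs distance sort with explicit (distance, id) tie-break."""
    out = []
    for i, (x, y) in enumerate(dest_xy):
        d = np.hypot(station_xy[:, 0] - x, station_xy[:, 1] - y)
        order = sorted(range(len(d)), key=lambda j: (d[j], station_ids[j]))
        out.append([(int(station_ids[j]), float(d[j])) for j in order[:k]])
    return out


def brute_force_theil(pop: np.ndarray, val: np.ndarray, group: np.ndarray) -> dict:
    """Direct loop evaluation of the Theil sums, no shared code."""
    import math

    y = [p * v for p, v in zip(pop, val)]
    Y, P = sum(y), sum(pop)
    T = sum((yi / Y) * math.log((yi / Y) / (pi / P)) for yi, pi in zip(y, pop) if yi > 0)
    groups = sorted(set(group))
    Ti, Yi_, Pi_ = {}, {}, {}
    for g in groups:
        idx = [i for i in range(len(y)) if group[i] == g]
        Yi = sum(y[i] for i in idx)
        Pi = sum(pop[i] for i in idx)
        Yi_[g], Pi_[g] = Yi, Pi
        Ti[g] = sum(
            (y[i] / Yi) * math.log((y[i] / Yi) / (pop[i] / Pi)) for i in idx if y[i] > 0
        )
    Twg = sum((Yi_[g] / Y) * Ti[g] for g in groups)
    Tbg = sum(
        (Yi_[g] / Y) * math.log((Yi_[g] / Y) / (Pi_[g] / P)) for g in groups if Yi_[g] > 0
    )
    return {"T": T, "Ti": Ti, "Twg": Twg, "Tbg": Tbg}
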