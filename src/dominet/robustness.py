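"""Network robustness under centrality-targeted node attacks.

A targeted attack removes nodes one at a time in descending order of a
centrality ranking; after each removal the size of the Largest Connected
Component (LCC) is recorded as a fraction of the original node count.  The
area under the resulting curve summarizes how quickly the network
disintegrates — smaller area means the ranking found more critical nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BinaryNetwork

__all__ = ["LCCCurve", "targeted_attack_curve", "lcc_area", "mean_curve"]


@dataclass
class LCCCurve:
    """LCC fraction after each removal step.

    fractions_removed is the grid 0, 1/N, ..., 1; lcc_fraction starts at 1
    for a connected network, is non-increasing, and ends at 0.
    """

    fractions_removed: np.ndarray
    lcc_fraction: np.ndarray
    ranking_metric: str = ""


def attack_order(ranking: np.ndarray) -> np.ndarray:
    """Removal order: descending ranking, ties broken by ascending node id."""
    ranking = np.asarray(ranking, dtype=float)
    ids = np.arange(ranking.size)
    return np.lexsort((ids, -ranking))


def targeted_attack_curve(
    net: BinaryNetwork, ranking: np.ndarray, metric_name: str = ""
) -> LCCCurve:
    """Simulate a non-adaptive targeted attack and track the LCC.

    The ranking is computed once on the intact network; nodes are then
    removed in descending order (ties: ascending node id) and the largest
    connected component of the remaining graph is measured after every
    removal, normalized by the original N.

    Implemented by processing removals in reverse (nodes are *added* back
    with union-find), which makes each curve O(N + E).
    """
    ranking = np.asarray(ranking, dtype=float)
    n = net.n_nodes
    if ranking.size != n:
        raise ValueError(f"ranking has length {ranking.size}, expected {n}")
    order = attack_order(ranking)

    # reverse percolation: add nodes back in reverse removal order
    adj = [np.flatnonzero(net.A[i]) for i in range(n)]
    parent = list(range(n))
    size = [1] * n

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    present = np.zeros(n, dtype=bool)
    lcc_sizes = np.zeros(n + 1, dtype=float)  # lcc after k removals, k = n..0
    current_max = 0
    for step, node in enumerate(order[::-1]):
        present[node] = True
        if size[find(node)] > current_max:
            current_max = size[find(node)]
        for nb in adj[node]:
            if present[nb]:
                ra, rb = find(node), find(nb)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
                    if size[ra] > current_max:
                        current_max = size[ra]
        lcc_sizes[n - 1 - step] = current_max
    lcc_sizes[n] = 0.0

    return LCCCurve(
        fractions_removed=np.arange(n + 1) / n,
        lcc_fraction=lcc_sizes / n,
        ranking_metric=metric_name,
    )


def lcc_area(curve: LCCCurve) -> float:
    """Trapezoidal area under the LCC curve over fraction-removed in [0, 1]."""
    return float(np.trapezoid(curve.lcc_fraction, curve.fractions_removed))


def mean_curve(curves: list[LCCCurve], metric_name: str = "") -> LCCCurve:
    """Group-level robustness: pointwise mean of subject curves."""
    if not curves:
        raise ValueError("no curves to average")
    grid = curves[0].fractions_removed
    for c in curves[1:]:
        if c.lcc_fraction.size != grid.size:
            raise ValueError("curves have mismatched lengths")
    return LCCCurve(
        fractions_removed=grid,
        lcc_fraction=np.mean([c.lcc_fraction for c in curves], axis=0),
        ranking_metric=metric_name,
    )
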