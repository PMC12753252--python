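"""Per-subject functional-network construction.

Regional time series are turned into a Fisher-z correlation matrix and then
binarized by proportional thresholding at a fixed edge density.  A spanning
backbone of the strongest connections is always retained first, so every
subject's network is connected and every subject contributes exactly the same
number of edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FCMatrix", "ThresholdConfig", "BinaryNetwork", "compute_fc", "threshold_mst"]

#: correlations are clipped to +/- (1 - R_CLIP) before the atanh transform
R_CLIP = 1e-7


@dataclass
class FCMatrix:
    """Fisher-z transformed functional connectivity of one subject.

    ``z`` is symmetric with a zero diagonal; all entries are finite because
    correlations are clipped away from +/-1 before atanh.
    """

    z: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise ValueError("z must be a square matrix")
        if not np.allclose(self.z, self.z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


@dataclass
class ThresholdConfig:
    """How to binarize a Fisher-z matrix.

    density
        Fraction of all possible edges to keep (proportional mode). The
        default 0.04 keeps the strongest 4 % of connections.
    mode
        ``"proportional"`` keeps a fixed edge count; ``"absolute"`` keeps
        every edge with z >= ``z_cutoff`` (plus the spanning backbone).
    ranking
        ``"signed"`` ranks edges by signed z (strong positive first);
        ``"magnitude"`` ranks by |z|.
    """

    density: float = 0.04
    mode: str = "proportional"
    ranking: str = "signed"
    z_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("proportional", "absolute"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.ranking not in ("signed", "magnitude"):
            raise ValueError(f"unknown edge ranking {self.ranking!r}")
        if self.mode == "proportional" and not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.mode == "absolute" and self.z_cutoff is None:
            raise ValueError("absolute mode requires z_cutoff")


@dataclass
class BinaryNetwork:
    """Thresholded binary adjacency plus the surviving edge weights.

    ``A`` is symmetric 0/1 with zero diagonal and a single connected
    component; ``weights`` holds the retained Fisher-z values on the edges of
    ``A`` (zero elsewhere).
    """

    A: np.ndarray
    weights: np.ndarray
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.region_ids is None:
            self.region_ids = np.arange(self.A.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, weight) with i < j, 0-based indices."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.A[iu, ju] > 0
        return [
            (int(i), int(j), float(self.weights[i, j]))
            for i, j in zip(iu[mask], ju[mask])
        ]


def compute_fc(ts: np.ndarray, subject_id: str = "") -> FCMatrix:
    """Pairwise Pearson correlation of regional time series, Fisher-z scale.

    Parameters
    ----------
    ts
        N x T array, one row per region. Requires T >= 3 and nonzero
        variance in every region.

    Returns
    -------
    FCMatrix with r clipped to +/-(1 - 1e-7) before atanh and the diagonal
    set to zero.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (regions x time) array")
    n, t = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 time points, got {t}")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"region {dead[0]} has zero variance")
    r = np.corrcoef(ts)
    r = np.clip(r, -(1 - R_CLIP), 1 - R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z=z, subject_id=subject_id)


def _edge_budget(n: int, density: float) -> int:
    """Rounded edge count; half-away-from-zero rounding."""
    return int(np.floor(density * n * (n - 1) / 2 + 0.5))


class _UnionFind:
    __slots__ = ("parent", "n_components")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.n_components = n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.n_components -= 1
        return True


def _sorted_edges(z: np.ndarray, ranking: str):
    """Upper-triangle edges sorted by descending key, ties lexicographic."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    key = np.abs(w) if ranking == "magnitude" else w
    # lexsort: last key is primary -> descending key, then i, then j
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], w[order]


def threshold_mst(fc: FCMatrix, cfg: ThresholdConfig | None = None) -> BinaryNetwork:
    """Binarize a Fisher-z matrix keeping connectivity via a spanning backbone.

    The maximum-weight spanning tree of the z matrix (the strongest possible
    backbone) is always retained; remaining capacity up to the edge budget
    round(density * N(N-1)/2) is filled with the strongest non-tree edges in
    descending order.  Equal-weight edges are broken lexicographically on
    (min id, max id) so output is deterministic.

    Raises
    ------
    ValueError if the requested density cannot accommodate the N-1 backbone
    edges.
    """
    if cfg is None:
        cfg = ThresholdConfig()
    z = fc.z
    n = z.shape[0]
    iu, ju, w = _sorted_edges(z, cfg.ranking)

    if cfg.mode == "proportional":
        budget = _edge_budget(n, cfg.density)
        if budget < n - 1:
            min_density = (n - 1) / (n * (n - 1) / 2)
            raise ValueError(
                f"density {cfg.density} gives {budget} edges but connectivity "
                f"needs at least {n - 1}; minimum feasible density is "
                f"{min_density:.6g}"
            )
    else:
        budget = None

    uf = _UnionFind(n)
    A = np.zeros((n, n), dtype=np.int8)
    W = np.zeros((n, n), dtype=float)
    n_taken = 0
    extra_quota = None if budget is None else budget - (n - 1)
    for i, j, wt in zip(iu.tolist(), ju.tolist(), w.tolist()):
        is_tree = uf.union(i, j)
        if is_tree:
            take = True
        elif budget is None:
            take = wt >= cfg.z_cutoff
        else:
            take = extra_quota > 0
            if take:
                extra_quota -= 1
        if take:
            A[i, j] = A[j, i] = 1
            W[i, j] = W[j, i] = wt
            n_taken += 1
        if budget is not None and n_taken == budget and uf.n_components == 1:
            break
        if budget is None and uf.n_components == 1 and wt < cfg.z_cutoff:
            break
    return BinaryNetwork(A=A, weights=W, subject_id=fc.subject_id)
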