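"""Binary graph construction from SL matrices and small-world / efficiency
metrics with an Erdős–Rényi null calibration.

Metrics on an undirected, unweighted graph over ``n`` channels:

* characteristic path length  L = (1/(n(n-1))) sum_{i != j} d_ij
* clustering coefficient      C = mean_i  t_i / (k_i (k_i - 1) / 2)
* small-worldness             SWN = (C / C_rand) / (L / L_rand)
* global efficiency           E_g = (1/(n(n-1))) sum_{i != j} 1 / d_ij
* nodal ("local") efficiency  E_l,i = sum_{j != i} 1 / d_ij, normalized
  either by n(n-1) (so E_g = sum_i E_l,i) or by n-1 (per-node form, bounded
  by 1).

Unreachable pairs are excluded from L's average (the graph is flagged as
disconnected) and contribute 0 to the efficiencies; the identical rule is
applied inside the null ensemble so that SWN compares like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sync_likelihood import SLMatrix

__all__ = [
    "AdjacencyMatrix",
    "GraphMetrics",
    "NullEnsembleSummary",
    "binarize_by_density",
    "binarize_by_threshold",
    "shortest_path_lengths",
    "characteristic_path_length",
    "clustering_coefficient",
    "global_efficiency",
    "nodal_efficiency",
    "er_null_ensemble",
    "small_worldness",
    "compute_metrics",
]


@dataclass
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal adjacency matrix."""

    a: np.ndarray
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        a = (a != 0).astype(np.int8)
        if np.any(np.diag(a)):
            raise ValueError("self-loops not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.a = a

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n
        return 2.0 * self.n_edges / (n * (n - 1)) if n > 1 else 0.0


@dataclass
class NullEnsembleSummary:
    """Mean clustering and path length of a G(n, p) ensemble."""

    c_rand: float
    l_rand: float
    n_realizations: int
    p: float
    seed: int | None = None


@dataclass
class GraphMetrics:
    """The five metrics of one graph plus the null used for SWN."""

    L: float
    C: float
    SWN: float
    Eg: float
    El: np.ndarray
    connected: bool
    null_summary: NullEnsembleSummary | None = None
    el_normalization: str = "per_node"


# ---------------------------------------------------------------------------
# SL -> graph
# ---------------------------------------------------------------------------


def binarize_by_density(sl: SLMatrix | np.ndarray, density: float,
                        channel_labels: tuple[str, ...] = ()) -> AdjacencyMatrix:
    """Keep the strongest off-diagonal pairs as edges at a fixed density.

    The ``floor(q n(n-1)/2)`` largest SL values become edges. Ties at the
    cutoff are broken deterministically toward the pair with the lower
    channel indices.
    """
    if isinstance(sl, SLMatrix):
        values = sl.values
        channel_labels = channel_labels or sl.channel_labels
    else:
        values = np.asarray(sl, dtype=float)
    n = values.shape[0]
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n_edges = int(np.floor(density * n * (n - 1) / 2))
    if n_edges == 0:
        raise ValueError(f"density {density} yields zero edges for n={n}")
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    # sort by (-weight, i, j): equal weights resolved toward lower indices
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_edges]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return AdjacencyMatrix(a, channel_labels)


def binarize_by_threshold(sl: SLMatrix | np.ndarray, threshold: float,
                          channel_labels: tuple[str, ...] = ()) -> AdjacencyMatrix:
    """Absolute-threshold alternative: edge iff SL > threshold."""
    if isinstance(sl, SLMatrix):
        values = sl.values
        channel_labels = channel_labels or sl.channel_labels
    else:
        values = np.asarray(sl, dtype=float)
    a = (values > threshold).astype(np.int8)
    np.fill_diagonal(a, 0)
    return AdjacencyMatrix(a, channel_labels)


# ---------------------------------------------------------------------------
# Distances (batched boolean matrix powers — exact for unweighted graphs)
# ---------------------------------------------------------------------------


def _batched_distances(a_stack: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths for a stack of adjacency matrices.

    ``a_stack`` has shape (batch, n, n). Returns float distances with inf
    for unreachable pairs and 0 on the diagonal. Breadth-first search is
    realised as repeated boolean matrix products, which vectorizes across
    the batch.
    """
    a = a_stack.astype(bool)
    batch, n, _ = a.shape
    dist = np.full((batch, n, n), np.inf)
    eye = np.eye(n, dtype=bool)
    dist[:, eye] = 0.0
    reach = a.copy()
    reach_any = reach & ~eye
    dist[reach_any] = 1.0
    frontier = reach | eye
    for step in range(2, n):
        new = np.matmul(frontier.astype(np.float32), a.astype(np.float32)) > 0
        grown = new & ~frontier
        if not grown.any():
            break
        dist[grown & ~eye] = float(step)
        frontier |= new
    return dist


def shortest_path_lengths(adj: AdjacencyMatrix) -> np.ndarray:
    """All-pairs geodesic lengths (inf where unreachable)."""
    return _batched_distances(adj.a[None])[0]


def _path_stats(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-graph (L, Eg, connected) from batched distance matrices."""
    batch, n, _ = dist.shape
    off = ~np.eye(n, dtype=bool)
    d_off = dist[:, off].reshape(batch, -1)
    finite = np.isfinite(d_off)
    n_finite = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        L = np.where(
            n_finite > 0,
            np.where(finite, d_off, 0.0).sum(axis=1) / np.maximum(n_finite, 1),
            np.nan,
        )
    inv = np.where(finite, 1.0 / np.where(finite, d_off, 1.0), 0.0)
    Eg = inv.sum(axis=1) / (n * (n - 1))
    connected = n_finite == n * (n - 1)
    return L, Eg, connected


def _batched_clustering(a_stack: np.ndarray) -> np.ndarray:
    """Mean clustering coefficient per graph in a stack."""
    a = a_stack.astype(np.float64)
    k = a.sum(axis=2)
    triangles = np.einsum("bij,bjk,bki->bi", a, a, a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(possible > 0, triangles / possible, 0.0)
    return ci.mean(axis=1)


# ---------------------------------------------------------------------------
# Public metric operations
# ---------------------------------------------------------------------------


def characteristic_path_length(adj: AdjacencyMatrix) -> tuple[float, bool]:
    """Mean geodesic over reachable ordered pairs.

    Returns ``(L, connected)``; unreachable pairs are excluded from the
    average and ``connected`` is False when any exist. An edgeless graph has
    no finite distances and raises.
    """
    if adj.n < 2:
        raise ValueError("need at least 2 nodes")
    dist = shortest_path_lengths(adj)
    L, _, connected = _path_stats(dist[None])
    if np.isnan(L[0]):
        raise ValueError("graph has no edges: path length undefined")
    return float(L[0]), bool(connected[0])


def clustering_coefficient(adj: AdjacencyMatrix) -> tuple[np.ndarray, float]:
    """Per-node and mean clustering coefficient.

    ``C_i = t_i / (k_i (k_i - 1)/2)`` with ``t_i`` the triangles through
    node i; nodes of degree < 2 contribute 0.
    """
    a = adj.a.astype(np.float64)
    k = a.sum(axis=1)
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(possible > 0, t / possible, 0.0)
    return ci, float(ci.mean())


def global_efficiency(adj: AdjacencyMatrix) -> float:
    """Mean inverse geodesic over ordered pairs (0 for unreachable pairs)."""
    if adj.n < 2:
        raise ValueError("need at least 2 nodes")
    dist = shortest_path_lengths(adj)
    _, Eg, _ = _path_stats(dist[None])
    return float(Eg[0])


def nodal_efficiency(adj: AdjacencyMatrix,
                     normalization: str = "per_node") -> np.ndarray:
    """Per-node efficiency vector.

    ``per_node``: E_l,i = (1/(n-1)) sum_{j != i} 1/d_ij, bounded by 1.
    ``global_sum``: E_l,i = (1/(n(n-1))) sum_{j != i} 1/d_ij, so that the
    values sum to the global efficiency. The two differ only by the factor
    n. See the package methods note for why ``per_node`` is the default.
    """
    if adj.n < 2:
        raise ValueError("need at least 2 nodes")
    if normalization not in ("per_node", "global_sum"):
        raise ValueError(f"unknown normalization {normalization!r}")
    dist = shortest_path_lengths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    row = inv.sum(axis=1)
    n = adj.n
    if normalization == "per_node":
        return row / (n - 1)
    return row / (n * (n - 1))


def er_null_ensemble(
    n: int,
    p: float,
    n_realizations: int = 100,
    seed: int | None = None,
) -> NullEnsembleSummary:
    """Mean C and L of an Erdős–Rényi G(n, p) ensemble.

    Each of the n(n-1)/2 possible edges is drawn independently with
    probability p; no self-loops or multi-edges. L uses the same
    unreachable-pair exclusion as the observed graphs. Edgeless draws carry
    no finite distance and are excluded from the L average; if every draw is
    edgeless an error is raised.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    draws = rng.random((n_realizations, iu.size)) < p
    a = np.zeros((n_realizations, n, n), dtype=bool)
    a[:, iu, ju] = draws
    a |= a.transpose(0, 2, 1)

    dist = _batched_distances(a)
    L, _, _ = _path_stats(dist)
    C = _batched_clustering(a)
    valid = ~np.isnan(L)
    if not valid.any():
        raise ValueError("all null realizations are edgeless; increase p")
    return NullEnsembleSummary(
        c_rand=float(C.mean()),
        l_rand=float(L[valid].mean()),
        n_realizations=n_realizations,
        p=p,
        seed=seed,
    )


def small_worldness(adj_or_metrics, null: NullEnsembleSummary) -> float:
    """SWN = (C / C_rand) / (L / L_rand) = C L_rand / (L C_rand)."""
    if isinstance(adj_or_metrics, AdjacencyMatrix):
        L, _ = characteristic_path_length(adj_or_metrics)
        _, C = clustering_coefficient(adj_or_metrics)
    else:
        L, C = adj_or_metrics  # (L, C) tuple
    if null.c_rand <= 0:
        raise ValueError("degenerate null: C_rand = 0")
    if L <= 0:
        raise ValueError("L must be positive")
    return C * null.l_rand / (L * null.c_rand)


def compute_metrics(
    adj: AdjacencyMatrix,
    null_realizations: int = 100,
    seed: int | None = None,
    el_normalization: str = "per_node",
    null: NullEnsembleSummary | None = None,
) -> GraphMetrics:
    """All five metrics of one graph, with a density-matched ER null.

    The null ensemble is G(n, p) at the observed edge density unless an
    explicit ``null`` summary is supplied.
    """
    L, connected = characteristic_path_length(adj)
    _, C = clustering_coefficient(adj)
    Eg = global_efficiency(adj)
    El = nodal_efficiency(adj, el_normalization)
    if null is None:
        null = er_null_ensemble(adj.n, adj.density, null_realizations, seed)
    swn = small_worldness((L, C), null)
    return GraphMetrics(L=L, C=C, SWN=swn, Eg=Eg, El=El, connected=connected,
                        null_summary=null, el_normalization=el_normalization)
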