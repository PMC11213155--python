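"""Graph-theoretic features of morphological similarity networks.

Each weighted MSN is binarised at a sweep of sparsity levels (fraction of
retained edges), nodal and global measures are computed at every level,
global measures are normalised against degree-preserving random networks,
and each measure is finally integrated over the sweep by the area under
its sparsity curve (AUC).

Nodal measures (per region): degree centrality (DC), clustering
coefficient (CC), betweenness centrality (BC), local efficiency (LE).
Global measures: small-worldness (SW), global efficiency (GE),
assortativity (AST), characteristic path length (CPL).

Distance-based quantities are computed with breadth-first all-pairs
shortest paths on the adjacency matrix (``scipy.sparse.csgraph``), which
keeps the 100-null-network normalisation tractable and gives explicit
control over disconnected node pairs (CPL is averaged over connected
pairs only, with a fragmentation flag).  Betweenness uses networkx's
Brandes implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import DK_ROI_LABELS
from .msn import MSNMatrix

__all__ = [
    "SparsityScheme",
    "BinaryGraph",
    "NetworkFeatureSet",
    "threshold_by_sparsity",
    "degree_centrality",
    "clustering_coefficient",
    "betweenness_centrality",
    "local_efficiency",
    "global_efficiency",
    "characteristic_path_length",
    "assortativity",
    "random_reference_networks",
    "small_worldness",
    "normalized_global_features",
    "auc_over_sparsity",
    "compute_feature_set",
    "GraphFeatureExtractor",
]

NODAL_MEASURES = ("cc", "dc", "bc", "le")
GLOBAL_MEASURES = ("sw", "ge", "ast", "cpl")


@dataclass(frozen=True)
class SparsityScheme:
    """Ordered sparsity levels for the threshold sweep (default 0.05-0.50)."""

    levels: tuple[float, ...] = tuple(np.round(np.arange(1, 11) * 0.05, 2))

    def __post_init__(self) -> None:
        lv = tuple(float(x) for x in self.levels)
        if not lv:
            raise ValueError("at least one sparsity level required")
        if any(not 0 < x <= 1 for x in lv):
            raise ValueError(f"sparsity levels must lie in (0, 1], got {lv}")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("sparsity levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray = field(repr=False)
    level: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError(f"adjacency must be square, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def sparsity(self) -> float:
        """Achieved edge fraction: edges / (n*(n-1)/2)."""
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def edge_array(self) -> np.ndarray:
        """Edges as an (E, 2) array of node indices with i < j."""
        i, j = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([i, j])

    def to_networkx(self) -> nx.Graph:
        g = nx.empty_graph(self.n_nodes)
        g.add_edges_from(map(tuple, self.edge_array()))
        return g


def threshold_by_sparsity(msn: MSNMatrix | np.ndarray, level: float) -> BinaryGraph:
    """Binarise a weighted similarity matrix at an edge-fraction *level*.

    Retains the ``k = round(level * n(n-1)/2)`` highest-weight off-diagonal
    edges.  Ties at the cutoff are broken deterministically by ascending
    (i, j) node-index order.
    """
    if not 0 < level <= 1:
        raise ValueError(f"sparsity level must lie in (0, 1], got {level}")
    w = msn.values if isinstance(msn, MSNMatrix) else np.asarray(msn, dtype=float)
    n = w.shape[0]
    ii, jj = np.triu_indices(n, 1)
    weights = w[ii, jj]
    k = int(np.round(level * n * (n - 1) / 2))
    # primary key: descending weight; ties: ascending (i, j)
    order = np.lexsort((jj, ii, -weights))[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[order], jj[order]] = 1
    adj |= adj.T
    return BinaryGraph(adj, level=float(level))


# ---------------------------------------------------------------------------
# nodal measures
# ---------------------------------------------------------------------------

def degree_centrality(g: BinaryGraph) -> np.ndarray:
    """Number of neighbours of each node."""
    return g.adjacency.sum(axis=1).astype(float)


def clustering_coefficient(g: BinaryGraph) -> np.ndarray:
    """Fraction of realised triangles among each node's neighbour pairs.

    ``CC(i) = 2 T(i) / (k_i (k_i - 1))``; zero for nodes of degree < 2.
    """
    a = g.adjacency.astype(float)
    deg = a.sum(axis=1)
    closed_walks = np.einsum("ij,jk,ki->i", a, a, a)  # = 2 * triangles per node
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(denom > 0, closed_walks / denom, 0.0)
    return cc


def betweenness_centrality(g: BinaryGraph) -> np.ndarray:
    """Unnormalised betweenness: summed fraction of shortest s-t paths
    (s < t, both distinct from the node) passing through each node."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return np.array([bc[i] for i in range(g.n_nodes)], dtype=float)


def _distance_matrix(adj: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(adj), method="D", unweighted=True)


def _global_efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g: BinaryGraph) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph.

    Zero for nodes with fewer than two neighbours.
    """
    adj = g.adjacency
    le = np.zeros(g.n_nodes)
    for i in range(g.n_nodes):
        nb = np.nonzero(adj[i])[0]
        if nb.size < 2:
            continue
        le[i] = _global_efficiency_from_dist(_distance_matrix(adj[np.ix_(nb, nb)]))
    return le


# ---------------------------------------------------------------------------
# global measures
# ---------------------------------------------------------------------------

def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs
    (disconnected pairs contribute zero)."""
    return _global_efficiency_from_dist(_distance_matrix(g.adjacency))


class CPLResult(NamedTuple):
    value: float
    fragmented: bool

    # allow transparent use as a number in arithmetic
    def __float__(self) -> float:
        return self.value


def characteristic_path_length(g: BinaryGraph) -> CPLResult:
    """Mean shortest-path length over *connected* node pairs.

    ``fragmented`` is set when the graph splits into more than one
    non-trivial (>= 2 node) component, in which case the value covers
    only within-component pairs and should be interpreted with care.
    """
    dist = _distance_matrix(g.adjacency)
    n = g.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    value = float(dist[finite].mean()) if finite.any() else float("nan")
    _, labels = connected_components(csr_array(g.adjacency), directed=False)
    sizes = np.bincount(labels)
    fragmented = int((sizes >= 2).sum()) > 1 or (finite.any() and not finite[off].all())
    return CPLResult(value, fragmented)


def assortativity(g: BinaryGraph) -> float:
    """Degree assortativity: Pearson correlation of the degrees at the two
    endpoints of every edge (both orientations).

    Undefined (NaN, with a warning) for graphs with no edges or with zero
    degree variance over edge endpoints (e.g. regular graphs).
    """
    edges = g.edge_array()
    if edges.shape[0] == 0:
        warnings.warn("assortativity undefined: graph has no edges", stacklevel=2)
        return float("nan")
    deg = degree_centrality(g)
    x = np.concatenate([deg[edges[:, 0]], deg[edges[:, 1]]])
    y = np.concatenate([deg[edges[:, 1]], deg[edges[:, 0]]])
    if np.ptp(x) == 0:
        warnings.warn(
            "assortativity undefined: zero endpoint-degree variance (regular graph)",
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# random reference networks
# ---------------------------------------------------------------------------

def random_reference_networks(
    g: BinaryGraph,
    n_random: int = 100,
    seed: int | np.random.Generator | None = None,
    n_swap_per_edge: int = 10,
) -> list[BinaryGraph]:
    """Degree-preserving null networks via Maslov-Sneppen rewiring.

    Each null starts from *g* and undergoes ``n_swap_per_edge * E``
    attempted double-edge swaps: two edges (a, b), (c, d) are replaced by
    (a, d), (c, b) whenever the four nodes are distinct and neither new
    edge already exists.  Every output has exactly the degree sequence of
    the source graph; the sequence of nulls is deterministic under a seed.
    """
    if n_random < 1:
        raise ValueError(f"n_random must be >= 1, got {n_random}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base_edges = g.edge_array()
    n_edges = base_edges.shape[0]
    out: list[BinaryGraph] = []
    for _ in range(n_random):
        if n_edges < 2:
            out.append(BinaryGraph(g.adjacency.copy(), level=g.level))
            continue
        adj = g.adjacency.copy()
        edges = base_edges.copy()
        n_attempts = n_swap_per_edge * n_edges
        pairs = rng.integers(0, n_edges, size=(n_attempts, 2))
        flips = rng.integers(0, 2, size=n_attempts)
        _attempt_swaps(adj, edges, pairs, flips)
        out.append(BinaryGraph(adj, level=g.level))
    return out


def _attempt_swaps_py(adj, edges, pairs, flips) -> None:
    """Apply a sequence of proposed double-edge swaps in place."""
    for t in range(pairs.shape[0]):
        e1, e2 = pairs[t, 0], pairs[t, 1]
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if flips[t]:
            c, d = d, c
        # proposed replacement: (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b


try:  # the swap loop is branch-heavy; JIT it when numba is available
    from numba import njit

    _attempt_swaps = njit(cache=False)(_attempt_swaps_py)
except ImportError:  # pragma: no cover
    _attempt_swaps = _attempt_swaps_py


def _global_summary(adj: np.ndarray) -> tuple[float, float, float, float]:
    """(mean clustering, CPL over connected pairs, GE, AST) for one graph,
    from a single all-pairs distance computation."""
    n = adj.shape[0]
    a = adj.astype(float)
    deg = a.sum(axis=1)
    denom = deg * (deg - 1)
    closed = np.einsum("ij,jk,ki->i", a, a, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = float(np.where(denom > 0, closed / np.where(denom > 0, denom, 1), 0.0).mean())
    dist = _distance_matrix(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    cpl = float(dist[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    ge = float(inv.mean())
    i, j = np.nonzero(np.triu(adj, 1))
    if i.size == 0:
        ast = float("nan")
    else:
        x = np.concatenate([deg[i], deg[j]])
        y = np.concatenate([deg[j], deg[i]])
        ast = float(np.corrcoef(x, y)[0, 1]) if np.ptp(x) > 0 else float("nan")
    return cc, cpl, ge, ast


def small_worldness(g: BinaryGraph, randoms: Sequence[BinaryGraph]) -> float:
    """``SW = (C / <C_rand>) / (L / <L_rand>)`` with C the mean clustering
    coefficient and L the characteristic path length; SW >> 1 indicates
    small-world organisation relative to the degree-matched nulls."""
    if len(randoms) == 0:
        raise ValueError("small_worldness requires at least one random network")
    c = float(clustering_coefficient(g).mean())
    l = characteristic_path_length(g).value
    c_rand = float(np.mean([clustering_coefficient(r).mean() for r in randoms]))
    l_rand = float(np.mean([characteristic_path_length(r).value for r in randoms]))
    if c_rand == 0 or l_rand == 0 or not np.isfinite(c_rand) or not np.isfinite(l_rand):
        return float("nan")
    gamma = c / c_rand
    lam = l / l_rand
    return float(gamma / lam) if lam != 0 else float("nan")


def normalized_global_features(
    g: BinaryGraph, randoms: Sequence[BinaryGraph]
) -> dict[str, float]:
    """Global measures normalised by their mean over the random networks.

    GE, AST and CPL are each divided by the corresponding null-ensemble
    mean; SW is the clustering/path-length double ratio.  A zero or
    undefined null mean propagates as NaN.
    """
    if len(randoms) == 0:
        raise ValueError("normalization requires at least one random network")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nulls may be regular -> NaN AST, handled below
        cc_g, cpl_g, ge_g, ast_g = _global_summary(g.adjacency)
        summaries = np.array([_global_summary(r.adjacency) for r in randoms])
    cc_r, cpl_r, ge_r, ast_r = summaries.mean(axis=0)
    raw = {"ge": ge_g, "ast": ast_g, "cpl": cpl_g}
    means = {"ge": ge_r, "ast": ast_r, "cpl": cpl_r}
    if cc_r and cpl_r and np.isfinite(cc_r) and np.isfinite(cpl_r) and cpl_g:
        out = {"sw": float((cc_g / cc_r) / (cpl_g / cpl_r))}
    else:
        out = {"sw": float("nan")}
    for key in ("ge", "ast", "cpl"):
        m = means[key]
        if not np.isfinite(m) or m == 0:
            warnings.warn(
                f"null-ensemble mean for {key.upper()} is zero or undefined; "
                "normalized value flagged missing",
                stacklevel=2,
            )
            out[key] = float("nan")
        else:
            out[key] = float(raw[key] / m)
    return out


def auc_over_sparsity(values, scheme: SparsityScheme) -> float:
    """Trapezoidal area under a measure's curve across the sparsity sweep."""
    values = np.asarray(values, dtype=float)
    levels = np.asarray(scheme.levels)
    if values.shape[0] != levels.shape[0]:
        raise ValueError(
            f"got {values.shape[0]} values for {levels.shape[0]} sparsity levels"
        )
    out = np.trapezoid(values, levels, axis=0)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# per-subject feature sets
# ---------------------------------------------------------------------------

@dataclass
class NetworkFeatureSet:
    """AUC-integrated features for one subject.

    ``nodal`` maps measure name -> length-68 vector; ``global_`` maps
    measure name -> scalar (normalised against the null ensemble before
    integration).  ``qc_flags`` lists sparsity levels at which the
    thresholded graph was fragmented.
    """

    subject_id: str
    nodal: dict[str, np.ndarray]
    global_: dict[str, float]
    qc_flags: list[float]
    roi_order: tuple[str, ...] = DK_ROI_LABELS

    def to_row(self) -> dict[str, float]:
        """Flatten to a feature->value mapping (columns ``<measure>__<roi>``
        for nodal features, bare measure name for global ones)."""
        row: dict[str, float] = {}
        for measure in NODAL_MEASURES:
            for roi, v in zip(self.roi_order, self.nodal[measure]):
                row[f"{measure}__{roi}"] = float(v)
        for measure in GLOBAL_MEASURES:
            row[measure] = float(self.global_[measure])
        return row


def compute_feature_set(
    msn: MSNMatrix,
    scheme: SparsityScheme | None = None,
    n_random: int = 100,
    seed: int | np.random.Generator | None = None,
    n_swap_per_edge: int = 10,
) -> NetworkFeatureSet:
    """Threshold-sweep feature extraction for one subject's MSN.

    At every sparsity level the MSN is binarised, the four nodal measures
    are computed per region, and the four global measures are normalised
    against ``n_random`` degree-preserving nulls.  Each measure is then
    integrated over the sweep with the trapezoid rule.
    """
    scheme = scheme or SparsityScheme()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_levels = len(scheme.levels)
    nodal_curves = {m: np.zeros((n_levels, len(msn.roi_order))) for m in NODAL_MEASURES}
    global_curves = {m: np.zeros(n_levels) for m in GLOBAL_MEASURES}
    qc: list[float] = []
    for li, level in enumerate(scheme.levels):
        g = threshold_by_sparsity(msn, level)
        nodal_curves["dc"][li] = degree_centrality(g)
        nodal_curves["cc"][li] = clustering_coefficient(g)
        nodal_curves["bc"][li] = betweenness_centrality(g)
        nodal_curves["le"][li] = local_efficiency(g)
        if characteristic_path_length(g).fragmented:
            qc.append(level)
        randoms = random_reference_networks(g, n_random, rng, n_swap_per_edge)
        norm = normalized_global_features(g, randoms)
        for m in GLOBAL_MEASURES:
            global_curves[m][li] = norm[m]
    nodal = {m: auc_over_sparsity(c, scheme) for m, c in nodal_curves.items()}
    global_ = {m: auc_over_sparsity(c, scheme) for m, c in global_curves.items()}
    return NetworkFeatureSet(msn.subject_id, nodal, global_, qc, msn.roi_order)


class GraphFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform MSN matrices into AUC-integrated network features.

    ``transform`` accepts a sequence of :class:`MSNMatrix` (or an array of
    shape ``(n_subjects, 68, 68)``) and returns a pandas DataFrame with
    4x68 nodal columns (``cc__<roi>`` ...) and 4 normalised global columns
    (``sw, ge, ast, cpl``).  Fragmentation flags are collected per subject
    in ``qc_log_``.

    Parameters
    ----------
    levels : tuple of float
        Sparsity sweep (default 0.05 ... 0.50 in steps of 0.05).
    n_random : int
        Null networks per level for global-measure normalisation.
    n_swap_per_edge : int
        Attempted Maslov-Sneppen swaps per edge when rewiring.
    random_state : int or None
        Root seed; per-subject substreams are spawned from it, so results
        are reproducible and independent of chunking.
    """

    def __init__(self, levels: tuple[float, ...] = SparsityScheme().levels,
                 n_random: int = 100, n_swap_per_edge: int = 10,
                 random_state: int | None = None):
        self.levels = levels
        self.n_random = n_random
        self.n_swap_per_edge = n_swap_per_edge
        self.random_state = random_state

    def fit(self, X, y=None) -> "GraphFeatureExtractor":
        SparsityScheme(tuple(self.levels))  # validates
        return self

    def transform(self, X) -> "pd.DataFrame":
        import pandas as pd

        scheme = SparsityScheme(tuple(self.levels))
        matrices = [
            m if isinstance(m, MSNMatrix) else MSNMatrix(f"S{i:04d}", np.asarray(m))
            for i, m in enumerate(X)
        ]
        seeds = np.random.SeedSequence(self.random_state).spawn(len(matrices))
        rows, ids = [], []
        self.qc_log_: dict[str, list[float]] = {}
        for m, ss in zip(matrices, seeds):
            fs = compute_feature_set(
                m, scheme, self.n_random, np.random.default_rng(ss),
                self.n_swap_per_edge,
            )
            rows.append(fs.to_row())
            ids.append(m.subject_id)
            if fs.qc_flags:
                self.qc_log_[m.subject_id] = fs.qc_flags
        df = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
        self.feature_names_out_ = list(df.columns)
        return df
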