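"""Global graph-theory features of a connectivity matrix.

Each subject's denoised Fisher-z matrix is summarized by a fixed catalog
of 26 whole-brain graph metrics.  Metrics either read the full weighted
matrix (absolute weights where non-negativity is required, raw signed
values for signed quantities such as assortativity and the positive-edge
summaries) or a binary graph obtained by proportional thresholding at 5%
link density — every subject keeps exactly the same number of strongest
edges, so binary metrics are comparable across subjects.  Nodal metrics
are reduced to one global value per subject by their catalog summary
(mean, median, or median of log for heavy-tailed quantities such as
subgraph centrality); modularity, small-worldness, resilience and the
other inherently global quantities pass through as scalars.

Small-worldness follows the ratio-of-ratios form
``SW = (C / C_rand) / (E_rand / E)`` with Erdos-Renyi null graphs of the
same node and edge count, and resilience is the slope of the log-log
degree distribution over logarithmically spaced bins.

A training-set outlier rule (any metric more than ``k_sd`` standard
deviations from the training mean, default 5) removes corrupted subjects;
the rule is fitted on training subjects only and applied frozen to all
splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Callable

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import yaml
from scipy.sparse.csgraph import shortest_path

from .connectome import ConnectivityMatrix

__all__ = [
    "MetricDef",
    "MetricCatalog",
    "GraphMetricVector",
    "OutlierRule",
    "default_catalog",
    "threshold_density",
    "small_worldness",
    "resilience",
    "compute_metric_vector",
    "exclude_metric_outliers",
]

DEFAULT_DENSITY = 0.05
DEFAULT_N_NULL = 20
_N_LOUVAIN_RUNS = 10


# ---------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class MetricDef:
    name: str
    matrix_form: str  # "weighted" | "binarized"
    summary: str  # "mean" | "median" | "median_log" | "scalar"


@dataclass
class MetricCatalog:
    entries: list[MetricDef]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("metric names must be unique")
        for e in self.entries:
            if e.matrix_form not in ("weighted", "binarized"):
                raise ValueError(f"{e.name}: bad matrix_form {e.matrix_form}")
            if e.summary not in ("mean", "median", "median_log", "scalar"):
                raise ValueError(f"{e.name}: bad summary {e.summary}")
            if e.name not in _REGISTRY:
                raise ValueError(f"unknown metric {e.name}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_yaml(self, path) -> None:
        payload = [
            {"name": e.name, "matrix_form": e.matrix_form, "summary": e.summary}
            for e in self.entries
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MetricCatalog":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls([MetricDef(d["name"], d["matrix_form"], d["summary"]) for d in payload])


def default_catalog() -> MetricCatalog:
    """The default 26-metric catalog (21 weighted-matrix, 5 binarized).

    Entries tagged "weighted" take the full signed Fisher-z matrix as
    input; small-worldness, resilience, rich-club and coreness derive
    their sparse graph from it by 5%-density thresholding internally, as
    those metrics are degenerate on complete graphs.
    """
    w, b = "weighted", "binarized"
    entries = [
        MetricDef("clustering_weighted", w, "mean"),
        MetricDef("modularity_weighted", w, "scalar"),
        MetricDef("global_efficiency_weighted", w, "scalar"),
        MetricDef("local_efficiency_weighted", w, "median"),
        MetricDef("char_path_length_weighted", w, "scalar"),
        MetricDef("strength", w, "median"),
        MetricDef("betweenness_weighted", w, "median"),
        MetricDef("eigenvector_centrality_weighted", w, "median"),
        MetricDef("subgraph_centrality_weighted", w, "median_log"),
        MetricDef("participation_coefficient", w, "median"),
        MetricDef("within_module_degree_z", w, "median"),
        MetricDef("assortativity_weighted", w, "scalar"),
        MetricDef("transitivity_weighted", w, "scalar"),
        MetricDef("small_worldness", w, "scalar"),
        MetricDef("resilience", w, "scalar"),
        MetricDef("rich_club_median_degree", w, "scalar"),
        MetricDef("coreness", w, "mean"),
        MetricDef("closeness_weighted", w, "median"),
        MetricDef("diversity_coefficient", w, "median"),
        MetricDef("positive_edge_density", w, "scalar"),
        MetricDef("median_positive_weight", w, "scalar"),
        MetricDef("degree_binary", b, "median"),
        MetricDef("clustering_binary", b, "mean"),
        MetricDef("global_efficiency_binary", b, "scalar"),
        MetricDef("modularity_binary", b, "scalar"),
        MetricDef("assortativity_binary", b, "scalar"),
    ]
    cat = MetricCatalog(entries)
    assert len(cat.entries) == 26
    assert sum(e.matrix_form == "binarized" for e in cat.entries) == 5
    return cat


@dataclass
class GraphMetricVector:
    subject_id: str
    values: dict[str, float]
    n_regions: int


# ---------------------------------------------------------------------------
# primitives


def threshold_density(z_matrix: np.ndarray, density: float = DEFAULT_DENSITY) -> np.ndarray:
    """Binarize by proportional thresholding.

    Exactly ``round(density * E)`` strongest upper-triangle edges (E =
    n(n-1)/2) are kept; ties at the cutoff are broken by (i, j)
    lexicographic order so the result is deterministic.
    """
    z = np.asarray(z_matrix, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(z, z.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if not (0.0 < density < 1.0):
        raise ValueError("density must be in (0, 1)")
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_edges = int(round(density * iu.size))
    if n_edges < 1:
        raise ValueError(f"density {density} yields zero edges for n={n}")
    vals = z[iu, ju]
    # primary key: descending weight; ties by ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    keep = order[:n_edges]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[keep], ju[keep]] = 1
    return adj + adj.T


def _binary_distances(adj: np.ndarray) -> np.ndarray:
    return shortest_path(adj.astype(float), method="D", unweighted=True)


def _efficiency_from_dist(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _binary_clustering(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    tri = np.diag(a @ a @ a) / 2.0
    k = a.sum(axis=0)
    denom = k * (k - 1) / 2.0
    out = np.zeros(adj.shape[0])
    mask = denom > 0
    out[mask] = tri[mask] / denom[mask]
    return out


def small_worldness(
    adjacency: np.ndarray, n_null: int = DEFAULT_N_NULL, seed: int = 0
) -> float:
    """Ratio-of-ratios small-worldness of a binary graph.

    ``SW = (C / C_rand) / (E_rand / E)`` where C and E are the average
    clustering coefficient and global efficiency of the graph, and C_rand,
    E_rand are means over ``n_null`` Erdos-Renyi graphs with the same node
    and edge count.
    """
    adj = (np.asarray(adjacency) != 0).astype(int)
    np.fill_diagonal(adj, 0)
    n = adj.shape[0]
    m = int(adj.sum() // 2)
    c_obs = float(_binary_clustering(adj).mean())
    e_obs = _efficiency_from_dist(_binary_distances(adj))
    if e_obs == 0:
        raise ValueError("graph has zero efficiency; small-worldness undefined")
    rng = np.random.default_rng(seed)
    c_null, e_null = [], []
    for _ in range(n_null):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
        a = nx.to_numpy_array(g, nodelist=range(n))
        c_null.append(float(_binary_clustering(a).mean()))
        e_null.append(_efficiency_from_dist(_binary_distances(a)))
    c_rand, e_rand = float(np.mean(c_null)), float(np.mean(e_null))
    if e_rand == 0:
        raise ValueError("null efficiency is zero; small-worldness undefined")
    if c_rand == 0:
        raise ValueError("null clustering is zero; small-worldness undefined")
    return (c_obs / c_rand) / (e_rand / e_obs)


def resilience(degree_sequence: np.ndarray, n_bins: int = 10) -> float:
    """Slope of the log-log degree distribution.

    Degrees are binned into ``n_bins`` logarithmically spaced bins between
    the minimum and maximum positive degree; the slope is the OLS fit of
    log(density) on log(bin center) over non-empty bins (density = count /
    bin width, so the slope estimates the exponent of a power-law degree
    distribution).
    """
    deg = np.asarray(degree_sequence, dtype=float)
    deg = deg[deg > 0]
    if deg.size == 0 or deg.min() == deg.max():
        raise ValueError("degenerate degree distribution (single value)")
    edges = np.logspace(math.log10(deg.min()), math.log10(deg.max()), n_bins + 1)
    counts, _ = np.histogram(deg, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        raise ValueError("fewer than 3 non-empty degree bins")
    x = np.log(centers[mask])
    y = np.log(counts[mask] / widths[mask])
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def _best_louvain(
    adj: np.ndarray, seed: int, n_runs: int = _N_LOUVAIN_RUNS
) -> tuple[list[set], float]:
    """Best-of-n seeded Louvain (multilevel) runs by modularity Q.

    Runs igraph's C implementation, seeding Python's ``random`` module
    (igraph's default RNG) per run; the first occurrence wins Q ties.
    """
    import random

    n = adj.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = adj[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights = adj[iu, ju][mask].tolist()
    g = ig.Graph(n=n, edges=edges)
    best_membership, best_q = None, -np.inf
    state = random.getstate()
    try:
        for k in range(n_runs):
            random.seed(seed + k)
            part = g.community_multilevel(weights=weights)
            q = g.modularity(part.membership, weights=weights)
            if q > best_q:
                best_membership, best_q = part.membership, q
    finally:
        random.setstate(state)
    comms: dict[int, set] = {}
    for node, c in enumerate(best_membership):
        comms.setdefault(c, set()).add(node)
    return list(comms.values()), float(best_q)


# ---------------------------------------------------------------------------
# per-subject computation context


class _GraphContext:
    """Caches the shared intermediates the metric functions draw on."""

    def __init__(self, z: np.ndarray, density: float, n_null: int, seed: int):
        self.z = np.asarray(z, dtype=float)
        self.n = self.z.shape[0]
        self.density = density
        self.n_null = n_null
        self.seed = seed
        self.W = np.abs(self.z)
        np.fill_diagonal(self.W, 0.0)

    @cached_property
    def lengths(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            ln = 1.0 / self.W
        ln[~np.isfinite(ln)] = 0.0  # 0 = no edge for csgraph
        np.fill_diagonal(ln, 0.0)
        return ln

    @cached_property
    def dist_w(self) -> np.ndarray:
        return shortest_path(self.lengths, method="D", directed=False)

    @cached_property
    def B(self) -> np.ndarray:
        return threshold_density(self.W, self.density)

    @cached_property
    def Gw(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        iu, ju = np.triu_indices(self.n, k=1)
        for i, j, w in zip(iu, ju, self.W[iu, ju]):
            if w > 0:
                g.add_edge(int(i), int(j), weight=float(w), length=1.0 / float(w))
        return g

    @cached_property
    def Gb(self) -> nx.Graph:
        g = nx.from_numpy_array(self.B)
        g.add_nodes_from(range(self.n))
        return g

    @cached_property
    def partition_w(self) -> tuple[list[set], float]:
        return _best_louvain(self.W, seed=self.seed)

    @cached_property
    def partition_b(self) -> tuple[list[set], float]:
        return _best_louvain(self.B.astype(float), seed=self.seed + 1000)

    @cached_property
    def module_labels(self) -> np.ndarray:
        lab = np.zeros(self.n, dtype=int)
        for s, comm in enumerate(self.partition_w[0]):
            for i in comm:
                lab[i] = s
        return lab


# -- weighted-matrix metrics -------------------------------------------------


def _m_clustering_w(ctx: _GraphContext) -> np.ndarray:
    wmax = ctx.W.max()
    if wmax == 0:
        return np.zeros(ctx.n)
    cbrt = np.cbrt(ctx.W / wmax)
    cyc3 = np.diag(cbrt @ cbrt @ cbrt)
    k = (ctx.W > 0).sum(axis=0)
    out = np.zeros(ctx.n)
    mask = k > 1
    out[mask] = cyc3[mask] / (k[mask] * (k[mask] - 1))
    return out


def _m_modularity_w(ctx: _GraphContext) -> float:
    return ctx.partition_w[1]


def _m_global_eff_w(ctx: _GraphContext) -> float:
    return _efficiency_from_dist(ctx.dist_w)


def _m_local_eff_w(ctx: _GraphContext) -> np.ndarray:
    out = np.zeros(ctx.n)
    for i in range(ctx.n):
        nb = np.flatnonzero(ctx.W[i] > 0)
        if nb.size < 2:
            continue
        sub = ctx.lengths[np.ix_(nb, nb)]
        d = shortest_path(sub, method="FW", directed=False)
        out[i] = _efficiency_from_dist(d)
    return out


def _m_cpl_w(ctx: _GraphContext) -> float:
    d = ctx.dist_w.copy()
    iu = np.triu_indices(ctx.n, k=1)
    vals = d[iu]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("graph fully disconnected; path length undefined")
    return float(vals.mean())


def _m_strength(ctx: _GraphContext) -> np.ndarray:
    return ctx.W.sum(axis=0)


def _m_betweenness_w(ctx: _GraphContext) -> np.ndarray:
    # igraph's exact Brandes algorithm on 1/|w| lengths; normalized as for
    # undirected graphs: divide by (n-1)(n-2)/2
    iu, ju = np.triu_indices(ctx.n, k=1)
    mask = ctx.W[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    lengths = (1.0 / ctx.W[iu, ju][mask]).tolist()
    g = ig.Graph(n=ctx.n, edges=edges)
    bc = np.array(g.betweenness(weights=lengths))
    if ctx.n > 2:
        bc = bc / ((ctx.n - 1) * (ctx.n - 2) / 2.0)
    return bc


def _m_eigenvector_w(ctx: _GraphContext) -> np.ndarray:
    vals, vecs = np.linalg.eigh(ctx.W)
    v = np.abs(vecs[:, -1])
    return v / np.linalg.norm(v)


def _m_subgraph_w(ctx: _GraphContext) -> np.ndarray:
    return np.diag(scipy.linalg.expm(ctx.W)).copy()


def _m_participation(ctx: _GraphContext) -> np.ndarray:
    k = ctx.W.sum(axis=0)
    out = np.zeros(ctx.n)
    mask = k > 0
    acc = np.zeros(ctx.n)
    for s in range(ctx.module_labels.max() + 1):
        members = ctx.module_labels == s
        kappa = ctx.W[:, members].sum(axis=1)
        acc[mask] += (kappa[mask] / k[mask]) ** 2
    out[mask] = 1.0 - acc[mask]
    return out


def _m_within_module_z(ctx: _GraphContext) -> np.ndarray:
    out = np.zeros(ctx.n)
    for s in range(ctx.module_labels.max() + 1):
        members = np.flatnonzero(ctx.module_labels == s)
        if members.size < 2:
            continue
        kappa = ctx.W[np.ix_(members, members)].sum(axis=1)
        sd = kappa.std()
        if sd > 0:
            out[members] = (kappa - kappa.mean()) / sd
    return out


def _m_assortativity_w(ctx: _GraphContext) -> float:
    # weighted Pearson correlation of endpoint (signed) strengths over
    # edges, edge weight |z_ij|; signed strengths keep the metric sensitive
    # to the sign structure of the residual matrix
    s = ctx.z.sum(axis=0)  # raw signed strength
    iu, ju = np.triu_indices(ctx.n, k=1)
    w = ctx.W[iu, ju]
    if w.sum() == 0:
        raise ValueError("no edges; assortativity undefined")
    x = np.concatenate([s[iu], s[ju]])
    y = np.concatenate([s[ju], s[iu]])
    ww = np.concatenate([w, w])
    ww = ww / ww.sum()
    mx = float(ww @ x)
    my = float(ww @ y)
    cov = float(ww @ ((x - mx) * (y - my)))
    vx = float(ww @ ((x - mx) ** 2))
    vy = float(ww @ ((y - my) ** 2))
    if vx == 0 or vy == 0:
        raise ValueError("zero strength variance; assortativity undefined")
    return cov / math.sqrt(vx * vy)


def _m_transitivity_w(ctx: _GraphContext) -> float:
    wmax = ctx.W.max()
    if wmax == 0:
        return 0.0
    cbrt = np.cbrt(ctx.W / wmax)
    cyc3 = float(np.trace(cbrt @ cbrt @ cbrt))
    k = (ctx.W > 0).sum(axis=0)
    denom = float((k * (k - 1)).sum())
    if denom == 0:
        return 0.0
    return cyc3 / denom


def _m_small_worldness(ctx: _GraphContext) -> float:
    return small_worldness(ctx.B, n_null=ctx.n_null, seed=ctx.seed + 2000)


def _m_resilience(ctx: _GraphContext) -> float:
    return resilience(ctx.B.sum(axis=0))


def _m_rich_club(ctx: _GraphContext) -> float:
    deg = ctx.B.sum(axis=0)
    k_med = float(np.median(deg))
    rich = np.flatnonzero(deg > k_med)
    if rich.size < 2:
        return 0.0
    sub = ctx.B[np.ix_(rich, rich)]
    m = rich.size
    return float(sub.sum() / (m * (m - 1)))


def _m_coreness(ctx: _GraphContext) -> np.ndarray:
    core = nx.core_number(ctx.Gb)
    return np.array([core[i] for i in range(ctx.n)], dtype=float)


def _m_closeness_w(ctx: _GraphContext) -> np.ndarray:
    out = np.zeros(ctx.n)
    n = ctx.n
    for i in range(n):
        d = ctx.dist_w[i]
        reach = np.isfinite(d) & (np.arange(n) != i)
        tot = d[reach].sum()
        if tot > 0:
            r = reach.sum()
            out[i] = (r / tot) * (r / (n - 1))
    return out


def _m_diversity(ctx: _GraphContext) -> np.ndarray:
    n_mod = ctx.module_labels.max() + 1
    if n_mod < 2:
        return np.zeros(ctx.n)
    k = ctx.W.sum(axis=0)
    out = np.zeros(ctx.n)
    p = np.zeros((ctx.n, n_mod))
    for s in range(n_mod):
        p[:, s] = ctx.W[:, ctx.module_labels == s].sum(axis=1)
    mask = k > 0
    p[mask] /= k[mask, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    out[mask] = -terms[mask].sum(axis=1) / math.log(n_mod)
    return out


def _m_pos_density(ctx: _GraphContext) -> float:
    iu = np.triu_indices(ctx.n, k=1)
    return float((ctx.z[iu] > 0).mean())


def _m_median_pos_weight(ctx: _GraphContext) -> float:
    iu = np.triu_indices(ctx.n, k=1)
    pos = ctx.z[iu]
    pos = pos[pos > 0]
    return float(np.median(pos)) if pos.size else 0.0


# -- binarized metrics -------------------------------------------------------


def _m_degree_b(ctx: _GraphContext) -> np.ndarray:
    return ctx.B.sum(axis=0).astype(float)


def _m_clustering_b(ctx: _GraphContext) -> np.ndarray:
    return _binary_clustering(ctx.B)


def _m_global_eff_b(ctx: _GraphContext) -> float:
    return _efficiency_from_dist(_binary_distances(ctx.B))


def _m_modularity_b(ctx: _GraphContext) -> float:
    return ctx.partition_b[1]


def _m_assortativity_b(ctx: _GraphContext) -> float:
    return float(nx.degree_assortativity_coefficient(ctx.Gb))


_REGISTRY: dict[str, Callable[[_GraphContext], "np.ndarray | float"]] = {
    "clustering_weighted": _m_clustering_w,
    "modularity_weighted": _m_modularity_w,
    "global_efficiency_weighted": _m_global_eff_w,
    "local_efficiency_weighted": _m_local_eff_w,
    "char_path_length_weighted": _m_cpl_w,
    "strength": _m_strength,
    "betweenness_weighted": _m_betweenness_w,
    "eigenvector_centrality_weighted": _m_eigenvector_w,
    "subgraph_centrality_weighted": _m_subgraph_w,
    "participation_coefficient": _m_participation,
    "within_module_degree_z": _m_within_module_z,
    "assortativity_weighted": _m_assortativity_w,
    "transitivity_weighted": _m_transitivity_w,
    "small_worldness": _m_small_worldness,
    "resilience": _m_resilience,
    "rich_club_median_degree": _m_rich_club,
    "coreness": _m_coreness,
    "closeness_weighted": _m_closeness_w,
    "diversity_coefficient": _m_diversity,
    "positive_edge_density": _m_pos_density,
    "median_positive_weight": _m_median_pos_weight,
    "degree_binary": _m_degree_b,
    "clustering_binary": _m_clustering_b,
    "global_efficiency_binary": _m_global_eff_b,
    "modularity_binary": _m_modularity_b,
    "assortativity_binary": _m_assortativity_b,
}


def _summarize(name: str, raw: "np.ndarray | float", summary: str) -> float:
    if summary == "scalar":
        if np.ndim(raw) != 0:
            raise ValueError(f"{name}: expected scalar, got array")
        return float(raw)
    arr = np.asarray(raw, dtype=float)
    if summary == "mean":
        return float(arr.mean())
    if summary == "median":
        return float(np.median(arr))
    if summary == "median_log":
        if np.any(arr <= 0):
            raise ValueError(f"{name}: non-positive values; log undefined")
        return float(np.median(np.log(arr)))
    raise ValueError(f"unknown summary {summary}")


def compute_metric_vector(
    cm: ConnectivityMatrix,
    catalog: MetricCatalog | None = None,
    seed: int = 0,
    density: float = DEFAULT_DENSITY,
    n_null: int = DEFAULT_N_NULL,
) -> GraphMetricVector:
    """Compute every catalog metric for one subject.

    Any non-finite result aborts with the metric and subject named — a
    non-finite metric signals an upstream problem, not a value to impute.
    """
    catalog = catalog or default_catalog()
    ctx = _GraphContext(cm.z, density=density, n_null=n_null, seed=seed)
    values: dict[str, float] = {}
    for entry in catalog.entries:
        raw = _REGISTRY[entry.name](ctx)
        val = _summarize(entry.name, raw, entry.summary)
        if not np.isfinite(val):
            raise ValueError(
                f"metric {entry.name} non-finite for subject {cm.subject_id}"
            )
        values[entry.name] = val
    return GraphMetricVector(
        subject_id=cm.subject_id, values=values, n_regions=ctx.n
    )


# ---------------------------------------------------------------------------
# training-based outlier exclusion


@dataclass
class OutlierRule:
    """Frozen per-metric (training mean, training sd) with a k-sd band."""

    means: dict[str, float]
    sds: dict[str, float]
    k_sd: float = 5.0

    @classmethod
    def fit(cls, training_vectors: list[GraphMetricVector], k_sd: float = 5.0) -> "OutlierRule":
        if not training_vectors:
            raise ValueError("no training vectors")
        names = list(training_vectors[0].values)
        data = np.array([[v.values[n] for n in names] for v in training_vectors])
        sds = data.std(axis=0, ddof=0)
        if np.any(sds == 0):
            bad = [names[i] for i in np.flatnonzero(sds == 0)]
            raise ValueError(f"zero training sd for metric(s) {bad}")
        return cls(
            means=dict(zip(names, data.mean(axis=0))),
            sds=dict(zip(names, sds)),
            k_sd=k_sd,
        )

    def is_outlier(self, vec: GraphMetricVector) -> list[str]:
        """Names of metrics outside the band (empty list = retained)."""
        flagged = []
        for name, mu in self.means.items():
            if abs(vec.values[name] - mu) > self.k_sd * self.sds[name]:
                flagged.append(name)
        return flagged


def exclude_metric_outliers(
    vectors: list[GraphMetricVector], rule: OutlierRule
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply a frozen outlier rule; returns (retained ids, exclusion log)."""
    retained, log = [], {}
    for vec in vectors:
        flagged = rule.is_outlier(vec)
        if flagged:
            log[vec.subject_id] = flagged
        else:
            retained.append(vec.subject_id)
    return retained, log


def vectors_to_frame(vectors: list[GraphMetricVector]) -> pd.DataFrame:
    """Stack metric vectors into a subjects x metrics DataFrame."""
    if not vectors:
        return pd.DataFrame()
    names = list(vectors[0].values)
    rows = {v.subject_id: [v.values[n] for n in names] for v in vectors}
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)
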