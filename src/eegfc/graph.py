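"""Weighted undirected graph measures for connectivity matrices.

The network model is weighted and undirected: edges keep their continuous
connectivity values instead of being binarized, and path-based measures use
the standard reciprocal mapping length = 1/weight.  Twelve global measures
(average degree, average strength, radius, diameter, characteristic path
length, global and local efficiency, clustering coefficient, transitivity,
modularity, assortativity, small-worldness) and five nodal measures
(degree, strength, global efficiency, local efficiency, clustering
coefficient) are provided.

Degree on a dense coherence matrix would saturate at N-1, so degree counts
edges above a configurable ``degree_threshold`` (default 0.5 for coherence
and 0.05 for PLI, the same cutoffs used for display); strength always sums
the unthresholded weights.  This thresholded-degree reading is an
interpretation, flagged here deliberately: every other measure runs on the
full weighted matrix.

Conventions for degenerate inputs: path measures are restricted to the
largest connected component; unreachable pairs contribute efficiency 0;
assortativity with zero endpoint-strength variance is NaN (undefined, not
an error).  No measure returns a silent NaN outside these documented cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix

GLOBAL_MEASURES: tuple[str, ...] = (
    "average_degree",
    "average_strength",
    "radius",
    "diameter",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "transitivity",
    "modularity",
    "assortativity",
    "small_worldness",
)

NODAL_MEASURES: tuple[str, ...] = (
    "degree",
    "strength",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
)


class NullModelError(ValueError):
    """Graph too small or disconnected for the rewiring null ensemble."""


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_connectivity(cls, m: ConnectivityMatrix) -> "WeightedGraph":
        return cls(m.values, m.channel_labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def lengths(self) -> np.ndarray:
        """Per-edge distances 1/weight; inf where there is no edge."""
        with np.errstate(divide="ignore"):
            ln = np.where(self.weights > 0, 1.0 / self.weights, np.inf)
        np.fill_diagonal(ln, 0.0)
        return ln


@dataclass(frozen=True)
class GraphConfig:
    """Shared configuration for a full measure set."""

    degree_threshold: float = 0.5
    n_nulls: int = 100
    rewires_per_edge: int = 10
    modularity_restarts: int = 10
    seed: int = 0
    global_measures: tuple[str, ...] = GLOBAL_MEASURES

    def __post_init__(self) -> None:
        if not 0.0 <= self.degree_threshold < 1.0:
            raise ValueError("degree_threshold must be in [0, 1)")
        unknown = set(self.global_measures) - set(GLOBAL_MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


def default_degree_threshold(method: str) -> float:
    """Display-cutoff-derived defaults: 0.5 for coherence, 0.05 for PLI."""
    return {"coherence": 0.5, "pli": 0.05}.get(method, 0.0)


@dataclass(frozen=True)
class GraphMeasureSet:
    """All measures for one connectivity matrix, with provenance."""

    global_measures: dict[str, float]
    nodal_measures: dict[str, np.ndarray]
    method: str = ""
    band: str = ""
    subject_id: str = ""
    condition: str = ""
    null_ensemble_meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# degree / strength

def degree_strength(
    g: WeightedGraph, degree_threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-node degree (edges with weight > threshold) and strength
    (unthresholded weight sum), plus their node averages."""
    if not 0.0 <= degree_threshold < 1.0:
        raise ValueError("degree_threshold must be in [0, 1)")
    adj = g.weights > degree_threshold
    degree = adj.sum(axis=1).astype(float)
    strength = g.weights.sum(axis=1)
    return degree, strength, float(degree.mean()), float(strength.mean())


# ---------------------------------------------------------------------------
# shortest-path family

def _distance_matrix(g: WeightedGraph) -> np.ndarray:
    return shortest_path(g.lengths(), method="D", directed=False)


def shortest_path_measures(
    g: WeightedGraph,
) -> tuple[float, float, float, float, np.ndarray]:
    """(characteristic_path_length, radius, diameter, global_efficiency,
    nodal_global_efficiency).

    Distances are shortest paths on 1/weight lengths.  CPL averages the
    finite pairwise distances; radius/diameter are the min/max eccentricity
    over the largest connected component; efficiency counts unreachable
    pairs as 0.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    dist = _distance_matrix(g)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off

    cpl = float(dist[finite].mean()) if finite.any() else float("inf")

    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(dist > 0, dist, np.inf), 0.0)
    glob_eff = float(inv[off].sum() / (n * (n - 1)))
    nodal_eff = inv.sum(axis=1) / (n - 1)

    # eccentricities on the largest component
    n_comp, labels = connected_components(
        (g.weights > 0).astype(int), directed=False
    )
    sizes = np.bincount(labels, minlength=n_comp)
    giant = labels == np.argmax(sizes)
    if giant.sum() < 2:
        radius = diameter = 0.0
    else:
        sub = dist[np.ix_(giant, giant)]
        ecc = np.max(np.where(np.isfinite(sub), sub, 0.0), axis=1)
        radius, diameter = float(ecc.min()), float(ecc.max())
    return cpl, radius, diameter, glob_eff, nodal_eff


# ---------------------------------------------------------------------------
# clustering family (geometric-mean / Onnela triangle form)

def _triangle_terms(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node weighted triangle count 2*t_i and triplet count k_i(k_i-1)."""
    cw = np.cbrt(w)
    t2 = np.einsum("ij,ih,jh->i", cw, cw, cw)  # = 2 t_i
    k = (w > 0).sum(axis=1).astype(float)
    triplets = k * (k - 1)
    return t2, triplets


def clustering_transitivity_local_efficiency(
    g: WeightedGraph,
) -> tuple[np.ndarray, float, float, np.ndarray, float]:
    """(nodal clustering, mean clustering, transitivity,
    nodal local efficiency, mean local efficiency)."""
    w = g.weights
    n = g.n_nodes
    t2, triplets = _triangle_terms(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        clustering = np.where(triplets > 0, t2 / triplets, 0.0)
    total_triplets = triplets.sum()
    transitivity = float(t2.sum() / total_triplets) if total_triplets > 0 else 0.0

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = WeightedGraph(w[np.ix_(nbrs, nbrs)])
        _, _, _, eff, _ = shortest_path_measures(sub)
        local_eff[i] = eff
    return clustering, float(clustering.mean()), transitivity, local_eff, float(
        local_eff.mean()
    )


# ---------------------------------------------------------------------------
# modularity

def modularity_q(w: np.ndarray, communities: np.ndarray) -> float:
    """Newman weighted modularity of a labelled partition."""
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for a zero-weight graph")
    s = w.sum(axis=1)
    same = communities[:, None] == communities[None, :]
    return float(((w - np.outer(s, s) / two_m) * same).sum() / two_m)


def _refine_partition(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedy single-node moves and pairwise community merges to a local
    optimum of Q (deterministic)."""
    labels = labels.copy()
    n = len(labels)
    improved = True
    while improved:
        improved = False
        best_q = modularity_q(w, labels)
        fresh = labels.max() + 1  # allow splitting off into a new community
        for i in range(n):
            current = labels[i]
            for target in list(np.unique(labels)) + [fresh]:
                if target == current:
                    continue
                labels[i] = target
                q = modularity_q(w, labels)
                if q > best_q + 1e-13:
                    best_q = q
                    current = target
                    improved = True
                else:
                    labels[i] = current
        # coordinated two-node moves escape the local optima single moves
        # cannot (balanced splits and cross-community exchanges); their cost
        # grows ~n^4 per pass, so they are reserved for small graphs where
        # hitting the exact optimum is attainable and expected
        fresh = labels.max() + 1
        pairs = itertools.combinations(range(n), 2) if n <= 12 else ()
        for i, j in pairs:
            if labels[i] != labels[j]:  # exchange communities
                trial = labels.copy()
                trial[i], trial[j] = labels[j], labels[i]
                q = modularity_q(w, trial)
                if q > best_q + 1e-13:
                    labels, best_q = trial, q
                    improved = True
            for target in list(np.unique(labels)) + [fresh]:  # joint move
                if target == labels[i] and target == labels[j]:
                    continue
                trial = labels.copy()
                trial[i] = trial[j] = target
                q = modularity_q(w, trial)
                if q > best_q + 1e-13:
                    labels, best_q = trial, q
                    improved = True
        for a, b in itertools.combinations(np.unique(labels), 2):
            trial = np.where(labels == b, a, labels)
            q = modularity_q(w, trial)
            if q > best_q + 1e-13:
                labels, best_q = trial, q
                improved = True
    return labels


def modularity(
    g: WeightedGraph, seed: int = 0, n_restarts: int = 10
) -> tuple[float, np.ndarray]:
    """Best (Q, community labels) from seeded Louvain restarts with greedy
    refinement; deterministic given the seed."""
    w = g.weights
    if w.sum() <= 0:
        raise ValueError("modularity undefined for a zero-weight graph")
    G = nx.from_numpy_array(w)
    best_q, best_labels = -np.inf, None
    starts: list[np.ndarray] = []
    for r in range(n_restarts):
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        labels = np.empty(g.n_nodes, dtype=int)
        for ci, members in enumerate(comms):
            labels[list(members)] = ci
        starts.append(labels)
    starts.append(np.arange(g.n_nodes))  # singleton start
    starts.append(np.zeros(g.n_nodes, dtype=int))  # one-community start
    for labels in starts:
        labels = _refine_partition(w, labels)
        q = modularity_q(w, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return float(best_q), best_labels


# ---------------------------------------------------------------------------
# assortativity

def assortativity(g: WeightedGraph) -> float:
    """Correlation of endpoint strengths over edges (NaN when the endpoint
    strength variance is degenerate)."""
    w = g.weights
    iu, ju = np.nonzero(np.triu(w, 1))
    if iu.size < 2:
        return float("nan")
    s = w.sum(axis=1)
    a = np.concatenate([s[iu], s[ju]])  # both orientations of each edge
    b = np.concatenate([s[ju], s[iu]])
    va = a.var()
    if va <= 1e-24:
        return float("nan")
    return float(((a - a.mean()) * (b - b.mean())).mean() / va)


# ---------------------------------------------------------------------------
# small-worldness

def _null_graph(
    g: WeightedGraph, rewires_per_edge: int, rng: np.random.Generator
) -> WeightedGraph:
    """Degree-sequence-preserving rewired topology with the original edge
    weights shuffled onto it."""
    n = g.n_nodes
    iu, ju = np.nonzero(np.triu(g.weights, 1))
    weights = g.weights[iu, ju]
    G = nx.from_edgelist(zip(iu.tolist(), ju.tolist()))
    G.add_nodes_from(range(n))
    n_edges = G.number_of_edges()
    max_possible = n * (n - 1) // 2
    if 0 < n_edges < max_possible:
        try:
            nx.double_edge_swap(
                G,
                nswap=rewires_per_edge * n_edges,
                max_tries=20 * rewires_per_edge * n_edges,
                seed=int(rng.integers(2**31 - 1)),
            )
        except nx.NetworkXAlgorithmError:
            pass  # dense graphs admit few swaps; keep what was achieved
    null_w = np.zeros_like(g.weights)
    perm = rng.permutation(len(weights))
    for (a, b), wv in zip(G.edges(), weights[perm]):
        null_w[a, b] = null_w[b, a] = wv
    return WeightedGraph(null_w)


def small_worldness(
    g: WeightedGraph,
    n_nulls: int = 100,
    rewires_per_edge: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """sigma = (C/<C_rand>) / (L/<L_rand>) against the rewired ensemble."""
    n = g.n_nodes
    if n < 4:
        raise NullModelError("small-worldness needs >= 4 nodes")
    n_comp, labels = connected_components((g.weights > 0).astype(int), directed=False)
    if np.bincount(labels).max() < n:
        raise NullModelError("small-worldness requires a connected graph")
    _, c_mean, _, _, _ = clustering_transitivity_local_efficiency(g)
    cpl, *_ = shortest_path_measures(g)
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    for _ in range(n_nulls):
        null = _null_graph(g, rewires_per_edge, rng)
        _, cn, _, _, _ = clustering_transitivity_local_efficiency(null)
        ln, *_ = shortest_path_measures(null)
        c_rand.append(cn)
        l_rand.append(ln)
    c_rand_mean = float(np.mean(c_rand))
    l_rand_mean = float(np.mean(l_rand))
    if c_rand_mean <= 0 or l_rand_mean <= 0 or not np.isfinite(l_rand_mean):
        raise NullModelError("degenerate null ensemble")
    sigma = (c_mean / c_rand_mean) / (cpl / l_rand_mean)
    return float(sigma), c_rand_mean, l_rand_mean


# ---------------------------------------------------------------------------
# everything at once

def all_measures(
    m: ConnectivityMatrix, config: GraphConfig | None = None
) -> GraphMeasureSet:
    """The full global + nodal measure set with shared configuration."""
    if config is None:
        config = GraphConfig(degree_threshold=default_degree_threshold(m.method))
    g = WeightedGraph.from_connectivity(m)
    want = set(config.global_measures)

    degree, strength, avg_deg, avg_str = degree_strength(g, config.degree_threshold)
    cpl, radius, diameter, glob_eff, nodal_eff = shortest_path_measures(g)
    clust, mean_clust, transitivity, local_eff, mean_local_eff = (
        clustering_transitivity_local_efficiency(g)
    )

    glob: dict[str, float] = {
        "average_degree": avg_deg,
        "average_strength": avg_str,
        "radius": radius,
        "diameter": diameter,
        "characteristic_path_length": cpl,
        "global_efficiency": glob_eff,
        "local_efficiency": mean_local_eff,
        "clustering_coefficient": mean_clust,
        "transitivity": transitivity,
    }
    null_meta: dict = {}
    if "modularity" in want:
        q, _ = modularity(g, seed=config.seed, n_restarts=config.modularity_restarts)
        glob["modularity"] = q
    if "assortativity" in want:
        glob["assortativity"] = assortativity(g)
    if "small_worldness" in want:
        sigma, c_rand, l_rand = small_worldness(
            g,
            n_nulls=config.n_nulls,
            rewires_per_edge=config.rewires_per_edge,
            seed=config.seed,
        )
        glob["small_worldness"] = sigma
        null_meta = {
            "n_nulls": config.n_nulls,
            "seed": config.seed,
            "c_rand_mean": c_rand,
            "l_rand_mean": l_rand,
        }
    glob = {k: v for k, v in glob.items() if k in want}

    nodal = {
        "degree": degree,
        "strength": strength,
        "global_efficiency": nodal_eff,
        "local_efficiency": local_eff,
        "clustering_coefficient": clust,
    }
    return GraphMeasureSet(
        global_measures=glob,
        nodal_measures=nodal,
        method=m.method,
        band=m.band.name,
        subject_id=m.subject_id,
        condition=m.condition,
        null_ensemble_meta=null_meta,
    )
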