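"""Brute-force reference implementations used only by the test suite.

These deliberately share no code with the package: shortest paths are
exhaustive Floyd-Warshall triple loops, modularity is an exhaustive search
over all set partitions (feasible for N <= 8), clustering/transitivity/
assortativity are direct formula evaluations with explicit Python loops.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances on lengths = 1/weight."""
    n = weights.shape[0]
    dist = np.full((n, n), math.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if i != j and weights[i, j] > 0:
                dist[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def path_measures(weights: np.ndarray) -> dict:
    """CPL, radius, diameter, global efficiency, nodal efficiency."""
    n = weights.shape[0]
    dist = floyd_warshall(weights)
    finite = []
    inv_sum = 0.0
    nodal = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if math.isfinite(dist[i, j]):
                finite.append(dist[i, j])
                inv_sum += 1.0 / dist[i, j]
                nodal[i] += 1.0 / dist[i, j]
    cpl = float(np.mean(finite)) if finite else math.inf
    geff = inv_sum / (n * (n - 1))
    nodal = nodal / (n - 1)

    # components by flood fill on positive weights
    comp = [-1] * n
    c = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        stack = [s]
        comp[s] = c
        while stack:
            u = stack.pop()
            for v in range(n):
                if weights[u, v] > 0 and comp[v] < 0:
                    comp[v] = c
                    stack.append(v)
        c += 1
    sizes = [comp.count(k) for k in range(c)]
    giant = max(range(c), key=lambda k: sizes[k])
    members = [i for i in range(n) if comp[i] == giant]
    if len(members) < 2:
        radius = diameter = 0.0
    else:
        eccs = []
        for i in members:
            eccs.append(max(dist[i, j] for j in members if j != i))
        radius, diameter = float(min(eccs)), float(max(eccs))
    return {
        "characteristic_path_length": cpl,
        "radius": radius,
        "diameter": diameter,
        "global_efficiency": float(geff),
        "nodal_global_efficiency": nodal,
    }


def clustering_measures(weights: np.ndarray) -> dict:
    """Onnela clustering, matched transitivity, weighted local efficiency."""
    n = weights.shape[0]
    clustering = np.zeros(n)
    tri_sum = 0.0
    triplet_sum = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        t = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            t += (weights[i, j] * weights[i, h] * weights[j, h]) ** (1.0 / 3.0)
        if k >= 2:
            clustering[i] = 2.0 * t / (k * (k - 1))
        tri_sum += 2.0 * t
        triplet_sum += k * (k - 1)
    transitivity = tri_sum / triplet_sum if triplet_sum > 0 else 0.0

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        local_eff[i] = path_measures(sub)["global_efficiency"]
    return {
        "nodal_clustering": clustering,
        "clustering_coefficient": float(clustering.mean()),
        "transitivity": float(transitivity),
        "nodal_local_efficiency": local_eff,
        "local_efficiency": float(local_eff.mean()),
    }


def set_partitions(items: list):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def modularity_of_partition(weights: np.ndarray, blocks: list[list[int]]) -> float:
    two_m = weights.sum()
    s = weights.sum(axis=1)
    q = 0.0
    for block in blocks:
        for i in block:
            for j in block:
                q += weights[i, j] - s[i] * s[j] / two_m
    return q / two_m


def exhaustive_modularity(weights: np.ndarray) -> float:
    """Maximum Newman Q over every partition (N <= 8)."""
    n = weights.shape[0]
    assert n <= 8, "exhaustive search is exponential"
    best = -math.inf
    for part in set_partitions(list(range(n))):
        q = modularity_of_partition(weights, part)
        if q > best:
            best = q
    return best


def edge_strength_assortativity(weights: np.ndarray) -> float:
    """Pearson correlation of endpoint strengths over the doubled edge list."""
    n = weights.shape[0]
    s = weights.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                xs += [s[i], s[j]]
                ys += [s[j], s[i]]
    if len(xs) < 4:
        return float("nan")
    x, y = np.array(xs), np.array(ys)
    vx = x.var()
    if vx <= 1e-24:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def degree_strength(weights: np.ndarray, threshold: float) -> tuple:
    n = weights.shape[0]
    deg = np.array(
        [sum(1 for j in range(n) if j != i and weights[i, j] > threshold) for i in range(n)],
        dtype=float,
    )
    st = np.array([sum(weights[i, j] for j in range(n)) for i in range(n)])
    return deg, st
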