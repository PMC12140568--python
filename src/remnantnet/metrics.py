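"""Weighted graph-theoretic features and the percent-shift statistic.

Seven features of weighted functional networks are computed: weighted
degree, clustering coefficient, eigenvector centrality, modularity,
characteristic path length, spectral radius and synchronizability.  The
first three are regional (with the regional mean as the network-level
value); the rest are global scalars.  The effect of removing a biophysical
network's edges is expressed as a percent shift

    Delta = 100 * (P_rfn - P_full) / P_full.

All features operate on nonnegative weights; signed networks are converted
upstream by the run's FC convention (magnitude or zero-clipped).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, dijkstra

from .network import WeightedNetwork

__all__ = [
    "weighted_degree",
    "clustering_coefficient",
    "eigenvector_centrality",
    "modularity",
    "modularity_q",
    "path_length",
    "spectral_radius",
    "synchronizability",
    "metric_shift",
    "regional_shift",
    "REGIONAL_METRICS",
    "GLOBAL_METRICS",
    "METRICS",
    "evaluate_metric",
]


def _check_nonnegative(net: WeightedNetwork) -> np.ndarray:
    w = net.weights
    if w.min() < 0:
        raise ValueError(
            "metric requires nonnegative weights; apply a sign convention first"
        )
    return w


def weighted_degree(net: WeightedNetwork) -> np.ndarray:
    """Per-region strength k_i = sum_j W_ij."""
    return net.weights.sum(axis=1)


def clustering_coefficient(net: WeightedNetwork) -> np.ndarray:
    """Weighted clustering coefficient (triangle intensity) per region.

    CC_i = [1 / (b_i (b_i - 1))] * sum_{j,h} (w_ij w_ih w_jh)^(1/3)
    with weights first scaled by the network-wide maximum (the Brain
    Connectivity Toolbox convention) when ``normalize_weights`` is left on,
    and b_i the number of neighbors of i.  CC_i = 0 when b_i < 2.
    """
    return _clustering(net, normalize_weights=True)


def _clustering(net: WeightedNetwork, normalize_weights: bool = True) -> np.ndarray:
    w = _check_nonnegative(net)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(net.n)
    ww = w / wmax if normalize_weights else w
    cr = np.cbrt(ww)
    cyc = np.diag(cr @ cr @ cr)  # sum over ordered (j, h) of cube-root products
    b = (w > 0).sum(axis=1).astype(float)
    denom = b * (b - 1)
    out = np.zeros(net.n)
    ok = denom > 0
    out[ok] = cyc[ok] / denom[ok]
    return out


def _largest_component(w: np.ndarray) -> np.ndarray:
    ncomp, labels = connected_components(sparse.csr_matrix(w != 0), directed=False)
    if ncomp == 1:
        return np.ones(w.shape[0], dtype=bool)
    sizes = np.bincount(labels)
    return labels == sizes.argmax()


def eigenvector_centrality(net: WeightedNetwork) -> np.ndarray:
    """Dominant-eigenvector centrality, unit Euclidean norm, nonnegative.

    If the network is disconnected, the centrality is computed on the
    largest connected component (other regions get zero) with a warning.
    """
    w = _check_nonnegative(net)
    keep = _largest_component(w)
    if not keep.all():
        warnings.warn(
            f"network disconnected; eigenvector centrality computed on the "
            f"largest component ({keep.sum()} of {net.n} regions)",
            stacklevel=2,
        )
    sub = w[np.ix_(keep, keep)]
    vals, vecs = np.linalg.eigh(sub)
    v = vecs[:, -1]
    # Perron-Frobenius: the dominant eigenvector is one-signed; fix it up
    if v.sum() < 0:
        v = -v
    v = np.abs(v)
    out = np.zeros(net.n)
    out[keep] = v / np.linalg.norm(v)
    return out


def modularity_q(
    net: WeightedNetwork, partition: np.ndarray, gamma: float = 1.0
) -> float:
    """Evaluate Newman-Girvan modularity of a given partition.

    Q = (1 / 2m) * sum_ij (W_ij - gamma * k_i k_j / 2m) * delta(c_i, c_j).
    """
    w = _check_nonnegative(net)
    c = np.asarray(partition)
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("network has no edges; modularity undefined")
    same = c[:, None] == c[None, :]
    B = w - gamma * np.outer(k, k) / two_m
    return float(B[same].sum() / two_m)


def modularity(
    net: WeightedNetwork,
    gamma: float = 1.0,
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Louvain community detection; best Q and partition over seeded restarts."""
    w = _check_nonnegative(net)
    if not np.any(w):
        raise ValueError("empty network")
    G = nx.from_numpy_array(w)
    rng = np.random.default_rng(seed)
    best_q, best_c = -np.inf, None
    for _ in range(n_restarts):
        run_seed = int(rng.integers(2**31 - 1))
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=run_seed
        )
        c = np.empty(net.n, dtype=int)
        for label, members in enumerate(comms):
            c[list(members)] = label
        q = modularity_q(net, c, gamma=gamma)
        if q > best_q:
            best_q, best_c = q, c
    return best_q, best_c


def path_length(net: WeightedNetwork) -> float:
    """Characteristic path length on inverse-weight edge lengths.

    Edge length is 1/weight (strong connections are short); L is the mean
    Dijkstra shortest-path distance over ordered region pairs.  Unreachable
    pairs are excluded with a warning — remnant networks keep ~84% of their
    edges, so disconnection is pathological rather than expected.
    """
    w = _check_nonnegative(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(sparse.csr_matrix(lengths), directed=False)
    off = d[~np.eye(net.n, dtype=bool)]
    finite = np.isfinite(off)
    if not finite.any():
        raise ValueError("fully disconnected network; path length undefined")
    n_inf = int((~finite).sum())
    if n_inf:
        warnings.warn(
            f"{n_inf} unreachable ordered pairs excluded from path length",
            stacklevel=2,
        )
    return float(off[finite].mean())


def spectral_radius(net: WeightedNetwork) -> float:
    """Largest absolute eigenvalue of the weight matrix."""
    return float(np.max(np.abs(np.linalg.eigvalsh(net.weights))))


def synchronizability(net: WeightedNetwork) -> float:
    """Laplacian eigenratio lambda_2 / lambda_n, L = K - W.

    lambda_2 is the algebraic connectivity; it vanishes on a disconnected
    network, where synchronizability is undefined.
    """
    w = _check_nonnegative(net)
    L = np.diag(w.sum(axis=1)) - w
    vals = np.linalg.eigvalsh(L)
    lam2, lamn = vals[1], vals[-1]
    if lam2 <= 1e-10 * max(lamn, 1.0):
        ncomp, _ = connected_components(sparse.csr_matrix(w != 0), directed=False)
        raise ValueError(
            f"network has {ncomp} connected components; synchronizability "
            "requires a connected graph"
        )
    return float(lam2 / lamn)


def metric_shift(p_full: float, p_rfn: float) -> float:
    """Percent shift Delta = 100 * (P_rfn - P_full) / P_full."""
    if p_full == 0:
        raise ValueError("baseline feature is zero; percent shift undefined")
    return 100.0 * (p_rfn - p_full) / p_full


def regional_shift(vec_full: np.ndarray, vec_rfn: np.ndarray) -> np.ndarray:
    """Per-region percent shift; regions with a zero baseline yield NaN."""
    full = np.asarray(vec_full, dtype=float)
    rfn = np.asarray(vec_rfn, dtype=float)
    out = np.full(full.shape, np.nan)
    ok = full != 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} regions have zero baseline; shift set to NaN",
            stacklevel=2,
        )
    out[ok] = 100.0 * (rfn[ok] - full[ok]) / full[ok]
    return out


# registry: regional metrics are averaged across regions for global reports
REGIONAL_METRICS = {
    "weighted_degree": weighted_degree,
    "clustering_coefficient": clustering_coefficient,
    "eigenvector_centrality": eigenvector_centrality,
}

GLOBAL_METRICS = {
    "modularity": lambda net, **kw: modularity(net, **kw)[0],
    "path_length": lambda net, **kw: path_length(net),
    "spectral_radius": lambda net, **kw: spectral_radius(net),
    "synchronizability": lambda net, **kw: synchronizability(net),
}

METRICS = tuple(REGIONAL_METRICS) + tuple(GLOBAL_METRICS)


def evaluate_metric(net: WeightedNetwork, name: str, **kw) -> float:
    """Network-level value of a named metric (regional metrics averaged)."""
    if name in REGIONAL_METRICS:
        return float(REGIONAL_METRICS[name](net).mean())
    if name in GLOBAL_METRICS:
        return float(GLOBAL_METRICS[name](net, **kw))
    raise KeyError(f"unknown metric {name!r}")
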