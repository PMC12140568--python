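"""Search information: bits to follow shortest paths in a weighted network.

Search information SI(i -> j) is the negative log2 probability that a
memoryless random walker — stepping from node u to neighbor v with
probability w_uv / s_u, where s_u is the strength of u — follows a
shortest path (on inverse-weight edge lengths) from i to j.  When several
shortest paths tie, their probabilities are summed before the log.  The
matrix is symmetrized by averaging the two directions, reversed
(SI_max - SI) so that large values mean easy-to-reach pairs, and used to
predict functional connectivity profiles region by region.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .network import WeightedNetwork

__all__ = ["search_info_matrix", "reverse_si", "nodewise_r2"]


def _shortest_path_probabilities(w: np.ndarray, d: np.ndarray) -> np.ndarray:
    """P[i, j]: probability a memoryless walker takes a shortest i->j path.

    Dynamic programming per target j over nodes ordered by decreasing
    distance-to-j: P(i -> j) sums, over neighbors v of i lying on a
    shortest path (l_iv + d_vj = d_ij), the step probability w_iv / s_i
    times P(v -> j).
    """
    n = w.shape[0]
    s = w.sum(axis=1)
    with np.errstate(divide="ignore"):
        l = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    P = np.zeros((n, n))
    for j in range(n):
        order = np.argsort(d[:, j], kind="stable")  # closest to j first
        P[j, j] = 1.0
        for i in order:
            if i == j or not np.isfinite(d[i, j]):
                continue
            nbrs = np.nonzero(w[i] > 0)[0]
            slack = 1e-10 * max(d[i, j], 1.0)  # cross-run Dijkstra rounding
            on_path = nbrs[np.abs(l[i, nbrs] + d[nbrs, j] - d[i, j]) <= slack]
            P[i, j] = np.sum(w[i, on_path] / s[i] * P[on_path, j])
    return P


def search_info_matrix(net: WeightedNetwork) -> WeightedNetwork:
    """Symmetrized search-information matrix in bits.

    Negative weights are clamped to zero (signed similarity networks carry
    no meaning for a random walker), shortest paths use inverse-weight
    lengths, and SI(i, j) = -log2 of the walker's probability of reaching j
    from i along any shortest path, averaged over the two directions.
    """
    w = np.maximum(net.weights, 0.0)
    if np.any(w.sum(axis=1) == 0):
        raise ValueError("network has an isolated region; SI undefined")
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = dijkstra(sparse.csr_matrix(lengths), directed=False)
    if not np.all(np.isfinite(d)):
        raise ValueError("network is disconnected; SI undefined for some pairs")
    P = _shortest_path_probabilities(w, d)
    with np.errstate(divide="ignore"):
        si = -np.log2(P)
    si = (si + si.T) / 2.0
    np.fill_diagonal(si, 0.0)
    return WeightedNetwork(si, kind="SI", signed=False)


def reverse_si(si: WeightedNetwork) -> WeightedNetwork:
    """Reverse SI so high values mean strongly coupled pairs: SI_max - SI.

    ``SI_max`` is the largest off-diagonal entry (the hardest-to-reach
    pair, which maps to zero).  The diagonal stays zero.
    """
    w = si.weights
    iu = np.triu_indices(si.n, k=1)
    si_max = w[iu].max()
    rev = si_max - w
    np.fill_diagonal(rev, 0.0)
    return WeightedNetwork(rev, kind="SI", signed=False)


def nodewise_r2(si_rev: WeightedNetwork, fc: WeightedNetwork) -> dict:
    """Per-region R^2 of FC profiles regressed on reversed-SI profiles.

    For each region i the off-diagonal FC row fc(i, .) is regressed on the
    reversed-SI row si_rev(i, .) by simple linear regression; the
    coefficient of determination equals the squared Pearson correlation.
    Regions with a degenerate (zero-variance) predictor or target are
    recorded as NaN with a warning.
    """
    if si_rev.n != fc.n:
        raise ValueError("SI and FC dimensions disagree")
    n = fc.n
    if n < 4:
        raise ValueError("need at least four regions for nodewise regression")
    r2 = np.full(n, np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        x = si_rev.weights[i, keep]
        y = fc.weights[i, keep]
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"region {i} has a constant profile; R^2 recorded as missing",
                stacklevel=2,
            )
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[i] = r * r
    valid = r2[np.isfinite(r2)]
    return {
        "r2": r2,
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
    }
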