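"""Null models and empirical significance for removal-induced shifts.

Three nulls benchmark the shift a biophysical edge removal induces:

* random removal — remove the same number of edges uniformly at random;
* degree-preserving rewiring — Maslov-Sneppen double-edge swaps of the
  binarized biophysical edge set, so each region loses the same number of
  edges as in the real removal;
* hemisphere-matched removal — random removal stratified to match the
  biophysical edge set's intra-left, intra-right and inter-hemispheric
  edge counts exactly.

Empirical p-values use the add-one permutation rule so that p is never
zero with finitely many iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np

from .network import EdgeMask, WeightedNetwork
from .parcellation import Parcellation

__all__ = [
    "NullDistribution",
    "random_removal_null",
    "rewire_preserving_degree",
    "hemisphere_matched_null",
    "empirical_p",
]


@dataclass(frozen=True)
class NullDistribution:
    """Vector of null feature shifts with its provenance."""

    model: str
    metric: str
    values: np.ndarray
    iterations: int
    seed: int

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if self.model not in {"random", "rewired", "hemisphere"}:
            raise ValueError(f"unknown null model {self.model!r}")
        if len(vals) != self.iterations:
            raise ValueError("value count must equal the iteration count")
        object.__setattr__(self, "values", vals)


def _percent_shift(baseline: float, value: float) -> float:
    return 100.0 * (value - baseline) / baseline


def _null_from_removals(
    fc: WeightedNetwork,
    feature_fn: Callable[[WeightedNetwork], float],
    draw_edges: Callable[[np.random.Generator], tuple[np.ndarray, np.ndarray]],
    iters: int,
    seed: int,
    model: str,
    metric: str,
) -> NullDistribution:
    baseline = float(feature_fn(fc))
    if baseline == 0:
        raise ValueError("baseline feature is zero; null shifts undefined")
    rng = np.random.default_rng(seed)
    vals = np.empty(iters)
    for it in range(iters):
        ii, jj = draw_edges(rng)
        w = fc.weights.copy()
        w[ii, jj] = 0.0
        w[jj, ii] = 0.0
        vals[it] = _percent_shift(baseline, float(feature_fn(fc.with_weights(w))))
    return NullDistribution(
        model=model, metric=metric, values=vals, iterations=iters, seed=seed
    )


def random_removal_null(
    fc: WeightedNetwork,
    m_edges: int,
    feature_fn: Callable[[WeightedNetwork], float],
    iters: int = 1000,
    seed: int = 0,
    metric: str = "feature",
) -> NullDistribution:
    """Shifts from removing ``m_edges`` uniformly random nonzero FC edges."""
    i, j = np.triu_indices(fc.n, k=1)
    nz = fc.weights[i, j] != 0
    i, j = i[nz], j[nz]
    if m_edges >= len(i):
        raise ValueError("cannot remove as many edges as the network holds")

    def draw(rng):
        pick = rng.choice(len(i), size=m_edges, replace=False)
        return i[pick], j[pick]

    return _null_from_removals(
        fc, feature_fn, draw, iters, seed, "random", metric
    )


def rewire_preserving_degree(
    bio_mask: EdgeMask, n_swaps_per_edge: int = 10, seed: int = 0
) -> EdgeMask:
    """Degree-preserving randomization of a binary edge set.

    Maslov-Sneppen double-edge swaps on the mask's graph; every node keeps
    its degree exactly, and no self-loops or duplicate edges appear.  If a
    valid swap cannot be found within the attempt budget, the partially
    rewired mask is returned with a warning.
    """
    edges = bio_mask.edge_list()
    m = len(edges)
    if m < 2:
        raise ValueError("need at least two edges to rewire")
    G = nx.Graph()
    G.add_nodes_from(range(bio_mask.n))
    G.add_edges_from(map(tuple, edges))
    degrees_in = dict(G.degree())
    nswap = n_swaps_per_edge * m
    try:
        nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXAlgorithmError as err:
        warnings.warn(f"rewiring stopped early: {err}", stacklevel=2)
    if dict(G.degree()) != degrees_in:  # defining invariant, asserted per call
        raise AssertionError("degree sequence changed during rewiring")
    sel = np.zeros((bio_mask.n, bio_mask.n), dtype=bool)
    for a, b in G.edges():
        sel[a, b] = sel[b, a] = True
    return EdgeMask(sel)


def _hemisphere_strata(n: int, parcels: Parcellation) -> np.ndarray:
    """Stratum code per upper-triangle pair: 0 intra-L, 1 intra-R, 2 inter."""
    left = parcels.hemisphere_index()
    i, j = np.triu_indices(n, k=1)
    both_left = left[i] & left[j]
    both_right = ~left[i] & ~left[j]
    return np.where(both_left, 0, np.where(both_right, 1, 2))


def hemisphere_matched_null(
    fc: WeightedNetwork,
    mask: EdgeMask,
    parcels: Parcellation,
    feature_fn: Callable[[WeightedNetwork], float],
    iters: int = 1000,
    seed: int = 0,
    metric: str = "feature",
) -> NullDistribution:
    """Random removal matching the mask's hemispheric edge composition."""
    if fc.n != mask.n or fc.n != parcels.n_regions:
        raise ValueError("network, mask and parcellation dimensions disagree")
    i, j = np.triu_indices(fc.n, k=1)
    strata = _hemisphere_strata(fc.n, parcels)
    nz = fc.weights[i, j] != 0
    sel = mask.selected[i, j]
    counts = [int(np.count_nonzero(sel & (strata == s))) for s in range(3)]
    pools = []
    for s in range(3):
        pool = np.nonzero(nz & (strata == s))[0]
        if counts[s] > len(pool):
            raise ValueError(
                f"stratum {s} has {len(pool)} available edges but the mask "
                f"removes {counts[s]}"
            )
        pools.append(pool)

    def draw(rng):
        picks = [
            rng.choice(pools[s], size=counts[s], replace=False)
            for s in range(3)
            if counts[s] > 0
        ]
        flat = np.concatenate(picks) if picks else np.empty(0, dtype=int)
        return i[flat], j[flat]

    return _null_from_removals(
        fc, feature_fn, draw, iters, seed, "hemisphere", metric
    )


def empirical_p(
    observed: float, null: NullDistribution, tail: str = "magnitude"
) -> float:
    """Add-one empirical p-value of an observed shift against a null.

    ``magnitude`` (default) is one-sided on |shift|, matching how removal
    effects are reported; ``two-sided`` compares signed exceedances in both
    directions.
    """
    vals = null.values
    if vals.size == 0:
        raise ValueError("empty null distribution")
    if tail == "magnitude":
        exceed = np.count_nonzero(np.abs(vals) >= abs(observed))
    elif tail == "two-sided":
        hi = np.count_nonzero(vals >= abs(observed))
        lo = np.count_nonzero(vals <= -abs(observed))
        exceed = hi + lo
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + exceed) / (1 + vals.size)
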