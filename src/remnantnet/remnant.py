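"""Remnant functional networks and edge-level comparison constructs.

A remnant functional network (RFN) is the functional connectivity matrix
with every edge removed that coincides with one of the strongest edges of
a reference biophysical network at a matched density d (the average
structural-connectome density, 16.07% in the source datasets).  Removing
d of the pairs from a fully connected FC leaves an RFN of density 1 - d.

This module also provides the comparison constructs used to interpret
RFN shifts: the combined-rank network (average of per-network edge ranks),
the strongest-edge benchmark (removing the top-d edges of FC itself), the
shift ratio between a biophysical removal and that benchmark, top-x%
edge-set overlap, and the connected-vs-unconnected edge-strength contrast.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import stats as sstats

from .network import (
    EdgeMask,
    RemnantNetwork,
    WeightedNetwork,
    apply_mask,
    threshold_top,
)

__all__ = [
    "build_rfn",
    "combined_rank_network",
    "overlap_fraction",
    "strongest_edge_benchmark",
    "shift_ratio",
    "edge_strength_groups",
    "write_rfn",
]


def build_rfn(
    fc: WeightedNetwork, bio: WeightedNetwork, d: float
) -> RemnantNetwork:
    """Remove the top-``d`` edges of ``bio`` from ``fc``."""
    if fc.n != bio.n:
        raise ValueError("FC and biophysical network dimensions disagree")
    if not (0 < d < 1):
        raise ValueError("removal density must lie strictly in (0, 1)")
    mask = threshold_top(bio, d)
    return RemnantNetwork(
        base=fc,
        mask=mask,
        result=apply_mask(fc, mask),
        source_kind=bio.kind,
        threshold_density=d,
    )


def strongest_edge_benchmark(fc: WeightedNetwork, d: float) -> RemnantNetwork:
    """Benchmark RFN: remove the top-``d`` strongest edges of FC itself."""
    return build_rfn(fc, fc, d)


def shift_ratio(delta_bio: float, delta_top: float) -> float:
    """Ratio of a biophysical shift to the strongest-edge benchmark shift."""
    if delta_top == 0:
        raise ZeroDivisionError("benchmark shift is zero; ratio undefined")
    return delta_bio / delta_top


def combined_rank_network(
    nets: list[WeightedNetwork], include_sc: bool = True
) -> WeightedNetwork:
    """Average of per-network edge ranks (stronger edge = higher rank).

    Each network's off-diagonal pairs are dense-ranked on weight magnitude
    so that zero / absent edges share the minimal rank (sparse SC would
    otherwise skew the ranking — hence the ``include_sc`` switch).  The
    entrywise mean rank is returned as a COMBINED network for the caller to
    threshold at the matched density.
    """
    nets = [x for x in nets if include_sc or x.kind != "SC"]
    if len(nets) < 2:
        raise ValueError("need at least two networks to combine ranks")
    n = nets[0].n
    if any(x.n != n for x in nets):
        raise ValueError("networks must share dimensions")
    iu = np.triu_indices(n, k=1)
    ranks = np.mean(
        [sstats.rankdata(np.abs(x.weights[iu]), method="dense") for x in nets],
        axis=0,
    )
    W = np.zeros((n, n))
    W[iu] = ranks
    W = W + W.T
    return WeightedNetwork(W, kind="COMBINED", signed=False)


def overlap_fraction(
    fc: WeightedNetwork, nets: list[WeightedNetwork], x: float
) -> dict:
    """Percent of FC's top-``x`` edges present in the top-``x`` of any net.

    Returns ``{"any": pct, "per_net": {kind: pct}}``; "any" counts FC edges
    covered by at least one thresholded reference network.
    """
    fc_mask = threshold_top(fc, x).selected
    iu = np.triu_indices(fc.n, k=1)
    fc_edges = fc_mask[iu]
    total = fc_edges.sum()
    union = np.zeros_like(fc_edges)
    per_net = {}
    for net in nets:
        sel = threshold_top(net, x).selected[iu]
        per_net[net.kind] = 100.0 * np.count_nonzero(fc_edges & sel) / total
        union |= sel
    return {
        "any": 100.0 * np.count_nonzero(fc_edges & union) / total,
        "per_net": per_net,
    }


def edge_strength_groups(fc: WeightedNetwork, mask: EdgeMask) -> dict:
    """Compare FC edge strengths on vs off a biophysical edge set.

    Splits the upper-triangle FC weights by mask membership and returns
    group means with a two-sample t test (connected minus unconnected).
    """
    if fc.n != mask.n:
        raise ValueError("network and mask dimensions disagree")
    iu = np.triu_indices(fc.n, k=1)
    sel = mask.selected[iu]
    connected = fc.weights[iu][sel]
    unconnected = fc.weights[iu][~sel]
    if connected.size == 0 or unconnected.size == 0:
        raise ValueError("mask must leave both edge groups nonempty")
    t, p = _two_sample_t(connected, unconnected)
    return {
        "mean_connected": float(connected.mean()),
        "mean_unconnected": float(unconnected.mean()),
        "t": float(t),
        "p": float(p),
    }


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled two-sample t; degenerate equal-constant groups give t = 0."""
    if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sstats.ttest_ind(a, b)
    return float(t), float(p)


def write_rfn(rfn: RemnantNetwork, matrix_path, sidecar_path, region_id=None):
    """Serialize an RFN: result matrix + JSON provenance sidecar."""
    from .network import write_matrix

    write_matrix(rfn.result, matrix_path, region_id=region_id)
    with open(sidecar_path, "w") as fh:
        json.dump(rfn.provenance(), fh, indent=2)
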