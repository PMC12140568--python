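"""Group-contrast t-value networks and biophysically resolved deltas.

For a clinical contrast (patients vs controls), an edgewise two-sample
t test produces a t-value network; removing a biophysical network's
strongest edges from it and comparing the remaining average t value with
the full-matrix average quantifies how much of the group difference is
carried by that biophysical edge set:

    Delta = 100 * (<RFN_tval> - <Tval>) / <Tval>

with <.> the average t value.  A positive Delta means the removed edges
were pulling the average down — i.e. the biophysical connections acted to
decrease average FC in the clinical group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import EdgeMask, WeightedNetwork, threshold_top

__all__ = [
    "GroupStudy",
    "ContrastReport",
    "edgewise_ttest",
    "tvalue_rfn_delta",
    "connected_vs_unconnected_t",
]


@dataclass(frozen=True)
class GroupStudy:
    """Two groups of subject-level FC networks sharing a parcellation."""

    group_a: tuple
    group_b: tuple
    labels: tuple = ("control", "clinical")

    def __post_init__(self):
        a, b = tuple(self.group_a), tuple(self.group_b)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least two subjects")
        n = a[0].n
        if any(net.n != n for net in a + b):
            raise ValueError("all subjects must share region count and order")
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)

    @property
    def n(self) -> int:
        return self.group_a[0].n


@dataclass
class ContrastReport:
    """Edgewise contrast plus per-biophysical-source deltas."""

    tval_net: WeightedNetwork
    mean_t: float
    delta_pct: dict = field(default_factory=dict)
    stratum_means: dict = field(default_factory=dict)
    null_p: dict = field(default_factory=dict)


def edgewise_ttest(study: GroupStudy, welch: bool = False) -> WeightedNetwork:
    """Edgewise independent-sample t network (clinical minus control).

    Positive t means the edge is stronger in ``group_b`` (the clinical
    group).  The pooled-variance Student t is the default; ``welch``
    switches to the unequal-variance form.  Edges with zero variance in
    both groups get t = 0 with a warning.
    """
    a = np.stack([net.weights for net in study.group_a])
    b = np.stack([net.weights for net in study.group_b])
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    if welch:
        se2 = va / na + vb / nb
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    zero = se2 == 0
    # off-diagonal degenerate edges are flagged; the diagonal is always zero
    if np.any(zero & ~np.eye(study.n, dtype=bool)):
        warnings.warn(
            "edges with zero pooled variance; their t set to 0", stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, (mb - ma) / np.sqrt(np.where(zero, 1.0, se2)))
    np.fill_diagonal(t, 0.0)
    return WeightedNetwork(t, kind="TVAL", signed=True)


def tvalue_rfn_delta(
    tval_net: WeightedNetwork,
    bio: WeightedNetwork | None,
    d: float,
    mean_floor: float = 1e-3,
    mask: EdgeMask | None = None,
) -> float:
    """Percent change in average t after removing a biophysical edge set.

    The edges removed are the top-``d`` of ``bio`` (or an explicit
    ``mask``).  The full-matrix average runs over every off-diagonal pair;
    the RFN average runs over the remaining nonzero entries.  A near-zero
    full-matrix mean makes the ratio unstable, hence the floor.
    """
    if mask is None:
        if bio is None or tval_net.n != bio.n:
            raise ValueError("t-value and biophysical network dimensions disagree")
        mask = threshold_top(bio, d)
    elif tval_net.n != mask.n:
        raise ValueError("t-value network and mask dimensions disagree")
    iu = np.triu_indices(tval_net.n, k=1)
    t = tval_net.weights[iu]
    mean_full = t.mean()
    if abs(mean_full) < mean_floor:
        raise ValueError(
            f"|mean t| = {abs(mean_full):.2e} below the stability floor "
            f"{mean_floor}; delta undefined"
        )
    removed = mask.selected[iu]
    remaining = t[~removed]
    remaining = remaining[remaining != 0]
    if remaining.size == 0:
        raise ValueError("removal left no nonzero t values")
    return 100.0 * (remaining.mean() - mean_full) / mean_full


def connected_vs_unconnected_t(
    tval_net: WeightedNetwork, mask: EdgeMask
) -> dict:
    """Average t on vs off a biophysical edge set, with a two-sample test."""
    if tval_net.n != mask.n:
        raise ValueError("network and mask dimensions disagree")
    iu = np.triu_indices(tval_net.n, k=1)
    sel = mask.selected[iu]
    connected = tval_net.weights[iu][sel]
    unconnected = tval_net.weights[iu][~sel]
    if connected.size == 0 or unconnected.size == 0:
        raise ValueError("both strata must be nonempty")
    from .remnant import _two_sample_t

    t, p = _two_sample_t(connected, unconnected)
    return {
        "mean_connected": float(connected.mean()),
        "mean_unconnected": float(unconnected.mean()),
        "t": float(t),
        "p": float(p),
    }
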