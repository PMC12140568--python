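"""Core weighted-network data model.

Every matrix in the pipeline — functional connectivity (FC), structural
connectivity (SC), Euclidean proximity (DC), gene-expression similarity
(GC), receptor congruence (RC), their distance-corrected variants, t-value
contrasts and search-information matrices — travels as a
:class:`WeightedNetwork`: a symmetric, zero-diagonal, finite weight matrix
with a modality tag.  Density accounting, density-matched thresholding,
the magnitude / zero-clipped sign conventions and subject-level group
averaging all live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KINDS",
    "WeightedNetwork",
    "EdgeMask",
    "RemnantNetwork",
    "density",
    "threshold_top",
    "apply_mask",
    "to_magnitude",
    "clip_negative",
    "group_average",
    "n_pairs",
    "round_half_away",
    "read_matrix",
    "write_matrix",
]

KINDS = frozenset(
    {"FC", "SC", "DC", "GC", "RC", "GCd", "RCd", "TVAL", "COMBINED", "SI"}
)

_SYM_TOL = 1e-12


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric zero-diagonal weighted matrix with a modality tag.

    Parameters
    ----------
    weights
        ``(n, n)`` real matrix; symmetrized must hold to ``1e-12``.
    kind
        Modality tag, one of :data:`KINDS`.
    signed
        Whether negative weights are meaningful.  Unsigned FC must lie in
        ``[0, 1]`` (BOLD correlation magnitudes).
    """

    weights: np.ndarray
    kind: str = "FC"
    signed: bool = False

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] < 2:
            raise ValueError("a network needs at least two regions")
        if self.kind not in KINDS:
            raise ValueError(f"unknown network kind {self.kind!r}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.max(np.abs(w - w.T)) > _SYM_TOL:
            raise ValueError("weights must be symmetric to within 1e-12")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if self.kind == "FC" and not self.signed and (w.min() < 0 or w.max() > 1):
            raise ValueError("unsigned FC weights must lie in [0, 1]")
        # exact symmetry simplifies downstream eigen/solver work
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: np.ndarray, **kw) -> "WeightedNetwork":
        return replace(self, weights=weights, **kw)


@dataclass(frozen=True)
class EdgeMask:
    """Symmetric boolean edge-pair selection with a false diagonal."""

    selected: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.selected, dtype=bool)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("mask must be square")
        if not np.array_equal(s, s.T):
            raise ValueError("mask must be symmetric")
        if np.any(np.diag(s)):
            raise ValueError("mask diagonal must be false")
        s = s.copy()
        s.flags.writeable = False
        object.__setattr__(self, "selected", s)

    @property
    def n(self) -> int:
        return self.selected.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of selected unordered pairs."""
        return int(np.count_nonzero(np.triu(self.selected, 1)))

    def edge_list(self) -> np.ndarray:
        """(m, 2) array of selected (i, j) pairs with i < j, lexicographic."""
        i, j = np.nonzero(np.triu(self.selected, 1))
        return np.column_stack([i, j])


@dataclass(frozen=True)
class RemnantNetwork:
    """An FC (or t-value) network with one biophysical network's edges removed.

    ``result`` equals ``base`` with every masked edge set to zero; the mask
    is the top-``threshold_density`` edge set of the reference network whose
    tag is recorded in ``source_kind``.
    """

    base: WeightedNetwork
    mask: EdgeMask
    result: WeightedNetwork
    source_kind: str
    threshold_density: float

    def __post_init__(self):
        if not (0 < self.threshold_density <= 1):
            raise ValueError("threshold_density must lie in (0, 1]")
        if self.base.n != self.mask.n or self.base.n != self.result.n:
            raise ValueError("base, mask and result dimensions disagree")
        expected = self.base.weights.copy()
        expected[self.mask.selected] = 0.0
        if not np.array_equal(expected, self.result.weights):
            raise ValueError("result is not base with masked edges zeroed")

    @property
    def n_removed(self) -> int:
        """Unordered pairs actually zeroed (nonzero in base and masked)."""
        hit = self.mask.selected & (self.base.weights != 0)
        return int(np.count_nonzero(np.triu(hit, 1)))

    def provenance(self) -> dict:
        return {
            "source_kind": self.source_kind,
            "threshold_density": self.threshold_density,
            "mask_edges": self.mask.n_edges,
            "removed_edges": self.n_removed,
            "result_density": density(self.result),
        }


def n_pairs(n: int) -> int:
    return n * (n - 1) // 2


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), for reproducible edge counts."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def density(net: WeightedNetwork) -> float:
    """Fraction of strictly nonzero off-diagonal unordered pairs."""
    iu = np.triu_indices(net.n, k=1)
    return float(np.count_nonzero(net.weights[iu])) / n_pairs(net.n)


def threshold_top(net: WeightedNetwork, d: float) -> EdgeMask:
    """Mask of the exactly ``round(d * n(n-1)/2)`` strongest edge pairs.

    Strength is the stored weight, so for the proximity-coded DC network the
    retained pairs are the spatially closest regions.  Ties are broken by
    (i, j) lexicographic order so the selection is deterministic.
    """
    if not (0 < d <= 1):
        raise ValueError("density d must lie in (0, 1]")
    m = round_half_away(d * n_pairs(net.n))
    if m == 0:
        raise ValueError(f"density {d} selects zero edges at n={net.n}")
    i, j = np.triu_indices(net.n, k=1)
    w = net.weights[i, j]
    # primary key: weight descending; ties by (i, j) ascending
    order = np.lexsort((j, i, -w))
    keep = order[:m]
    sel = np.zeros((net.n, net.n), dtype=bool)
    sel[i[keep], j[keep]] = True
    sel |= sel.T
    return EdgeMask(sel)


def apply_mask(net: WeightedNetwork, mask: EdgeMask) -> WeightedNetwork:
    """Zero the masked edges of ``net``."""
    if net.n != mask.n:
        raise ValueError("network and mask dimensions disagree")
    w = net.weights.copy()
    w[mask.selected] = 0.0
    return net.with_weights(w)


def to_magnitude(net: WeightedNetwork) -> WeightedNetwork:
    """Elementwise absolute value; the result is unsigned."""
    return net.with_weights(np.abs(net.weights), signed=False)


def clip_negative(net: WeightedNetwork) -> WeightedNetwork:
    """Zero every negative weight (the zero-thresholded FC convention)."""
    return net.with_weights(np.maximum(net.weights, 0.0), signed=False)


def group_average(
    stack: Sequence[WeightedNetwork], fisher_z: bool = False
) -> WeightedNetwork:
    """Entrywise arithmetic mean of subject-level networks.

    The default is the plain mean of the subject matrices.  ``fisher_z``
    averages arctanh-transformed weights and transforms back, for users who
    prefer the variance-stabilized convention for correlations.
    """
    stack = list(stack)
    if not stack:
        raise ValueError("need at least one network to average")
    n = stack[0].n
    if any(net.n != n for net in stack):
        raise ValueError("all networks in the stack must share dimensions")
    arrs = np.stack([net.weights for net in stack])
    if fisher_z:
        z = np.arctanh(np.clip(arrs, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = arrs.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    return stack[0].with_weights(mean, signed=any(net.signed for net in stack))


def read_matrix(path, kind: str = "FC", signed: bool = False) -> WeightedNetwork:
    """Read a square weighted matrix from delimited text.

    First row and first column carry region ids; comma or tab delimited;
    transparently gzipped when the filename ends in ``.gz``.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns) and list(map(str, df.index)) != list(
        df.columns
    ):
        raise ValueError("matrix row and column region ids disagree")
    return WeightedNetwork(df.to_numpy(dtype=float), kind=kind, signed=signed)


def write_matrix(
    net: WeightedNetwork, path, region_id: Iterable | None = None
) -> None:
    ids = list(region_id) if region_id is not None else list(range(net.n))
    pd.DataFrame(net.weights, index=ids, columns=ids).to_csv(path)
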