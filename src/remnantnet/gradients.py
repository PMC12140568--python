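"""Connectivity gradients: diffusion-map embedding and the shift statistic.

A gradient is a component of a low-dimensional diffusion-map embedding of
the similarity between regional connectivity profiles.  The pipeline is:
row-wise sparsification of the connectivity matrix (top 10% of each row's
entries kept), cosine similarity between the sparsified profiles, an
anisotropic (alpha = 0.5) diffusion embedding, Procrustes alignment of
remnant-network gradients to the full-network gradients, and the gradient
shift delta = 1 - |R| with R the Pearson correlation of aligned gradient
maps across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import pearsonr

from .network import WeightedNetwork, round_half_away

__all__ = [
    "GradientSet",
    "affinity",
    "diffusion_map",
    "procrustes_align",
    "gradient_shift",
    "variance_explained_compare",
]


@dataclass(frozen=True)
class GradientSet:
    """n x k gradient coordinates with their eigen-spectrum.

    ``variance_fraction`` is each retained eigenvalue over the sum of all
    non-trivial positive eigenvalues of the diffusion operator.
    ``reference_id`` records alignment provenance ("unaligned" or the id of
    the gradient set the coordinates were Procrustes-aligned to).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    reference_id: str = "unaligned"

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        evals = np.asarray(self.eigenvalues, dtype=float)
        vf = np.asarray(self.variance_fraction, dtype=float)
        if coords.ndim != 2 or coords.shape[1] < 2:
            raise ValueError("need at least two gradient components")
        if evals.shape != (coords.shape[1],) or vf.shape != evals.shape:
            raise ValueError("eigenvalue bookkeeping does not match coordinates")
        if np.any(vf < 0) or np.any(vf > 1) or np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing in [0, 1]")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "eigenvalues", evals)
        object.__setattr__(self, "variance_fraction", vf)

    @property
    def n(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"g{i + 1}": self.coordinates[:, i] for i in range(self.k)}
        return pd.DataFrame(cols)


def affinity(net: WeightedNetwork, row_sparsity: float = 0.9) -> np.ndarray:
    """Cosine-similarity affinity from row-sparsified connectivity profiles.

    Per row, only the largest ``(1 - row_sparsity)`` fraction of entries is
    kept (the gradient-toolbox convention); cosine similarity between the
    sparsified rows follows, negatives clamped to zero.  The diagonal is 1
    by construction.
    """
    if not (0 <= row_sparsity < 1):
        raise ValueError("row_sparsity must lie in [0, 1)")
    w = net.weights
    n = net.n
    keep = max(1, round_half_away((1.0 - row_sparsity) * n))
    sparse_w = np.zeros_like(w)
    for i in range(n):
        order = np.argsort(-w[i], kind="stable")[:keep]
        sparse_w[i, order] = w[i, order]
    norms = np.linalg.norm(sparse_w, axis=1)
    if np.any(norms == 0):
        bad = np.nonzero(norms == 0)[0]
        raise ValueError(f"rows with no surviving entries: {bad.tolist()}")
    cos = (sparse_w @ sparse_w.T) / np.outer(norms, norms)
    cos = np.clip(cos, 0.0, 1.0)
    return (cos + cos.T) / 2.0


def diffusion_map(
    aff: np.ndarray, k: int = 2, alpha: float = 0.5
) -> GradientSet:
    """Anisotropic diffusion-map embedding of an affinity matrix.

    The affinity is alpha-normalized (W / (q_i q_j)^alpha with q the row
    sums), turned into a random-walk operator, and eigendecomposed through
    its symmetric conjugate.  Components are ordered by eigenvalue; at
    diffusion time zero coordinates are scaled by lambda / (1 - lambda).
    Sign is fixed by making the first region's coordinate nonnegative.
    """
    W = np.asarray(aff, dtype=float)
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    if np.max(np.abs(W - W.T)) > 1e-10:
        raise ValueError("affinity must be symmetric")
    q = W.sum(axis=1)
    if np.any(q == 0):
        raise ValueError("affinity has an all-zero row")
    Wa = W / np.outer(q, q) ** alpha
    d = Wa.sum(axis=1)
    dis = 1.0 / np.sqrt(d)
    M = dis[:, None] * Wa * dis[None, :]  # symmetric conjugate of D^-1 Wa
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] < -1e-10:
        raise ValueError("diffusion operator is not positive semidefinite")
    # drop the trivial stationary component (lambda ~ 1, constant map)
    lam = evals[1:]
    psi = dis[:, None] * evecs[:, 1:]  # right eigenvectors of the walk operator
    pos = lam > 1e-12
    if pos.sum() < k:
        raise ValueError(f"only {int(pos.sum())} informative components available")
    lam_pos = lam[pos]
    psi = psi[:, pos]
    scale = lam_pos / (1.0 - np.minimum(lam_pos, 1 - 1e-12))
    coords = psi[:, :k] * scale[:k]
    # deterministic sign convention
    for c in range(k):
        if coords[0, c] < 0:
            coords[:, c] = -coords[:, c]
    vf = lam_pos / lam_pos.sum()
    return GradientSet(
        coordinates=coords,
        eigenvalues=lam_pos[:k],
        variance_fraction=vf[:k],
    )


def procrustes_align(src: GradientSet, ref: GradientSet) -> GradientSet:
    """Orthogonally align ``src`` coordinates to ``ref`` (no scaling).

    The transform minimizing the Frobenius distance to the reference over
    rotations and reflections is applied to the source coordinates.
    """
    if src.n != ref.n or src.k != ref.k:
        raise ValueError("gradient sets must share shape for alignment")
    if np.linalg.norm(src.coordinates) == 0 or np.linalg.norm(ref.coordinates) == 0:
        raise ValueError("degenerate zero-norm coordinates cannot be aligned")
    R, _ = orthogonal_procrustes(src.coordinates, ref.coordinates)
    return GradientSet(
        coordinates=src.coordinates @ R,
        eigenvalues=src.eigenvalues,
        variance_fraction=src.variance_fraction,
        reference_id="procrustes",
    )


def gradient_shift(
    g_full: GradientSet, g_rfn: GradientSet, component: int = 0
) -> float:
    """Gradient shift delta = 1 - |Pearson R| of one aligned component."""
    if g_full.n != g_rfn.n:
        raise ValueError("gradient sets must share region count")
    a = g_full.coordinates[:, component]
    b = g_rfn.coordinates[:, component]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance gradient component; shift undefined")
    r = pearsonr(a, b).statistic
    return float(1.0 - abs(r))


def variance_explained_compare(sets: dict[str, GradientSet]) -> pd.DataFrame:
    """Side-by-side variance fractions per gradient for several networks."""
    if len(sets) < 2:
        raise ValueError("need at least two gradient sets to compare")
    rows = []
    for name, gs in sets.items():
        for c in range(gs.k):
            rows.append(
                {
                    "network": name,
                    "gradient": c + 1,
                    "variance_fraction": gs.variance_fraction[c],
                }
            )
    return pd.DataFrame(rows)
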