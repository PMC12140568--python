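"""Seeded generator of coupled multimodal synthetic connectomes.

The generator emulates the statistical structure the analysis assumes of
real multimodal data, with recorded ground truth:

* a bilateral ~200-region parcellation with mirrored centroids and
  log-normal region volumes;
* a sparse, distance-dependent structural connectome (Poisson streamline
  counts with an exponential distance decay, volume-normalized);
* spatially autocorrelated molecular profiles (gene expression, receptor
  density) whose similarity networks therefore decay with distance;
* functional connectivity sampled as the Pearson correlation of
  multivariate-normal "time series" whose latent covariance is a known
  mixture of the biophysical networks plus planted community blocks;
* two-group clinical studies with an edgewise effect planted on a chosen
  biophysical edge set.

Everything is reproducible from ``(parameters, seed)``; the truth record
carries the mixing weights, the dominant factor tag, the community labels
and the distance-decay scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biophysical import dc_from_centroids, sc_from_streamlines, similarity_network
from .biophysical import StreamlineCounts
from .clinical import GroupStudy
from .network import WeightedNetwork
from .parcellation import Parcellation

__all__ = [
    "SyntheticSuite",
    "make_parcellation",
    "make_biophysical_suite",
    "make_fc",
    "make_clinical",
    "make_suite",
]

@dataclass(frozen=True)
class SyntheticSuite:
    """Parcellation + coupled biophysical networks + FC + ground truth."""

    parcels: Parcellation
    sc: WeightedNetwork
    dc: WeightedNetwork
    gc: WeightedNetwork
    rc: WeightedNetwork
    fc: WeightedNetwork
    truth: dict = field(default_factory=dict)

    def biophysical(self) -> dict[str, WeightedNetwork]:
        return {"SC": self.sc, "DC": self.dc, "GC": self.gc, "RC": self.rc}


def make_parcellation(n: int = 200, seed: int = 0) -> Parcellation:
    """Bilateral parcellation: half-ellipsoid right hemisphere, mirrored left.

    Centroids are sampled uniformly inside a brain-scale half-ellipsoid
    (semi-axes 65 x 85 x 60 mm, x > 2 mm), mirrored through the
    mid-sagittal plane for the left hemisphere; volumes are log-normal
    around ~5 cm^3, the scale of a 200-region cortical parcellation.
    """
    if n < 4:
        raise ValueError("need at least four regions")
    if n % 2:
        raise ValueError("region count must be even (bilateral parcellation)")
    rng = np.random.default_rng(seed)
    half = n // 2
    axes = np.array([65.0, 85.0, 60.0])
    pts = []
    while len(pts) < half:
        cand = rng.uniform(-1, 1, size=3)
        if cand @ cand <= 1.0 and cand[0] * axes[0] > 2.0:
            pts.append(cand * axes)
    right = np.asarray(pts)
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    vols = rng.lognormal(mean=np.log(5000.0), sigma=0.4, size=half)
    return Parcellation(
        region_id=tuple(
            [f"L{i:03d}" for i in range(half)] + [f"R{i:03d}" for i in range(half)]
        ),
        hemisphere=tuple(["L"] * half + ["R"] * half),
        centroid=centroids,
        volume=np.concatenate([vols, vols]),  # homotopic pairs share volume
    )


def _spatial_profiles(D, n_features, length_scale, rng):
    """Gaussian feature profiles with inter-regional covariance exp(-D/ls)."""
    K = np.exp(-D / length_scale)
    # jitter keeps the Cholesky factor well conditioned
    L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
    return L @ rng.standard_normal((K.shape[0], n_features))


def make_biophysical_suite(
    parcels: Parcellation,
    decay_mm: float = 35.0,
    profile_dims: int = 60,
    spatial_rho: float = 1.0,
    sc_density: float = 0.1607,
    seed: int = 0,
) -> dict[str, WeightedNetwork]:
    """Coupled SC / DC / GC / RC networks with known distance dependence.

    SC streamline counts are Poisson with rate proportional to
    exp(-D / decay_mm) (so long-range structural connections are rare),
    volume-normalized and sparse at roughly ``sc_density``.  GC and RC come
    from independent spatially autocorrelated profile matrices with
    correlation length ``spatial_rho * decay_mm``; at ``spatial_rho = 0``
    the profiles are spatially white and similarity is distance-free.
    """
    if decay_mm <= 0:
        raise ValueError("decay_mm must be positive")
    rng = np.random.default_rng(seed)
    D = parcels.distance_matrix()
    n = parcels.n_regions

    # sparse distance-dependent streamline counts; rate tuned so that the
    # nonzero density comfortably exceeds the target before thresholding
    rate = 40.0 * np.exp(-D / decay_mm)
    counts = rng.poisson(rate)
    counts = np.triu(counts, 1)
    counts = counts + counts.T
    sc = sc_from_streamlines(StreamlineCounts(counts.astype(float)), parcels)
    sc = _threshold_connected(sc, sc_density)

    dc = dc_from_centroids(parcels)

    if spatial_rho > 0:
        ls = spatial_rho * decay_mm
        gc_prof = _spatial_profiles(D, profile_dims, ls, rng)
        rc_prof = _spatial_profiles(D, profile_dims, ls, rng)
    else:
        gc_prof = rng.standard_normal((n, profile_dims))
        rc_prof = rng.standard_normal((n, profile_dims))
    gc = similarity_network(gc_prof, kind="GC", region_id=parcels.region_id)
    rc = similarity_network(rc_prof, kind="RC", region_id=parcels.region_id)
    return {"SC": sc, "DC": dc, "GC": gc, "RC": rc}


def _threshold_connected(net: WeightedNetwork, d: float) -> WeightedNetwork:
    """Keep the strongest edges at density ``d`` while staying connected.

    A maximum-spanning-tree backbone of the weighted graph is always
    retained; the remaining budget goes to the strongest edges.  Keeps a
    structural connectome realistic — sparse but without isolated regions.
    """
    from scipy import sparse
    from scipy.sparse.csgraph import minimum_spanning_tree

    from .network import n_pairs, round_half_away

    n = net.n
    m = round_half_away(d * n_pairs(n))
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    mst = minimum_spanning_tree(sparse.csr_matrix(lengths)).toarray()
    sel = (mst > 0) | (mst.T > 0)
    i, j = np.triu_indices(n, k=1)
    order = np.argsort(-w[i, j], kind="stable")
    count = int(np.count_nonzero(np.triu(sel, 1)))
    for idx in order:
        if count >= m:
            break
        a, b = i[idx], j[idx]
        if w[a, b] > 0 and not sel[a, b]:
            sel[a, b] = sel[b, a] = True
            count += 1
    out = np.where(sel, w, 0.0)
    return net.with_weights(out)


def _rescale01(w: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(w.shape[0], k=1)
    vals = w[iu]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(w)
    if hi > lo:
        out[iu] = (vals - lo) / (hi - lo)
    out = out + out.T
    return out


def _nearest_correlation(S: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and renormalize to a valid correlation matrix."""
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, eig_floor)
    S = (vecs * vals) @ vecs.T
    dinv = 1.0 / np.sqrt(np.diag(S))
    S = dinv[:, None] * S * dinv[None, :]
    np.fill_diagonal(S, 1.0)
    return S


def _latent_covariance(
    suite: dict[str, WeightedNetwork],
    mix: dict[str, float],
    community_labels: np.ndarray,
    community_weight: float,
    noise: float,
) -> np.ndarray:
    n = next(iter(suite.values())).n
    S = np.zeros((n, n))
    for tag, w in mix.items():
        if w:
            S += w * _rescale01(np.abs(suite[tag].weights))
    if community_weight:
        same = community_labels[:, None] == community_labels[None, :]
        block = same.astype(float)
        np.fill_diagonal(block, 0.0)
        S += community_weight * block
    # scale the off-diagonal mixture into correlation range, add unit diag
    off_max = np.abs(S).max()
    if off_max > 0:
        S = 0.7 * S / off_max
    S += noise * np.eye(n)
    np.fill_diagonal(S, 1.0)
    return _nearest_correlation(S)


def make_fc(
    parcels: Parcellation,
    suite: dict[str, WeightedNetwork],
    mix: dict[str, float],
    community_weight: float = 0.15,
    n_communities: int = 4,
    T_timepoints: int = 400,
    seed: int = 0,
    signed: bool = False,
) -> tuple[WeightedNetwork, dict]:
    """FC as the sample correlation of draws from a planted covariance.

    The latent covariance is a nonnegative mixture of the (rescaled)
    biophysical networks plus a community block term and white noise,
    projected to the nearest valid correlation matrix; ``T_timepoints``
    i.i.d. multivariate-normal draws are correlated to produce FC.  The
    default output stores correlation magnitudes (the main-analysis FC
    convention); ``signed`` keeps the raw correlations.
    """
    if any(v < 0 for v in mix.values()):
        raise ValueError("mixing weights must be nonnegative")
    rng = np.random.default_rng(seed)
    n = parcels.n_regions
    labels = rng.integers(n_communities, size=n)
    S = _latent_covariance(suite, mix, labels, community_weight, noise=0.5)
    L = np.linalg.cholesky(S)
    ts = (L @ rng.standard_normal((n, T_timepoints))).T
    fc = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(fc, 0.0)
    net = WeightedNetwork(fc, kind="FC", signed=True)
    if not signed:
        net = net.with_weights(np.abs(fc), signed=False)
    truth = {
        "mix": dict(mix),
        "dominant": max(mix, key=mix.get) if mix and max(mix.values()) > 0 else None,
        "community_labels": labels,
        "community_weight": community_weight,
        "T": T_timepoints,
        "seed": seed,
    }
    return net, truth


def make_suite(
    n: int = 200,
    mix: dict[str, float] | None = None,
    decay_mm: float = 35.0,
    spatial_rho: float = 1.0,
    T_timepoints: int = 400,
    seed: int = 0,
) -> SyntheticSuite:
    """One-call generator: parcellation, biophysical networks, FC, truth."""
    if mix is None:
        mix = {"SC": 0.3, "DC": 0.3, "GC": 0.3, "RC": 0.3}
    parcels = make_parcellation(n=n, seed=seed)
    bio = make_biophysical_suite(
        parcels, decay_mm=decay_mm, spatial_rho=spatial_rho, seed=seed + 1
    )
    fc, truth = make_fc(
        parcels, bio, mix, T_timepoints=T_timepoints, seed=seed + 2
    )
    truth["decay_mm"] = decay_mm
    truth["spatial_rho"] = spatial_rho
    truth["master_seed"] = seed
    return SyntheticSuite(
        parcels=parcels,
        sc=bio["SC"],
        dc=bio["DC"],
        gc=bio["GC"],
        rc=bio["RC"],
        fc=fc,
        truth=truth,
    )


def make_clinical(
    suite: SyntheticSuite,
    base_mix: dict[str, float],
    effect_edges: np.ndarray,
    effect_size: float,
    n_a: int = 20,
    n_b: int = 20,
    T_timepoints: int = 200,
    seed: int = 0,
) -> GroupStudy:
    """Two-group study with a covariance effect planted on an edge set.

    Group A subjects are drawn from the base generative covariance; group
    B subjects from the same covariance with ``effect_size`` added to the
    entries of ``effect_edges`` (re-projected to a valid correlation
    matrix).  Each subject's FC is the correlation of its own
    ``T_timepoints`` draws, stored as magnitudes.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least two subjects")
    rng = np.random.default_rng(seed)
    n = suite.parcels.n_regions
    labels = suite.truth["community_labels"]
    cw = suite.truth.get("community_weight", 0.15)
    S_a = _latent_covariance(suite.biophysical(), base_mix, labels, cw, noise=0.5)
    S_b = S_a.copy()
    eff = np.asarray(effect_edges, dtype=bool)
    S_b[eff] += effect_size
    S_b = _nearest_correlation(S_b)
    La, Lb = np.linalg.cholesky(S_a), np.linalg.cholesky(S_b)

    def draw_subject(L):
        ts = (L @ rng.standard_normal((n, T_timepoints))).T
        fc = np.corrcoef(ts, rowvar=False)
        np.fill_diagonal(fc, 0.0)
        return WeightedNetwork(np.abs(fc), kind="FC", signed=False)

    group_a = tuple(draw_subject(La) for _ in range(n_a))
    group_b = tuple(draw_subject(Lb) for _ in range(n_b))
    return GroupStudy(group_a=group_a, group_b=group_b)
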