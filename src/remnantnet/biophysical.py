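"""Construction of the four biophysical reference networks.

* SC — structural connectivity: streamline counts normalized by the summed
  volumes of the two regions, ``A_ij = T_ij / (v_i + v_j)``.
* DC — Euclidean proximity: ``DC = D_max - D`` so that strong weights mean
  spatially close regions and density-matched thresholding retains the
  shortest connections.
* GC — gene-expression ("genetic") similarity: regional transcriptomic
  profiles built from microarray samples (probe background filtering,
  differential-stability probe selection, robust-sigmoid normalization,
  sample-to-region assignment with bilateral mirroring), correlated between
  regions.
* RC — neuroreceptor congruence: Pearson correlation between z-scored
  regional receptor-density profiles.

GCd / RCd are the distance-corrected variants: the distance-predictable
part of the similarity is regressed out and the residuals form the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .network import WeightedNetwork
from .parcellation import Parcellation

__all__ = [
    "StreamlineCounts",
    "ExpressionBundle",
    "ReceptorMaps",
    "sc_from_streamlines",
    "dc_from_centroids",
    "similarity_network",
    "zscore_receptors",
    "filter_probes_by_intensity",
    "differential_stability",
    "select_probes",
    "robust_sigmoid_rescale",
    "normalize_expression",
    "assign_samples_to_regions",
    "region_gene_matrix",
    "distance_correct",
    "build_gc",
]

# normal-consistent IQR scaling: IQR of a standard normal is ~1.349 sigma
_IQR_NORM = 2.0 * stats.norm.ppf(0.75)


@dataclass(frozen=True)
class StreamlineCounts:
    """Symmetric nonnegative region-pair streamline counts."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("counts diagonal must be zero")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c)


@dataclass(frozen=True)
class ExpressionBundle:
    """Microarray expression data: donors, samples, probes.

    ``intensities`` is probe x sample; ``above_background`` flags, per probe
    and sample, whether the measured intensity exceeded background noise.
    """

    donors: tuple
    sample_donor: np.ndarray  # (m,) donor id per sample
    sample_xyz: np.ndarray  # (m, 3) mm coordinates
    intensities: np.ndarray  # (p, m)
    probe_gene: tuple  # (p,) gene symbol per probe
    above_background: np.ndarray  # (p, m) bool

    def __post_init__(self):
        m = len(self.sample_donor)
        p = len(self.probe_gene)
        xyz = np.asarray(self.sample_xyz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        ab = np.asarray(self.above_background, dtype=bool)
        if xyz.shape != (m, 3):
            raise ValueError("sample coordinates must be (m, 3)")
        if inten.shape != (p, m) or ab.shape != (p, m):
            raise ValueError("intensity/background shapes must be (probes, samples)")
        if not set(self.sample_donor) <= set(self.donors):
            raise ValueError("every sample must belong to a listed donor")
        object.__setattr__(self, "sample_xyz", xyz)
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "above_background", ab)
        object.__setattr__(self, "sample_donor", np.asarray(self.sample_donor))

    @property
    def n_probes(self) -> int:
        return len(self.probe_gene)

    @property
    def n_samples(self) -> int:
        return len(self.sample_donor)


@dataclass(frozen=True)
class ReceptorMaps:
    """Region x receptor density table."""

    densities: pd.DataFrame

    def __post_init__(self):
        df = pd.DataFrame(self.densities).astype(float)
        if df.shape[1] < 2:
            raise ValueError("need at least two receptors for profile correlation")
        if not np.all(np.isfinite(df.to_numpy())):
            raise ValueError("receptor densities must be finite")
        object.__setattr__(self, "densities", df)


def sc_from_streamlines(
    counts: StreamlineCounts, parcels: Parcellation
) -> WeightedNetwork:
    """Volume-normalized structural connectivity, A_ij = T_ij / (v_i + v_j)."""
    T = counts.counts
    if T.shape[0] != parcels.n_regions:
        raise ValueError("streamline counts do not match the parcellation")
    v = parcels.volume
    if np.any(v <= 0):
        raise ValueError("region volumes must be positive")
    A = T / (v[:, None] + v[None, :])
    np.fill_diagonal(A, 0.0)
    return WeightedNetwork(A, kind="SC", signed=False)


def dc_from_centroids(parcels: Parcellation) -> WeightedNetwork:
    """Euclidean proximity network DC = D_max - D.

    ``D_max`` is the largest off-diagonal inter-centroid distance, so the
    farthest region pair gets weight zero and close pairs get large weights.
    The diagonal (which the transform would send to ``D_max``) is forced to
    zero: self-connections are never analyzed.
    """
    D = parcels.distance_matrix()
    off = D[np.triu_indices(parcels.n_regions, k=1)]
    if np.any(off == 0):
        warnings.warn(
            "duplicate centroids: zero distance becomes maximal proximity",
            stacklevel=2,
        )
    dmax = off.max()
    if dmax == 0:
        raise ValueError("all centroids coincide; proximity undefined")
    DC = dmax - D
    np.fill_diagonal(DC, 0.0)
    return WeightedNetwork(DC, kind="DC", signed=False)


def similarity_network(
    profiles: np.ndarray, kind: str, region_id=None
) -> WeightedNetwork:
    """Inter-regional Pearson correlation of row profiles (GC / RC style)."""
    X = np.asarray(profiles, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least three features per region")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.argmax(sd == 0))
        label = region_id[bad] if region_id is not None else bad
        raise ValueError(f"region {label!r} has a constant profile")
    R = np.corrcoef(X)
    np.fill_diagonal(R, 0.0)
    return WeightedNetwork(R, kind=kind, signed=True)


def zscore_receptors(maps: ReceptorMaps) -> ReceptorMaps:
    """Standardize each receptor map to zero mean, unit SD across regions."""
    df = maps.densities
    sd = df.std(axis=0, ddof=0)
    if np.any(sd.to_numpy() == 0):
        bad = sd.index[sd.to_numpy() == 0].tolist()
        raise ValueError(f"receptor column(s) with zero variance: {bad}")
    return ReceptorMaps((df - df.mean(axis=0)) / sd)


def filter_probes_by_intensity(
    bundle: ExpressionBundle, frac: float = 0.5
) -> ExpressionBundle:
    """Discard probes below background in at least ``frac`` of all samples."""
    below = 1.0 - bundle.above_background.mean(axis=1)
    keep = below < frac
    if not np.any(keep):
        raise ValueError("intensity filtering discarded every probe")
    return replace(
        bundle,
        intensities=bundle.intensities[keep],
        probe_gene=tuple(np.asarray(bundle.probe_gene)[keep]),
        above_background=bundle.above_background[keep],
    )


def differential_stability(
    bundle: ExpressionBundle, region_of_sample: np.ndarray
) -> pd.Series:
    """Differential stability Delta_sp per probe.

    For each probe, regional expression profiles are built per donor
    (samples averaged within region) and Delta_sp is the mean Spearman rank
    correlation between the profiles of every donor pair, over the regions
    both donors cover.  Pairs sharing fewer than three regions are skipped;
    a probe with no valid pair is scored NaN.
    """
    region_of_sample = np.asarray(region_of_sample)
    donors = list(bundle.donors)
    if len(donors) < 2:
        raise ValueError("differential stability needs at least two donors")
    assigned = region_of_sample >= 0
    regions = np.unique(region_of_sample[assigned])
    # per-donor region x probe mean expression
    per_donor = {}
    for d in donors:
        rows = []
        idx = []
        sel_d = (bundle.sample_donor == d) & assigned
        for r in regions:
            sel = sel_d & (region_of_sample == r)
            if np.any(sel):
                rows.append(bundle.intensities[:, sel].mean(axis=1))
                idx.append(r)
        per_donor[d] = (np.asarray(idx), np.asarray(rows))  # (k,), (k, p)
    scores = np.full(bundle.n_probes, np.nan)
    pair_rhos = [[] for _ in range(bundle.n_probes)]
    for a in range(len(donors)):
        for b in range(a + 1, len(donors)):
            ia, xa = per_donor[donors[a]]
            ib, xb = per_donor[donors[b]]
            common, ca, cb = np.intersect1d(ia, ib, return_indices=True)
            if len(common) < 3:
                warnings.warn(
                    f"donor pair ({donors[a]}, {donors[b]}) shares "
                    f"{len(common)} regions; pair skipped",
                    stacklevel=2,
                )
                continue
            pa, pb = xa[ca], xb[cb]  # (k, p)
            for p in range(bundle.n_probes):
                rho = stats.spearmanr(pa[:, p], pb[:, p]).statistic
                pair_rhos[p].append(rho)
    for p in range(bundle.n_probes):
        if pair_rhos[p]:
            scores[p] = float(np.mean(pair_rhos[p]))
    return pd.Series(scores, index=list(bundle.probe_gene), name="delta_sp")


def select_probes(bundle: ExpressionBundle, ds: pd.Series) -> ExpressionBundle:
    """Keep, per gene, the probe with the highest differential stability."""
    genes = np.asarray(bundle.probe_gene)
    keep = np.zeros(bundle.n_probes, dtype=bool)
    vals = ds.to_numpy()
    for g in pd.unique(genes):
        idx = np.nonzero(genes == g)[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best = idx[np.nanargmax(vals[idx])] if np.any(
                np.isfinite(vals[idx])
            ) else idx[0]
        keep[best] = True
    return replace(
        bundle,
        intensities=bundle.intensities[keep],
        probe_gene=tuple(genes[keep]),
        above_background=bundle.above_background[keep],
    )


def robust_sigmoid_rescale(values: np.ndarray) -> np.ndarray:
    """Robust sigmoid normalization followed by min-max rescaling to [0, 1].

    ``x_norm = 1 / (1 + exp(-(x - median) / IQR_z))`` with ``IQR_z`` the
    normal-consistent interquartile range (IQR / 1.349), then min-max
    rescaled.  Strictly monotone, so orderings survive.
    """
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct values")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr_z = (q75 - q25) / _IQR_NORM
    if iqr_z == 0:
        raise ValueError("zero interquartile range; robust sigmoid undefined")
    xn = 1.0 / (1.0 + np.exp(-(x - med) / iqr_z))
    return (xn - xn.min()) / (xn.max() - xn.min())


def normalize_expression(matrix: np.ndarray) -> np.ndarray:
    """Two-pass robust-sigmoid normalization of a gene x sample matrix.

    First across genes within each sample (column), then across samples
    within each gene (row).
    """
    X = np.asarray(matrix, dtype=float).copy()
    for j in range(X.shape[1]):
        X[:, j] = robust_sigmoid_rescale(X[:, j])
    for i in range(X.shape[0]):
        X[i, :] = robust_sigmoid_rescale(X[i, :])
    return X


def assign_samples_to_regions(
    bundle: ExpressionBundle,
    parcels: Parcellation,
    radius_mm: float = 2.0,
    mirror: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign tissue samples to regions by nearest centroid within a radius.

    Returns ``(region_of_sample, sample_index)`` where mirrored copies of
    the samples (x -> -x) are appended after the originals when ``mirror``
    is on; ``sample_index`` maps each (possibly mirrored) row back to its
    source sample.  Samples farther than ``radius_mm`` from every centroid
    get region ``-1``.
    """
    xyz = bundle.sample_xyz
    if mirror:
        mirrored = xyz * np.array([-1.0, 1.0, 1.0])
        xyz = np.vstack([xyz, mirrored])
        sample_index = np.concatenate(
            [np.arange(bundle.n_samples), np.arange(bundle.n_samples)]
        )
    else:
        sample_index = np.arange(bundle.n_samples)
    dist = cdist(xyz, parcels.centroid)
    nearest = dist.argmin(axis=1)
    within = dist[np.arange(len(xyz)), nearest] <= radius_mm
    region = np.where(within, nearest, -1)
    if not np.any(region >= 0):
        raise ValueError("no sample lies within the radius of any region")
    return region, sample_index


def region_gene_matrix(
    bundle: ExpressionBundle,
    region_of_sample: np.ndarray,
    sample_index: np.ndarray,
    n_regions: int,
) -> np.ndarray:
    """Region x gene expression, averaged within donor then across donors."""
    donors = list(bundle.donors)
    donor_of_row = bundle.sample_donor[sample_index]
    out = np.full((n_regions, bundle.n_probes), np.nan)
    for r in range(n_regions):
        per_donor = []
        for d in donors:
            sel = (region_of_sample == r) & (donor_of_row == d)
            if np.any(sel):
                cols = sample_index[sel]
                per_donor.append(bundle.intensities[:, cols].mean(axis=1))
        if per_donor:
            out[r] = np.mean(per_donor, axis=0)
    return out


def build_gc(
    bundle: ExpressionBundle,
    parcels: Parcellation,
    radius_mm: float = 2.0,
    mirror: bool = True,
    background_frac: float = 0.5,
) -> WeightedNetwork:
    """Full gene-expression similarity pipeline, raw bundle to GC network.

    Steps: background-intensity probe filtering; sample-to-region
    assignment (bilateral mirroring by default); differential-stability
    probe selection (one probe per gene); robust-sigmoid normalization
    across genes per sample then across samples per gene; within-donor and
    cross-donor regional averaging; inter-regional Pearson correlation.
    Regions with no assigned sample propagate NaN and raise here, since a
    similarity entry would be undefined.
    """
    bundle = filter_probes_by_intensity(bundle, background_frac)
    region, sample_index = assign_samples_to_regions(
        bundle, parcels, radius_mm=radius_mm, mirror=mirror
    )
    ds = differential_stability(
        bundle, _region_per_source(region, sample_index, bundle.n_samples)
    )
    bundle = select_probes(bundle, ds)
    norm = replace(bundle, intensities=normalize_expression(bundle.intensities))
    expr = region_gene_matrix(norm, region, sample_index, parcels.n_regions)
    if np.any(~np.isfinite(expr)):
        bad = np.nonzero(~np.isfinite(expr).all(axis=1))[0]
        raise ValueError(f"regions without any assigned sample: {bad.tolist()}")
    return similarity_network(expr, kind="GC", region_id=parcels.region_id)


def _region_per_source(region, sample_index, n_samples):
    """Collapse mirrored assignment rows to one region label per source sample.

    Differential stability works on donor regional profiles; a mirrored
    sample contributes at its reflected region too, so we keep whichever
    assignment(s) landed inside a parcel, preferring the unmirrored one.
    """
    out = np.full(n_samples, -1)
    for row, src in enumerate(sample_index):
        if region[row] >= 0 and out[src] < 0:
            out[src] = region[row]
    return out


def distance_correct(
    net: WeightedNetwork, parcels: Parcellation
) -> WeightedNetwork:
    """Regress Euclidean distance out of a similarity network (GC/RC -> GCd/RCd).

    Ordinary least squares of the upper-triangle edge weights on the
    inter-centroid distance; the residuals, symmetrized with a zero
    diagonal, form the distance-corrected network.
    """
    if net.kind not in {"GC", "RC"}:
        raise ValueError("distance correction applies to GC or RC networks")
    D = parcels.distance_matrix()
    iu = np.triu_indices(net.n, k=1)
    d, w = D[iu], net.weights[iu]
    if np.std(d) == 0:
        raise ValueError("zero distance variance; regression undefined")
    slope, intercept = np.polyfit(d, w, 1)
    resid = w - (slope * d + intercept)
    R = np.zeros_like(net.weights)
    R[iu] = resid
    R = R + R.T
    return WeightedNetwork(R, kind=net.kind + "d", signed=True)
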