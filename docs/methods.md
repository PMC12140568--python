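# Methods

This note documents the models, conventions and numerical choices behind
`remnantnet`, the way a maintainer (or reviewer) would want them stated.

## The removal model

The analysis treats a biophysical network as a hypothesis about which
functional connections it supports. The test is destructive: threshold
the biophysical network to its strongest `d` fraction of region pairs,
zero those pairs in the functional connectivity (FC) matrix, and measure
how features of the network change. The matched density `d` is taken from
the structural connectome — the sparsest modality — so that every source
removes the same number of edges; when no sparse SC is supplied the
default is `d = 0.1607`. With a fully connected FC, the remnant network
(RFN) has density exactly `1 − d` up to the integer edge count
(`round(d · n(n−1)/2)` pairs, rounding half away from zero so edge counts
are bit-reproducible).

Feature shifts are percent changes `Δ = 100 (P_RFN − P_Full) / P_Full`.
Regional metrics (weighted degree, clustering, eigenvector centrality)
are averaged across regions before the shift for network-level reports
and shifted per region for regional maps; the mean-|Δ| marginals over
sources and over metrics are both exposed, since an "average |Δ|" is
ambiguous between the two.

### Conventions

* **FC sign handling.** The main convention is correlation magnitude
  (|r|); a zero-clipped variant (negatives set to 0) is a constructor
  switch. All graph metrics operate on nonnegative weights.
* **Group FC** is the plain arithmetic mean of subject matrices. A
  Fisher-z option exists but is off by default.
* **Thresholding ties** break by (i, j) lexicographic order. Weights in
  practice are continuous, so ties are measure-zero; determinism matters
  only for testing.
* **DC stores proximity** (`D_max − D`, `D_max` the largest off-diagonal
  distance), so "strongest" uniformly means "most supported" across
  sources and thresholding DC retains the shortest connections. The DC
  diagonal, which the transform would send to `D_max`, is forced to zero
  because self-connections are never analyzed.

## Biophysical network construction

* **SC**: `A_ij = T_ij / (v_i + v_j)` — streamline counts normalized by
  the summed region volumes. Normalization precedes any thresholding.
* **GC**: probes below background intensity in ≥ 50% of samples are
  discarded; one probe per gene is kept by maximal differential
  stability `Δsp` (mean pairwise Spearman correlation of the probe's
  regional profile across donors; donor pairs sharing fewer than three
  regions are skipped and the mean runs over the valid pairs);
  expression is normalized with a robust sigmoid
  `1/(1+exp(−(x−median)/IQR_z))` (with `IQR_z` the normal-consistent
  IQR / 1.349) followed by min-max rescaling, first across genes within
  each sample and then across samples within each gene; samples are
  assigned to the nearest region centroid within 2 mm (a centroid-based
  stand-in for voxelwise parcel membership — parcel surfaces are out of
  scope; the radius is configurable) with bilateral mirroring
  (x → −x, assuming a symmetric coordinate frame); values are averaged
  within donor, then across donors; regions are correlated (Pearson).
  Mirroring can inflate homotopic similarity; no correction is applied.
* **RC**: receptor maps are z-scored per receptor across regions and
  regional profiles correlated.
* **GCd / RCd**: ordinary least squares of upper-triangle similarity on
  Euclidean inter-centroid distance; the residual network is the
  distance-corrected variant. Linear OLS is the default reading of
  "regressing out distance"; an exponential-decay fit could be swapped in
  where distance dependence is strongly nonlinear.

## Graph metrics

All seven features follow the standard weighted definitions; two require
committed choices:

* **Clustering** scales weights by the network maximum before the
  cube-root triangle product (the Brain Connectivity Toolbox convention);
  `CC_i = 0` for nodes with fewer than two neighbors.
* **Modularity** is Newman–Girvan `Q` with the `1/2m` normalization and
  null `P_ij = k_i k_j / 2m` at resolution γ = 1, optimized by seeded
  Louvain. Point estimates use 20–100 restarts; null-distribution
  evaluations default to 3 restarts each, since a thousand full
  optimizations per source would dominate runtime while the null only
  needs the distribution of shifts, not each draw's exact optimum.
* **Path length** uses inverse weights as lengths and excludes
  unreachable ordered pairs with a warning (RFNs retain ~84% of edges, so
  disconnection signals pathological input rather than an expected
  regime). Eigen-computations use dense symmetric solvers.
* **Eigenvector centrality** on a disconnected network is computed on the
  largest component (other regions get zero) with a warning;
  synchronizability raises instead, since λ₂ = 0 makes the eigenratio
  meaningless.

## Gradients

Connectivity profiles are sparsified row-wise (top 10% of each row kept;
a global threshold is available but the row-wise form matches the
gradient-toolbox convention), compared by cosine similarity with
negatives clamped to zero so the result is a valid affinity, and embedded
by an anisotropic diffusion map (α = 0.5, diffusion time 0, i.e.
eigenvectors scaled by λ/(1−λ); component sign fixed by making region 0's
coordinate nonnegative). The number of components retained is 2 by
default. RFN gradients are aligned to the full-FC gradients by orthogonal
Procrustes (rotations and reflections, no scaling) and the shift is
`δ = 1 − |R|` per component, which is invariant to sign flips and joint
orthogonal re-alignment.

## Null models and significance

Three nulls: (1) uniformly random removal of the same number of nonzero
FC edges; (2) Maslov–Sneppen double-edge swaps of the binarized
biophysical edge set (degrees preserved exactly — asserted on every
call); (3) random removal stratified to match the edge set's intra-left /
intra-right / inter-hemispheric counts exactly. The default iteration
count is 1000; the test suite and acceptance script use 200 (and the KS
calibration check 99) to keep runtimes in seconds at the scaled-down
problem sizes below. Significance is the add-one permutation p-value
`(1 + #{|null| ≥ |observed|}) / (1 + iters)`, one-sided on |Δ| by default
(removal effects are reported as magnitudes); a two-sided option exists.
Random-removal nulls sample from the currently nonzero FC edges, which
coincides with "all pairs" on a fully connected FC.

## Search information

SI(i→j) is the negative log2 probability that a memoryless random walker
(step probability `w_uv / s_u`) follows a shortest path (inverse-weight
lengths) from i to j. The walker is memoryless — the incoming edge is not
excluded — which is the simpler of the two conventions in circulation and
is recorded here as the package's choice. If several shortest paths tie,
their probabilities are summed before the log (with continuous weights
this is measure-zero). The matrix is symmetrized by averaging both
directions, reversed as `SI_max − SI` (`SI_max` the largest off-diagonal
entry) so large values mean well-coupled pairs, and each region's
reversed-SI profile predicts its FC profile by simple linear regression
(R² per region, summarized as mean ± sd). Signed similarity networks are
clamped at zero before SI since negative weights carry no meaning for the
walker.

## Clinical contrasts

Edgewise two-sample t (pooled-variance Student by default, Welch
optional; positive t = stronger in the clinical group) gives a t-value
network; removing a biophysical edge set from it yields
`Δ = 100 (⟨RFN_tval⟩ − ⟨Tval⟩)/⟨Tval⟩`, where the full average runs over
all off-diagonal pairs and the RFN average over the remaining nonzero
entries. A near-zero full-matrix mean makes Δ explode, so a denominator
floor (|mean t| ≥ 1e−3) raises instead of returning a meaningless number.
No multiple-comparison correction is applied at the edge level — the
statistic of interest is the average t, not thresholded discoveries.

## Synthetic data

The generator emulates the statistical structure the analysis assumes of
real multimodal data, not the physics behind it:

* **Parcellation**: n/2 centroids uniform in a half-ellipsoid
  (65 × 85 × 60 mm semi-axes, brain scale), mirrored for the left
  hemisphere; volumes log-normal around 5 cm³ (the scale of a 200-region
  cortical parcellation), shared between homotopic pairs.
* **SC**: Poisson streamline counts with rate ∝ exp(−D / 35 mm),
  volume-normalized, thresholded to 16.07% density while retaining a
  maximum-spanning-tree backbone so the connectome is sparse but never
  has isolated regions — the regime in which path length, SI and
  synchronizability are defined.
* **GC / RC**: Gaussian feature profiles (60 features) with
  inter-regional covariance exp(−D / ρ·35 mm); ρ = 1 by default, ρ = 0
  gives spatially white profiles and distance-free similarity.
* **FC**: latent covariance = nonnegative mixture of the min-max-rescaled
  biophysical networks + a 4-community random block term + white noise,
  projected to the nearest valid correlation matrix by eigenvalue
  clipping at 1e−6 and renormalization (the single place synthetic FC
  deviates from an exact linear mixture); FC is the sample Pearson
  correlation of T multivariate-normal draws. Defaults n = 200, T = 400
  mimic a desk-scale resting run; the test suite and acceptance script
  run at n = 60, T = 200.
* **Clinical studies** add the effect size to the latent covariance on a
  chosen edge set for group B and re-project; each subject correlates its
  own T draws.

What passing tests show — and what they do not: the generator produces
i.i.d. Gaussian "timepoints" (no hemodynamic autocorrelation), exact
covariance mixtures (real FC is not a linear function of biophysics),
noiseless biophysical networks, and effects planted uniformly on an edge
set. Recovery of planted factors here demonstrates that the pipeline's
attribution logic is correct, not that real FC decomposes this way.

## Known limitations

* The GC pipeline's nearest-centroid sample assignment and bilateral
  mirroring are coarser than surface-based parcel membership.
* Louvain is a heuristic; Q values are lower bounds on the optimum
  (exhaustive search verifies exactness only at n ≤ 8 in the tests).
* The memoryless-walker SI convention differs from variants that exclude
  the incoming edge; values are not comparable across conventions.
* Near-zero mean t makes the clinical Δ undefined; the floor makes this
  an explicit error rather than a silent blow-up.
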