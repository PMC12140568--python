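# remnantnet

Quantify how biophysical relationships between brain regions — structural
wiring, spatial proximity, gene-expression similarity, neuroreceptor
congruence — shape the organization of functional brain connectivity.

## The idea

Functional connectivity (FC) is the region-by-region matrix of Pearson
correlations between fMRI BOLD time series. Each biophysical factor defines
its own reference network over the same regions:

* **SC** — structural connectivity, streamline counts normalized by region
  volumes, `A_ij = T_ij / (v_i + v_j)`;
* **DC** — Euclidean proximity, `DC = D_max − D` (so strong weight = close);
* **GC** — gene-expression similarity, the inter-regional Pearson
  correlation of regional transcriptomic profiles (with probe background
  filtering, differential-stability probe selection, and robust-sigmoid
  normalization);
* **RC** — neuroreceptor congruence, the correlation of z-scored regional
  receptor-density profiles;
* **GCd / RCd** — the same similarities with the Euclidean-distance trend
  regressed out.

A **remnant functional network (RFN)** is FC with every edge removed that
coincides with one of the strongest edges of a reference network at matched
density `d` (the density of the sparse structural connectome; removing the
top 16.07% of pairs from a fully connected FC leaves an RFN of density
83.93%). The influence of a biophysical factor on an FC feature `P` is the
percent shift

```
Δ = 100 · (P_RFN − P_Full) / P_Full
```

measured for seven weighted graph features (weighted degree, clustering
coefficient, eigenvector centrality, modularity, path length, spectral
radius, synchronizability), for diffusion-map connectivity gradients
(shift `δ = 1 − |R|` between Procrustes-aligned gradient maps), and — for
clinical two-group contrasts — for the average edgewise t value. Every
shift is benchmarked against null models: random edge removal,
degree-preserving (Maslov–Sneppen) rewiring of the biophysical edge set,
and hemisphere-matched random removal. Search-information (SI) matrices
derived from each biophysical network additionally predict FC profiles
region by region.

A seeded synthetic-data generator produces coupled multimodal connectomes
(bilateral parcellation, distance-dependent sparse SC, spatially
autocorrelated molecular similarity networks, FC sampled from a known
covariance mixture, two-group studies with planted edgewise effects) so the
whole pipeline is testable with known ground truth.

## Worked example

```python
import remnantnet as rn

# a synthetic multimodal connectome whose FC is dominated by the
# receptor-congruence factor (n=60 regions, 200 "timepoints")
suite = rn.make_suite(n=60, mix={"SC": 0.1, "DC": 0.1, "GC": 0.1, "RC": 0.8},
                      T_timepoints=200, seed=7)

model = rn.RemnantNetworkModel(suite.fc, suite.biophysical(),
                               parcellation=suite.parcels)
results = model.fit(metrics=("weighted_degree", "clustering_coefficient",
                             "modularity"),
                    null="random", n_null=200, seed=7)
print(results.summary())
```

```
Remnant Functional Network analysis
================================================================
regions: 60   FC convention: magnitude
matched removal density: 0.1605 (RFN density 0.8395)
null model: random (200 iterations, seed 7)

Percent shift (delta) by metric and removed source:
source                      DC      GC      RC      SC  TOP_FC
metric
clustering_coefficient  -3.216   0.635  10.497  -1.698  56.570
modularity             -17.202 -27.250 -12.169 -13.691 -48.741
weighted_degree        -30.813 -29.075 -31.564 -28.849 -34.638

Empirical p (add-one, one-sided on |delta|):
source                     DC     GC      RC     SC  TOP_FC
metric
clustering_coefficient  1.000  1.000  0.9950  1.000     NaN
modularity              0.005  0.005  0.0846  0.010     NaN
weighted_degree         0.005  0.005  0.0050  0.005     NaN
```

Reading the table: each column is one biophysical source whose top-16%
edges were removed from FC; `TOP_FC` is the benchmark that removes the
strongest FC edges themselves. The planted dominant factor (RC) produces
the largest weighted-degree shift (−31.56%), and the removal shifts for
weighted degree are far beyond what removing the same number of random
edges does (p = 0.005 at 200 null iterations, the add-one minimum).
`results.shift_ratios()` relates each source to the `TOP_FC` benchmark,
`model.gradient_analysis()` reports the gradient shifts `δ`, and
`model.search_information_analysis()` the nodewise SI→FC R².

The same analysis graph is scriptable from the shell:

```sh
remnantnet simulate --n-regions 60 --seed 7 --out suite/
remnantnet all --seed 7 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `remnantnet.network` | `WeightedNetwork` / `EdgeMask` / `RemnantNetwork`, density, thresholding, sign conventions, group averaging, matrix I/O |
| `remnantnet.parcellation` | region metadata (hemisphere, centroid, volume) |
| `remnantnet.biophysical` | SC, DC, GC, RC construction and distance correction |
| `remnantnet.remnant` | RFN construction, combined-rank network, strongest-edge benchmark, overlap and edge-strength analyses |
| `remnantnet.metrics` | the seven weighted graph features and percent shifts |
| `remnantnet.gradients` | affinity, diffusion-map embedding, Procrustes alignment, gradient shift δ |
| `remnantnet.nulls` | random-removal, rewired and hemisphere-matched nulls; empirical p |
| `remnantnet.search_info` | search-information matrices and nodewise FC prediction |
| `remnantnet.clinical` | edgewise group contrasts and t-value RFN deltas |
| `remnantnet.synthetic` | the seeded multimodal connectome generator |
| `remnantnet.model` | the `RemnantNetworkModel` / `RFNResults` interface |
| `remnantnet.pipeline`, `remnantnet.cli` | config-driven orchestration and the `remnantnet` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
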