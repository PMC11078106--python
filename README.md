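# hotspotter

Spatial statistics of synaptic input to reconstructed neurons.

Primate retinal ganglion cells (RGCs) that co-stratify in the inner
plexiform layer draw on the same presynaptic bipolar cell types, yet can
sample them very differently. The ON smooth monostratified RGC has a
receptive field with isolated regions of high sensitivity ("hotspots"),
while the co-stratifying ON parasol RGC is spatially homogeneous. Given
skeletonized EM reconstructions (annotation disks with x,y,z in µm and
soma/dendrite/axon tags) and synapse tables (ribbon = bipolar input,
conventional = amacrine input), this package quantifies whether — and
where — bipolar input clusters:

- **Hotspot detection.** Ribbon-synapse x–y coordinates are fit with
  mixtures of K = 2..10 full-covariance Gaussians; the best K maximizes
  the Calinski–Harabasz index on hard assignments,

      CH = [Σₖ n_k‖c_k − c‖² / (K−1)] / [Σₖ Σ_{i∈k} ‖d_i − c_k‖² / (N−K)],

  with c the global centroid and n_k, c_k the size and centroid of
  cluster k. Points with Mahalanobis distance d = √((x−µ)ᵀΣ⁻¹(x−µ)) > 3
  SD from *every* component are excluded before per-cluster composition
  is computed.
- **Density maps.** Smoothed 2D histograms of synapse and dendrite
  positions (second-order Whittaker penalty, λ = 1, exactly
  mass-conserving), with bin sizes scaled to the dendritic-field
  diameter (9.7 µm synapse / 6.3 µm dendrite bins at 153 µm).
- **Morphometry.** Dendritic-field diameter as the equivalent circular
  diameter 2·√(A/π) of the dendritic convex hull; soma diameter; IPL
  stratification depth profiles (0 % at INL/IPL, 100 % at IPL/GCL).
- **Connectivity statistics.** Amacrine/bipolar proportions; the
  geometric run-length null p^N for N consecutive amacrine synapses
  along a dendrite; per-partner synapse loads; classification rates;
  Fisher's exact test; overlap of one cell's synapses with another
  cell's dendritic field.
- **Synthetic reconstructions.** A seeded generator that emulates the
  study geometry — one ~153 µm sparse radiate cell vs ~57 µm dense
  tortuous cells, a 1.6:1 amacrine:bipolar ratio, and bipolar synapses
  drawn homogeneously or from a planted K-component Gaussian intensity —
  so every stage can be verified against known ground truth.

## Worked example

```python
import numpy as np
import hotspotter as h

dataset, truth = h.generate_paired_scene(seed=7)   # 4 planted hotspots
smooth = next(c for c, r in truth["roles"].items() if r == "smooth")
ribbon = h.subset_synapses(dataset, smooth, kind="ribbon")
pts = np.array([[s.x, s.y] for s in ribbon])

model, ch_by_k = h.select_components(pts, 2, 10, n_restarts=5, seed=0)
h.flag_outliers(pts, model, threshold=3.0)
print(model.K, int(model.outlier_mask.sum()))
```

prints `4 0`: the CH index peaks at four components (CH rises from 97.5
at K=2 to 674.7 at K=4, then falls), recovering the four planted
hotspots — their fitted means land 0.8–3.0 µm from the planted centers —
and no synapse lies beyond 3 SD of all four clusters. The scripts in
`examples/` walk through each capability (simulation, morphometry,
density maps, hotspot detection, connectivity statistics, the full
pipeline) and print the numbers with a line on what they mean, e.g.

```
$ python examples/05_connectivity_stats.py
p = 1.6/2.6 = 0.6154
  P(5 consecutive amacrine synapses) = 8.8 %
  P(14 consecutive amacrine synapses) = 0.1 %
smooth cell: 126 synapses / 69 bipolar partners = 1.8 synapses per cell
parasol:     186.3 / 40.7 = 4.58 synapses per cell
```

— long amacrine runs are far less likely than observed by chance, and
the large cell samples each bipolar partner far more lightly than the
small cells do.

A thin CLI mirrors the library (`hotspotter simulate / run / morpho /
density / hotspots / stats / overlap`); `hotspotter run --config
analysis.yaml` executes the whole pipeline on an exported dataset
directory and emits a validated JSON report.

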