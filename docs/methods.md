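# Methods

This note documents the models, estimators, and design choices behind
`hotspotter`, and what the synthetic-data tests do and do not establish
about real reconstructions.

## Data model

A reconstruction is a rooted forest of annotation disks (node id, parent
id, x/y/z in µm, radius, soma/dendrite/axon tag); a synapse record links
a presynaptic cell to a postsynaptic cell at a 3D point and is either a
ribbon synapse (bipolar input) or a conventional synapse (amacrine
input). Coordinates are µm, right-handed, z increasing from the INL/IPL
boundary toward the ganglion-cell layer. All planar analyses (hulls,
density maps, clustering, overlap) use x–y only, because the cells under
study are monostratified: their dendrites and inputs lie in a thin IPL
slab, so the informative structure is planar. IPL boundaries are modeled
as constant z-planes; warped-surface boundaries across the ~200 µm field
would be an extension of the same interface.

Synapses are attached to skeletons by nearest node in 3D Euclidean
distance, ties broken toward the lower node id — deterministic and
adequate when synapses are annotated on or near the dendrite membrane.

## Morphometry

The dendritic-field diameter is the equivalent circular diameter
2·√(A/π) of the convex hull of the dendrite-tagged annotations. The
equivalent-circle form is preferred over a max-chord definition because
dendritic fields can be asymmetric; soma- and axon-tagged nodes are
excluded so the hull reflects the dendritic field alone. Soma diameter
is twice the maximum radius among soma-tagged disks (the largest
annotated soma profile); an average-over-profiles alternative would bias
low because peripheral soma sections are smaller. IPL depth is
100·(z − z_INL/IPL)/(z_IPL/GCL − z_INL/IPL); the mean summarizes RGC
dendrites while the binned mode (1 % bins, ties toward the shallower
bin) summarizes bipolar axon terminals, whose long descending axon
otherwise dominates the mean. Group comparisons use the pooled-variance
two-sample t test; with zero pooled variance and equal means p = 1 by
convention.

## Density maps

A density map is a 2D count histogram over the bounding box (padded by
one bin; origin floored to a bin multiple so maps are reproducible and
translation-equivariant) smoothed by a second-order difference-penalty
(Whittaker) smoother applied separably: each row, then each column,
solves (I + λDᵀD)z = y with D the second-difference matrix. Because D
annihilates constants, 1ᵀz = 1ᵀy exactly — total mass equals the point
count for every λ ≥ 0, and λ = 0 reproduces the raw histogram
bit-exactly. λ = 1 is the default (minimum) smoothing. The smoother can
produce tiny negative lobes next to sharp peaks; they are clamped to
zero only when the implied mass change is below 10⁻⁹ relative, so the
conservation guarantee is never silently violated. A Gaussian-kernel
backend exists for sensitivity checks; it is not mass-exact at edges.
Default bin sizes scale with the field diameter (diameter/15.8 for
synapse maps, /24.3 for dendrite maps, anchored at 9.7 and 6.3 µm for a
153.1 µm field) and are always overridable.

## Hotspot clustering

Ribbon-synapse x–y coordinates are fit with full-covariance Gaussian
mixtures by EM (k-means++-style initialization, best of 10 restarts by
log-likelihood, convergence at mean log-likelihood change < 10⁻⁸,
diagonal regularization 10⁻⁶ scaled to the data's average variance; all
exposed in config, deterministic given the seed). Per-component full
covariances are used because hotspots differ in size and orientation.

Model selection scans K = 2..10 and maximizes the Calinski–Harabasz
index computed on hard (argmax-responsibility) assignments, with cluster
centroids taken as the empirical centroids of assigned points — the
partition form the index is defined on. Ties break toward smaller K
(parsimony); K values whose fit failed or left an empty hard cluster are
recorded as NaN and skipped. Data without genuine multi-cluster
structure produce a CH curve without a pronounced interior maximum; the
winning model is flagged `low_contrast` when max CH < 2× the median CH
over the scanned range. Zero within-cluster dispersion returns +inf as a
sentinel.

Outliers are points whose Mahalanobis distance d = √((x−µ)ᵀΣ⁻¹(x−µ))
exceeds 3 SD from **every** component — a point inside any cluster's
3-SD bound is kept. The square-rooted form is used so the threshold is
in standard-deviation units. Per-cluster composition (presynaptic-type
proportions) is computed over non-outlier members; clusters emptied by
exclusion are reported as empty rather than dropped.

## Connectivity statistics

The null probability of N consecutive amacrine synapses uninterrupted by
a bipolar synapse is geometric, p^N, with p the per-synapse amacrine
probability. p can come from observed synapse counts or from an
amacrine:bipolar cell ratio a:b as a/(a+b) — a 1.6:1 ratio gives
p = 0.6154, hence p⁵ = 8.8 % and p¹⁴ = 0.1 %.

"Consecutive" is operationalized as follows: synapses are attached to
skeleton nodes, ordered by cumulative arc length along each root-to-leaf
path, and maximal runs of conventional (amacrine) records are collected
per path; runs repeated across paths sharing a prefix are reported once
(a run whose member set is contained in another reported run is
dropped). Runs that straddle a branch point therefore continue along
each daughter path and are deduplicated, which matches counting a
terminal-branch pair fed solely by amacrine input as a single region.
Whether such regions should be counted per dendrite or per path is
ambiguous; per-path maximal runs are one consistent reading.

Partner profiles count synapses per presynaptic cell with totals by type
and the mean load per partner; Fisher's exact test (two-sided by
minimum-likelihood summation, the common convention; a tail-doubling
variant is available behind a flag) compares type proportions between
cells. Overlap analysis classifies one cell's synapses against another
cell's dendritic hull with boundary-inclusive membership (10⁻⁹ µm
tolerance) and reports 2D distances to the hull's area centroid plus
shared presynaptic partners by type.

## Synthetic reconstructions

The generator provides ground truth the EM volume cannot: planted
hotspot centers, known amacrine fraction, known type proportions.

*Skeletons* grow by fixed-length segments whose direction is the parent
direction plus Gaussian angular noise, bifurcating with a per-segment
probability, terminated at the field radius (with a generous step budget
and node cap so growth always terminates). Defaults emulate the study
geometry: a 12-primary, lightly-noised radiate tree reaching a ~153 µm
hull versus 5-primary, strongly-noised, heavily-branching trees of
~57 µm; soma radii 7.25 / 7.45 µm give 14.5 / 14.9 µm soma diameters.
The size and cable-density contrast (~0.6 vs ~2.5 dendrite nodes/µm²)
is what the analysis needs; the trees are not biophysical models (no
self-avoidance, no tapering, no realistic branch statistics).

*Synapses*: each of n records is independently amacrine with probability
0.615 (the 1.6:1 ratio), otherwise bipolar with a type drawn from
configured proportions (defaults DB5 0.55 / DB4 0.30 / giant 0.15 for
the large cell — DB5-dominant, as in the measured hotspot composition).
Amacrine synapses are uniform over dendrite nodes. Bipolar synapses are
placed by rejection sampling over dendrite nodes; in mixture mode the
planted Gaussian mixture is interpreted as an **areal** intensity, so
acceptance is proportional to intensity divided by the local cable
density (6 µm grid estimate, winsorized at the 99th percentile so a
stray node in a near-empty cell cannot stall sampling). This keeps
synapses on the cable while decoupling synaptic clustering from dendrite
density — the distinction the analysis itself is designed to probe.
Positions get an isotropic 1.5 µm lateral jitter (synapses sit on the
membrane near an annotation disk, not at its center); without it,
coincident points create zero-variance sub-clusters that degenerate the
CH index. Presynaptic ids are drawn from per-type partner pools sized by
a mean-synapses-per-partner parameter (1.8 for the large cell, 4.57 for
the small cells). The default planted mixture is four equal-weight 8 µm
components on a 45 µm ring (adjacent centers 63.6 µm apart).

Under these conditions, CH selection recovers K = 4 and component means
land within 4 µm of distinct planted centers in ≥ 16 of 20 seeded scenes
(residual misses are the expected sampling tail at ~31 points per
component, not bias). Passing these tests shows the detection pipeline
recovers planted planar Gaussian structure on realistic cable at study
sample sizes; it does not validate the ultrastructural synapse
annotations, the bipolar-type classifications, or hotspot shapes far
from Gaussian.

## Pipeline

Stages run in fixed order (morphometry → density → clustering → stats →
overlap). Each stage draws from an RNG stream derived from the master
seed by a stable hash of the stage name, so adding a stage never
perturbs another's draws; a failed stage is recorded and the rest still
run. Reports are pydantic models — the published JSON schema
(`report.schema.json`, from `Report.model_json_schema()`) is written
next to every report, and re-validation happens on load. Reports carry
provenance (package version, master and per-stage seeds, config hash)
and no timestamps, so a rerun with the same seed is byte-identical.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale defaults: 126 planted
bipolar synapses per scene, 20 scenes for recovery statistics, 10⁴
synapses for generator calibration, 100 random instances for the CH
cross-check, 50 point sets × λ ∈ {0, 1, 10} for mass conservation, and
all 2×2 tables with margins ≤ 12 for the Fisher enumeration. Geometric
tolerances: 10⁻⁹ µm for hull membership; 10⁻⁹ relative for mass
conservation; covariance regularization 10⁻⁶·mean-variance. Degenerate
inputs fail loudly: < 3 or collinear points for hulls, coincident IPL
boundaries, singular covariances, empty clusters, all-zero contingency
tables.

## Known limitations

Constant-plane IPL boundaries; planar (x–y) cluster analysis only;
skeleton generator is phenomenological; the arc-length run definition is
one reading of "consecutive along a dendrite"; CH selection is the only
built-in model-selection rule (by design — alternatives like BIC can sit
behind flags but are not the contract); no spatial point-process
statistics (e.g. Ripley's K) and no receptive-field modeling from cone
inputs.
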