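# Methods

## Problem setting

Satellite active-fire products report sub-pixel thermal anomalies as point
records: a pixel-centre coordinate (1 km for MODIS, 375 m for VIIRS), an
acquisition date/time, a 0–100 retrieval confidence, and fire radiative
power (FRP, MW) — a composite of flame temperature and burning area that
proxies fire intensity. Persistent combustion sources (gas flares, burn
pits) appear as dense recurring point clusters; scan geometry ("bow-tie"
pixel overlap near swath edges), geolocation error and sporadic fires
produce scattered spurious detections. The package identifies persistent
sources by density-based clustering per calendar year, treats unclustered
detections as noise (which implicitly absorbs bow-tie duplication), links
clusters to base geocodes, and summarises exposure. All confidence levels
are retained throughout: smoldering waste fires burn cool and are
systematically assigned low confidence, so a confidence filter would
remove exactly the sources of greatest interest.

## Distance geometry

All distances are great-circle (haversine) on a sphere of radius
6371.0088 km. At the 5 km buffer scale the sphere-vs-ellipsoid
discrepancy is below 10 m — negligible against ~1 km pixel geolocation
error — so no ellipsoidal solver or projected CRS is used. A cluster's
location is the **medoid** of its member fires (the member minimising
summed distance to the others): robust to outlying members and always an
actual detection. Medoid ties break to the lowest input index.

## Clustering model

HDBSCAN is implemented from first principles with a single parameter *k*
serving as both the neighbourhood size (min_samples) and the minimum
cluster size, because exactly one "minimum points per cluster" parameter
is tuned. Conventions, in order of application:

- **Core distance**: distance to the k-th nearest neighbour counting the
  point itself as rank 1, so k coincident detections form a valid cluster.
- **Mutual reachability**: `max(core(a), core(b), d(a, b))`.
- **MST**: exact Prim in O(n²) over the complete mutual-reachability
  graph; ties break to the lowest index pair, making the hierarchy
  deterministic. O(n²) is deliberate: annual scenes are at most a few
  tens of thousands of points and the test bed uses ≤ ~1,500, where the
  dense algorithm is simpler and fast enough (well under a second).
- **Condensation** at λ = 1/weight with minimum cluster size k: at each
  dendrogram split, a side with fewer than k points falls out of the
  current node at that λ; every side with ≥ k points opens a *new* child
  node born at that λ. Zero-weight merges (duplicate coordinates) are
  capped at λ = 10⁹ /km. Note the deliberate deviation from the common
  library convention, which lets a ≥ k side continue its parent node when
  its sibling is small ("runt pruning"): under the convention used here,
  stragglers shed on the approach to a dense core compete through the
  stability criterion and end up as noise when no selected cluster claims
  them, instead of being absorbed as low-probability members. An isolated
  detection tens of km from two tight clusters is labelled noise here,
  where the library convention would attach it to the nearer cluster with
  probability ≈ 0.
- **Extraction** by excess of mass: node stability is
  Σ_points (λ_p − λ_birth) with pass-through points leaving at the
  child's birth level; a node is selected when its stability strictly
  exceeds its children's propagated total. The root is never selected
  when it has ≥ 2 children, so a year cannot collapse into one
  all-encompassing cluster.
- **Labels and membership**: a point belongs to the selected
  ancestor-or-self of its fall-out node, else it is noise. Membership
  probability is λ_p / λ_max within the cluster: 1 at the densest core,
  → 0 at the sparsest edge, exactly 0 for noise. The formula is the
  natural density-ratio operationalisation of a qualitative "closeness to
  the dense core" score; its range and interpretation properties are
  verified by tests.

The hierarchy is validated two independent ways: the cut at any λ = 1/ε
must reproduce brute-force DBSCAN* components (union-find over
mutual-reachability edges ≤ ε among points with core distance ≤ ε), and
MST weights must match an independent Kruskal implementation. A
non-binding differential check against scikit-learn's HDBSCAN logs the
adjusted Rand agreement (typically high; exact agreement is not expected
because of the condensation convention above and tie handling).

## Tuning

Per year, `sweep_k` runs a full clustering for each k in an inclusive
range — 3–8 for dense Iraq-like scenes, 2–8 for sparse
Afghanistan/Djibouti-like scenes, configurable — and `select_k` picks the
k minimising the noise count among sweeps whose largest cluster holds at
most `max_share` (default 0.90) of the clustered fires. Ties go to the
smaller k; if no k satisfies the cap, the unconstrained minimum is used
with a logged warning. The share cap operationalises "meaningful cluster
structure": the noise argmin punishes fragmentation at small k, the cap
punishes the single engulfing cluster at large k. Years with fewer
detections than min(k_range) are flagged degenerate and fully noise.

One deliberate exception: the MODIS-vs-VIIRS **site comparison** disables
the share cap (max_share = 1.0). There the detections are pooled within
5 km of one known site, so a single cluster holding ~100% of the local
fires is the expected structure; with the cap in force the selector is
pushed into k = 2 fragmentation and the comparison becomes meaningless.

## Linkage and exposure

A cluster links to a base when **any member fire** lies within the
inclusive buffer radius (default 5 km) — clusters are irregular, so a
medoid-inside-buffer rule would miss elongated clusters that reach a
base. The medoid distance and the nearest-member distance are both
reported. A cluster near several bases is counted for each; pooled
statistics deduplicate fires, and bases within 5 km of one another are
additionally reported as proximity groups (connected components, so
membership is transitive). Medians and IQRs use numpy's
linear-interpolation quantile rule for bit-reproducibility.

Window exposure per base: presence (≥ 1 linked in-window fire), fire
count, median FRP, and the inverse-distance-weighted sum
Σ_clusters n_in_window / clamp(d_medoid, d_floor, radius). The divisor
floor (default 0.5 km, half a MODIS pixel) keeps on-base burning finite;
the ceiling at the linkage radius keeps the sum ≥ count/radius even when
a cluster links through an outlying member while its medoid sits beyond
the buffer.

## Synthetic scenes

The generator emulates the statistical structure the analysis relies on,
with defaults frozen as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| flare activity / FRP | 0.9 daily, lognormal median 26 MW (σ_log 0.4) | persistent oil/gas flaring; the observed median FRP at flare-dominated sites is ~26 MW |
| pit activity / FRP | 0.3 daily, median 6 MW (σ_log 0.5) | intermittent waste burning; burn-pit-dominated sites show ~6 MW medians; wider spread for heterogeneous waste |
| background | Poisson 0.4/day over a 1° box, median 20 MW (σ_log 0.8) | sporadic regional burning, ~10% of detections under default sampling |
| MODIS model | midpoint 8 MW, slope 2 MW, jitter σ 0.5 km, 2 overpasses/day | 1 km pixels; two satellites (Terra, Aqua) |
| VIIRS model | midpoint 2.5 MW, slope 2 MW, jitter σ 0.1875 km | anchored at the documented 2.5 MW nadir sensitivity; 375 m pixels |
| confidence | clip(9 + 23·ln FRP + N(0, 10), 0, 100) | cool fires score low, hot fires pile up at 100, matching the skew of real archives |
| FRP noise | multiplicative lognormal σ 0.2 | retrieval uncertainty |

Detection is Bernoulli with probability logistic((FRP − midpoint)/slope).
No detection-probability curve is published for either instrument, so the
midpoints are calibration knobs: with these values a Monte-Carlo
integral over the pit FRP distribution gives an expected VIIRS/MODIS
detection ratio of ≈ 2.2, consistent with the several-fold gap observed
at real burn-pit sites. The calibration was fixed analytically before any
end-to-end run and is not adjusted to test outcomes.

What the generator does **not** model: orbital mechanics and overpass
timing (slots are abstract), bow-tie geometric distortion (only an
optional along-scan jitter multiplier), plume transport, FRP
retrieval physics (FRP is sampled, not derived from temperature fields),
cloud obscuration, and spatially varying background rates. Passing tests
therefore demonstrate the pipeline's correctness and its behaviour under
the assumed statistical structure — not detection performance on real
archives, where duplicate scan overlaps, clouds and terrain effects are
additional error sources.

A scale-invariance caveat worth knowing: density-based clustering cannot
distinguish a uniform field from clusters at any *fixed* density, so a
background-only scene at moderate density clusters its own fluctuations;
background is rejected as noise only in the presence of denser planted
sources (the realistic regime), and the noise share of a background-only
scene approaches 1 only as the expected annual count falls below k.

## Determinism

Every random draw descends from one integer seed through named child
streams (sources, activity, detection, background, bases), so adding a
stage never perturbs another stage's draws, and a rerun with the same
configuration and seed is byte-identical file-for-file (the manifest
contains no timestamps). Clustering is deterministic for a fixed input
order and invariant under input permutation up to label renaming.

## Limitations

- The medoid summarises irregular clusters by one member; for ring-shaped
  flare fields the medoid can sit off the emission centroid.
- Membership probabilities are normalised within each cluster, so they
  are comparable within, not across, clusters or instruments.
- Per-year clustering cannot represent sources persisting across a year
  boundary with very few detections in each year (they degrade to noise);
  the k-range lower bound of 2 mitigates but cannot remove this.
- The O(n²) distance matrix bounds practical scene size to a few tens of
  thousands of detections per year (~10 GB at 40k points would exceed
  memory; the intended desk scale is well below that).
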