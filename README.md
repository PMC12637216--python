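# fireclust

Reconstruction of combustion-source exposure near military bases from
satellite active-fire detections.

Ground-level air monitoring was essentially absent during land-based
military operations in Iraq and Afghanistan, yet personnel were stationed
near persistent combustion sources — open-air burn pits on base, oil and
gas flaring nearby. Daily thermal-anomaly ("active fire") products from
the MODIS and VIIRS radiometers are the only systematic record of that
burning. `fireclust` turns those point detections into exposure evidence:
it clusters each year's detections, rejects aberrant ones as noise, links
fire clusters to base geocodes, tracks their multi-year persistence, and
derives deployment-window exposure metrics. It is written for exposure
scientists and epidemiologists building objective, reproducible deployment
exposure histories.

## Method

Each detection is a point record (pixel-centre latitude/longitude,
acquisition date/time, instrument, confidence 0–100, fire radiative power
*FRP* in MW). Per calendar year, detections are clustered with a
from-scratch **HDBSCAN** on the great-circle metric with a single tuned
parameter *k* (minPts):

1. core distance `core_k(p)` = distance to the *k*-th nearest neighbour
   (self counts as rank 1);
2. mutual reachability `d_mr(a,b) = max(core_k(a), core_k(b), d(a,b))`;
3. exact MST of the mutual-reachability graph (Prim, O(n²));
4. the single-linkage hierarchy is condensed at density level λ = 1/w with
   minimum cluster size *k*;
5. clusters are extracted by excess of mass over the condensed tree;
   unassigned points are **noise**, and members get a membership
   probability λ_p / λ_max ∈ (0, 1].

*k* is selected per year by sweeping an integer range (3–8 for dense
scenes, 2–8 for sparse ones) and minimising the noise count subject to a
largest-cluster-share cap, which together avoid fragmentation (k too
small) and all-engulfing clusters (k too large).

Clusters link to a base when any member fire lies within an inclusive
5 km buffer of its geocode. Per base the package reports linked-fire
counts, persistence (years with ≥ 1 linked cluster), and window exposure
metrics including the inverse-distance-weighted sum
`Σ_clusters n_fires / clamp(d_medoid, 0.5 km, 5 km)` (fires/km).

Because real base geocodes are access-restricted and FIRMS archives are
bulky, a seedable synthetic scene generator provides the test bed: flares
(lognormal FRP, median 26 MW, ~daily activity), burn pits (median 6 MW,
intermittent), Poisson background, and instrument models whose detection
probability rises logistically with FRP (midpoints 8 MW for 1 km MODIS,
2.5 MW for 375 m VIIRS), with half-pixel geolocation jitter.

## Worked example

```python
import fireclust as fc

scene = fc.SceneConfig()                      # 2 flares + 1 burn pit + background
sources = fc.simulate_sources(scene, seed=1)
dets, truth = fc.simulate_detections(
    sources, fc.MODIS, (scene.start, scene.end), seed=1,
    bbox=scene.bbox, background_rate_per_day=scene.background_rate_per_day)
(yc,) = fc.annual_clustering(dets, (3, 8)).values()
print(yc.k, yc.n_clusters, round(100 * yc.noise_fraction, 1))
```

prints

```
5 9 5.8
```

i.e. the tuned minPts is 5, the year resolves into 9 clusters (the three
planted sources plus small background groupings), and 5.8% of the 1490
detections are rejected as noise — close to the ~9% of detections that
were planted as scattered background. Linking against synthetic base
geocodes (`examples/link_bases.py`) prints, per base, the signature that
separates source types: flare-adjacent bases accumulate ~630–650 linked
fires at median FRP ≈ 26 MW, while the burn-pit base shows 82 weaker
fires at ≈ 8 MW.

Each script in `examples/` exercises one capability (simulation,
clustering, linkage, exposure windows, MODIS-vs-VIIRS comparison) and
explains its printed numbers. The same stages run from the shell:

```sh
fireclust run-all --config examples/scene.yaml --out run1 --seed 1
```

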