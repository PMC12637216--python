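"""Compare MODIS and VIIRS detection of the same low-FRP burn pit.

Both instruments observe the identical source; the comparison pools each
instrument's detections within 5 km of the site, clusters them with the
tuned pipeline, and reports the fire count at the site cluster. VIIRS's
2.5 MW detection midpoint (vs 8 MW for MODIS at 1 km resolution) makes it
several-fold more sensitive to ~6 MW smoldering fires.
"""

import fireclust as fc

scene = fc.SceneConfig(n_flares=0, n_burn_pits=1)
sources = fc.simulate_sources(scene, seed=1)
pit = sources[0]

modis_dets, _ = fc.simulate_detections(sources, fc.MODIS, (scene.start, scene.end), seed=1)
viirs_dets, _ = fc.simulate_detections(sources, fc.VIIRS, (scene.start, scene.end), seed=1)

comp = fc.instrument_comparison(
    {"MODIS": modis_dets, "VIIRS": viirs_dets}, pit.location
)

print(f"burn pit at {pit.location}, true median FRP {pit.frp_median} MW")
for name, stats in sorted(comp.stats.items()):
    print(f"  {name}: {stats['n_clustered']} clustered fires at the site "
          f"(k={stats['k']}), median membership "
          f"{stats['median_membership_prob']:.2f}, "
          f"median FRP {stats['median_frp']:.1f} MW")
print(f"VIIRS/MODIS ratio: {comp.ratio:.2f}")
# The ratio lands near the calibrated expectation of ~2-3x. Median FRP is
# lower for VIIRS because it detects the weak fires MODIS misses; membership
# probabilities are normalised within each cluster, so the two instruments'
# values are not directly comparable.
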