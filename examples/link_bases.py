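"""Link fire clusters to base geocodes through inclusive 5 km buffers and
build per-base persistence timelines.

A cluster links to a base when any member fire lies within the buffer; the
5 km radius absorbs the ~1 km pixel geolocation error and imprecise base
coordinates. Each base's timeline counts linked fires, clusters and the
years with activity, and summarises FRP and membership probability over
the linked fires.
"""

import fireclust as fc

scene = fc.SceneConfig()
sources = fc.simulate_sources(scene, seed=1)
detections, _ = fc.simulate_detections(
    sources, fc.MODIS, (scene.start, scene.end), seed=1,
    bbox=scene.bbox, background_rate_per_day=scene.background_rate_per_day,
)
bases = fc.scene_bases(sources, seed=1)  # synthetic geocodes 1-3 km from sources

clusterings = fc.annual_clustering(detections, (3, 8))
links = fc.link_clusters_to_bases(clusterings, detections, bases, radius_km=5.0)
timelines = fc.persistence_timeline(links, detections)

print(f"{len(links)} cluster-base links")
for t in timelines:
    print(f"  {t.base_id}: {t.total_linked_fires} fires in {t.total_clusters} "
          f"cluster(s) over years {list(t.years_with_clusters)}; "
          f"median FRP {t.median_frp:.1f} MW, "
          f"median membership {t.median_membership_prob:.2f}")
groups = fc.base_proximity_groups(bases, 5.0)
print(f"base proximity groups (within 5 km of each other): {groups}")
# Flare-adjacent bases show hundreds of linked fires at ~26 MW; the
# pit-adjacent base shows far fewer, weaker fires - the signature that
# distinguishes oil/gas flaring from open-air waste burning.
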