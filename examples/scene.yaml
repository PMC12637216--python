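# Example flat config for `fireclust run-all --config scene.yaml`.
# Every key maps onto a RunConfig field; scene_* keys configure the
# synthetic scene used when no `fires:` input is given.

out_dir: fireclust_run        # all stage outputs and the manifest land here
seed: 1                       # single seed driving every random draw

# clustering / tuning
k_min: 3                      # minPts sweep lower bound (3 for dense scenes,
k_max: 8                      #   2 for sparse ones), inclusive
max_share: 0.9                # largest-cluster share cap during k selection

# linkage / exposure
radius_km: 5.0                # inclusive buffer around each base geocode
d_floor: 0.5                  # km; IDW divisor floor (half a MODIS pixel)
window_start: 2007-04-01      # exposure window (omit for the full period)
window_end: 2007-09-30

# synthetic scene (ignored when `fires:` points at a real FIRMS CSV)
scene_bbox: [33.4, 43.8, 34.4, 44.8]   # south, west, north, east
scene_start: 2007-01-01
scene_end: 2007-12-31
scene_n_flares: 2             # persistent high-FRP sources
scene_n_burn_pits: 1          # intermittent low-FRP sources
scene_flare_frp_median: 26.0  # MW, lognormal median
scene_pit_frp_median: 6.0     # MW
scene_background_rate_per_day: 0.4   # Poisson ignitions/day over the bbox

# to analyse real exports instead, uncomment:
# fires: modis_archive.csv
# bases: base_geocodes.csv
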