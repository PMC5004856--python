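"""Advect passive larvae from a ring of seamount release points.

Places 8 release points around the 1000 m contour of the synthetic guyot,
releases them quarterly through one season, and tracks each for 30 days at
a 1-hour timestep, printing where they ended up and why.
"""

from collections import Counter

import numpy as np

from larvalsens import design as dz
from larvalsens import synthetic_ocean as so
from larvalsens import tracker as tk
from larvalsens.dst_analysis import haversine_km

grid = so.GridSpec(lon_min=-13.5, lon_max=-8.5, lat_min=55.0, lat_max=59.5,
                   z_levels=tuple(so.levitus_levels(150, 2000)),
                   n_snapshots=130)
topo = so.make_guyot_topography(grid)
series = so.generate_velocity_series(grid, topo, so.EddyFieldParams(seed=0))

points = dz.ring_release_points(topo, 1250.0, 8)  # ring on the 1250 m contour
points = [dz.ReleasePoint(id=p.id, lon=p.lon, lat=p.lat, depth=1000.0,
                          contour_depth=1250.0) for p in points]
schedule = dz.build_release_schedule(1, 4, year_length_days=365.0)
config = tk.TrackerConfig(timestep_s=3600.0, pld_days=30.0)

tracks = tk.run_release_set(series, dz.ExperimentDesign(points=points,
                                                        schedule=schedule),
                            config)
tk.write_tracks_csv(tracks, "tracks.csv")

print(f"{len(tracks)} tracks of {config.n_records} daily positions each")
print("final status:", dict(Counter(t.status for t in tracks)))
dists = [haversine_km((t.lons[0], t.lats[0]), (t.lons[-1], t.lats[-1]))
         for t in tracks]
print(f"net displacement over 30 d: median {np.median(dists):.1f} km, "
      f"max {max(dists):.1f} km")
print("\nwrote tracks.csv — beached larvae hit the seamount flank and are")
print("frozen at their last valid position; escaped ones left the model")
print("domain; both keep emitting positions so replicate designs stay full.")
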