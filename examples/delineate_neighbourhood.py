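"""Delineate the greater-park-ecosystem sample for one protected area.

Builds a small all-land grid with a single 4x4 protected area, grows the
square search window outward until a candidate region of twice the
footprint's area is collected, and samples an equal-area pixel set from it.
"""

import numpy as np

from parkshed import delineate
from parkshed.landscape import LandscapeGrid, PPARecord

grid = LandscapeGrid(
    n_rows=30,
    n_cols=30,
    pixel_size_m=30.0,
    lat_top=52.0,
    lat_bottom=51.0,
    water_mask=np.zeros((30, 30), bool),
    agri_mask=np.zeros((30, 30), bool),
)
ppa = PPARecord(
    id="DEMO",
    footprint=frozenset((r, c) for r in range(13, 17) for c in range(13, 17)),
    establishment_year=1990,
    iucn="II",
)

gpe = delineate(ppa, [ppa], grid, master_seed=42)

print(f"footprint pixels:   {ppa.n_pixels}")
print(f"candidate pixels:   {gpe.n_candidate}  (target 2x footprint)")
print(f"sample pixels:      {gpe.n_sample}  (equal area)")
print(f"rings searched:     {gpe.max_ring_used}  (Chebyshev distance)")
print(f"complete:           {gpe.complete}")
# The candidate is the nearest unmasked 2x-area shell around the park; the
# sample is the equal-area random subset actually compared against the park.
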