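"""Read a CRU CL-style whitespace climatology and regrid it.

Real gridded climatologies of this family are plain text: one line per
10' cell, 'lat lon' followed by 12 monthly values.  The reader infers
the grid from the coordinates; regrid_bilinear moves fields between
grids.
"""

import tempfile
from pathlib import Path

import numpy as np

from peatenvelope import GridSpec, RasterField, regrid_bilinear
from peatenvelope.grids import read_cru_monthly

# write a tiny 2x2-cell fixture in the text dialect
lines = []
for lat in (32.25, 32.25 + 1 / 6):
    for lon in (102.75, 102.75 + 1 / 6):
        vals = " ".join(f"{10 + m + lat - lon / 10:.2f}" for m in range(12))
        lines.append(f"{lat:.4f} {lon:.4f} {vals}")
path = Path(tempfile.mkdtemp()) / "tmp_grid.txt"
path.write_text("\n".join(lines) + "\n")

grid, values, units = read_cru_monthly(path, "tmp")
print(f"inferred grid: {grid.n_lat} x {grid.n_lon} cells at "
      f"{grid.resolution:.0f}', units: {units}")
print(f"January layer:\n{np.round(values[0], 2)}")

# double the resolution with bilinear interpolation
fine = GridSpec(lat_min=grid.lat_min, lat_max=grid.lat_max,
                lon_min=grid.lon_min, lon_max=grid.lon_max,
                resolution=grid.resolution / 2)
jan = regrid_bilinear(RasterField(grid=grid, values=values[0]), fine)
print(f"\nregridded January layer ({fine.n_lat} x {fine.n_lon}; corners "
      "outside the source-centre hull stay missing):")
print(np.round(jan.values, 2))
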