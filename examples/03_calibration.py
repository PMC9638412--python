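"""Calibrate the size-filter cutoff from an irregular-component sample.

The cutoff is the nearest-rank 90th percentile of the observed spurious
component areas; combined with the `area <= cutoff` removal rule it filters
out 90% of them.  The pixel-to-cell conversion shows what the cutoff means
biologically at 0.23 um/px with 13.5 um tumor cells.
"""

import numpy as np

from pnikit.calibration import (
    PixelGeometry,
    calibrate_cutoff,
    cells_to_pixels,
    pixels_to_cells,
)
from pnikit.synthetic import SceneSpec, generate_scene

# collect spurious-component areas from a batch of synthetic scenes
areas = []
for seed in range(10):
    areas.extend(generate_scene(SceneSpec(seed=seed)).noise_areas_px2)

for alpha in (0.10, 0.05):
    cutoff = calibrate_cutoff(areas, alpha)
    eq = pixels_to_cells(cutoff)
    print(f"alpha={alpha:>4}: cutoff {cutoff:8.0f} px^2  (~{eq.cells:.1f} cells)")

geom = PixelGeometry(mpp=0.23, cell_diameter_um=13.5)
print(f"\nreference cutoff 21,632 px^2 = {pixels_to_cells(21_632, geom).cells:.2f} cells "
      f"-> detection limit ~{pixels_to_cells(21_632, geom).rounded} cells")
print(f"a 40,000 px^2 component = {pixels_to_cells(40_000, geom).cells:.1f} cells")
print(f"one cell covers {cells_to_pixels(1, geom):.0f} px^2")
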