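"""Generate one synthetic histology scene and describe its ground truth.

The scene holds elliptical nerves (with perineurium rings), tumor-cell nests
planted against half of them (the PNI-positive ones), and spurious blobs for
the size filter to remove.
"""

import numpy as np
from scipy import ndimage

from pnikit.synthetic import SceneSpec, generate_scene

scene = generate_scene(SceneSpec(seed=42))

print(f"canvas: {scene.image.shape[1]}x{scene.image.shape[0]} px "
      f"at {scene.spec.mpp} um/px")
for rec in scene.nerve_records:
    r0, c0, r1, c1 = rec.bbox
    print(f"  nerve {rec.id}: bbox {r1 - r0}x{c1 - c0} px, truth = {rec.truth_class}")

labeled, n_nests = ndimage.label(scene.pni_truth, np.ones((3, 3)))
nest_areas = np.bincount(labeled.ravel())[1:]
print(f"planted nests: {n_nests}, areas {sorted(int(a) for a in nest_areas)} px^2 "
      "(all above the 21,632 px^2 size-filter cutoff, i.e. > ~8 tumor cells)")
print(f"noise blobs drawn: {len(scene.noise_areas_px2)}, "
      f"{sum(a <= 21_632 for a in scene.noise_areas_px2)} of them below the cutoff")
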