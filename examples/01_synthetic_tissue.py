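"""Generate a synthetic mesenchyme section with full ground truth.

Builds a 150x150 μm field of nuclei at ~10 μm spacing with 40% of cells
carrying an S-phase label, renders DAPI-like and label channels, and
prints the realized packing statistics against the generator's targets.
"""

import numpy as np
from scipy.spatial import cKDTree

from mesomap import default_validation_spec, generate_centroid_field, render_section_image

spec = default_validation_spec(seed=1)
field, truth = generate_centroid_field(spec)
nuclear, label = render_section_image(field, spec)

tree = cKDTree(field.points)
nn = tree.query(field.points, k=2)[0][:, 1]
interior = ((field.points > 15) & (field.points < 135)).all(axis=1)

print(f"nuclei generated:            {len(field)}")
print(f"target spacing:              10.0 μm")
print(f"realized mean NN distance:   {nn[interior].mean():.2f} μm (interior cells)")
print(f"labelled fraction:           {field.label_flags.mean():.3f} (target 0.40)")
print(f"nuclear channel:             {nuclear.shape[1]}x{nuclear.shape[0]} px, "
      f"peak {nuclear.max()}, background sd ~{spec.noise_sd:g}")
# The realized nearest-neighbour distance tracks the target spacing because the
# dart-throwing exclusion radius is calibrated to the saturated packing density;
# the labelled fraction is a Bernoulli draw at each cell's local probability.
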