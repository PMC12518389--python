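"""Screw-axis decomposition and the three clinical displacement parameters.

Any rigid motion equals a rotation about one axis in space plus a slide
along it.  rScrew is that rotation magnitude; MTPM and mTRE are the
maximum and mean per-vertex displacement over the implant surface mesh.
"""

import numpy as np

from implmotion.kinematics import (
    displacement_outcome,
    heatmap_colors,
    relative_motion,
    screw_decompose,
)
from implmotion.volio import RigidTransform

# Per-object repositioning matrices, e.g. as estimated by registration.
t_implant = RigidTransform.from_euler_deg(rotation_deg=(0.5, 0.2, 2.0), translation_mm=(1.1, -0.4, 0.6))
t_bone = RigidTransform.from_euler_deg(rotation_deg=(0.5, 0.2, 0.0), translation_mm=(1.0, -0.5, 0.5))

t_rel = relative_motion(t_implant, t_bone)
screw = screw_decompose(t_rel)
print(
    f"screw axis: {screw.angle_deg:.3f} deg about {np.round(screw.direction, 3)}, "
    f"slide {screw.slide_mm:.3f} mm"
)

# A toy implant point cloud: a 30 mm plate footprint.
rng = np.random.default_rng(0)
vertices = rng.uniform([-15, -15, -2], [15, 15, 2], size=(2000, 3))
outcome = displacement_outcome(t_rel, vertices)
print(f"rScrew {outcome.rscrew_deg:.3f} deg, MTPM {outcome.mtpm_mm:.3f} mm, mTRE {outcome.mtre_mm:.3f} mm")

colors = heatmap_colors(outcome.per_vertex_mm)
print(f"heatmap: 0 mm -> {colors[np.argmin(outcome.per_vertex_mm)]}, "
      f"max -> {colors[np.argmax(outcome.per_vertex_mm)]} (blue to red, saturating at 0.5 mm)")
print("MTPM >= mTRE always; they coincide only for a pure translation.")
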