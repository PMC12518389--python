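# implmotion

Quantifies the rigid displacement of a tibial knee implant **relative to the
tibia** from a pair of CT scans acquired under opposite bending loads
(valgus / varus). A loose implant moves measurably with respect to the bone
between the two load directions; a well-fixed one barely moves. The package
is aimed at researchers in orthopedic image analysis who need the full
measurement chain — segmentation, meshing, registration, kinematics and the
study-level statistics — plus a synthetic phantom that provides ground-truth
motion for validation, since clinical CT pairs of this kind are not public.

## Method

For each object (implant, tibia) the workflow estimates a 4×4 rigid
*repositioning matrix* from the valgus scan to the varus scan:

1. **Segmentation** — masks are supplied as files (e.g. predictions of an
   external deep-learning model) or grown semi-automatically by seeded,
   threshold-based region growing. Post-processing keeps the largest
   connected component per class and carves the bone mask where it overlaps
   the implant mask dilated by a ≥ 3 mm spherical margin.
2. **Meshing** — marching cubes at iso-level 0.5 turns each mask into a
   triangle mesh in world millimetres with outward vertex normals.
3. **Registration** — the implant mesh is roughly aligned by Iterative
   Closest Point; then a *double contour* (grey values sampled in the valgus
   scan at ±0.3 mm along the vertex normals) is registered to the varus scan
   by maximising the Pearson correlation between the contour's reference
   grey values and trilinearly interpolated target values, over 3
   translations + 3 rotations with Nelder–Mead downhill simplex. The tibia
   runs the same stage from an identity initialisation.
4. **Kinematics** — the implant motion in the bone frame,
   `T_rel = T_bone⁻¹ · T_implant`, is decomposed into its screw (helical)
   axis. Reported parameters:
   - **rScrew** (deg): rotation magnitude about the screw axis,
     `θ = acos((tr R − 1)/2)`;
   - **MTPM** (mm): maximum of `‖T_rel p − p‖` over implant-mesh vertices;
   - **mTRE** (mm): mean of the same per-vertex displacements.
   A blue→red heatmap (saturating at 0.5 mm) colours the implant mesh.

The `stats` module supplies the evaluation machinery used in displacement
studies: exact/approximate Wilcoxon signed-rank and Mann–Whitney U tests,
percentile-bootstrap median CIs (R = 1000), ICC(A,1) inter-operator
reliability with F-based CIs, Bonferroni correction and `ns`/`*`/`**`
significance labels.

The `phantom` module renders valgus/varus pairs analytically from solid
primitives — a tapered elliptical bone with cortical shell and a
plate-plus-stem implant — with a configurable ground-truth screw motion,
global repositioning, soft partial-volume edges, noise and streak
artefacts. See `docs/methods.md` for the model details.

## Worked example

`examples/03_register_pair.py` builds a 128³ phantom pair (0.45 mm voxels)
in which the implant rotates 2.0° about its stem axis relative to the bone
while the whole scene is repositioned, then runs the full workflow:

```
parameter      recovered       truth
rScrew deg         1.993       2.000
MTPM mm            0.799       0.794
mTRE mm            0.394       0.396

implant correlation 0.9983, bone correlation 0.9984
```

The recovered parameters agree with the ground truth to ~0.01 deg /
~0.005 mm — an order of magnitude below the voxel size — and the final
correlations near 1 indicate that both double contours found their
intensity pattern in the varus scan. The other examples cover phantom
generation, the segmentation arm, the kinematics primitives and the group
statistics; each prints a closing line explaining its numbers.

A thin CLI mirrors the library (`implmotion generate/grow/postprocess/mesh/
run/batch/quantify/compare`).

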