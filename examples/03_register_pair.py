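"""Full displacement workflow on a phantom pair with known ground truth.

Runs masks -> post-processing -> meshes -> ICP -> double-contour
point-to-image registration -> screw-axis kinematics, then compares the
recovered displacement parameters with the phantom's ground truth.
"""

from implmotion.phantom import PhantomSpec, ScrewMotion, generate_pair, ground_truth_outcome
from implmotion.pipeline import PairMasks, PipelineConfig, run_pair
from implmotion.volio import RigidTransform

spec = PhantomSpec(
    true_motion=ScrewMotion(angle_deg=2.0),
    global_motion=RigidTransform.from_euler_deg(
        rotation_deg=(0.5, 0.0, 1.0), translation_mm=(1.0, -0.5, 0.5)
    ),
    noise_sd=10.0,
    seed=3,
)
valgus, varus, labels_valgus, labels_varus, truth = generate_pair(spec)

masks = PairMasks(
    implant_valgus=labels_valgus, implant_varus=labels_varus, bone_valgus=labels_valgus
)
result = run_pair(valgus, varus, PipelineConfig(), masks=masks, out_dir="scratch/run_pair")
expected = ground_truth_outcome(truth, result.implant_mesh)

print(f"{'parameter':<12}{'recovered':>12}{'truth':>12}")
print(f"{'rScrew deg':<12}{result.outcome.rscrew_deg:>12.3f}{expected.rscrew_deg:>12.3f}")
print(f"{'MTPM mm':<12}{result.outcome.mtpm_mm:>12.3f}{expected.mtpm_mm:>12.3f}")
print(f"{'mTRE mm':<12}{result.outcome.mtre_mm:>12.3f}{expected.mtre_mm:>12.3f}")
print(
    f"\nimplant correlation {result.implant_registration.final_correlation:.4f}, "
    f"bone correlation {result.bone_registration.final_correlation:.4f}"
)
print("Recovered values within ~0.1 deg / 0.1 mm of truth indicate sub-voxel registration.")
print("Artifacts (transforms, heatmap PLY, JSON log) are under scratch/run_pair/.")
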