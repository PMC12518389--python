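"""Synthetic valgus/varus CT phantom with known implant-relative-to-bone motion.

The phantom emulates the acquisition geometry of a loaded knee CT pair:
one scan per load direction, isotropic 0.45 mm voxels, a tibia-like bone
(tapered cylinder with a cortical shell and trabecular interior) carrying a
plate-plus-stem metal implant.  Between the two volumes the implant moves
relative to the bone by a configurable screw motion (the quantity the
pipeline must recover) and the whole scene undergoes a rigid repositioning
(the patient moving on the table).

Both volumes are rendered *analytically* from solid geometric primitives at
their respective poses — never by resampling a moved volume — so that
interpolation artefacts cannot contaminate registration-accuracy tests.
Intensities follow a soft-edge model: each tissue contributes its mean
value weighted by an erf profile of the analytic signed distance to its
boundary (``edge_sigma_mm``), emulating the finite point-spread function
of a CT reconstruction.  A hard, infinitely sharp phantom (``edge_sigma_mm
= 0``) is available for voxel-exact segmentation oracles, but subvoxel
intensity-based registration is only meaningful on band-limited data.
Ground-truth label masks always come from hard voxel-center occupancy.
Optional degradations: additive Gaussian noise, a radial streak pattern
emanating from the implant (a stand-in for metal artefacts), and a
Gaussian partial-volume blur (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .kinematics import ScrewAxis, DisplacementOutcome, displacement_outcome
from .volio import (
    ImageVolume,
    LabelVolume,
    RigidTransform,
    LABEL_IMPLANT,
    LABEL_CORTICAL,
    LABEL_TRABECULAR,
    write_volume,
    write_transform,
)

__all__ = [
    "BoneGeometry",
    "ImplantGeometry",
    "ScrewMotion",
    "PhantomSpec",
    "generate_pair",
    "ground_truth_outcome",
    "spec_from_config",
    "write_pair",
]


@dataclass(frozen=True)
class BoneGeometry:
    """Tapered elliptical cylinder along z with a cortical shell (mm, bone frame).

    The elliptical cross-section (``aspect_ratio`` = y-radius / x-radius)
    mimics the azimuthal asymmetry of a real tibia; a circular bone would
    make rotation about its own long axis invisible to intensity-based
    registration.
    """

    z_bottom: float = -25.0
    z_top: float = 5.0
    radius_bottom: float = 13.0
    radius_top: float = 18.0
    aspect_ratio: float = 0.75
    cortical_thickness_mm: float = 3.0


@dataclass(frozen=True)
class ImplantGeometry:
    """Plate-plus-stem implant: a box tray over a cylindrical stem (mm)."""

    plate_half_extent: tuple[float, float, float] = (16.0, 16.0, 1.5)
    plate_center_z: float = 7.6
    stem_radius: float = 4.0
    stem_z_top: float = 7.0
    stem_z_bottom: float = -14.0

    @property
    def centroid(self) -> np.ndarray:
        return np.array([0.0, 0.0, 0.5 * (self.plate_center_z + self.stem_z_bottom)])


@dataclass(frozen=True)
class ScrewMotion:
    """Screw-motion parameters of the implant relative to the bone."""

    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    axis_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    angle_deg: float = 0.0
    slide_mm: float = 0.0

    def to_transform(self) -> RigidTransform:
        d = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ValueError("screw axis direction must be nonzero")
        return ScrewAxis(
            direction=d / norm,
            point_on_axis=np.asarray(self.axis_point, dtype=float),
            angle_deg=float(self.angle_deg),
            slide_mm=float(self.slide_mm),
        ).to_transform()


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic valgus/varus pair.

    Intensities are dimensionless HU-like means; their ordering
    (metal > cortical > trabecular > background) is validated.  The bone
    solid is carved so that no bone voxel lies within ``carve_margin_mm``
    of the implant at its first-volume pose, keeping the two solids
    disjoint (as the post-processed masks of the real workflow are).
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing_mm: float = 0.45
    bone_geometry: BoneGeometry = field(default_factory=BoneGeometry)
    implant_geometry: ImplantGeometry = field(default_factory=ImplantGeometry)
    intensity_background: float = 0.0
    intensity_trabecular: float = 300.0
    intensity_cortical: float = 1500.0
    intensity_metal: float = 3000.0
    noise_sd: float = 10.0
    edge_sigma_mm: float = 0.3
    streak_amplitude: float = 0.0
    streak_spokes: int = 12
    streak_decay_mm: float = 20.0
    smooth_sigma_mm: float = 0.0
    carve_margin_mm: float = 2.0
    true_motion: ScrewMotion = field(default_factory=ScrewMotion)
    global_motion: RigidTransform = field(default_factory=RigidTransform.identity)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if self.bone_geometry.cortical_thickness_mm < 2 * self.spacing_mm:
            raise ValueError("cortical shell must be at least 2 voxels thick")
        order = (
            self.intensity_metal,
            self.intensity_cortical,
            self.intensity_trabecular,
            self.intensity_background,
        )
        if not all(a > b for a, b in zip(order, order[1:])):
            raise ValueError("intensities must satisfy metal > cortical > trabecular > background")
        if self.carve_margin_mm <= 0:
            raise ValueError("carve_margin_mm must be positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.full(3, self.spacing_mm)

    @property
    def origin(self) -> np.ndarray:
        # Center the world origin in the grid so rotations stay in-frame.
        return -(np.asarray(self.grid_shape) - 1) / 2.0 * self.spacing_mm

    def truth_transform(self) -> RigidTransform:
        """Implant-relative-to-bone motion, in the bone frame of volume 1."""
        return self.true_motion.to_transform()


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    """World coordinates of all voxel centers, shape (nx, ny, nz, 3)."""
    axes = [
        spec.origin[i] + np.arange(spec.grid_shape[i]) * spec.spacing_mm
        for i in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1)


def _implant_signed_distance(q: np.ndarray, geo: ImplantGeometry) -> np.ndarray:
    """Exact signed Euclidean distance to the plate-plus-stem solid.

    Negative inside, positive outside; the union of the two primitives is
    the pointwise minimum of their signed distances.
    """
    h = np.asarray(geo.plate_half_extent)
    delta = np.abs(q - np.array([0.0, 0.0, geo.plate_center_z])) - h
    d_plate = np.linalg.norm(np.maximum(delta, 0.0), axis=-1) + np.minimum(
        delta.max(axis=-1), 0.0
    )
    dr = np.hypot(q[..., 0], q[..., 1]) - geo.stem_radius
    dz = np.maximum(geo.stem_z_bottom - q[..., 2], q[..., 2] - geo.stem_z_top)
    d_stem = np.minimum(np.maximum(dr, dz), 0.0) + np.hypot(
        np.maximum(dr, 0.0), np.maximum(dz, 0.0)
    )
    return np.minimum(d_plate, d_stem)


def _tapered_cylinder_signed_distance(
    q: np.ndarray, bone: BoneGeometry, shrink_mm: float = 0.0
) -> np.ndarray:
    """Signed distance to the tapered elliptical bone cylinder, optionally shrunk.

    The radial term is the first-order exact distance to the z-dependent
    ellipse (level-set value divided by its gradient magnitude); the
    slight axial taper tilts the true normal by a few degrees, which only
    rescales the edge profile marginally and is ignored.
    """
    x, y, z = q[..., 0], q[..., 1], q[..., 2]
    frac = np.clip((z - bone.z_bottom) / (bone.z_top - bone.z_bottom), 0.0, 1.0)
    radius = bone.radius_bottom + frac * (bone.radius_top - bone.radius_bottom)
    a = radius - shrink_mm
    b = bone.aspect_ratio * radius - shrink_mm
    r_norm = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    grad = np.sqrt((x / a**2) ** 2 + (y / b**2) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dr = np.where(grad > 1e-12, (r_norm - 1.0) / np.maximum(grad, 1e-12),
                      (r_norm - 1.0) * np.minimum(a, b))
    dz = np.maximum(
        (bone.z_bottom + shrink_mm) - z, z - (bone.z_top - shrink_mm)
    )
    return np.minimum(np.maximum(dr, dz), 0.0) + np.hypot(
        np.maximum(dr, 0.0), np.maximum(dz, 0.0)
    )


def _scene_signed_distances(
    q_bone: np.ndarray, q_impl: np.ndarray, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(implant, carved bone, carved trabecular) signed distances.

    The bone solid excludes a ``carve_margin_mm`` neighbourhood of the
    implant at its first-volume pose (where bone-frame and implant-frame
    coordinates coincide), keeping the two solids disjoint.
    """
    d_impl = _implant_signed_distance(q_impl, spec.implant_geometry)
    # Carve against the implant at its bone-frame pose so the bone solid
    # stays rigid: distance measured in bone-frame coordinates.
    carve = spec.carve_margin_mm - np.maximum(
        _implant_signed_distance(q_bone, spec.implant_geometry), 0.0
    )
    bone = spec.bone_geometry
    d_bone = np.maximum(_tapered_cylinder_signed_distance(q_bone, bone), carve)
    d_trab = np.maximum(
        _tapered_cylinder_signed_distance(q_bone, bone, shrink_mm=bone.cortical_thickness_mm),
        carve,
    )
    return d_impl, d_bone, d_trab


def _soft_occupancy(d: np.ndarray, sigma_mm: float) -> np.ndarray:
    """Erf edge profile of a signed distance; hard indicator when sigma = 0."""
    if sigma_mm <= 0:
        return (d <= 0).astype(float)
    from scipy.special import erfc

    return 0.5 * erfc(d / (np.sqrt(2.0) * sigma_mm))


def _render(
    spec: PhantomSpec,
    centers: np.ndarray,
    bone_pose: RigidTransform,
    implant_pose: RigidTransform,
    rng: np.random.Generator,
) -> tuple[ImageVolume, LabelVolume]:
    """Render one volume with the bone and implant at the given world poses."""
    flat = centers.reshape(-1, 3)
    q_bone = bone_pose.inverse().apply(flat).reshape(centers.shape)
    q_impl = implant_pose.inverse().apply(flat).reshape(centers.shape)

    d_impl, d_bone, d_trab = _scene_signed_distances(q_bone, q_impl, spec)

    # Labels from hard voxel-center occupancy, independent of edge model.
    implant = d_impl <= 0
    bone_inside = d_bone <= 0
    trabecular = d_trab <= 0
    cortical = bone_inside & ~trabecular
    if np.any(implant & bone_inside):
        raise ValueError("implant and bone solids overlap; increase carve_margin_mm or reduce motion")

    # Soft-edge intensity model: tissue means weighted by the erf profile
    # of the signed distance (CT reconstruction PSF stand-in).
    bg = spec.intensity_background
    intensity = (
        bg
        + (spec.intensity_cortical - bg) * _soft_occupancy(d_bone, spec.edge_sigma_mm)
        + (spec.intensity_trabecular - spec.intensity_cortical)
        * _soft_occupancy(d_trab, spec.edge_sigma_mm)
        + (spec.intensity_metal - bg) * _soft_occupancy(d_impl, spec.edge_sigma_mm)
    )

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[trabecular] = LABEL_TRABECULAR
    labels[cortical] = LABEL_CORTICAL
    labels[implant] = LABEL_IMPLANT

    if spec.streak_amplitude != 0.0:
        # Fixed-pattern radial streaks centered on the implant centroid and
        # rigidly attached to the implant pose.
        rel = q_impl - spec.implant_geometry.centroid
        phi = np.arctan2(rel[..., 1], rel[..., 0])
        rho = np.hypot(rel[..., 0], rel[..., 1])
        intensity += (
            spec.streak_amplitude
            * np.cos(spec.streak_spokes * phi)
            * np.exp(-rho / spec.streak_decay_mm)
        )

    if spec.smooth_sigma_mm > 0:
        intensity = gaussian_filter(intensity, sigma=spec.smooth_sigma_mm / spec.spacing_mm)

    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    volume = ImageVolume(grid=intensity, spacing=spec.spacing, origin=spec.origin)
    label_volume = LabelVolume(grid=labels, spacing=spec.spacing, origin=spec.origin)
    return volume, label_volume


def generate_pair(
    spec: PhantomSpec,
) -> tuple[ImageVolume, ImageVolume, LabelVolume, LabelVolume, RigidTransform]:
    """Render the valgus/varus pair and return the ground-truth motion.

    Volume 1 ("valgus") has the bone and implant at identity.  In volume 2
    ("varus") the bone sits at the global repositioning ``G`` and the
    implant at ``G @ S`` where ``S`` is the true screw motion, so the
    implant-relative-to-bone transform in the bone frame of volume 1 is
    exactly ``S`` — the returned truth.  Identical specs (including the
    seed) produce bit-identical outputs.
    """
    centers = _voxel_centers(spec)
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth_transform()
    identity = RigidTransform.identity()
    g = spec.global_motion

    vol1, lab1 = _render(spec, centers, identity, identity, rng)
    vol2, lab2 = _render(spec, centers, g, g @ truth, rng)
    return vol1, vol2, lab1, lab2, truth


def ground_truth_outcome(truth: RigidTransform, implant_mesh) -> DisplacementOutcome:
    """Displacement parameters implied by the true motion and implant mesh.

    ``implant_mesh`` is anything exposing ``vertices`` (an (N, 3) mm
    array); used as the oracle in recovery tests.
    """
    vertices = np.asarray(getattr(implant_mesh, "vertices", implant_mesh), dtype=float)
    if vertices.size == 0:
        raise ValueError("implant mesh has no vertices")
    return displacement_outcome(truth, vertices)


# --- configuration file support (flat key-value YAML) ---------------------

def spec_from_config(path: str | Path) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a flat key-value YAML file.

    Recognised keys mirror the dataclass fields; nested geometry uses
    dotted-prefix flattening, e.g. ``bone.radius_top: 18.0``,
    ``implant.stem_radius: 4.0``, ``true_motion.angle_deg: 2.0``,
    ``global_motion.translation: [1, 0, 0]`` /
    ``global_motion.rotation_deg: [0, 0, 1]``.  Unknown keys raise.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    top: dict = {}
    bone: dict = {}
    implant: dict = {}
    motion: dict = {}
    glob: dict = {}
    for key, value in raw.items():
        if key.startswith("bone."):
            bone[key[5:]] = value
        elif key.startswith("implant."):
            implant[key[8:]] = value
        elif key.startswith("true_motion."):
            motion[key[12:]] = value
        elif key.startswith("global_motion."):
            glob[key[14:]] = value
        elif key == "grid_shape":
            top[key] = tuple(value)
        else:
            top[key] = value
    spec = PhantomSpec(**top)
    if bone:
        spec = replace(spec, bone_geometry=replace(spec.bone_geometry, **bone))
    if implant:
        if "plate_half_extent" in implant:
            implant["plate_half_extent"] = tuple(implant["plate_half_extent"])
        spec = replace(spec, implant_geometry=replace(spec.implant_geometry, **implant))
    if motion:
        for k in ("axis_direction", "axis_point"):
            if k in motion:
                motion[k] = tuple(motion[k])
        spec = replace(spec, true_motion=replace(spec.true_motion, **motion))
    if glob:
        g = RigidTransform.from_euler_deg(
            rotation_deg=glob.get("rotation_deg", (0.0, 0.0, 0.0)),
            translation_mm=glob.get("translation", (0.0, 0.0, 0.0)),
            center=glob.get("center", (0.0, 0.0, 0.0)),
        )
        spec = replace(spec, global_motion=g)
    return spec


def write_pair(spec: PhantomSpec, out_dir: str | Path, *, fmt: str = "nii.gz") -> dict[str, Path]:
    """Generate a pair and write volumes, labels and the truth transform.

    Returns a mapping of artifact names to paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol1, vol2, lab1, lab2, truth = generate_pair(spec)
    paths = {
        "valgus": out / f"valgus.{fmt}",
        "varus": out / f"varus.{fmt}",
        "labels_valgus": out / f"labels_valgus.{fmt}",
        "labels_varus": out / f"labels_varus.{fmt}",
        "truth": out / "truth_transform.txt",
    }
    write_volume(vol1, paths["valgus"])
    write_volume(vol2, paths["varus"])
    write_volume(lab1, paths["labels_valgus"])
    write_volume(lab2, paths["labels_varus"])
    write_transform(truth, paths["truth"])
    return paths
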