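"""Screw-axis kinematics and clinical displacement parameters.

Any rigid displacement is equivalent to a rotation about a unique axis in
space combined with a translation along that same axis (the screw, or
helical, axis).  Given the per-object repositioning matrices estimated by
registration, this module expresses the implant's motion in the bone frame
and summarises it with the three clinically used parameters:

* ``rScrew`` — magnitude of the rotation about the screw axis (degrees);
* ``MTPM``  — maximum total point motion, the largest per-vertex
  displacement over the implant surface mesh (mm);
* ``mTRE``  — mean target registration error, the mean per-vertex
  displacement over the same mesh (mm).

MTPM and mTRE are computed over *all* implant-mesh vertices; no marker
subsets are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volio import RigidTransform

__all__ = [
    "ScrewAxis",
    "DisplacementOutcome",
    "relative_motion",
    "screw_decompose",
    "rscrew",
    "point_displacements",
    "mtpm",
    "mtre",
    "displacement_outcome",
    "heatmap_colors",
]

# Below this rotation magnitude the axis direction is numerically undefined
# and the motion is treated as a pure slide.
_ANGLE_EPSILON_DEG = 1e-7


@dataclass(frozen=True)
class ScrewAxis:
    """Helical-axis parameters of a rigid displacement.

    ``direction`` is a unit vector, ``point_on_axis`` a world-mm point the
    axis passes through, ``angle_deg`` the rotation magnitude in
    ``[0, 180]`` and ``slide_mm`` the translation along the axis (signed).
    """

    direction: np.ndarray
    point_on_axis: np.ndarray
    angle_deg: float
    slide_mm: float

    def to_transform(self) -> RigidTransform:
        """Reconstruct the 4x4 matrix from the four screw parameters."""
        d = np.asarray(self.direction, dtype=float)
        c = np.asarray(self.point_on_axis, dtype=float)
        theta = np.deg2rad(self.angle_deg)
        k = np.array(
            [[0.0, -d[2], d[1]], [d[2], 0.0, -d[0]], [-d[1], d[0], 0.0]]
        )
        r = np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)
        t = (np.eye(3) - r) @ c + self.slide_mm * d
        return RigidTransform.from_rotation_translation(r, t)


@dataclass(frozen=True)
class DisplacementOutcome:
    """The three displacement parameters plus per-vertex magnitudes (mm)."""

    rscrew_deg: float
    mtpm_mm: float
    mtre_mm: float
    per_vertex_mm: np.ndarray


def relative_motion(t_implant: RigidTransform, t_bone: RigidTransform) -> RigidTransform:
    """Implant motion relative to the bone, in the bone frame of the first scan.

    Both inputs are valgus-to-varus repositioning matrices of the same
    scene; the result is ``t_bone^-1 @ t_implant``, which removes the
    shared patient/bone repositioning and leaves only the implant's motion
    with respect to the bone.
    """
    return t_bone.inverse() @ t_implant


def screw_decompose(t: RigidTransform) -> ScrewAxis:
    """Decompose a rigid transform into its screw (helical) axis.

    The rotation angle comes from the trace of the rotation block, the
    axis from the skew-symmetric part (with a symmetric-part fallback near
    180 degrees where the skew part cancels catastrophically), the slide
    is the translation component along the axis, and the axis point solves
    the helical-axis equation so that no off-axis translation remains.
    The decomposition is exact: ``ScrewAxis.to_transform`` reproduces the
    input to machine precision.
    """
    r = t.rotation
    trans = t.translation
    cos_theta = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    # Skew part gives sin(theta) * axis; using atan2 keeps the angle
    # accurate where acos loses precision (near 0 and 180 degrees).
    skew = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    sin_theta = 0.5 * np.linalg.norm(skew)
    theta = np.arctan2(sin_theta, cos_theta)
    angle_deg = float(np.rad2deg(theta))

    if angle_deg < _ANGLE_EPSILON_DEG:
        # Pure slide: direction from the translation when nonzero, else z.
        norm = np.linalg.norm(trans)
        if norm > 0:
            direction = trans / norm
            slide = norm
        else:
            direction = np.array([0.0, 0.0, 1.0])
            slide = 0.0
        return ScrewAxis(direction=direction, point_on_axis=np.zeros(3), angle_deg=0.0, slide_mm=float(slide))

    if angle_deg > 179.0:
        # Near 180 deg the skew part vanishes; R + R^T + (1 - trace) I
        # equals 2(1 - cos)(a a^T) up to O(theta - pi), whose dominant
        # column is parallel to the axis.
        b = r + r.T + (1.0 - np.trace(r)) * np.eye(3)
        col = b[:, int(np.argmax(np.linalg.norm(b, axis=0)))]
        direction = col / np.linalg.norm(col)
        # Fix the sign so the skew part (if any) agrees.
        if sin_theta > 1e-12 and np.dot(skew, direction) < 0:
            direction = -direction
    else:
        direction = skew / (2.0 * sin_theta)
        direction = direction / np.linalg.norm(direction)

    slide = float(np.dot(direction, trans))
    t_perp = trans - slide * direction
    # Helical-axis point: solve (I - R) c = t_perp with c orthogonal to the
    # axis; closed form c = 1/2 (t_perp + (d x t_perp) / tan(theta/2)).
    c = 0.5 * (t_perp + np.cross(direction, t_perp) / np.tan(theta / 2.0))
    return ScrewAxis(direction=direction, point_on_axis=c, angle_deg=angle_deg, slide_mm=slide)


def rscrew(t: RigidTransform) -> float:
    """Rotation magnitude about the screw axis, degrees."""
    return screw_decompose(t).angle_deg


def point_displacements(vertices: np.ndarray, t_rel: RigidTransform) -> np.ndarray:
    """Euclidean displacement ``|t_rel p - p|`` per vertex, mm."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.size == 0:
        raise ValueError("vertex set is empty")
    return np.linalg.norm(t_rel.apply(vertices) - vertices, axis=-1)


def mtpm(per_vertex_mm: np.ndarray) -> float:
    """Maximum total point motion: the largest per-vertex displacement."""
    per_vertex_mm = np.asarray(per_vertex_mm, dtype=float)
    if per_vertex_mm.size == 0:
        raise ValueError("no per-vertex displacements")
    return float(np.max(per_vertex_mm))


def mtre(per_vertex_mm: np.ndarray) -> float:
    """Mean target registration error: the mean per-vertex displacement."""
    per_vertex_mm = np.asarray(per_vertex_mm, dtype=float)
    if per_vertex_mm.size == 0:
        raise ValueError("no per-vertex displacements")
    return float(np.mean(per_vertex_mm))


def displacement_outcome(t_rel: RigidTransform, vertices: np.ndarray) -> DisplacementOutcome:
    """All three displacement parameters for one implant mesh and motion."""
    d = point_displacements(vertices, t_rel)
    return DisplacementOutcome(
        rscrew_deg=rscrew(t_rel),
        mtpm_mm=mtpm(d),
        mtre_mm=mtre(d),
        per_vertex_mm=d,
    )


def heatmap_colors(per_vertex_mm: np.ndarray, *, vmax_mm: float = 0.5) -> np.ndarray:
    """Map displacement magnitudes onto a blue-to-red heatmap.

    Values are clamped to ``[0, vmax_mm]`` and mapped linearly: 0 mm is
    pure blue, ``vmax_mm`` (default 0.5 mm) and above pure red.  Returns
    uint8 RGB, one row per vertex.
    """
    v = np.asarray(per_vertex_mm, dtype=float)
    if np.any(v < 0):
        raise ValueError("displacement magnitudes must be non-negative")
    f = np.clip(v, 0.0, vmax_mm) / vmax_mm
    rgb = np.stack([f, np.zeros_like(f), 1.0 - f], axis=-1)
    return np.round(rgb * 255.0).astype(np.uint8)
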