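"""Surface meshing of masks and grey-level double-contour sampling.

A polygon mesh is extracted from each segmentation mask with the Marching
Cubes algorithm; the mesh vertices then serve as the registration
template.  For intensity-based refinement a *double contour* is sampled
from the reference (valgus) scan: grey values at +0.3 mm and -0.3 mm along
the outward vertex normal.  The paired inner/outer values straddle the
object boundary and anchor the correlation objective of the point-to-image
registration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.ndimage import map_coordinates
from skimage.measure import marching_cubes

from .volio import ImageVolume, LabelVolume

__all__ = [
    "TriMesh",
    "DoubleContour",
    "extract_mesh",
    "sample_double_contour",
    "trilinear_sample",
    "save_mesh",
]


@dataclass
class TriMesh:
    """Triangulated surface in world mm with outward unit vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a vertex out of range")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def to_trimesh(self, vertex_colors: np.ndarray | None = None) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(
            vertices=self.vertices,
            faces=self.faces,
            vertex_normals=self.vertex_normals,
            vertex_colors=vertex_colors,
            process=False,
        )

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


@dataclass
class DoubleContour:
    """Mesh vertices with grey values sampled at +/- ``offset_mm`` along normals.

    ``ref_outer`` holds the reference-scan grey values at
    ``base + offset * normal`` (outside the object), ``ref_inner`` at
    ``base - offset * normal`` (inside).  ``n_dropped`` counts vertices
    discarded because a sample fell outside the reference volume.
    """

    base_points: np.ndarray
    normals: np.ndarray
    offset_mm: float
    ref_outer: np.ndarray
    ref_inner: np.ndarray
    n_dropped: int = 0

    def __post_init__(self) -> None:
        n = len(self.base_points)
        if not (len(self.normals) == len(self.ref_outer) == len(self.ref_inner) == n):
            raise ValueError("double-contour arrays must have equal length")
        if self.offset_mm <= 0:
            raise ValueError("offset_mm must be positive")

    def __len__(self) -> int:
        return len(self.base_points)

    @property
    def reference_values(self) -> np.ndarray:
        """Inner and outer grey values concatenated (the template vector)."""
        return np.concatenate([self.ref_inner, self.ref_outer])


def _area_weighted_vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Vertex normals as the normalised sum of adjacent face-area vectors."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    face_vec = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * area
    normals = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(normals, faces[:, i], face_vec)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


def extract_mesh(mask: LabelVolume, label: int = 1) -> TriMesh:
    """Marching-cubes mesh of the ``label`` region, in world mm.

    The binary indicator is padded by one background voxel so meshes from
    masks touching the grid boundary stay closed, and contoured at
    iso-level 0.5.  Vertex normals are area-weighted face normals with the
    outward orientation verified against the mask interior (normals point
    from the labelled region toward background).
    """
    indicator = (mask.grid == label).astype(np.float32)
    if not indicator.any():
        raise ValueError(f"label {label} absent from mask")
    padded = np.pad(indicator, 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    # Undo the one-voxel pad, then move into world coordinates.
    verts = verts - mask.spacing + mask.origin
    normals = _area_weighted_vertex_normals(verts, faces)

    # Outward check: the indicator should be lower a little way along the
    # normal than against it.
    probe = 0.25 * float(np.min(mask.spacing))
    outside = _sample_indicator(padded, mask, verts + probe * normals)
    inside = _sample_indicator(padded, mask, verts - probe * normals)
    if outside.mean() > inside.mean():
        normals = -normals
        faces = faces[:, ::-1]
    return TriMesh(vertices=verts, faces=faces, vertex_normals=normals)


def _sample_indicator(padded: np.ndarray, mask: LabelVolume, points: np.ndarray) -> np.ndarray:
    idx = (points - mask.origin) / mask.spacing + 1.0  # +1 for the pad
    return map_coordinates(padded, idx.T, order=1, mode="constant", cval=0.0)


def trilinear_sample(volume: ImageVolume, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of ``volume`` at world-mm ``points``.

    Returns ``(values, valid)`` where ``valid`` flags points whose
    fractional index lies fully inside the grid; values of invalid points
    are 0 and must not be used.
    """
    idx = volume.world_to_index(points)
    upper = np.asarray(volume.grid.shape) - 1
    valid = np.all((idx >= 0) & (idx <= upper), axis=-1)
    values = map_coordinates(volume.grid.astype(float), idx.T, order=1, mode="constant", cval=0.0)
    return values, valid


def sample_double_contour(
    mesh: TriMesh,
    reference: ImageVolume,
    offset_mm: float = 0.3,
) -> DoubleContour:
    """Sample the double contour of ``mesh`` in the reference volume.

    Grey values are read by trilinear interpolation at
    ``vertex +/- offset_mm * normal``.  Vertices whose inner or outer
    sample falls outside the volume are dropped (never clamped) and
    counted in ``n_dropped``.
    """
    if len(mesh) == 0:
        raise ValueError("mesh has no vertices")
    outer_pts = mesh.vertices + offset_mm * mesh.vertex_normals
    inner_pts = mesh.vertices - offset_mm * mesh.vertex_normals
    outer, ok_outer = trilinear_sample(reference, outer_pts)
    inner, ok_inner = trilinear_sample(reference, inner_pts)
    keep = ok_outer & ok_inner
    if not keep.any():
        raise ValueError("all double-contour sample points fall outside the reference volume")
    return DoubleContour(
        base_points=mesh.vertices[keep],
        normals=mesh.vertex_normals[keep],
        offset_mm=offset_mm,
        ref_outer=outer[keep],
        ref_inner=inner[keep],
        n_dropped=int(len(mesh) - keep.sum()),
    )


def save_mesh(mesh: TriMesh, path: str | Path, vertex_colors: np.ndarray | None = None) -> None:
    """Export a mesh as PLY (optionally with per-vertex RGB) or STL."""
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".stl"):
        raise ValueError(f"unsupported mesh format {path.suffix!r}; use .ply or .stl")
    mesh.to_trimesh(vertex_colors=vertex_colors).export(path)
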