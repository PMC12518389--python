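"""Volume and transform containers plus file I/O.

World-coordinate convention used throughout the package:

* Volumes are scalar grids indexed ``grid[i, j, k]`` where axis 0 maps to
  world x, axis 1 to world y and axis 2 to world z.
* Voxel *centers* anchor the index-to-world map: the world position of
  voxel index ``v`` is ``origin + v * spacing`` (mm).  Indices are 0-based.
* No direction-cosine rotation is supported; files carrying a non-identity
  direction matrix are rejected rather than silently reinterpreted.

Meshes, contours and rigid transforms all live in world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "RigidTransform",
    "LABEL_BACKGROUND",
    "LABEL_IMPLANT",
    "LABEL_CORTICAL",
    "LABEL_TRABECULAR",
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
]

#: Label codes shared by every mask in the pipeline.
LABEL_BACKGROUND = 0
LABEL_IMPLANT = 1
LABEL_CORTICAL = 2
LABEL_TRABECULAR = 3

_VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_IMPLANT, LABEL_CORTICAL, LABEL_TRABECULAR})

_VOLUME_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with axis-aligned world geometry.

    Parameters
    ----------
    grid
        3-D array of intensities (dimensionless, HU-like).
    spacing
        Per-axis voxel size in mm; all components must be positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    grid: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def same_geometry(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return (
            self.grid.shape == other.grid.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelVolume(ImageVolume):
    """An integer mask grid aligned to an :class:`ImageVolume`.

    Codes: 0 = background, 1 = implant, 2 = cortical bone, 3 = trabecular
    bone.  Binary masks from region growing use 0/1.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        present = set(np.unique(self.grid).tolist())
        if not present <= _VALID_LABELS:
            raise ValueError(f"unknown label codes present: {sorted(present - _VALID_LABELS)}")


class RigidTransform:
    """A 4x4 homogeneous rigid transform acting on world-mm column vectors.

    The upper-left 3x3 block must be orthonormal with determinant +1 and
    the last row ``(0, 0, 0, 1)``.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray, *, atol: float = 1e-6):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 matrix, got shape {m.shape}")
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=atol):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block has determinant -1 (reflection rejected)")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=atol):
            raise ValueError("last row must be (0, 0, 0, 1)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def from_euler_deg(
        cls,
        rotation_deg: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
        translation_mm: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
        center: np.ndarray | tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Rigid transform from intrinsic XYZ Euler angles (degrees) about
        ``center``, followed by a translation in mm."""
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("XYZ", np.asarray(rotation_deg, dtype=float), degrees=True).as_matrix()
        center = np.asarray(center, dtype=float)
        t = np.asarray(translation_mm, dtype=float) + center - r @ center
        return cls.from_rotation_translation(r, t)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (N, 3) array (or a single point)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self @ other`` (apply ``other`` first, then ``self``)."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        m = np.eye(4)
        m[:3, :3] = rt
        m[:3, 3] = -rt @ self.translation
        return RigidTransform(m)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(\n{np.array_str(self.matrix, precision=6, suppress_small=True)}\n)"


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _VOLUME_EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path.name!r}; expected one of {_VOLUME_EXTENSIONS}"
        )


def read_volume(path: str | Path, *, as_labels: bool = False) -> ImageVolume:
    """Read a NIfTI or MetaImage volume.

    Returns an :class:`ImageVolume` (or :class:`LabelVolume` when
    ``as_labels``) with spacing/origin taken from the header.  Files with a
    non-identity direction matrix are rejected: the package's axis-aligned
    world convention cannot represent them.
    """
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path.name}: non-identity direction matrix is not supported "
            "(axis-aligned volumes only)"
        )
    # SimpleITK arrays come back index-ordered [z, y, x]; transpose to [x, y, z].
    grid = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    cls = LabelVolume if as_labels else ImageVolume
    if as_labels and not np.issubdtype(grid.dtype, np.integer):
        grid = grid.astype(np.int16)
    return cls(grid=grid, spacing=spacing, origin=origin)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Label volumes keep their integer dtype on disk.
    """
    path = Path(path)
    _check_extension(path)
    grid = volume.grid
    if isinstance(volume, LabelVolume):
        grid = grid.astype(np.int16, copy=False)
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:  # unwritable directory etc.
        raise OSError(f"could not write volume to {path}: {exc}") from exc


def read_transform(path: str | Path) -> RigidTransform:
    """Read a 4x4 rigid transform from a whitespace-separated text file."""
    values = np.loadtxt(path, dtype=float)
    if values.size != 16:
        raise ValueError(f"{path}: expected 16 numbers, got {values.size}")
    return RigidTransform(values.reshape(4, 4))


def write_transform(transform: RigidTransform, path: str | Path) -> None:
    """Write a 4x4 transform as plain text, row-major, full precision."""
    np.savetxt(path, transform.matrix, fmt="%.17g")
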