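"""Threshold-based region growing, mask post-processing and overlap metrics.

The semi-automatic segmentation of the clinical workflow is a seeded,
threshold-based region growing: the user places a seed inside the implant
(or cortex) and the mask is the connected component of the thresholded
volume containing that seed.  Post-processing keeps the largest connected
component per class and carves a safety margin out of the bone mask around
the implant so the two surfaces cannot interfere during registration.

Dice and HD95 evaluate mask agreement.  HD95 here is the 95th percentile
(linear-interpolation percentile) of the *pooled* symmetric set of
surface-voxel nearest-neighbour distances — variants of HD95 differ across
tools, so the definition is fixed and documented.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volio import ImageVolume, LabelVolume

__all__ = [
    "region_grow",
    "largest_component",
    "carve_margin",
    "dice",
    "hd95",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def region_grow(
    volume: ImageVolume,
    seed: tuple[int, int, int],
    low: float,
    high: float = math.inf,
    connectivity: int = 26,
) -> LabelVolume:
    """Grow a binary mask from ``seed`` over voxels with intensity in [low, high].

    The result is the connected component (under the stated connectivity)
    of the thresholded volume that contains the seed; deterministic, and
    invariant to the choice of seed within that component.
    """
    if low >= high:
        raise ValueError(f"threshold range requires low < high, got [{low}, {high}]")
    seed = tuple(int(s) for s in seed)
    shape = volume.grid.shape
    if len(seed) != 3 or any(s < 0 or s >= n for s, n in zip(seed, shape)):
        raise IndexError(f"seed {seed} outside grid of shape {shape}")
    value = volume.grid[seed]
    if not (low <= value <= high):
        raise ValueError(
            f"seed intensity {value} outside threshold range [{low}, {high}]"
        )
    in_range = (volume.grid >= low) & (volume.grid <= high)
    components, _ = ndimage.label(in_range, structure=_structure(connectivity))
    mask = components == components[seed]
    return LabelVolume(grid=mask.astype(np.int16), spacing=volume.spacing, origin=volume.origin)


def largest_component(mask: LabelVolume, label: int = 1, connectivity: int = 26) -> LabelVolume:
    """Keep only the largest connected component of ``label``.

    Other labels are untouched.  Ties between equally sized components are
    broken in favour of the component containing the smallest linear voxel
    index (C-order), which makes the operation deterministic.
    """
    selected = mask.grid == label
    if not selected.any():
        raise ValueError(f"label {label} absent from mask")
    components, n = ndimage.label(selected, structure=_structure(connectivity))
    sizes = np.bincount(components.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if len(candidates) > 1:
        # First occurrence in C-order decides the tie.
        flat = components.ravel()
        first = {c: np.argmax(flat == c) for c in candidates}
        winner = min(candidates, key=lambda c: first[c])
    else:
        winner = candidates[0]
    out = mask.grid.copy()
    out[selected & (components != winner)] = 0
    return LabelVolume(grid=out, spacing=mask.spacing, origin=mask.origin)


def _ball_structure(radius_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Spherical (in world mm) structuring element on the voxel grid.

    Per-axis voxel radius is ``ceil(radius_mm / spacing)``; a voxel offset
    belongs to the ball when its world-mm distance from the center is
    within the voxel-radius ball scaled back to mm per axis.
    """
    r_vox = np.ceil(radius_mm / np.asarray(spacing)).astype(int)
    grids = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    dist2 = sum((g / r) ** 2 for g, r in zip(grids, r_vox))
    return dist2 <= 1.0


def carve_margin(
    bone_mask: LabelVolume,
    implant_mask: LabelVolume,
    radius_mm: float = 3.0,
) -> LabelVolume:
    """Remove bone voxels inside a dilation of the implant mask.

    The implant mask is dilated with a spherical structuring element of
    per-axis radius ``ceil(radius_mm / spacing)`` voxels and the overlap is
    carved out of the bone mask, leaving a clean margin at the
    bone-implant interface.  The implant mask is never modified and no
    voxels are ever added to the bone mask.
    """
    if not bone_mask.same_geometry(implant_mask):
        raise ValueError("bone and implant masks must share shape, spacing and origin")
    structure = _ball_structure(radius_mm, bone_mask.spacing)
    dilated = ndimage.binary_dilation(implant_mask.grid > 0, structure=structure)
    out = bone_mask.grid.copy()
    out[dilated] = 0
    return LabelVolume(grid=out, spacing=bone_mask.spacing, origin=bone_mask.origin)


def dice(a: LabelVolume, b: LabelVolume, label: int = 1) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)`` for ``label``.

    Two empty masks agree perfectly by convention: returns 1.0.
    """
    if a.grid.shape != b.grid.shape:
        raise ValueError("masks must share shape")
    sa = a.grid == label
    sb = b.grid == label
    denom = int(sa.sum()) + int(sb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((sa & sb).sum()) / denom


def _surface_points_mm(selected: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """World-mm coordinates (origin-free) of surface voxels of a binary mask.

    A voxel is on the surface when at least one 6-neighbour lies outside
    the mask (or it touches the grid boundary).
    """
    eroded = ndimage.binary_erosion(
        selected, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surface = selected & ~eroded
    return np.argwhere(surface) * spacing


def hd95(a: LabelVolume, b: LabelVolume, label: int = 1) -> float:
    """95th-percentile symmetric surface distance between two masks, mm.

    Surface voxels of each mask are matched to their nearest surface voxel
    of the other mask; the A-to-B and B-to-A distances are pooled and the
    95th percentile (linear interpolation) of the pooled set is returned.
    Translation of the shared origin does not affect the result.
    """
    if a.grid.shape != b.grid.shape or not np.allclose(a.spacing, b.spacing):
        raise ValueError("masks must share shape and spacing")
    sa = a.grid == label
    sb = b.grid == label
    if not sa.any() or not sb.any():
        raise ValueError(f"label {label} must be present in both masks")
    pa = _surface_points_mm(sa, a.spacing)
    pb = _surface_points_mm(sb, b.spacing)
    d_ab, _ = cKDTree(pb).query(pa, workers=-1)
    d_ba, _ = cKDTree(pa).query(pb, workers=-1)
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95.0))
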