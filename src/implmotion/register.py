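"""Rigid registration: ICP rough alignment and grey-level point-to-image refinement.

Each object (implant, tibia) is registered from the valgus scan to the
varus scan in two stages.  First the valgus implant mesh is roughly
aligned onto the varus implant mesh with Iterative Closest Point (the
tibia starts from identity).  Then the double-contour grey values sampled
in the valgus scan are registered to the varus scan by maximising the
Pearson correlation between the contour's reference grey values and the
values trilinearly sampled at the transformed point locations.  The search
space has six parameters — three translations (mm) and three rotations
(degrees, about the contour centroid) — explored with the derivative-free
Nelder-Mead downhill simplex, stopped when the simplex objective spread
falls below a tolerance or a maximum number of iterations is reached.

Pearson correlation is invariant to any positive affine rescaling of the
target intensities, which makes the objective insensitive to global
brightness/contrast differences between the two scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .surface import DoubleContour, TriMesh, sample_double_contour, trilinear_sample
from .volio import ImageVolume, RigidTransform

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "icp_align",
    "point_to_image",
    "register_object",
]


@dataclass
class RegistrationOptions:
    """Knobs of the point-to-image stage.

    ``initial_step_translation`` / ``initial_step_rotation`` set the edge
    lengths of the starting simplex (mm and degrees); the optimiser is
    restarted once from the found optimum with steps divided by 10.
    ``rotation_center`` defaults to the contour centroid, which largely
    decorrelates the rotation and translation parameters for the simplex.
    Candidates that push more than ``max_dropped_fraction`` of the contour
    points out of the target volume are penalised with correlation -1.
    """

    max_iterations: int = 500
    correlation_tolerance: float = 1e-6
    initial_step_translation: float = 1.0
    initial_step_rotation: float = 1.0
    rotation_center: np.ndarray | None = None
    min_correlation: float = 0.5
    max_dropped_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.correlation_tolerance <= 0:
            raise ValueError("correlation_tolerance must be positive")


@dataclass
class RegistrationResult:
    """Per-object repositioning matrix with optimisation diagnostics."""

    transform: RigidTransform
    final_correlation: float
    iterations_used: int
    converged: bool


def icp_align(
    source: TriMesh,
    target: TriMesh,
    max_iter: int = 50,
    tol_mm: float = 1e-6,
) -> RigidTransform:
    """Iterative Closest Point rigid alignment of two vertex clouds.

    Alternates nearest-neighbour correspondence with the least-squares
    rigid update (orthogonal Procrustes via SVD) until the mean
    correspondence distance changes by less than ``tol_mm``.  Returns the
    source-to-target transform.
    """
    src = np.asarray(source.vertices, dtype=float)
    tgt = np.asarray(target.vertices, dtype=float)
    for pts, name in ((src, "source"), (tgt, "target")):
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
            raise ValueError(f"{name} mesh is degenerate (needs >= 3 non-collinear vertices)")
    tree = cKDTree(tgt)
    current = RigidTransform.identity()
    prev_mean = np.inf
    moved = src
    for _ in range(max_iter):
        dist, nn = tree.query(moved, workers=-1)
        mean_dist = float(dist.mean())
        if abs(prev_mean - mean_dist) < tol_mm:
            break
        prev_mean = mean_dist
        corr = tgt[nn]
        update = _procrustes(moved, corr)
        current = update @ current
        moved = current.apply(src)
    return current


def _procrustes(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping point set ``a`` onto ``b``."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(r, cb - r @ ca)


def _params_to_transform(params: np.ndarray, center: np.ndarray) -> RigidTransform:
    return RigidTransform.from_euler_deg(
        rotation_deg=params[3:6], translation_mm=params[0:3], center=center
    )


def point_to_image(
    contour: DoubleContour,
    target: ImageVolume,
    init: RigidTransform | None = None,
    options: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Refine a rigid transform by correlating contour grey values with the target.

    The objective is the Pearson correlation between the contour's
    reference grey values (inner and outer concatenated) and the grey
    values trilinearly sampled in ``target`` at the transformed point
    locations.  Points leaving the target volume are dropped pairwise with
    their reference partners.  The returned transform is the best
    six-parameter perturbation composed with ``init`` and never scores a
    lower correlation than ``init`` itself.
    """
    init = init or RigidTransform.identity()
    options = options or RegistrationOptions()
    ref = contour.reference_values
    if np.std(ref) <= 1e-10 * max(1.0, float(np.abs(ref).mean())):
        raise ValueError("contour reference grey values are constant; correlation undefined")
    center = (
        np.asarray(options.rotation_center, dtype=float)
        if options.rotation_center is not None
        else contour.base_points.mean(axis=0)
    )
    inner_pts = contour.base_points - contour.offset_mm * contour.normals
    outer_pts = contour.base_points + contour.offset_mm * contour.normals
    points = np.concatenate([inner_pts, outer_pts])
    n = len(contour)

    def objective(params: np.ndarray) -> float:
        total = _params_to_transform(params, center) @ init
        values, valid = trilinear_sample(target, total.apply(points))
        keep = valid[:n] & valid[n:]
        if keep.mean() < 1.0 - options.max_dropped_fraction:
            return 1.0  # correlation -1: candidate mostly out of bounds
        kept = np.concatenate([keep, keep])
        v = values[kept]
        r = ref[kept]
        if np.std(v) == 0 or np.std(r) == 0:
            return 1.0
        return -float(np.corrcoef(r, v)[0, 1])

    steps = np.array(
        [options.initial_step_translation] * 3 + [options.initial_step_rotation] * 3
    )
    x = np.zeros(6)
    iterations = 0
    converged = False
    for scale in (1.0, 0.1):  # one restart from the optimum with steps / 10
        simplex = np.vstack([x, x + np.diag(steps * scale)])
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxiter": options.max_iterations,
                "fatol": options.correlation_tolerance,
                "xatol": 1e-6,
            },
        )
        x = res.x
        iterations += int(res.nit)
        converged = bool(res.success)

    best = objective(x)
    if objective(np.zeros(6)) <= best:
        # Never return a transform scoring below the initial one.
        x = np.zeros(6)
        best = objective(x)
    correlation = -best
    return RegistrationResult(
        transform=_params_to_transform(x, center) @ init,
        final_correlation=correlation,
        iterations_used=iterations,
        converged=converged and correlation >= options.min_correlation,
    )


def register_object(
    mesh: TriMesh,
    reference: ImageVolume,
    target: ImageVolume,
    target_mesh_for_init: TriMesh | None = None,
    options: RegistrationOptions | None = None,
    offset_mm: float = 0.3,
) -> RegistrationResult:
    """Full per-object stage: optional ICP init, double contour, refinement.

    Run once for the implant (with the varus implant mesh as ICP init
    target) and once for the tibia (identity init).  The reference volume
    is the scan the mesh was segmented from (valgus); the target is the
    other scan (varus).
    """
    init = (
        icp_align(mesh, target_mesh_for_init)
        if target_mesh_for_init is not None
        else RigidTransform.identity()
    )
    contour = sample_double_contour(mesh, reference, offset_mm=offset_mm)
    return point_to_image(contour, target, init=init, options=options)
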