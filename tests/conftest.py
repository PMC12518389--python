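"""Shared fixtures: desk-scale phantom specs sized for fast unit tests.

The small phantom keeps the full scene structure (elliptical tapered bone
with cortical shell, plate-plus-stem implant, carved margin) in a 64-voxel
cube so that rendering and registration run in seconds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from implmotion.phantom import BoneGeometry, ImplantGeometry, PhantomSpec, ScrewMotion, generate_pair
from implmotion.volio import LabelVolume, RigidTransform, LABEL_IMPLANT


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A 64^3 phantom with scaled-down scene geometry (28.8 mm cube)."""
    base = dict(
        grid_shape=(64, 64, 64),
        spacing_mm=0.45,
        bone_geometry=BoneGeometry(
            z_bottom=-11.0,
            z_top=2.0,
            radius_bottom=6.5,
            radius_top=9.0,
            aspect_ratio=0.75,
            cortical_thickness_mm=1.5,
        ),
        implant_geometry=ImplantGeometry(
            plate_half_extent=(8.0, 8.0, 1.0),
            plate_center_z=3.6,
            stem_radius=2.0,
            stem_z_top=3.0,
            stem_z_bottom=-6.0,
        ),
        carve_margin_mm=1.2,
        noise_sd=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def binary_label(mask: LabelVolume, label: int = LABEL_IMPLANT) -> LabelVolume:
    return LabelVolume(
        grid=(mask.grid == label).astype(np.int16), spacing=mask.spacing, origin=mask.origin
    )


@pytest.fixture(scope="session")
def still_pair():
    """Noise-free small phantom pair with no motion at all."""
    return generate_pair(small_phantom_spec())


@pytest.fixture(scope="session")
def offset_pair():
    """Noise-free small pair with a known global scene offset only."""
    g = RigidTransform.from_euler_deg(rotation_deg=(0.0, 0.0, 1.0), translation_mm=(1.0, 0.0, 0.0))
    spec = small_phantom_spec(global_motion=g)
    return spec, generate_pair(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 180.0, max_trans: float = 10.0) -> RigidTransform:
    """Uniform-ish random rigid transform for property tests."""
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, np.deg2rad(max_angle_deg))
    r = Rotation.from_rotvec(angle * axis).as_matrix()
    t = rng.uniform(-max_trans, max_trans, 3)
    return RigidTransform.from_rotation_translation(r, t)
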