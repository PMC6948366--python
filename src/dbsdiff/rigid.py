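"""Rigid (6-parameter) transforms and trilinear volume resampling.

Coordinate convention: 0-based voxel indices; world (mm) coordinates are
``index × voxel_size`` with no oblique affine.  Rotations are extrinsic
x-y-z Euler rotations in degrees about the grid centre.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Head motion as translation (mm) and rotation (degrees about x/y/z)."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "rotation_deg", np.asarray(self.rotation_deg, dtype=float).reshape(3)
        )

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @property
    def is_identity(self) -> bool:
        return bool(
            np.all(np.abs(self.translation) < 1e-12)
            and np.all(np.abs(self.rotation_deg) < 1e-12)
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation_deg])

    @classmethod
    def from_params(cls, p: np.ndarray) -> "RigidTransform":
        p = np.asarray(p, dtype=float).reshape(6)
        return cls(p[:3], p[3:])


def grid_center_mm(shape, voxel_size) -> np.ndarray:
    shape = np.asarray(shape, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float)
    return (shape - 1.0) / 2.0 * voxel_size


def apply_rigid(points_mm: np.ndarray, transform: RigidTransform, center_mm: np.ndarray) -> np.ndarray:
    """Forward-map world points p ↦ R(p − c) + c + t."""
    R = transform.matrix
    return (points_mm - center_mm) @ R.T + center_mm + transform.translation


def resample_moved(volume: np.ndarray, transform: RigidTransform, voxel_size) -> np.ndarray:
    """Resample ``volume`` as observed after head motion ``transform``.

    The observed image is v_obs(x) = v(R⁻¹(x − c − t) + c); trilinear
    interpolation, zero padding outside the grid.
    """
    return _resample(volume, transform, voxel_size, inverse=True)


def resample_corrected(volume: np.ndarray, transform: RigidTransform, voxel_size) -> np.ndarray:
    """Undo head motion ``transform``: v_corr(x) = v_obs(R(x − c) + c + t)."""
    return _resample(volume, transform, voxel_size, inverse=False)


def _resample(volume, transform, voxel_size, inverse):
    vs = np.asarray(voxel_size, dtype=float).reshape(3)
    c = grid_center_mm(volume.shape, vs)
    R = transform.matrix
    t = transform.translation
    if inverse:
        # sample at R⁻¹(S x − c − t) + c, i.e. voxel-space matrix S⁻¹ R⁻¹ S
        M = (R.T * vs[None, :]) / vs[:, None]
        offset = (R.T @ (-c - t) + c) / vs
    else:
        # sample at R(S x − c) + c + t, i.e. voxel-space matrix S⁻¹ R S
        M = (R * vs[None, :]) / vs[:, None]
        offset = (R @ (-c) + c + t) / vs
    return ndimage.affine_transform(
        volume, matrix=M, offset=offset, order=1, mode="constant", cval=0.0
    )


def random_rigid_transforms(
    n: int,
    max_translation_mm: float,
    max_rotation_deg: float,
    rng: np.random.Generator,
) -> list[RigidTransform]:
    """Draw ``n`` independent rigid transforms, uniform in each component."""
    out = []
    for _ in range(n):
        t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
        r = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
        out.append(RigidTransform(t, r))
    return out
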