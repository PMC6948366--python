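"""Diffusion gradient tables and FSL-dialect bval/bvec text I/O.

A gradient table holds one diffusion weighting *b* (s/mm²) and one unit
direction *g* per acquired volume.  Volumes with b = 0 carry no diffusion
weighting and conventionally a zero direction vector.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class GradientTable:
    """Per-volume b-values (s/mm²) and unit gradient directions.

    Invariants enforced at construction: all b-values are non-negative, at
    least one volume is a b0 (b = 0), and every nonzero direction vector has
    Euclidean norm 1 within 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.size} b-values"
            )
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(bvals == 0):
            raise ValueError("gradient table must contain at least one b0 volume")
        norms = np.linalg.norm(bvecs, axis=1)
        nonzero = norms > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > _UNIT_TOL):
            raise ValueError("nonzero gradient directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def b0_index(self) -> int:
        """Index of the first b0 volume (the registration reference)."""
        return int(np.argmax(self.b0_mask))

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    def rotated(self, rotations: np.ndarray) -> "GradientTable":
        """Return a table with per-volume rotation matrices applied to bvecs.

        ``rotations`` has shape (n_volumes, 3, 3); each direction g_v is
        replaced by R_v @ g_v.  Norms are preserved by construction.
        """
        rotations = np.asarray(rotations, dtype=float)
        if rotations.shape != (self.n_volumes, 3, 3):
            raise ValueError("need one 3x3 rotation per volume")
        new = np.einsum("vij,vj->vi", rotations, self.bvecs)
        return GradientTable(self.bvals.copy(), new)


def read_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL-style bval/bvec text files (bvecs as 3 rows × N columns)."""
    bvals = np.loadtxt(bval_path, ndmin=1)
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # Ambiguous square case: FSL convention is rows = x/y/z components.
        bvecs = bvecs.T
    return GradientTable(bvals, bvecs)


def save_bvals_bvecs(
    table: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL-style bval (one row) and bvec (3 rows × N) text files."""
    np.savetxt(bval_path, table.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, table.bvecs.T, fmt="%.8f")


def _sphere_spiral(n: int) -> np.ndarray:
    """Near-uniform points on the unit sphere via the golden-angle spiral."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def electrostatic_directions(n: int, iterations: int = 300, step: float = 0.02) -> np.ndarray:
    """Antipodally-symmetric electrostatic-repulsion direction scheme.

    Starts from a golden-angle spiral and relaxes pairwise 1/r² repulsion
    acting on both a point and its antipode (gradient directions are axes,
    not vectors).  Deterministic: no random state involved.
    """
    pts = _sphere_spiral(n)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    for _ in range(iterations):
        force = np.zeros_like(pts)
        for sign in (1.0, -1.0):
            diff = pts[:, None, :] - sign * pts[None, :, :]
            dist2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sign < 0:
                dist2[dist2 < 1e-12] = np.inf  # a point vs its own antipode
            force += np.sum(diff / (dist2[..., None] ** 1.5 + 1e-12), axis=1)
        # tangential component only, with a capped step for stability
        force -= np.sum(force * pts, axis=1, keepdims=True) * pts
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        force = np.where(norm > 1.0, force / norm, force)
        pts = pts + step * force
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_scheme(n_directions: int = 32, b: float = 800.0, n_b0: int = 1) -> GradientTable:
    """Default single-shell acquisition: ``n_b0`` b0 volumes followed by
    ``n_directions`` electrostatically spread directions at b-value ``b``."""
    dirs = electrostatic_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientTable(bvals, bvecs)
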