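"""Voxel-wise diffusion tensor estimation and FA/MD/RD scalar maps.

The estimator is weighted log-linear least squares (weights = squared
signal), which is deterministic, needs no iteration, and is exact on
noiseless single-tensor data.  Scalars follow the standard eigenvalue
formulas with λ1 ≥ λ2 ≥ λ3:

    MD = (λ1 + λ2 + λ3) / 3
    RD = (λ2 + λ3) / 2
    FA = sqrt(3/2) · ‖λ − λ̄‖ / ‖λ‖        (dimensionless, in [0, 1])
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dwi import DWIVolume, save_nifti

SCALAR_KINDS = ("fa", "md", "rd")


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor as sorted eigenvalues (mm²/s,
    descending) and orthonormal eigenvectors (columns of ``evecs``)."""

    evals: np.ndarray        # (x, y, z, 3), λ1 ≥ λ2 ≥ λ3
    evecs: np.ndarray        # (x, y, z, 3, 3); evecs[..., :, i] pairs with evals[..., i]
    valid: np.ndarray        # (x, y, z) bool: brain voxels with a successful fit
    clamped: np.ndarray      # (x, y, z) bool: negative eigenvalues clamped to 0
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    @property
    def shape(self):
        return self.valid.shape


@dataclass
class ScalarMap:
    """One diffusion scalar map (FA dimensionless; MD/RD in mm²/s)."""

    kind: str
    values: np.ndarray
    valid: np.ndarray
    units: str
    session: str = ""
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def masked_values(self, roi_mask: np.ndarray | None = None) -> np.ndarray:
        m = self.valid if roi_mask is None else (self.valid & roi_mask)
        return self.values[m]

    def save(self, path: str | Path) -> None:
        save_nifti(self.values, self.voxel_size, path, dtype=np.float32)


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """Weighted log-linear least-squares tensor fit over the brain mask.

    Voxels with non-positive b0 signal or all-zero signal are marked invalid
    rather than raising; signal values ≤ 0 elsewhere are floored at machine
    epsilon times the voxel's b0 before the log transform (Rician magnitude
    data cannot be log-transformed at zero).  Negative eigenvalues are
    clamped to zero and the voxel flagged.
    """
    if dwi.n_volumes < 7:
        raise ValueError("tensor fit needs at least 7 volumes (6 directions + b0)")
    mask = dwi.brain_mask
    shape = dwi.spatial_shape

    S = dwi.signal[mask]                      # (V, N)
    b0 = S[:, dwi.b0_index]
    fittable = (b0 > 0) & np.any(S > 0, axis=1)

    X = _design_matrix(dwi.gradients.bvals, dwi.gradients.bvecs)   # (N, 7)
    evals_flat = np.zeros((S.shape[0], 3))
    evecs_flat = np.tile(np.eye(3), (S.shape[0], 1, 1))
    clamped_flat = np.zeros(S.shape[0], dtype=bool)

    if np.any(fittable):
        Sf = S[fittable]
        floor = np.finfo(float).eps * b0[fittable, None]
        Sf = np.maximum(Sf, floor)
        y = np.log(Sf)
        w = Sf**2
        XtWX = np.einsum("vn,ni,nj->vij", w, X, X)
        XtWy = np.einsum("vn,ni,vn->vi", w, X, y)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]    # (V, 7)
        D = np.empty((beta.shape[0], 3, 3))
        D[:, 0, 0] = beta[:, 1]
        D[:, 1, 1] = beta[:, 2]
        D[:, 2, 2] = beta[:, 3]
        D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
        D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
        D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
        w_evals, w_evecs = np.linalg.eigh(D)  # ascending
        w_evals = w_evals[:, ::-1]
        w_evecs = w_evecs[:, :, ::-1]
        neg = w_evals < 0
        clamped = np.any(neg, axis=1)
        w_evals = np.where(neg, 0.0, w_evals)
        evals_flat[fittable] = w_evals
        evecs_flat[fittable] = w_evecs
        clamped_flat[fittable] = clamped

    evals = np.zeros(shape + (3,))
    evecs = np.tile(np.eye(3), shape + (1, 1))
    valid = np.zeros(shape, dtype=bool)
    clamped_map = np.zeros(shape, dtype=bool)
    evals[mask] = evals_flat
    evecs[mask] = evecs_flat
    valid[mask] = fittable
    clamped_map[mask] = clamped_flat
    return TensorField(
        evals=evals, evecs=evecs, valid=valid, clamped=clamped_map,
        voxel_size=dwi.voxel_size,
    )


def scalar_map(tensors: TensorField, kind: str, session: str = "") -> ScalarMap:
    """Compute an FA, MD or RD map from a fitted tensor field."""
    kind = kind.lower()
    if kind not in SCALAR_KINDS:
        raise ValueError(f"unknown scalar kind '{kind}' (expected one of {SCALAR_KINDS})")
    ev = tensors.evals
    if kind == "md":
        values = ev.mean(axis=-1)
        units = "mm^2/s"
    elif kind == "rd":
        values = (ev[..., 1] + ev[..., 2]) / 2.0
        units = "mm^2/s"
    else:
        mean = ev.mean(axis=-1, keepdims=True)
        num = np.sqrt(np.sum((ev - mean) ** 2, axis=-1))
        den = np.sqrt(np.sum(ev**2, axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        values = np.clip(values, 0.0, 1.0)
        units = "dimensionless"
    values = np.where(tensors.valid, values, 0.0)
    return ScalarMap(
        kind=kind, values=values, valid=tensors.valid.copy(), units=units,
        session=session, voxel_size=tensors.voxel_size,
    )
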