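"""The in-memory diffusion-weighted session container and NIfTI session I/O.

A session directory mirrors a minimal FSL-style layout::

    session/
      dwi.nii.gz      4D signal (x, y, z, volume)
      bvals, bvecs    FSL-dialect gradient table
      labels.nii.gz   integer ROI labels (optional)
      masks/
        brain.nii.gz, gm.nii.gz, wm.nii.gz, air.nii.gz, [csf|artifact].nii.gz
      truth.json      generator ground truth (synthetic sessions only)
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientTable, read_bvals_bvecs, save_bvals_bvecs

MASK_NAMES = ("brain", "gm", "wm", "air", "csf", "artifact")


@dataclass
class DWIVolume:
    """One diffusion-weighted session: 4D signal plus acquisition metadata.

    ``signal`` is non-negative with shape (x, y, z, n_volumes); the number of
    volumes must equal the gradient-table length; all masks share the spatial
    shape; the gray-matter, white-matter and air masks are mutually disjoint.
    """

    signal: np.ndarray
    gradients: GradientTable
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    session: str = "pre"
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if self.signal.shape[-1] != self.gradients.n_volumes:
            raise ValueError(
                f"{self.signal.shape[-1]} volumes but "
                f"{self.gradients.n_volumes} gradient-table entries"
            )
        self.voxel_size = tuple(float(v) for v in np.asarray(self.voxel_size).reshape(3))
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.spatial_shape:
                raise ValueError(f"mask '{name}' shape {mask.shape} != {self.spatial_shape}")
            self.masks[name] = mask
        for a, b in (("gm", "wm"), ("gm", "air"), ("wm", "air")):
            if a in self.masks and b in self.masks:
                if np.any(self.masks[a] & self.masks[b]):
                    raise ValueError(f"masks '{a}' and '{b}' overlap")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[-1]

    @property
    def b0_index(self) -> int:
        return self.gradients.b0_index

    @property
    def b0(self) -> np.ndarray:
        return self.signal[..., self.b0_index]

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"session has no '{name}' mask")
        return self.masks[name]

    @property
    def brain_mask(self) -> np.ndarray:
        return self.mask("brain")

    def copy_with(self, signal=None, gradients=None, meta_update=None) -> "DWIVolume":
        meta = dict(self.meta)
        if meta_update:
            meta.update(meta_update)
        return DWIVolume(
            signal=self.signal.copy() if signal is None else signal,
            gradients=self.gradients if gradients is None else gradients,
            voxel_size=self.voxel_size,
            session=self.session,
            masks={k: v.copy() for k, v in self.masks.items()},
            meta=meta,
        )


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(data: np.ndarray, voxel_size, path: str | Path, dtype=None) -> None:
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def save_session(dwi: DWIVolume, directory: str | Path, truth: dict | None = None) -> Path:
    """Write a session directory (dwi.nii.gz, bvals/bvecs, masks, truth.json)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_nifti(dwi.signal, dwi.voxel_size, directory / "dwi.nii.gz", dtype=np.float32)
    save_bvals_bvecs(dwi.gradients, directory / "bvals", directory / "bvecs")
    maskdir = directory / "masks"
    maskdir.mkdir(exist_ok=True)
    for name, mask in dwi.masks.items():
        save_nifti(mask, dwi.voxel_size, maskdir / f"{name}.nii.gz")
    if "labels" in dwi.meta:
        save_nifti(
            np.asarray(dwi.meta["labels"]), dwi.voxel_size,
            directory / "labels.nii.gz", dtype=np.int16,
        )
    info = {"session": dwi.session}
    if truth is not None:
        info.update(truth)
    with open(directory / "truth.json", "w") as fh:
        json.dump(_jsonable(info), fh, indent=2)
    return directory


def load_session(directory: str | Path) -> DWIVolume:
    directory = Path(directory)
    signal, vs = load_nifti(directory / "dwi.nii.gz")
    table = read_bvals_bvecs(directory / "bvals", directory / "bvecs")
    masks = {}
    maskdir = directory / "masks"
    if maskdir.is_dir():
        for p in sorted(maskdir.glob("*.nii.gz")):
            masks[p.name.replace(".nii.gz", "")] = load_nifti(p)[0].astype(bool)
    meta: dict = {}
    truth_path = directory / "truth.json"
    session = "pre"
    if truth_path.exists():
        with open(truth_path) as fh:
            meta["truth"] = json.load(fh)
        session = meta["truth"].get("session", session)
    labels_path = directory / "labels.nii.gz"
    if labels_path.exists():
        meta["labels"] = load_nifti(labels_path)[0].astype(int)
    return DWIVolume(
        signal=np.asarray(signal, dtype=float),
        gradients=table,
        voxel_size=vs,
        session=session,
        masks=masks,
        meta=meta,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
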