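"""Mask-based SNR and CNR quality metrics.

Per volume v:

    SNR_v = Mean_GM(v) / SD_AIR(v)
    CNR_v = (Mean_GM(v) − Mean_WM(v)) / SD_AIR(v)

where SD_AIR is the sample standard deviation (n − 1) over the air mask.
The reported session values are the per-volume values averaged across all
volumes of the corrected diffusion images (b0 included by default; pass
``exclude_b0=True`` to average over diffusion-weighted volumes only).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dwi import DWIVolume

_MIN_MASK_VOXELS = 30


@dataclass
class QualityReport:
    session: str
    snr_per_volume: np.ndarray
    cnr_per_volume: np.ndarray
    snr: float                    # volume-averaged
    cnr: float                    # volume-averaged
    mask_voxels: dict[str, int]
    exclude_b0: bool = False

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snr": self.snr_per_volume, "cnr": self.cnr_per_volume}
        )

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(csv_path, index_label="volume")
        if json_path is not None:
            summary = {
                "session": self.session,
                "snr_mean": self.snr,
                "snr_sd": float(np.std(self.snr_per_volume, ddof=1))
                if self.snr_per_volume.size > 1 else 0.0,
                "cnr_mean": self.cnr,
                "cnr_sd": float(np.std(self.cnr_per_volume, ddof=1))
                if self.cnr_per_volume.size > 1 else 0.0,
                "mask_voxels": self.mask_voxels,
                "exclude_b0": self.exclude_b0,
            }
            with open(json_path, "w") as fh:
                json.dump(summary, fh, indent=2)


def _volume_selector(dwi: DWIVolume, exclude_b0: bool) -> np.ndarray:
    return dwi.gradients.dwi_mask if exclude_b0 else np.ones(dwi.n_volumes, dtype=bool)


def _air_sd(dwi: DWIVolume, sel: np.ndarray) -> np.ndarray:
    air = dwi.signal[dwi.mask("air")][:, sel]
    if air.shape[0] < _MIN_MASK_VOXELS:
        raise ValueError(f"air mask has fewer than {_MIN_MASK_VOXELS} voxels")
    sd = air.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            "air standard deviation is zero in at least one volume "
            "(degenerate noiseless input — simulate with sigma > 0)"
        )
    return sd


def compute_snr(dwi: DWIVolume, exclude_b0: bool = False) -> tuple[np.ndarray, float]:
    """Per-volume and volume-averaged SNR (Mean_GM / SD_AIR)."""
    sel = _volume_selector(dwi, exclude_b0)
    gm = dwi.signal[dwi.mask("gm")][:, sel]
    if gm.shape[0] < _MIN_MASK_VOXELS:
        raise ValueError(f"gray-matter mask has fewer than {_MIN_MASK_VOXELS} voxels")
    snr = gm.mean(axis=0) / _air_sd(dwi, sel)
    return snr, float(snr.mean())


def compute_cnr(dwi: DWIVolume, exclude_b0: bool = False) -> tuple[np.ndarray, float]:
    """Per-volume and volume-averaged CNR ((Mean_GM − Mean_WM) / SD_AIR).

    May legitimately be negative when white matter is brighter than gray.
    """
    sel = _volume_selector(dwi, exclude_b0)
    gm = dwi.signal[dwi.mask("gm")][:, sel]
    wm = dwi.signal[dwi.mask("wm")][:, sel]
    if gm.shape[0] == 0 or wm.shape[0] == 0:
        raise ValueError("gray- and white-matter masks must be non-empty")
    cnr = (gm.mean(axis=0) - wm.mean(axis=0)) / _air_sd(dwi, sel)
    return cnr, float(cnr.mean())


def quality_report(dwi: DWIVolume, exclude_b0: bool = False) -> QualityReport:
    snr_pv, snr = compute_snr(dwi, exclude_b0)
    cnr_pv, cnr = compute_cnr(dwi, exclude_b0)
    return QualityReport(
        session=dwi.session,
        snr_per_volume=snr_pv,
        cnr_per_volume=cnr_pv,
        snr=snr,
        cnr=cnr,
        mask_voxels={
            name: int(dwi.mask(name).sum()) for name in ("gm", "wm", "air")
        },
        exclude_b0=exclude_b0,
    )
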