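"""Tract-retention statistics: connection-probability index, streamline
density, percent change, and the voxel-wise pre/post comparison.

The *index of connection probability* is the mean number of samples per
seed voxel whose streamline reached the classification target (so its range
is [0, samples-per-voxel] — the per-voxel success counts are not divided by
the sample count).  The *streamline density* is the percentage of seed
voxels generating at least one successful streamline.  Percent change is
100 × (pre − post) / pre, reported at one-decimal rounding half away from
zero.  The voxel-wise comparison is a two-tailed heteroscedastic (Welch)
t-test on the connection-value maps within the target ROI; p > 0.05 is
reported as "similar" (similarity-by-nonrejection, not equivalence).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tract import TractographyResult


@dataclass
class ConnectivityMetrics:
    tract: str
    session: str
    index: float             # mean successful samples per seed voxel
    density: float           # % of seed voxels with ≥ 1 successful streamline
    n_seed_voxels: int
    samples_per_voxel: int


def connection_probability_index(result: TractographyResult) -> float:
    """Σ per-seed-voxel success counts / number of seed voxels."""
    counts = result.seed_counts
    if counts.size == 0:
        raise ValueError("seed mask is empty")
    return float(counts.sum() / counts.size)


def streamline_density(result: TractographyResult) -> float:
    """100 × (# seed voxels with ≥ 1 successful streamline) / (# seed voxels)."""
    counts = result.seed_counts
    if counts.size == 0:
        raise ValueError("seed mask is empty")
    return float(100.0 * np.count_nonzero(counts) / counts.size)


def connectivity_metrics(
    result: TractographyResult, tract: str = "", session: str = ""
) -> ConnectivityMetrics:
    return ConnectivityMetrics(
        tract=tract,
        session=session,
        index=connection_probability_index(result),
        density=streamline_density(result),
        n_seed_voxels=result.n_seed_voxels,
        samples_per_voxel=result.samples_per_voxel,
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used in printed tables)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percent_change(pre: float, post: float) -> float:
    """100 × (pre − post) / pre; NaN (with a warning) when pre is zero."""
    if pre == 0:
        warnings.warn("percent change undefined for pre = 0; reporting NaN")
        return float("nan")
    return 100.0 * (pre - post) / pre


def compare_connection_maps(
    pre: TractographyResult | np.ndarray,
    post: TractographyResult | np.ndarray,
    target_mask: np.ndarray,
) -> tuple[float, bool]:
    """Welch two-sample two-tailed t-test on the pre vs post connection
    values within the target ROI.

    Returns (p-value, similar) where similar ⇔ p > 0.05.  Voxels are
    treated as independent observations; spatial autocorrelation is ignored,
    as in the comparison this reproduces.
    """
    pre_map = pre.visitation if isinstance(pre, TractographyResult) else np.asarray(pre)
    post_map = post.visitation if isinstance(post, TractographyResult) else np.asarray(post)
    target_mask = np.asarray(target_mask, dtype=bool)
    if pre_map.shape != post_map.shape or pre_map.shape != target_mask.shape:
        raise ValueError("maps and target mask must share a grid")
    a = pre_map[target_mask].astype(float)
    b = post_map[target_mask].astype(float)
    if a.size < 2:
        raise ValueError("target mask must contain at least 2 voxels")
    if np.array_equal(a, b):
        return 1.0, True
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if not np.isfinite(p):
        # identical within-group variances of zero but different means
        p = 0.0
    return p, p > 0.05


def connectivity_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy per-tract table: index and density per session, percent change
    (half-away one-decimal rounding), Welch p with a similarity star."""
    df = pd.DataFrame(rows)
    if not len(df):
        return df
    for col in ("index_percent_change", "density_percent_change"):
        if col in df:
            df[col] = df[col].map(lambda x: round_half_away(x, 1))
    if "welch_p" in df:
        df["similar"] = df["welch_p"] > 0.05
    return df
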