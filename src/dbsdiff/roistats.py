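"""Per-ROI scalar statistics and the pre/post statistical decision tree.

For each (ROI, scalar) pair the two sessions' voxel values — paired by
voxel index, since both sessions live on the same phantom grid — enter a
two-sample Kolmogorov–Smirnov test.  If KS rejects at alpha the branch is a
paired Wilcoxon signed-rank test (zero differences dropped); otherwise a
paired t-test with a 95% confidence interval for the mean difference
(post − pre).  ROIs intersecting the susceptibility-artifact mask in at
least one voxel are classified "affected".

A p-value above alpha is reported as "similar" to mirror the convention of
the study design this reproduces; note this is similarity-by-nonrejection,
not an equivalence test.  No multiple-testing correction is applied by
default; Benjamini–Hochberg is available as an option.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_MIN_VOXELS = 10


@dataclass
class ROISample:
    """Valid-voxel scalar values of one ROI in both sessions (index-paired)."""

    roi: str
    label: int
    kind: str
    pre: np.ndarray
    post: np.ndarray
    affected: bool

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)

    @property
    def pre_mean(self) -> float:
        return float(self.pre.mean())

    @property
    def post_mean(self) -> float:
        return float(self.post.mean())


@dataclass
class ComparisonResult:
    """One row of the per-ROI comparison table.

    Exactly one of the two branch tests is populated: ``branch`` is
    ``"signed-rank"`` iff the KS test rejected at ``alpha``; a confidence
    interval is present iff the branch is ``"paired-t"``.
    """

    roi: str
    label: int
    kind: str
    n: int
    ks_p: float
    branch: str
    branch_p: float
    ci_low: float | None
    ci_high: float | None
    percent_change: float
    pre_mean: float
    post_mean: float
    affected: bool
    alpha: float
    degenerate: bool = False

    @property
    def distributions_differ(self) -> bool:
        return self.ks_p < self.alpha

    @property
    def similar(self) -> bool:
        return self.branch_p > self.alpha


def classify_affected(
    labels: np.ndarray, artifact_mask: np.ndarray, roi_defs: dict[str, int]
) -> tuple[dict[str, bool], float]:
    """Affected ⇔ the ROI shares at least one voxel with the artifact mask.

    Returns the per-ROI flags and the fraction of ROIs affected.  Raises if
    a configured label is absent from the label volume.
    """
    labels = np.asarray(labels)
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if labels.shape != artifact_mask.shape:
        raise ValueError("label volume and artifact mask must share a grid")
    present = set(np.unique(labels).tolist())
    flags: dict[str, bool] = {}
    for name, label in sorted(roi_defs.items(), key=lambda kv: kv[1]):
        if label not in present:
            raise ValueError(f"ROI label {label} ('{name}') absent from label volume")
        flags[name] = bool(np.any(artifact_mask[labels == label]))
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return flags, fraction


def extract_roi_samples(
    pre_map, post_map, labels: np.ndarray, roi_defs: dict[str, int],
    affected: dict[str, bool],
) -> list[ROISample]:
    """Collect index-paired valid-voxel values per ROI from two scalar maps
    of the same kind (valid in both sessions)."""
    if pre_map.kind != post_map.kind:
        raise ValueError("scalar maps must be of the same kind")
    valid = pre_map.valid & post_map.valid
    samples = []
    for name, label in sorted(roi_defs.items(), key=lambda kv: kv[1]):
        m = (labels == label) & valid
        samples.append(
            ROISample(
                roi=name,
                label=label,
                kind=pre_map.kind,
                pre=pre_map.values[m],
                post=post_map.values[m],
                affected=affected.get(name, False),
            )
        )
    return samples


def compare_roi(
    pre: np.ndarray,
    post: np.ndarray,
    alpha: float = 0.05,
    roi: str = "",
    label: int = 0,
    kind: str = "",
    affected: bool = False,
) -> ComparisonResult:
    """Run the KS → signed-rank / paired-t decision tree on one ROI."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post vectors must have equal length (voxel pairing)")
    if pre.size < _MIN_VOXELS:
        raise ValueError(f"need at least {_MIN_VOXELS} paired voxels, got {pre.size}")

    ks_p = float(stats.ks_2samp(pre, post).pvalue)
    diffs = post - pre
    degenerate = False
    ci_low = ci_high = None
    if ks_p < alpha:
        branch = "signed-rank"
        nonzero = diffs[diffs != 0]
        if nonzero.size == 0:
            branch_p, degenerate = 1.0, True
        else:
            branch_p = float(stats.wilcoxon(nonzero).pvalue)
    else:
        branch = "paired-t"
        if np.all(diffs == 0):
            branch_p, degenerate = 1.0, True
            ci_low = ci_high = 0.0
        else:
            res = stats.ttest_rel(post, pre)
            branch_p = float(res.pvalue)
            ci = res.confidence_interval(1.0 - alpha)
            ci_low, ci_high = float(ci.low), float(ci.high)
            if not np.isfinite(branch_p):  # zero-variance nonzero shift
                branch_p, degenerate = 0.0, True

    pre_mean = float(pre.mean())
    post_mean = float(post.mean())
    pct = 100.0 * (pre_mean - post_mean) / pre_mean if pre_mean != 0 else float("nan")
    return ComparisonResult(
        roi=roi, label=label, kind=kind, n=int(pre.size),
        ks_p=ks_p, branch=branch, branch_p=branch_p,
        ci_low=ci_low, ci_high=ci_high, percent_change=pct,
        pre_mean=pre_mean, post_mean=post_mean,
        affected=affected, alpha=alpha, degenerate=degenerate,
    )


def analyze_rois(samples: list[ROISample], alpha: float = 0.05) -> list[ComparisonResult]:
    return [
        compare_roi(
            s.pre, s.post, alpha=alpha, roi=s.roi, label=s.label,
            kind=s.kind, affected=s.affected,
        )
        for s in samples
    ]


def results_table(results: list[ComparisonResult], bh_correct: bool = False) -> pd.DataFrame:
    """Tidy table, one row per (ROI, scalar); optional Benjamini–Hochberg
    adjusted branch p-values (off by default)."""
    df = pd.DataFrame(
        {
            "roi": [r.roi for r in results],
            "label": [r.label for r in results],
            "scalar": [r.kind for r in results],
            "n_voxels": [r.n for r in results],
            "ks_p": [r.ks_p for r in results],
            "test": [r.branch for r in results],
            "p": [r.branch_p for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "pre_mean": [r.pre_mean for r in results],
            "post_mean": [r.post_mean for r in results],
            "percent_change": [r.percent_change for r in results],
            "affected": [r.affected for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )
    if bh_correct and len(df):
        df["p_bh"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
    return df


def _stratum_summary(res: list[ComparisonResult], alpha: float) -> dict:
    n = len(res)
    if n == 0:
        return {
            "n": 0,
            "pct_different_distribution": None,
            "pct_equal_medians_of_different": None,
            "pct_equal_means_of_similar": None,
            "pct_lower_post": None,
        }
    differ = [r for r in res if r.ks_p < alpha]
    similar_dist = [r for r in res if r.ks_p >= alpha]
    out = {
        "n": n,
        "pct_different_distribution": 100.0 * len(differ) / n,
        "pct_lower_post": 100.0 * sum(r.post_mean < r.pre_mean for r in res) / n,
    }
    out["pct_equal_medians_of_different"] = (
        100.0 * sum(r.branch_p > alpha for r in differ) / len(differ) if differ else None
    )
    out["pct_equal_means_of_similar"] = (
        100.0 * sum(r.branch_p > alpha for r in similar_dist) / len(similar_dist)
        if similar_dist else None
    )
    return out


def cohort_summary(results: list[ComparisonResult]) -> dict:
    """Cohort-level percentages per scalar kind and affected stratum.

    Per stratum: percent of ROIs with KS-different distributions; of those,
    percent with signed-rank p > alpha ("equal medians"); of the KS-similar,
    percent with t-test p > alpha ("equal means"); percent with lower post
    means.  Empty strata report None (not applicable) rather than zero.
    """
    if not results:
        raise ValueError("cohort_summary needs at least one comparison result")
    alpha = results[0].alpha
    kinds = sorted({r.kind for r in results})
    summary: dict = {"alpha": alpha, "n_results": len(results), "by_kind": {}}
    for kind in kinds:
        sub = [r for r in results if r.kind == kind]
        entry = {"all": _stratum_summary(sub, alpha)}
        for stratum, flag in (("affected", True), ("unaffected", False)):
            entry[stratum] = _stratum_summary(
                [r for r in sub if r.affected is flag], alpha
            )
        summary["by_kind"][kind] = entry
    rois = {(r.roi, r.affected) for r in results}
    n_rois = len({roi for roi, _ in rois})
    n_affected = len({roi for roi, aff in rois if aff})
    summary["fraction_rois_affected"] = n_affected / n_rois if n_rois else 0.0
    return summary
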