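import numpy as np
import pytest

import dbsdiff as dd
from dbsdiff.phantom import ball_mask
from dbsdiff.roistats import (
    analyze_rois,
    classify_affected,
    cohort_summary,
    compare_roi,
    extract_roi_samples,
    results_table,
)
from dbsdiff.tensor import fit_tensor, scalar_map


class TestClassifyAffected:
    def setup_method(self):
        shape = (16, 16, 16)
        self.labels = np.zeros(shape, dtype=int)
        self.labels[ball_mask(shape, (4, 4, 4), 2)] = 1      # inside artifact
        self.labels[ball_mask(shape, (11, 11, 11), 2)] = 2   # disjoint
        self.labels[ball_mask(shape, (4, 11, 4), 2)] = 3     # single-voxel touch
        self.artifact = ball_mask(shape, (4, 4, 4), 3)
        self.artifact[4, 9, 4] = True  # one voxel inside ROI 3
        self.defs = {"inside": 1, "far": 2, "touch": 3}

    def test_threshold_is_one_voxel(self):
        flags, frac = classify_affected(self.labels, self.artifact, self.defs)
        assert flags == {"inside": True, "far": False, "touch": True}
        assert frac == pytest.approx(2 / 3)

    def test_missing_label_raises(self):
        with pytest.raises(ValueError, match="absent"):
            classify_affected(self.labels, self.artifact, {"ghost": 9})

    def test_idempotent_and_order_independent(self):
        a = classify_affected(self.labels, self.artifact, self.defs)
        b = classify_affected(
            self.labels, self.artifact,
            dict(reversed(list(self.defs.items()))),
        )
        assert a == (b[0], b[1])


class TestCompareROI:
    def test_identical_vectors_take_t_branch_with_p_one(self):
        x = np.linspace(0.1, 0.9, 50)
        r = compare_roi(x, x.copy())
        assert r.branch == "paired-t"
        assert r.ks_p == pytest.approx(1.0)
        assert r.branch_p == pytest.approx(1.0)
        assert r.ci_low <= 0.0 <= r.ci_high
        assert r.degenerate

    def test_constant_shift_takes_signed_rank_and_rejects(self):
        rng = np.random.default_rng(7)
        pre = rng.normal(50, 5, 200)
        post = pre + 10.0
        r = compare_roi(pre, post)
        assert r.branch == "signed-rank"
        assert r.branch_p < 1e-6

    def test_branch_exclusivity(self):
        """Exactly one branch p per ROI; CI present iff paired-t."""
        rng = np.random.default_rng(11)
        for _ in range(30):
            pre = rng.normal(0, 1, 60)
            post = pre + rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), 60)
            r = compare_roi(pre, post)
            assert r.branch in ("signed-rank", "paired-t")
            has_ci = r.ci_low is not None
            assert has_ci == (r.branch == "paired-t")
            assert (r.branch == "signed-rank") == (r.ks_p < r.alpha)

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_roi(np.zeros(20), np.zeros(21))

    def test_too_few_voxels_raise(self):
        with pytest.raises(ValueError, match="at least 10"):
            compare_roi(np.zeros(5), np.zeros(5))

    def test_percent_change_of_means(self):
        pre = np.full(20, 10.0) + np.linspace(-1, 1, 20)
        post = np.full(20, 8.0) + np.linspace(-1, 1, 20)
        r = compare_roi(pre, post)
        assert r.percent_change == pytest.approx(20.0)


class TestCohortSummary:
    def _result(self, kind="fa", ks_p=0.01, branch_p=0.5, affected=False,
                pre_mean=1.0, post_mean=2.0):
        return dd.ComparisonResult(
            roi="r", label=1, kind=kind, n=20, ks_p=ks_p,
            branch="signed-rank" if ks_p < 0.05 else "paired-t",
            branch_p=branch_p, ci_low=None, ci_high=None,
            percent_change=0.0, pre_mean=pre_mean, post_mean=post_mean,
            affected=affected, alpha=0.05,
        )

    def test_all_rejecting_gives_100_percent(self):
        res = [self._result(ks_p=0.001) for _ in range(10)]
        out = cohort_summary(res)
        assert out["by_kind"]["fa"]["all"]["pct_different_distribution"] == 100.0

    def test_empty_stratum_reports_none(self):
        res = [self._result(affected=False) for _ in range(5)]
        out = cohort_summary(res)
        assert out["by_kind"]["fa"]["affected"]["pct_different_distribution"] is None

    def test_conditional_percentages(self):
        res = [
            self._result(ks_p=0.01, branch_p=0.5),   # different, equal medians
            self._result(ks_p=0.01, branch_p=0.01),  # different, unequal medians
            self._result(ks_p=0.5, branch_p=0.5),    # similar, equal means
            self._result(ks_p=0.5, branch_p=0.01),   # similar, unequal means
        ]
        s = cohort_summary(res)["by_kind"]["fa"]["all"]
        assert s["pct_different_distribution"] == 50.0
        assert s["pct_equal_medians_of_different"] == 50.0
        assert s["pct_equal_means_of_similar"] == 50.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            cohort_summary([])


def test_results_table_optional_bh_column():
    rng = np.random.default_rng(3)
    pre = rng.normal(0, 1, 40)
    results = [compare_roi(pre, pre + rng.normal(0, 1, 40), roi=f"r{i}")
               for i in range(6)]
    plain = results_table(results)
    assert "p_bh" not in plain.columns
    bh = results_table(results, bh_correct=True)
    assert np.all(bh["p_bh"] >= bh["p"] - 1e-12)


def test_artifact_rois_show_larger_fa_shift(scheme32):
    """End-to-end direction: with post-session signal dropout, affected ROIs
    change more in FA between sessions than unaffected ROIs."""
    ph = dd.build_study_phantom()
    sigma = 15.0
    pre = dd.simulate_dwi(ph, scheme32, sigma=sigma, seed=61, session="pre")
    post = dd.simulate_dwi(
        ph, scheme32, sigma=sigma, seed=62, session="post",
        dropout_mask=ph.artifact_mask, dropout_attenuation=0.05,
    )
    affected, _ = classify_affected(ph.roi_labels, ph.artifact_mask,
                                    ph.spec.roi_defs)
    fa_pre = scalar_map(fit_tensor(pre), "fa")
    fa_post = scalar_map(fit_tensor(post), "fa")
    samples = extract_roi_samples(fa_pre, fa_post, ph.roi_labels,
                                  ph.spec.roi_defs, affected)
    shifts = {s.roi: abs(s.post_mean - s.pre_mean) for s in samples}
    aff = [v for s, v in shifts.items() if affected[s]]
    unaff = [v for s, v in shifts.items() if not affected[s]]
    assert np.mean(aff) > np.mean(unaff)

    results = analyze_rois(samples)
    assert len({r.roi for r in results}) == len(samples)
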