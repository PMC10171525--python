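import numpy as np
import pandas as pd
import pytest

from brainsig import evaluation, signature
from brainsig.clusters import SignatureMaskSet
from brainsig.volumes import BinaryMask, Volume
from conftest import make_cohort_table


def _mask_set(shape, sl):
    data = np.zeros(shape, dtype=bool)
    data[sl] = True
    return SignatureMaskSet({3.0: BinaryMask(data)})


def _brainy_cohort(n=120, seed=0, shape=(8, 8, 8)):
    """Cohort whose outcome loads on GM inside the first half of the grid."""
    r = np.random.default_rng(seed)
    cohort = make_cohort_table(n, seed=seed)
    vols = {}
    signal = r.standard_normal(n)
    for i, sid in enumerate(cohort.subject_ids):
        data = np.full(shape, 1.0) + 0.05 * r.standard_normal(shape)
        data[0:4] += 0.1 * signal[i]
        vols[sid] = Volume(data)
    cohort.table["memory"] = (
        0.8 * signal
        - 0.02 * cohort.table["age"]
        + 0.03 * cohort.table["education"]
        + 0.3 * r.standard_normal(n)
    )
    return cohort, vols


class TestReplicationTrial:
    def test_identical_models_on_identity_line(self):
        cohort, vols = _brainy_cohort(80, seed=1)
        mset = _mask_set((8, 8, 8), np.s_[0:4])
        paired = evaluation.replication_trial(
            cohort, vols, mset, mset, "memory", n_subsets=10, subset_size=40, seed=3
        )
        np.testing.assert_allclose(paired.table["r2_a"], paired.table["r2_b"], atol=1e-12)
        ba = evaluation.bland_altman(paired)
        assert ba.bias == 0.0 and not ba.significant_bias

    def test_seeded_rerun_identical(self):
        cohort, vols = _brainy_cohort(60, seed=2)
        mset = _mask_set((8, 8, 8), np.s_[0:4])
        kw = dict(n_subsets=6, subset_size=30, seed=9)
        a = evaluation.replication_trial(cohort, vols, mset, mset, "memory", **kw)
        b = evaluation.replication_trial(cohort, vols, mset, mset, "memory", **kw)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_similar_masks_give_correlated_fits(self):
        cohort, vols = _brainy_cohort(150, seed=4)
        mset_a = _mask_set((8, 8, 8), np.s_[0:4])
        mset_b = _mask_set((8, 8, 8), np.s_[0:3])  # overlapping variant
        paired = evaluation.replication_trial(
            cohort, vols, mset_a, mset_b, "memory", n_subsets=20, subset_size=75, seed=5
        )
        r = np.corrcoef(paired.table["r2_a"], paired.table["r2_b"])[0, 1]
        assert r > 0.9

    def test_discovery_overlap_asserted(self):
        cohort, vols = _brainy_cohort(40, seed=6)
        mset = _mask_set((8, 8, 8), np.s_[0:4])
        with pytest.raises(ValueError, match="overlaps discovery"):
            evaluation.replication_trial(
                cohort, vols, mset, mset, "memory",
                n_subsets=2, subset_size=20, seed=0,
                discovery_ids=[cohort.subject_ids[0]],
            )


class TestBlandAltman:
    def test_all_zero_differences(self):
        res = evaluation.bland_altman(np.zeros(20))
        assert res.bias == 0.0
        assert res.loa_lower == 0.0 and res.loa_upper == 0.0
        assert not res.significant_bias
        assert res.degenerate

    def test_symmetric_differences_zero_bias(self):
        d = np.array([0.01, -0.01] * 10)
        res = evaluation.bland_altman(d)
        assert res.bias == pytest.approx(0.0, abs=1e-15)
        assert not res.significant_bias

    def test_closed_form_on_gaussian_sample(self):
        """bias ~ 0.004 and limits ~ bias +- 1.96*SD for N(0.004, 0.01^2)."""
        r = np.random.default_rng(0)
        d = r.normal(0.004, 0.01, 50)
        res = evaluation.bland_altman(d)
        assert res.bias == pytest.approx(d.mean(), abs=1e-15)
        sd = d.std(ddof=1)
        assert res.loa_upper == pytest.approx(d.mean() + 1.96 * sd, abs=1e-12)
        assert res.loa_lower == pytest.approx(d.mean() - 1.96 * sd, abs=1e-12)
        assert res.bias == pytest.approx(0.004, abs=0.004)
        assert res.loa_upper - res.loa_lower == pytest.approx(2 * 1.96 * 0.01, rel=0.35)
        from scipy import stats

        half = stats.t.ppf(0.975, 49) * sd / np.sqrt(50)
        assert res.ci_lower == pytest.approx(d.mean() - half, abs=1e-12)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            evaluation.bland_altman(np.array([0.1, 0.2]))

    def test_invariant_lower_leq_bias_leq_upper(self, rng):
        for _ in range(5):
            d = rng.normal(rng.normal(), abs(rng.normal()) + 1e-3, 30)
            res = evaluation.bland_altman(d)
            assert res.loa_lower <= res.bias <= res.loa_upper


class TestBootstrapDifference:
    def _setup(self, n=100, seed=0):
        cohort, vols = _brainy_cohort(n, seed=seed)
        mset = _mask_set((8, 8, 8), np.s_[0:4])
        ids = list(cohort.subject_ids)
        means = signature.roi_mean_vector(vols, mset, ids=ids)
        return cohort, means

    def test_self_comparison_is_identically_zero(self):
        cohort, means = self._setup(60, seed=1)
        res = evaluation.bootstrap_r2_difference(
            cohort, means, "memory", competitor="signature", n_boot=50, seed=2
        )
        assert res.point_difference == 0.0
        for lv, (lo, hi) in res.intervals.items():
            assert lo == 0.0 and hi == 0.0
            assert not res.superiority[lv]

    def test_interval_nesting_across_levels(self):
        cohort, means = self._setup(100, seed=3)
        res = evaluation.bootstrap_r2_difference(
            cohort, means, "memory", competitor="demographics", n_boot=400, seed=4
        )
        lvls = sorted(res.intervals)
        for a, b in zip(lvls, lvls[1:]):
            lo_a, hi_a = res.intervals[a]
            lo_b, hi_b = res.intervals[b]
            assert lo_b <= lo_a and hi_a <= hi_b

    def test_superiority_flags_monotone(self):
        cohort, means = self._setup(100, seed=5)
        res = evaluation.bootstrap_r2_difference(
            cohort, means, "memory", competitor="demographics", n_boot=400, seed=6
        )
        lvls = sorted(res.superiority)
        for a, b in zip(lvls, lvls[1:]):
            # superiority at the wider (higher) level implies it at the narrower
            assert res.superiority[a] or not res.superiority[b]

    def test_brain_signal_beats_demographics(self):
        cohort, means = self._setup(120, seed=7)
        res = evaluation.bootstrap_r2_difference(
            cohort, means, "memory", competitor="demographics", n_boot=300, seed=8
        )
        assert res.point_difference > 0
        assert res.superiority[0.8]

    def test_bca_intervals_close_to_percentile(self):
        """BCa corrects but should not wildly disagree with percentile
        intervals on a well-behaved difference distribution."""
        cohort, means = self._setup(100, seed=11)
        kw = dict(competitor="demographics", n_boot=300, seed=12)
        pct = evaluation.bootstrap_r2_difference(cohort, means, "memory", **kw)
        bca = evaluation.bootstrap_r2_difference(cohort, means, "memory", method="bca", **kw)
        lo_p, hi_p = pct.intervals[0.95]
        lo_b, hi_b = bca.intervals[0.95]
        width = hi_p - lo_p
        assert abs(lo_b - lo_p) < width and abs(hi_b - hi_p) < width
        lvls = sorted(bca.intervals)
        for a, b in zip(lvls, lvls[1:]):
            assert bca.intervals[b][0] <= bca.intervals[a][0]
            assert bca.intervals[a][1] <= bca.intervals[b][1]

    def test_drop_covariate_variant_runs(self):
        cohort, means = self._setup(80, seed=9)
        res = evaluation.bootstrap_r2_difference(
            cohort, means, "memory", competitor="demographics",
            drop_covariates=("age",), n_boot=100, seed=10,
        )
        assert np.isfinite(res.point_difference)


class TestDiagnosisInteraction:
    def _cohort_with_s(self, n, slope_by_group, seed=0):
        r = np.random.default_rng(seed)
        cohort = make_cohort_table(n, seed=seed)
        s = r.standard_normal(n)
        groups = np.array(["CN", "MCI", "Dementia"])[r.integers(0, 3, n)]
        cohort.table["diagnosis"] = groups
        slope = np.vectorize(slope_by_group.get)(groups)
        cohort.table["memory"] = (
            slope * s + 0.5 * (groups == "Dementia") + 0.1 * r.standard_normal(n)
        )
        return cohort, pd.Series(s, index=pd.Index(cohort.subject_ids, name="subject_id"))

    def test_single_level_rejected(self):
        cohort, s = self._cohort_with_s(40, {"CN": 1, "MCI": 1, "Dementia": 1})
        cohort.table["diagnosis"] = "CN"
        with pytest.raises(ValueError, match="2 levels"):
            evaluation.diagnosis_interaction(cohort, s, "memory")

    def test_equal_slopes_interaction_calibrated(self):
        """Under a common S-slope the interaction test rejects ~ alpha."""
        rejections = 0
        n_sims = 40
        for seed in range(n_sims):
            cohort, s = self._cohort_with_s(90, {"CN": 1.0, "MCI": 1.0, "Dementia": 1.0}, seed)
            rep = evaluation.diagnosis_interaction(cohort, s, "memory")
            rejections += int(rep.p_interaction < 0.05)
        # binomial(40, .05): observing > 7 rejections has p < 1e-3
        assert rejections <= 7

    def test_slope_gap_increases_power(self):
        def mean_p(gap):
            ps = []
            for seed in range(10):
                cohort, s = self._cohort_with_s(
                    90, {"CN": 1.0, "MCI": 1.0, "Dementia": 1.0 + gap}, seed
                )
                ps.append(evaluation.diagnosis_interaction(cohort, s, "memory").p_interaction)
            return np.mean(ps)

        assert mean_p(0.8) < mean_p(0.15) <= mean_p(0.0) + 0.5

    def test_main_effects_detected(self):
        cohort, s = self._cohort_with_s(120, {"CN": 1.0, "MCI": 1.0, "Dementia": 1.0}, seed=3)
        rep = evaluation.diagnosis_interaction(cohort, s, "memory")
        assert rep.p_signature < 0.001
        assert rep.p_diagnosis < 0.001  # Dementia offset planted
        assert rep.levels == ("CN", "Dementia", "MCI")
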