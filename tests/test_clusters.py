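import numpy as np
import pytest

from brainsig import clusters, glm
from brainsig.volumes import BinaryMask, Volume
from conftest import bfs_components, make_cohort_table, random_mask


class TestLabelClusters:
    def test_face_neighbors_one_cluster_at_6(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1, 1, 1] = data[1, 1, 2] = True
        cs = clusters.label_clusters(BinaryMask(data), connectivity=6)
        assert cs.sizes == [2]

    def test_corner_neighbors_split_at_6_join_at_26(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1, 1, 1] = data[2, 2, 2] = True
        assert clusters.label_clusters(BinaryMask(data), 6).sizes == [1, 1]
        assert clusters.label_clusters(BinaryMask(data), 26).sizes == [2]

    def test_empty_mask_gives_empty_set(self):
        cs = clusters.label_clusters(BinaryMask(np.zeros((4, 4, 4), dtype=bool)), 26)
        assert cs.clusters == [] and cs.max_size == 0

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_flood_fill_oracle(self, connectivity, seed):
        m = random_mask((12, 12, 12), 0.25, seed)
        got = clusters.label_clusters(m, connectivity).clusters
        want = bfs_components(m.data, connectivity)
        assert len(got) == len(want)
        for g, w in zip(got, want):
            np.testing.assert_array_equal(g, w)

    def test_ordering_size_desc_then_first_index(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[0, 0, 0:2] = True  # size 2, first index 0
        data[4, 4, 4:6] = True  # size 2, later index
        data[2, 2, 2] = True  # size 1
        cs = clusters.label_clusters(BinaryMask(data), 6)
        assert cs.sizes == [2, 2, 1]
        assert cs.clusters[0][0] < cs.clusters[1][0]


class TestSignificantMask:
    def _obs(self, sizes, shape=(10, 10, 128)):
        data = np.zeros(shape, dtype=bool)
        row = 0
        for s in sizes:
            data[row, 0, :s] = True
            row += 2
        return clusters.label_clusters(BinaryMask(data), 6)

    def test_quantile_definition_boundary(self):
        null = clusters.NullClusterDistribution(np.arange(1, 101), 100, 3.0, None)
        assert null.threshold(0.05) == 95
        obs = self._obs([95, 94])
        sig = clusters.significant_mask(obs, null)
        assert sig.data.sum() == 95  # size-95 retained, size-94 dropped

    def test_all_null_zero_retains_everything(self):
        null = clusters.NullClusterDistribution(np.zeros(200, dtype=int), 200, 3.0, None)
        obs = self._obs([3, 1])
        assert clusters.significant_mask(obs, null).data.sum() == 4

    def test_observed_below_null_gives_empty(self):
        null = clusters.NullClusterDistribution(np.full(200, 50), 200, 3.0, None)
        obs = self._obs([5, 3])
        assert not clusters.significant_mask(obs, null).data.any()


class TestPermutationNull:
    def test_identity_permutation_reproduces_observed_max(self, small_sim, small_mask):
        null = clusters.permutation_null(
            small_sim.cohort, small_sim.volumes, small_mask, "memory",
            t_thresh=3.0, n_perm=1, seed=0, include_identity=True,
        )
        tm = glm.voxelwise_tmap(small_sim.cohort, small_sim.volumes, small_mask, "memory")
        obs = clusters.label_clusters(glm.signed_threshold(tm, 3.0, "positive"), 26)
        assert null.max_sizes[0] == obs.max_size

    def test_seed_determinism(self, small_sim, small_mask):
        kw = dict(t_thresh=3.0, n_perm=50, seed=123)
        a = clusters.permutation_null(
            small_sim.cohort, small_sim.volumes, small_mask, "memory", **kw
        )
        b = clusters.permutation_null(
            small_sim.cohort, small_sim.volumes, small_mask, "memory", **kw
        )
        np.testing.assert_array_equal(a.max_sizes, b.max_sizes)

    def test_exhaustive_equals_unique_draws_for_n6(self):
        """For 6 subjects, 720 distinct draws cover exactly all permutations."""
        import pandas as pd

        from brainsig.volumes import CohortTable

        r = np.random.default_rng(0)
        n = 6
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "age": [60, 64, 68, 72, 76, 80],
                "gender": [0, 1, 0, 1, 0, 1],
                "education": [12, 16, 12, 16, 12, 16],
                "memory": r.standard_normal(n),
            }
        )
        cohort = CohortTable(df, ("memory",))
        shape = (3, 3, 3)
        vols = {f"s{i}": Volume(r.standard_normal(shape)) for i in range(n)}
        mask = BinaryMask(np.ones(shape, dtype=bool))
        kw = dict(t_thresh=1.5, covariates=("age",))
        exact = clusters.permutation_null(
            cohort, vols, mask, "memory", n_perm=720, method="exhaustive", **kw
        )
        drawn = clusters.permutation_null(
            cohort, vols, mask, "memory", n_perm=720, method="unique", seed=5, **kw
        )
        assert sorted(exact.max_sizes) == sorted(drawn.max_sizes)

    def test_nperm_insensitivity_of_threshold(self, small_sim, small_mask):
        """Growing the null from 200 to 800 draws moves the 95th-percentile
        cutoff by no more than its own sampling error (a few voxels)."""
        t200 = clusters.permutation_null(
            small_sim.cohort, small_sim.volumes, small_mask, "memory",
            t_thresh=3.0, n_perm=200, seed=1,
        ).threshold()
        t800 = clusters.permutation_null(
            small_sim.cohort, small_sim.volumes, small_mask, "memory",
            t_thresh=3.0, n_perm=800, seed=2,
        ).threshold()
        assert abs(t200 - t800) <= max(3, 0.5 * t800)


class TestDiscovery:
    def test_seeded_run_reproducible(self, small_sim, small_mask):
        cfg = clusters.DiscoveryConfig(n_perm=60, seed=9)
        a = clusters.discover_signature_masks(
            small_sim.cohort, small_sim.volumes, small_mask, "memory", cfg
        )
        b = clusters.discover_signature_masks(
            small_sim.cohort, small_sim.volumes, small_mask, "memory", cfg
        )
        for t in a.t_levels:
            np.testing.assert_array_equal(a.mask_at(t).data, b.mask_at(t).data)

    def test_suprathreshold_nesting_before_significance(self, small_sim, small_mask):
        tm = glm.voxelwise_tmap(small_sim.cohort, small_sim.volumes, small_mask, "memory")
        m3 = glm.signed_threshold(tm, 3.0, "positive").data
        m5 = glm.signed_threshold(tm, 5.0, "positive").data
        m7 = glm.signed_threshold(tm, 7.0, "positive").data
        assert not (m5 & ~m3).any() and not (m7 & ~m5).any()

    def test_planted_effect_recovered_at_t3(self, small_sim, small_mask):
        cfg = clusters.DiscoveryConfig(n_perm=100, seed=4)
        mset = clusters.discover_signature_masks(
            small_sim.cohort, small_sim.volumes, small_mask, "memory", cfg
        )
        m3 = mset.mask_at(3.0)
        truth = small_sim.truth_mask.data
        # n=60 is a smoke scale: expect substantial but not full coverage
        assert (m3.data & truth).sum() > 0.3 * truth.sum()
        # and the retained voxels should be concentrated on the planted box
        assert (m3.data & truth).sum() > 0.5 * m3.data.sum()

    def test_null_cohort_usually_empty(self):
        """Without a planted effect, retained masks are usually empty."""
        from brainsig import synthetic
        from brainsig.volumes import make_analysis_mask

        empty_levels = 0
        total = 0
        for seed in range(5):
            sim = synthetic.simulate_cohort(
                synthetic.GenerativeConfig(
                    n_subjects=40, shape=(12, 12, 12), effects=(),
                    outcome_loading=0.0, seed=seed,
                )
            )
            mask = make_analysis_mask(sim.template, 0.5)
            mset = clusters.discover_signature_masks(
                sim.cohort, sim.volumes, mask, "memory",
                clusters.DiscoveryConfig(n_perm=100, seed=seed),
            )
            for t in mset.t_levels:
                total += 1
                empty_levels += int(not mset.mask_at(t).data.any())
        assert empty_levels >= 0.6 * total
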