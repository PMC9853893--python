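import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gmprog as g
from gmprog.errors import InsufficientDataError, PairingError, SpecValidationError
from gmprog.experiments import adjusted_values_bruteforce, step_up_rejections
from conftest import make_toy_model


class TestTwoSampleT:
    def test_identical_groups_give_null_map(self):
        model = make_toy_model(n_vox=5)
        data = np.tile(np.arange(5.0), (4, 1))
        m = g.two_sample_t_map(data, data.copy(), model)
        assert np.all(m.statistic == 0) and np.all(m.p == 1)
        assert m.n_zero_variance == 5

    def test_single_voxel_pooled_t_matches_hand_computation(self):
        # pooled-variance t for {1,2,3,4} vs {3,4,5,6}: t = -2.191, p = 0.071
        model = make_toy_model(n_vox=1)
        m = g.two_sample_t_map(
            np.array([[1.0], [2.0], [3.0], [4.0]]),
            np.array([[3.0], [4.0], [5.0], [6.0]]),
            model,
        )
        assert m.df == 6
        assert m.statistic[0] == pytest.approx(-2.1909, abs=1e-4)
        assert m.p[0] == pytest.approx(0.0710, abs=1e-3)

    def test_antisymmetric_under_group_swap(self):
        model = make_toy_model(n_vox=7)
        rng = np.random.default_rng(4)
        a, b = rng.random((5, 7)), rng.random((6, 7))
        m1 = g.two_sample_t_map(a, b, model)
        m2 = g.two_sample_t_map(b, a, model)
        np.testing.assert_allclose(m1.statistic, -m2.statistic, atol=1e-12)
        np.testing.assert_allclose(m1.p, m2.p, atol=1e-12)

    def test_peak_statistic_lies_inside_a_planted_region(self, cohort, model, stat_maps):
        _, _, truth = cohort
        m = stat_maps["ADT1_vs_HC"]
        peak_idx = model.indices[np.argmax(np.abs(m.statistic))]
        assert truth.label_image[tuple(peak_idx)] > 0

    def test_too_few_subjects_rejected(self):
        model = make_toy_model(n_vox=2)
        with pytest.raises(InsufficientDataError):
            g.two_sample_t_map(np.ones((2, 2)), np.ones((4, 2)), model)


class TestPairedT:
    def test_no_change_gives_null_map_with_warning(self):
        model = make_toy_model(n_vox=3)
        x = np.random.default_rng(0).random((5, 3))
        m = g.paired_t_map(x, x.copy(), list("abcde"), list("abcde"), model)
        assert np.all(m.p == 1) and m.n_zero_variance == 3

    def test_fixed_differences_match_hand_computation(self):
        # differences {-1,-2,-3}: t = -3.464, p = 0.0742 at df 2
        model = make_toy_model(n_vox=1)
        t1 = np.array([[1.0], [2.0], [3.0]])
        t2 = t1 + np.array([[-1.0], [-2.0], [-3.0]])
        m = g.paired_t_map(t1, t2, list("abc"), list("abc"), model)
        assert m.df == 2
        assert m.statistic[0] == pytest.approx(-3.4641, abs=1e-4)
        assert m.p[0] == pytest.approx(0.0742, abs=1e-3)

    def test_broken_pairing_names_subjects(self):
        model = make_toy_model(n_vox=1)
        with pytest.raises(PairingError, match="d"):
            g.paired_t_map(np.ones((3, 1)), np.ones((3, 1)), list("abc"), list("abd"), model)


class TestFdr:
    def test_textbook_example(self):
        q = g.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert np.all(q <= 0.05)

    def test_single_p_of_one(self):
        np.testing.assert_array_equal(g.fdr_bh(np.array([1.0])), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(SpecValidationError):
            g.fdr_bh(np.array([0.5, 1.2]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_exhaustive_step_up(self, ps, alpha):
        p = np.array(ps)
        q = g.fdr_bh(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        np.testing.assert_allclose(q, adjusted_values_bruteforce(p), atol=1e-12)
        np.testing.assert_array_equal(q <= alpha, step_up_rejections(p, alpha))


class TestClustering:
    def _fabricated_map(self, sig_grid, model):
        n = model.n_voxels
        sig = sig_grid[model.skeleton_mask]
        q = np.where(sig, 0.01, 0.5)
        t = np.where(sig, -5.0, 0.0)
        return g.StatMap(statistic=t, p=q.copy(), q=q, df=10, contrast="fab", model=model)

    def test_strict_cluster_extent_threshold(self):
        model = make_toy_model(shape=(20, 10, 2), n_vox=400)
        sig = np.zeros((20, 10, 2), dtype=bool)
        sig[:8, :2, :2] = True          # 32-voxel blob... make exactly 31
        sig[7, 1, 1] = False            # 31 voxels
        sig[12:19, 8:10, 0:2] = True    # 28 voxels, separated
        sig[18, 9, 1] = True            # 29
        m = self._fabricated_map(sig, model)
        rs = g.threshold_and_cluster(m, alpha=0.05, min_cluster_voxels=30, sign=-1)
        assert [c.size for c in rs.clusters] == [31]

    def test_corner_touching_blobs_merge_under_26_connectivity(self):
        model = make_toy_model(shape=(6, 6, 2), n_vox=72)
        sig = np.zeros((6, 6, 2), dtype=bool)
        sig[0:2, 0:2, 0] = True
        sig[2:4, 2:4, 1] = True  # touches only across a corner/edge diagonal
        m = self._fabricated_map(sig, model)
        rs = g.threshold_and_cluster(m, alpha=0.05, min_cluster_voxels=0, sign=-1)
        assert len(rs.clusters) == 1

    def test_no_significant_voxels_gives_empty_set(self):
        model = make_toy_model(n_vox=20)
        sig = np.zeros(model.skeleton_mask.shape, dtype=bool)
        m = self._fabricated_map(sig, model)
        assert g.threshold_and_cluster(m).is_empty


class TestRegionDerivation:
    def test_disjoint_significant_sets_give_empty_overlap(self):
        model = make_toy_model(shape=(8, 8, 2), n_vox=128)
        grid1 = np.zeros((8, 8, 2), dtype=bool); grid1[:4] = True
        grid2 = np.zeros((8, 8, 2), dtype=bool); grid2[4:] = True
        helper = TestClustering()
        m1 = helper._fabricated_map(grid1, model)
        m2 = helper._fabricated_map(grid2, model)
        assert g.overlapped_regions(m1, m2, min_cluster_voxels=0).is_empty

    def test_identical_significant_sets_are_idempotent(self):
        model = make_toy_model(shape=(8, 8, 2), n_vox=128)
        grid = np.zeros((8, 8, 2), dtype=bool); grid[2:6, 2:6, :] = True
        helper = TestClustering()
        m = helper._fabricated_map(grid, model)
        ov = g.overlapped_regions(m, m, min_cluster_voxels=0)
        np.testing.assert_array_equal(ov.mask(), grid)

    def test_empty_paired_map_gives_no_continuing_regions(self):
        model = make_toy_model(shape=(8, 8, 2), n_vox=128)
        grid = np.zeros((8, 8, 2), dtype=bool); grid[2:6, 2:6, :] = True
        helper = TestClustering()
        m = helper._fabricated_map(grid, model)
        empty = helper._fabricated_map(np.zeros_like(grid), model)
        assert g.continuing_regions(m, m, empty, min_cluster_voxels=0).is_empty

    def test_categories_are_mutually_disjoint(self, region_sets):
        ov, cont, prog = (region_sets[k] for k in ("overlapped", "continuing", "progressive"))
        assert not np.any(ov.mask() & cont.mask())
        assert not np.any(ov.mask() & prog.mask())
        assert not np.any(cont.mask() & prog.mask())

    def test_planted_regions_recovered_by_category(self, cohort, model, region_sets):
        _, _, truth = cohort
        skel = model.skeleton_mask
        from gmprog import dice

        for name, category in truth.expected_categories.items():
            tmask = np.asarray(truth.true_region_masks[name], bool) & skel
            best = max(
                (
                    dice(rs.cluster_mask(c.name), tmask)
                    for rs in region_sets.values()
                    for c in rs.clusters
                ),
                default=0.0,
            )
            assert best >= 0.5, f"{name} ({category}) not recovered (best Dice {best:.2f})"


class TestNullCalibration:
    def test_fdr_false_positive_rate_matches_nominal_level(self):
        """Under cohorts with no planted effects, the chance that the
        voxelwise FDR procedure rejects anything should sit at its nominal
        5% (checked within a 2-SE binomial tolerance over 150 cohorts)."""
        from gmprog.experiments import null_voxel_false_positive_rate

        n = 200
        rate = null_voxel_false_positive_rate(n_cohorts=n, seed=1)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestTotalGmv:
    def test_unit_volume_times_skeleton_size(self):
        model = make_toy_model(shape=(10, 10, 1), n_vox=100)
        vol = g.VolumeImage(np.ones((10, 10, 1)), voxel_size_mm=(2.0, 2.0, 2.0))
        assert g.total_gmv(vol, model) == pytest.approx(800.0)
        assert g.total_gmv(g.VolumeImage(np.zeros((10, 10, 1))), model) == 0.0

    def test_group_totals_ordered_hc_above_patients(self, group_scans, model):
        means = {
            k: np.mean([g.total_gmv(s.image, model) for s in v])
            for k, v in group_scans.items()
        }
        assert means["HC"] > means["AD-T1"] > means["AD-T2"]


class TestDemographics:
    def test_sex_table_matches_printed_chi_squared(self):
        chi2, p = g.sex_chi2_test(np.array([[22, 18], [27, 18]]))
        assert chi2 == pytest.approx(0.060, abs=1e-3)
        assert round(p, 2) == 0.81

    def test_age_summary_welch_matches_printed_p(self):
        _, p = g.welch_t_from_summary(75.73, 7.25, 40, 74.78, 4.95, 45)
        assert round(p, 2) == 0.49

    def test_full_table_on_synthetic_cohort(self, cohort):
        _, phen, _ = cohort
        table = g.cohort_demographic_tests(phen)
        assert set(table.comparison) == {"HC_vs_AD-T1", "HC_vs_AD-T2"}
        by = table.set_index(["measure", "comparison"])
        # strong clinical group differences are reproduced
        assert by.loc[("MMSE", "HC_vs_AD-T1"), "p"] < 0.001
        assert by.loc[("CDR", "HC_vs_AD-T2"), "p"] < 0.001
        # age and sex are matched by design
        assert by.loc[("age", "HC_vs_AD-T1"), "p"] > 0.05
        assert by.loc[("sex", "HC_vs_AD-T1"), "p"] > 0.05

    def test_identical_groups_give_p_one(self):
        import pandas as pd

        rows = []
        for grp in ("HC", "AD"):
            for i in range(5):
                rows.append(dict(subject_id=f"{grp}{i}", group=grp, timepoint="T1",
                                 sex="M" if i % 2 else "F", age=70.0, CDR=0.0,
                                 MMSE=25, MoCA=20.0))
        table = g.cohort_demographic_tests(pd.DataFrame(rows))
        assert (table[table.measure == "age"].p == 1.0).all()
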