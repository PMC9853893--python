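import numpy as np
import pandas as pd
import pytest

import gmprog as g
from gmprog.errors import ConstructionError, InsufficientDataError, PairingError
from conftest import make_toy_model


def tiny_scans(model, values):
    """One ScanVolume per (sid, tp, grid_value) triple on the toy grid."""
    scans = []
    for sid, tp, val in values:
        data = np.full(model.skeleton_mask.shape, float(val))
        scans.append(g.ScanVolume(sid, tp, "AD" if sid.startswith("AD") else "HC",
                                  g.VolumeImage(data)))
    return scans


class TestRoiMeans:
    def test_constant_volume_gives_constant_cells(self):
        model = make_toy_model(n_vox=10)
        scans = tiny_scans(model, [("AD001", "T1", 2.5), ("AD001", "T2", 2.5)])
        mask = model.skeleton_mask.copy()
        table = g.roi_mean_gmv(scans, {"all": mask}, model)
        assert (table["all"] == 2.5).all()

    def test_two_voxel_region_averages(self):
        model = make_toy_model(shape=(4, 1, 1), n_vox=4)
        data = np.zeros((4, 1, 1))
        data[0, 0, 0], data[1, 0, 0] = 1.0, 3.0
        scan = g.ScanVolume("AD001", "T1", "AD", g.VolumeImage(data))
        region = np.zeros((4, 1, 1), dtype=bool)
        region[:2] = True
        table = g.roi_mean_gmv([scan], {"r": region}, model)
        assert table.loc[("AD001", "T1"), "r"] == 2.0

    def test_empty_region_error_names_region(self):
        model = make_toy_model(n_vox=5)
        scans = tiny_scans(model, [("AD001", "T1", 1.0)])
        empty = np.zeros(model.skeleton_mask.shape, dtype=bool)
        with pytest.raises(ConstructionError, match="ghost"):
            g.roi_mean_gmv(scans, {"ghost": empty}, model)

    def test_group_means_reproduce_manifest_within_2_se(self, cohort, model, truth_roitable):
        scans, phen, truth = cohort
        groups = phen.set_index(["subject_id", "timepoint"])["group"]
        for region, truth_name in (("STG_left", "STG_left"), ("continuing", "cingulate")):
            for grp, tp in (("HC", "T1"), ("AD", "T2")):
                sel = [k for k in truth_roitable.index if groups[k] == grp and k[1] == tp]
                vals = truth_roitable.loc[sel, region]
                expected = truth.true_group_means[(grp, tp, truth_name)]
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                # region means ride below the medial-plane value because the
                # sphere also samples off-plane voxels; 2 SE plus that
                # profile offset
                assert abs(vals.mean() - expected) < 2 * se + 0.08


class TestChangeScores:
    def test_deltas_computed_per_subject(self):
        roitable = pd.DataFrame(
            {"r": [5.0, 4.5]},
            index=pd.MultiIndex.from_tuples(
                [("AD001", "T1"), ("AD001", "T2")], names=["subject_id", "timepoint"]
            ),
        )
        phen = pd.DataFrame(
            [
                dict(subject_id="AD001", group="AD", timepoint="T1", sex="M", age=70,
                     CDR=0.5, MMSE=24, MoCA=18.0),
                dict(subject_id="AD001", group="AD", timepoint="T2", sex="M", age=71,
                     CDR=1.0, MMSE=22, MoCA=16.0),
            ]
        )
        changes = g.change_scores(roitable, phen)
        assert changes.loc[0, "delta_r"] == pytest.approx(-0.5)
        assert changes.loc[0, "delta_moca"] == pytest.approx(-2.0)

    def test_missing_timepoint_raises_pairing_error(self):
        roitable = pd.DataFrame(
            {"r": [5.0]},
            index=pd.MultiIndex.from_tuples([("AD001", "T1")], names=["subject_id", "timepoint"]),
        )
        phen = pd.DataFrame(
            [dict(subject_id="AD001", group="AD", timepoint="T1", sex="M", age=70,
                  CDR=0.5, MMSE=24, MoCA=18.0)]
        )
        with pytest.raises(PairingError, match="AD001"):
            g.change_scores(roitable, phen)

    def test_default_cohort_yields_38_complete_moca_records(self, cohort, truth_roitable):
        _, phen, _ = cohort
        changes = g.change_scores(truth_roitable, phen)
        assert len(changes) == 40
        assert changes["delta_moca"].notna().sum() == 38


class TestBrainBehaviorCorrelation:
    def _frame(self, dgmv, dmoca):
        return pd.DataFrame({"delta_r": dgmv, "delta_moca": dmoca})

    def test_perfect_linear_relation(self):
        r, p, n = g.brain_behavior_correlation(self._frame([1, 2, 3, 4], [2, 4, 6, 8]), "r")
        assert r == pytest.approx(1.0)
        assert n == 4

    def test_hand_computed_half_correlation(self):
        # Pearson r of {1,2,3} with {1,3,2} is exactly 0.5
        r, _, _ = g.brain_behavior_correlation(
            self._frame([1, 2, 3, 1, 2, 3], [1, 3, 2, 1, 3, 2]), "r"
        )
        assert r == pytest.approx(0.5)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(20), rng.random(20)
        r1, p1, _ = g.brain_behavior_correlation(self._frame(x, y), "r")
        r2, p2, _ = g.brain_behavior_correlation(self._frame(3.0 * x - 1.0, 0.5 * y + 7.0), "r")
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            g.brain_behavior_correlation(self._frame([1, 2, 3], [1, 2, 3]), "r")

    def test_planted_coupling_visible_in_cohort(self, cohort, truth_roitable):
        _, phen, truth = cohort
        changes = g.change_scores(truth_roitable, phen)
        r, p, n = g.brain_behavior_correlation(changes, "STG_right")
        assert n == 38
        assert r > 0.2 and p < 0.05


class TestDice:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        a[:2] = True
        b = ~a
        assert g.dice(a, a) == 1.0
        assert g.dice(a, b) == 0.0
        assert g.dice(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_half_overlap(self):
        a = np.zeros(8, dtype=bool).reshape(2, 2, 2)
        b = a.copy()
        a.ravel()[:4] = True
        b.ravel()[2:6] = True
        assert g.dice(a, b) == pytest.approx(0.5)


class TestTruthMatching:
    def test_declining_clusters_get_anatomical_names(self, cohort, model, region_sets):
        # A planted within-patient-decline region can surface in either the
        # progressive or (when its group deficit crosses threshold) the
        # continuing set; the manifest lookup must name it in both cases.
        _, _, truth = cohort
        matched = set()
        for key in ("progressive", "continuing"):
            mapping = g.match_clusters_to_truth(
                region_sets[key], truth.true_region_masks, model
            )
            assert set(mapping.values()) <= set(truth.true_region_masks)
            matched |= set(mapping.values())
        assert {"STG_left", "STG_right", "caudate_left"} <= matched
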