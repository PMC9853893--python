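import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gmprog as g
from gmprog.errors import SpecValidationError
from gmprog.synthetic_cohort import SCORE_DISTRIBUTIONS, planted_change_table


class TestSpecValidation:
    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(n_ad_with_moca_both=41), "n_ad_with_moca_both"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(behavior_coupling=1.5), "behavior_coupling"),
            (dict(voxel_size_mm=-1.0), "voxel_size_mm"),
        ],
    )
    def test_invalid_field_named_in_error(self, overrides, field):
        with pytest.raises(SpecValidationError) as err:
            g.CohortSpec(seed=0, **overrides)
        assert err.value.field == field

    def test_sphere_outside_grid_rejected(self):
        bad = (g.RegionDef("edge", (0, 0, 6), 3.0),)
        with pytest.raises(SpecValidationError, match="outside the grid"):
            g.CohortSpec(seed=0, region_definitions=bad, atrophy_effects={},
                         covariance_loadings={}, behavior_regions=(),
                         causal_source_regions=(), causal_target_regions=())

    def test_delta_out_of_range_rejected(self):
        with pytest.raises(SpecValidationError, match="deltas"):
            g.CohortSpec(seed=0, atrophy_effects={"frontal": (1.0, 0.5)})


class TestPhenotypes:
    def test_design_counts_match_study(self, cohort):
        _, phen, _ = cohort
        sizes = phen.groupby(["group", "timepoint"]).size()
        assert sizes[("HC", "T1")] == 45
        assert sizes[("AD", "T1")] == 40
        assert sizes[("AD", "T2")] == 40
        ad_t1 = phen[(phen.group == "AD") & (phen.timepoint == "T1")]
        hc = phen[phen.group == "HC"]
        assert (ad_t1.sex == "M").sum() == 22 and (ad_t1.sex == "F").sum() == 18
        assert (hc.sex == "M").sum() == 27 and (hc.sex == "F").sum() == 18
        assert (hc.CDR == 0).all()
        # MoCA completion counts: 38/40 patients at both timepoints, 43/45 controls
        ad_moca = phen[phen.group == "AD"].pivot(index="subject_id", columns="timepoint", values="MoCA")
        assert ad_moca.dropna().shape[0] == 38
        assert hc.MoCA.notna().sum() == 43

    def test_controls_have_single_timepoint_and_patients_are_paired(self, cohort):
        _, phen, _ = cohort
        assert set(phen[phen.group == "HC"].timepoint) == {"T1"}
        per_subject = phen[phen.group == "AD"].groupby("subject_id").timepoint.apply(sorted)
        assert all(tp == ["T1", "T2"] for tp in per_subject)

    def test_scores_within_stated_ranges(self, cohort):
        _, phen, _ = cohort
        hc = phen[phen.group == "HC"]
        lo, hi = SCORE_DISTRIBUTIONS[("HC", "MMSE")][2:]
        assert hc.MMSE.between(lo, hi).all()
        ad1 = phen[(phen.group == "AD") & (phen.timepoint == "T1")]
        lo, hi = SCORE_DISTRIBUTIONS[("AD_T1", "CDR")][2:]
        assert ad1.CDR.between(lo, hi).all()

    def test_hc_mmse_mean_matches_truncated_normal_oracle(self):
        # Independent oracle: analytic mean of the truncated normal the
        # generator draws from (truncation pulls the mean below the
        # nominal 29.13).
        mean, sd, lo, hi = SCORE_DISTRIBUTIONS[("HC", "MMSE")]
        a, b = (lo - mean) / sd, (hi - mean) / sd
        expected = stats.truncnorm.stats(a, b, loc=mean, scale=sd, moments="m")
        sample_means = []
        for seed in range(200):
            phen = g.generate_phenotypes(g.CohortSpec(seed=seed))
            sample_means.append(phen[phen.group == "HC"].MMSE.mean())
        assert np.mean(sample_means) == pytest.approx(float(expected), abs=0.15)


class TestVolumes:
    def test_volume_count_and_grid(self, spec, cohort):
        scans, _, _ = cohort
        assert len(scans) == spec.n_hc + 2 * spec.n_ad == 125
        assert all(s.image.shape == spec.grid_shape for s in scans)

    def test_seed_determinism_and_seed_sensitivity(self):
        small = g.CohortSpec(seed=3, n_hc=4, n_ad=4, n_ad_with_moca_both=4,
                             n_hc_with_moca=4).scaled_down(0.5)
        a1, p1, _ = g.generate_cohort(small)
        a2, p2, _ = g.generate_cohort(small)
        pd.testing.assert_frame_equal(p1, p2)
        for s1, s2 in zip(a1, a2):
            np.testing.assert_array_equal(s1.image.data, s2.image.data)
        from dataclasses import replace

        b1, q1, _ = g.generate_cohort(replace(small, seed=4))
        assert not np.array_equal(a1[0].image.data, b1[0].image.data)

    def test_planted_region_means_match_manifest(self, spec, cohort):
        # Medial-plane voxel values inside each region average to
        # mu * (1 - delta) per group/timepoint, within sampling error.
        scans, _, truth = cohort
        z = truth.medial_plane_z
        for group, tp, scan_list in (
            ("HC", "T1", [s for s in scans if s.group == "HC"]),
            ("AD", "T2", [s for s in scans if s.group == "AD" and s.timepoint == "T2"]),
        ):
            for name in ("frontal", "cingulate"):
                mask = truth.true_region_masks[name].copy()
                mask[:, :, [k for k in range(spec.grid_shape[2]) if k != z]] = False
                vals = [s.image.data[mask].mean() for s in scan_list]
                expected = truth.true_group_means[(group, tp, name)]
                se = np.std(vals, ddof=1) / np.sqrt(len(vals))
                assert abs(np.mean(vals) - expected) < 4 * se + 0.005

    def test_null_spec_removes_all_planted_structure(self):
        ns = g.null_spec(seed=0)
        assert all(d == (0.0, 0.0) for d in ns.atrophy_effects.values())
        assert ns.behavior_coupling == 0.0
        loads = ns.covariance_loadings
        for (grp, name) in list(loads):
            other = ("AD" if grp == "HC" else "HC", name)
            assert loads[(grp, name)] == loads[other]


class TestBehaviorCoupling:
    def test_high_coupling_recovered_within_its_sampling_interval(self):
        # Oracle: a bivariate-normal correlation of 0.8 at n = 38 lands in
        # the Fisher 95% interval around 0.8.
        spec = g.CohortSpec(seed=2, n_ad=38, n_ad_with_moca_both=38,
                            behavior_coupling=0.8).scaled_down(0.5)
        changes = planted_change_table(spec)
        phen = g.generate_phenotypes(spec)
        moca = phen[phen.group == "AD"].pivot(index="subject_id", columns="timepoint", values="MoCA")
        dmoca = (moca["T2"] - moca["T1"]).dropna()
        dgmv = changes.set_index("subject_id").loc[dmoca.index, "delta_STG_right"]
        r = stats.pearsonr(dgmv, dmoca)[0]
        zlo, zhi = np.arctanh(0.8) - 1.96 / np.sqrt(35), np.arctanh(0.8) + 1.96 / np.sqrt(35)
        assert np.tanh(zlo) < r < np.tanh(zhi)
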