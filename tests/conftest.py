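"""Shared fixtures: one synthetic cohort and its derived stages, reused
across the suite (session scope keeps the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

import gmprog as g


@pytest.fixture(scope="session")
def spec() -> g.CohortSpec:
    return g.CohortSpec(seed=11)


@pytest.fixture(scope="session")
def cohort(spec):
    return g.generate_cohort(spec)


@pytest.fixture(scope="session")
def model(cohort) -> g.SkeletonModel:
    scans, _, _ = cohort
    return g.skeletonize(g.mean_image([s.image for s in scans]))


@pytest.fixture(scope="session")
def group_scans(cohort):
    scans, _, _ = cohort
    return {
        "HC": [s for s in scans if s.group == "HC"],
        "AD-T1": [s for s in scans if s.group == "AD" and s.timepoint == "T1"],
        "AD-T2": [s for s in scans if s.group == "AD" and s.timepoint == "T2"],
    }


@pytest.fixture(scope="session")
def stat_maps(group_scans, model):
    m_hc = g.sample_matrix([s.image for s in group_scans["HC"]], model)
    m_t1 = g.sample_matrix([s.image for s in group_scans["AD-T1"]], model)
    m_t2 = g.sample_matrix([s.image for s in group_scans["AD-T2"]], model)
    return {
        "ADT1_vs_HC": g.two_sample_t_map(m_t1, m_hc, model, contrast="ADT1_vs_HC"),
        "ADT2_vs_HC": g.two_sample_t_map(m_t2, m_hc, model, contrast="ADT2_vs_HC"),
        "paired": g.paired_t_map(
            m_t1,
            m_t2,
            [s.subject_id for s in group_scans["AD-T1"]],
            [s.subject_id for s in group_scans["AD-T2"]],
            model,
        ),
    }


@pytest.fixture(scope="session")
def region_sets(stat_maps):
    ov = g.overlapped_regions(stat_maps["ADT1_vs_HC"], stat_maps["ADT2_vs_HC"])
    cont = g.continuing_regions(
        stat_maps["ADT1_vs_HC"], stat_maps["ADT2_vs_HC"], stat_maps["paired"]
    )
    prog = g.progressive_regions(stat_maps["paired"], ov, cont)
    return {"overlapped": ov, "continuing": cont, "progressive": prog}


@pytest.fixture(scope="session")
def truth_roitable(cohort, model):
    """ROI table over the *planted* region masks, with the canonical
    feature-column names (overlapped/continuing categories pooled)."""
    scans, _, truth = cohort
    skel = model.skeleton_mask
    masks = {n: np.asarray(m, bool) for n, m in truth.true_region_masks.items()}
    columns = {
        "overlapped": (masks["frontal"] | masks["hippocampus"]) & skel,
        "continuing": masks["cingulate"] & skel,
        "STG_left": masks["STG_left"] & skel,
        "STG_right": masks["STG_right"] & skel,
        "caudate_left": masks["caudate_left"] & skel,
    }
    return g.roi_mean_gmv(scans, columns, model)


@pytest.fixture(scope="session")
def report():
    """One full default pipeline run (the synthetic replication run)."""
    return g.run_pipeline(g.PipelineConfig(cohort_spec=g.CohortSpec(seed=1), seed=1))


def make_toy_model(shape=(6, 6, 3), n_vox: int | None = None) -> g.SkeletonModel:
    """A skeleton model with an arbitrary flat mask, for unit tests of
    voxelwise statistics that need a model but no real skeleton."""
    mask = np.zeros(shape, dtype=bool)
    flat = mask.ravel()
    flat[: (n_vox if n_vox is not None else flat.size)] = True
    mask = flat.reshape(shape)
    mean_map = g.VolumeImage(np.ones(shape), voxel_size_mm=(2.0, 2.0, 2.0))
    return g.SkeletonModel(
        mean_map=mean_map, skeleton_mask=mask, gm_threshold=0.2, smoothing_sigma_mm=0.0
    )


@pytest.fixture
def toy_model():
    return make_toy_model
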