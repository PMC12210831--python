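"""Generator correctness: conservation, determinism, rendering, sampling."""

import numpy as np
import pandas as pd
import pytest

from nucfish import (
    AmplificationConfig,
    FlowSimConfig,
    NO_NOISE,
    NoiseModel,
    SceneConfig,
    fit_fold_per_round,
    generate_amplification_series,
    generate_fe_table,
    generate_flow_and_qpcr,
    generate_scene,
)
from nucfish.synthetic import AXIAL_PROFILE


def test_empty_scene_has_no_objects():
    cfg = SceneConfig(image_shape=(2, 64, 64), n_nuclei=0, noise_model=NO_NOISE)
    stack, mask, truth = generate_scene(cfg)
    assert truth.spots.empty and truth.sites.empty
    assert mask.max() == 0
    # background-only stack in the FISH channels
    assert np.allclose(stack.channel("exon"), cfg.background_level)
    assert np.allclose(stack.channel("intron"), cfg.background_level)


def test_single_site_renders_matched_exon_intron_pair():
    cfg = SceneConfig(
        image_shape=(3, 96, 96),
        n_nuclei=1,
        txn_sites_per_nucleus=1,
        single_spots_per_nucleus=0,
        noise_model=NO_NOISE,
        seed=4,
    )
    _, _, truth = generate_scene(cfg)
    exon = truth.spots[truth.spots.channel == "exon"]
    intron = truth.spots[truth.spots.channel == "intron"]
    assert len(exon) == 1 and len(intron) == 1
    assert exon.iloc[0][["z", "y", "x"]].tolist() == intron.iloc[0][["z", "y", "x"]].tolist()
    assert len(truth.sites) == 1


@pytest.mark.parametrize("seed", [0, 7])
def test_spot_count_conservation(seed):
    """Exon puncta = singles + sites; intron puncta = sites, per nucleus."""
    cfg = SceneConfig(
        image_shape=(3, 200, 200),
        n_nuclei=4,
        noise_model=NO_NOISE,
        seed=seed,
    )
    _, _, truth = generate_scene(cfg)
    for nid, sub in truth.spots.groupby("nucleus_id"):
        n_sites = len(truth.sites[truth.sites.nucleus_id == nid])
        assert (sub.channel == "intron").sum() == n_sites
        n_singles = ((sub.channel == "exon") & ~sub.is_txn_site).sum()
        assert (sub.channel == "exon").sum() == n_singles + n_sites


def test_noise_free_peak_equals_background_plus_amplitude():
    """Voxel at an isolated punctum's integer center is background + amplitude."""
    cfg = SceneConfig(
        image_shape=(3, 96, 96),
        n_nuclei=1,
        txn_sites_per_nucleus=0,
        single_spots_per_nucleus=3,
        noise_model=NO_NOISE,
        seed=2,
    )
    stack, _, truth = generate_scene(cfg)
    exon = stack.channel("exon")
    spots = truth.spots
    xy = spots[["y", "x"]].to_numpy()
    for _, row in spots.iterrows():
        d = np.hypot(xy[:, 0] - row.y, xy[:, 1] - row.x)
        if (d < 5 * cfg.spot_sigma_px).sum() > 1:
            continue  # not isolated
        # value at the punctum's continuous center sampled on its own grid
        yg, xg = np.mgrid[0:96, 0:96].astype(float)
        iy, ix = int(round(row.y)), int(round(row.x))
        expected = cfg.background_level + row.amplitude * np.exp(
            -((iy - row.y) ** 2 + (ix - row.x) ** 2) / (2 * cfg.spot_sigma_px**2)
        )
        assert exon[int(row.z), iy, ix] == pytest.approx(expected, rel=1e-6)


def test_seed_determinism_scene():
    cfg = SceneConfig(image_shape=(3, 128, 128), n_nuclei=2, seed=9)
    s1, m1, t1 = generate_scene(cfg)
    s2, m2, t2 = generate_scene(cfg)
    np.testing.assert_array_equal(s1.voxels, s2.voxels)
    np.testing.assert_array_equal(m1, m2)
    pd.testing.assert_frame_equal(t1.spots, t2.spots)


def test_mean_sites_per_nucleus_matches_poisson_mean():
    """Ground-truth mean sites/nucleus lands within 3 SE of the 1.5 average."""
    mean = 1.5
    cfg = SceneConfig(
        image_shape=(3, 620, 620),
        n_nuclei=500,
        nucleus_radius_px=(6.0, 0.5),
        txn_sites_per_nucleus=("poisson", mean),
        single_spots_per_nucleus=0,
        noise_model=NO_NOISE,
        seed=21,
    )
    _, _, truth = generate_scene(cfg)
    per_nucleus = truth.sites.groupby("nucleus_id").size().reindex(
        range(1, 501), fill_value=0
    )
    se = np.sqrt(mean / 500)
    assert abs(per_nucleus.mean() - mean) < 3 * se


def test_unplaceable_nuclei_fail_with_named_parameter():
    cfg = SceneConfig(image_shape=(2, 64, 64), n_nuclei=30, nucleus_radius_px=(20, 1))
    with pytest.raises(RuntimeError, match="n_nuclei|nucleus_radius_px"):
        generate_scene(cfg)


def test_axial_profile_center_weight_is_one():
    assert dict(AXIAL_PROFILE)[0] == 1.0


# --- amplification series ---------------------------------------------------


def test_noise_free_doubling_and_flat_series():
    series, fold = generate_amplification_series(
        AmplificationConfig(binding_efficiency=1.0, intensity_cv=0.0)
    )
    assert fold == 2.0
    means = [s.mean() for s in series.intensities]
    for a, b in zip(means, means[1:]):
        assert b == pytest.approx(2 * a)

    series, fold = generate_amplification_series(
        AmplificationConfig(binding_efficiency=0.5, intensity_cv=0.0, base_amplitude=100)
    )
    assert fold == 1.0
    assert all(np.allclose(s, 100.0) for s in series.intensities)


def test_amplification_sample_mean_converges():
    """Per-round sample mean approaches base * fold^k for large samples."""
    cfg = AmplificationConfig(
        binding_efficiency=0.871, intensity_cv=0.2, spots_per_round=10_000, seed=8
    )
    series, fold = generate_amplification_series(cfg)
    for k, samples in enumerate(series.intensities):
        expected = cfg.base_amplitude * fold**k
        se = samples.std(ddof=1) / np.sqrt(samples.size)
        assert abs(samples.mean() - expected) < 3 * se


def test_binding_efficiency_out_of_range_rejected():
    with pytest.raises(ValueError, match="binding_efficiency"):
        AmplificationConfig(binding_efficiency=1.2)
    with pytest.raises(ValueError, match="binding_efficiency"):
        AmplificationConfig(binding_efficiency=0.0)


# --- flow + qPCR ------------------------------------------------------------


def test_noise_free_qpcr_monotone_in_class_mean():
    events, qpcr, _ = generate_flow_and_qpcr(
        FlowSimConfig(qpcr_coupling_noise=0.0, seed=3)
    )
    assert qpcr["abundance"].is_monotonic_increasing
    class_means = events.groupby("latent_class")["fluorescence"].mean()
    assert class_means.loc[list(qpcr["group"])].is_monotonic_increasing


def test_flow_determinism_and_class_sizes():
    cfg = FlowSimConfig(n_events=50, seed=5)
    e1, q1, _ = generate_flow_and_qpcr(cfg)
    e2, q2, _ = generate_flow_and_qpcr(cfg)
    pd.testing.assert_frame_equal(e1, e2)
    pd.testing.assert_frame_equal(q1, q2)
    assert (e1.groupby("latent_class").size() == 50).all()


def test_nonincreasing_gate_means_rejected():
    with pytest.raises(ValueError, match="increasing"):
        FlowSimConfig(gate_means=(2.0, 1.0, 3.0), gate_sds=(0.2, 0.2, 0.2))


# --- FE tables --------------------------------------------------------------


def test_fe_table_null_effect_target_matches_control_distribution():
    fe = generate_fe_table(effect_size=0.0, n_replicates=4, base_fe_target=5.0,
                           base_fe_control=5.0, seed=6)
    # same construction for both genes when effect is 0 and bases equal:
    # group means should be statistically indistinguishable (loose sanity bound)
    by_gene = fe.groupby("gene")["FE"].mean()
    assert abs(by_gene["EEF2"] - by_gene["UBC"]) < 0.3


def test_fe_table_structure_and_effect_direction():
    fe = generate_fe_table(effect_size=1.0, n_replicates=3, noise_sd=0.0, seed=0)
    assert set(fe.gene) == {"EEF2", "UBC"}
    assert set(fe.amplicon) == {"5'UTR", "intron", "3'UTR"}
    assert (fe.groupby(["gene", "group", "replicate"]).size() == 3).all()
    target = fe[fe.gene == "EEF2"].groupby("group")["FE"].mean()
    assert target["G1"] > target["G2"] > target["G3"]  # FE drops as accessibility rises
    control = fe[fe.gene == "UBC"].groupby("group")["FE"].mean()
    assert control.nunique() == 1


def test_fe_table_rejects_no_replicates():
    with pytest.raises(ValueError, match="n_replicates"):
        generate_fe_table(effect_size=1.0, n_replicates=0)
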