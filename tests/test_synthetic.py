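"""Cohort feature generator and imaging phantom: moments, determinism."""

import numpy as np
import pytest

from hippolat.synthetic import (
    GROUP_TABLE,
    LABEL_CSF,
    LABEL_LEFT_HIPP,
    LABEL_OUTSIDE,
    GroupParams,
    PhantomConfig,
    draw_bilateral_values,
    generate_cohort_features,
    generate_control_cohort,
    generate_phantom_subject,
)

from conftest import SIX_TES


def with_n(params: GroupParams, n: int) -> GroupParams:
    import dataclasses
    return dataclasses.replace(params, n_subjects=n)


def test_feature_moments_match_generating_distribution():
    # MR-negative LTLE AI_SUVR: N(-0.61, 0.65); RTLE AI_T2: N(-1.11, 1.28)
    ltle = with_n(GROUP_TABLE["MRneg_LTLE"], 10**5)
    rtle = with_n(GROUP_TABLE["MRneg_RTLE"], 10**5)
    df = generate_cohort_features([ltle, rtle], seed=1)
    ai_suvr = df.loc[df.group == "MRneg_LTLE", "ai_suvr"]
    assert ai_suvr.mean() == pytest.approx(-0.61, abs=0.01)
    ai_t2 = df.loc[df.group == "MRneg_RTLE", "ai_t2"]
    assert ai_t2.std(ddof=1) == pytest.approx(1.28, abs=0.02)
    assert (df.loc[df.group == "MRneg_LTLE", "laterality"] == "L").all()
    assert (df.loc[df.group == "MRneg_RTLE", "laterality"] == "R").all()


def test_degenerate_sd_floor_gives_near_constant_draws():
    import dataclasses
    tiny = dataclasses.replace(
        GROUP_TABLE["HC"], ai_t2_mean=0.0, ai_t2_sd=1e-12,
        ai_suvr_mean=0.0, ai_suvr_sd=1e-12, n_subjects=50,
    )
    df = generate_cohort_features([tiny], seed=0)
    assert np.allclose(df.ai_t2, 0.0, atol=1e-9)
    assert np.allclose(df.ai_suvr, 0.0, atol=1e-9)


def test_nonpositive_sd_rejected():
    import dataclasses
    with pytest.raises(ValueError):
        dataclasses.replace(GROUP_TABLE["HC"], ai_t2_sd=0.0)


def test_feature_generation_deterministic_per_seed():
    groups = [GROUP_TABLE["MRneg_LTLE"], GROUP_TABLE["MRneg_RTLE"]]
    a = generate_cohort_features(groups, seed=42)
    b = generate_cohort_features(groups, seed=42)
    c = generate_cohort_features(groups, seed=43)
    assert a.equals(b)
    assert not a.equals(c)


def test_noiseless_phantom_is_exact_forward_model(noiseless_config):
    me, pet, labels, truth = generate_phantom_subject(
        noiseless_config, 110.0, 108.0, 0.93, 0.91, seed=0
    )
    left = labels == LABEL_LEFT_HIPP
    expected = 1000.0 * np.exp(-SIX_TES / 110.0)
    assert np.allclose(me.data[left], expected[None, :], rtol=0, atol=0)
    assert np.all(truth.data[labels == LABEL_CSF] == 2000.0)
    assert np.all(np.isnan(truth.data[labels == LABEL_OUTSIDE]))


def test_phantom_determinism_bit_identical(small_config):
    a = generate_phantom_subject(small_config, 110, 108, 0.93, 0.91, seed=5)
    b = generate_phantom_subject(small_config, 110, 108, 0.93, 0.91, seed=5)
    assert np.array_equal(a[0].data, b[0].data)
    assert np.array_equal(a[1].data, b[1].data, equal_nan=True)


def test_phantom_rejects_bad_geometry_and_params(small_config):
    with pytest.raises(ValueError):
        PhantomConfig(csf_t2=150.0)  # below the exclusion threshold
    with pytest.raises(ValueError):
        PhantomConfig(echo_times=(21.0, 10.5))
    with pytest.raises(ValueError):
        # overlapping hippocampal ellipsoids
        PhantomConfig(
            grid_shape=(32, 32, 16),
            geometry={"right_center": (9.6, 16.0, 8.0)},
        )
    with pytest.raises(ValueError):
        generate_phantom_subject(small_config, -1.0, 108, 0.93, 0.91, seed=0)


def test_control_cohort_delta_mean_and_boundaries(small_config):
    # feature-level check: mean left-minus-right T2 of healthy controls
    subs = generate_control_cohort(
        small_config, GROUP_TABLE["HC"], 10**4, seed=1, render=False
    )
    deltas = np.array([s.t2_left - s.t2_right for s in subs])
    assert deltas.mean() == pytest.approx(1.17, abs=0.1)
    suvr_deltas = np.array([s.suvr_left - s.suvr_right for s in subs])
    assert suvr_deltas.mean() == pytest.approx(0.02, abs=0.005)

    assert len(generate_control_cohort(
        small_config, GROUP_TABLE["HC"], 2, seed=0, render=False)) == 2
    with pytest.raises(ValueError):
        generate_control_cohort(small_config, GROUP_TABLE["HC"], 1, seed=0)


def test_control_cohort_seed_contract(small_config):
    a = generate_control_cohort(small_config, GROUP_TABLE["HC"], 3, seed=10,
                                render=False)
    b = generate_control_cohort(small_config, GROUP_TABLE["HC"], 3, seed=11,
                                render=False)
    assert any(x.t2_left != y.t2_left for x, y in zip(a, b))


def test_bilateral_marginal_moments_within_3_se():
    # moment recovery for every marginal of the bilateral draw
    params = GROUP_TABLE["MRHS_LTLE"]
    n = 20000
    rng = np.random.default_rng(0)
    df = draw_bilateral_values(params, n, rng)
    for col, mean, sd in (
        ("t2_left", params.t2_left_mean, params.t2_left_sd),
        ("t2_right", params.t2_right_mean, params.t2_right_sd),
        ("suvr_left", params.suvr_left_mean, params.suvr_left_sd),
        ("suvr_right", params.suvr_right_mean, params.suvr_right_sd),
    ):
        se_mean = sd / np.sqrt(n)
        assert abs(df[col].mean() - mean) < 3 * se_mean
        se_sd = sd / np.sqrt(2 * (n - 1))
        assert abs(df[col].std(ddof=1) - sd) < 3 * se_sd


def test_forward_fit_roundtrip_with_noise():
    # 2% noise: ROI-average recovery within 2 ms of the generating T2
    from hippolat.relaxometry import fit_t2_volume
    me, _, labels, _ = generate_phantom_subject(
        PhantomConfig(), 110.0, 110.0, 0.93, 0.91, seed=2
    )
    t2map = fit_t2_volume(me, labels != LABEL_OUTSIDE)
    assert np.nanmean(t2map.data[labels == LABEL_LEFT_HIPP]) == pytest.approx(
        110.0, abs=2.0
    )
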