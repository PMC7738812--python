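"""The twelve window statistics: closed forms, oracles, and invariances."""

import numpy as np
import pytest

from conftest import make_trace, random_trace
from fallstats.features import (
    FEATURE_NAMES,
    MobilityFeatureExtractor,
    compute_smv,
    extract_feature_table,
    extract_features,
)
from fallstats.trace_io import AccelTrace
from fallstats.windowing import AnalysisWindow, locate_analysis_window


def full_window(trace, a_wdiff_max=0.0):
    return AnalysisWindow(k_o=0, n_w=trace.n, a_wdiff_max=a_wdiff_max,
                          t_w=trace.n / trace.fs)


def test_smv_of_pure_gravity_is_one():
    trace = make_trace([0.0] * 8, 0.0, 1.0)
    np.testing.assert_array_equal(compute_smv(trace, full_window(trace)), 1.0)


def test_smv_345_identity():
    trace = make_trace([3.0, 0.0], [4.0, 0.0], [0.0, 1.0])
    smv = compute_smv(trace, full_window(trace))
    assert smv[0] == pytest.approx(5.0)


def test_smv_even_under_sign_flip(rng):
    trace = random_trace(rng, 40)
    flipped = make_trace(-trace.ax, -trace.ay, -trace.az)
    np.testing.assert_allclose(
        compute_smv(trace, full_window(trace)),
        compute_smv(flipped, full_window(flipped)),
    )


def test_constant_gravity_window_closed_forms():
    n_w = 50
    trace = make_trace([0.0] * n_w, 0.0, 1.0)
    fv = extract_features(trace, full_window(trace), vertical_axis="z")
    assert fv.mu_smv == pytest.approx(1.0)
    assert fv.sigma_smv == 0.0
    assert fv.mu_smv_diff == 0.0
    assert fv.mu_theta == 0.0
    assert fv.mu_ap == 0.0
    assert fv.a_wdiff_max == 0.0
    assert fv.smv_max == fv.smv_min == pytest.approx(1.0)
    assert fv.sma == pytest.approx(1.0)
    assert fv.energy == pytest.approx(n_w)  # Parseval: sum of squared samples
    assert np.isnan(fv.gamma_smv) and np.isnan(fv.mu_r)


def test_constant_tilted_vector_sma_and_horizontal_magnitude():
    trace = make_trace([0.5] * 10, [-0.5] * 10, [1.0] * 10)
    fv = extract_features(trace, full_window(trace), vertical_axis="z")
    assert fv.sma == pytest.approx(2.0)
    assert fv.mu_ap == pytest.approx(np.sqrt(0.5))


def test_mean_rotation_angle_alternating_unit_vectors():
    # 3 in-window pairs at 90 degrees each, 1/N_W prefactor with N_W = 4
    trace = make_trace([1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 0, 0])
    fv = extract_features(trace, full_window(trace), vertical_axis="z")
    assert fv.mu_theta == pytest.approx(3 * np.pi / 8, abs=1e-9)


def test_mean_autocorrelation_hand_example():
    # SMV = [2, 0, 2, 0] -> R = [1, -0.75, 0.5, -0.25], mean 0.125
    trace = make_trace([0.0] * 4, 0.0, [2.0, 0.0, 2.0, 0.0])
    fv = extract_features(trace, full_window(trace), vertical_axis="z")
    assert fv.mu_r == pytest.approx(0.125, abs=1e-9)


def test_energy_equals_parseval_sum(rng):
    for n_w in [2, 3, 5, 16, 17, 64, 127, 256]:
        trace = random_trace(rng, n_w)
        fv = extract_features(trace, full_window(trace), vertical_axis="z")
        direct = float((trace.components**2).sum())
        assert fv.energy == pytest.approx(direct, rel=1e-9)


def test_autocorrelation_lag_zero_is_one(rng):
    smv = np.abs(rng.normal(1, 0.5, 32))
    mu, sigma = smv.mean(), smv.std()
    c = smv - mu
    r0 = float((c @ c) / (sigma**2 * smv.size))
    assert r0 == pytest.approx(1.0, rel=1e-12)


ROTATION_INVARIANT = [
    "mu_smv", "sigma_smv", "mu_smv_diff", "mu_theta", "smv_max", "smv_min",
    "gamma_smv", "mu_r", "energy",
]


def test_rotation_invariance_of_magnitude_features(rng):
    from scipy.spatial.transform import Rotation

    trace = random_trace(rng, 60)
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    comp = trace.components @ rot.T
    rotated = make_trace(comp[:, 0], comp[:, 1], comp[:, 2])
    fv1 = extract_features(trace, full_window(trace), vertical_axis="z")
    fv2 = extract_features(rotated, full_window(rotated), vertical_axis="z")
    for name in ROTATION_INVARIANT:
        assert getattr(fv1, name) == pytest.approx(
            getattr(fv2, name), rel=1e-9, abs=1e-9
        ), name


def test_scale_equivariance(rng):
    c = 3.7
    trace = random_trace(rng, 60)
    scaled = make_trace(c * trace.ax, c * trace.ay, c * trace.az)
    w1 = locate_analysis_window(trace, 0.5)
    w2 = locate_analysis_window(scaled, 0.5)
    fv1 = extract_features(trace, w1, vertical_axis="z")
    fv2 = extract_features(scaled, w2, vertical_axis="z")
    linear = ["mu_smv", "sigma_smv", "mu_smv_diff", "mu_ap", "a_wdiff_max",
              "smv_max", "smv_min", "sma"]
    for name in linear:
        assert getattr(fv2, name) == pytest.approx(c * getattr(fv1, name),
                                                   rel=1e-9), name
    assert fv2.energy == pytest.approx(c**2 * fv1.energy, rel=1e-9)
    for name in ["mu_theta", "gamma_smv", "mu_r"]:
        assert getattr(fv2, name) == pytest.approx(getattr(fv1, name),
                                                   rel=1e-9), name


def test_smv_extremes_bound_every_sample(rng):
    trace = random_trace(rng, 80)
    w = locate_analysis_window(trace, 0.5)
    fv = extract_features(trace, w, vertical_axis="z")
    smv = compute_smv(trace, w)
    assert fv.smv_min <= smv.min() + 1e-12
    assert fv.smv_max >= smv.max() - 1e-12
    assert fv.smv_min <= fv.mu_smv <= fv.smv_max


def test_feature_table_has_fixed_schema_and_skips_short_traces(rng, caplog):
    import logging

    good = random_trace(rng, 100)
    good.trace_id, good.dataset = "good", "D1"
    short = random_trace(rng, 5)
    short.trace_id, short.dataset = "short", "D1"
    with caplog.at_level(logging.WARNING):
        table = extract_feature_table([good, short], t_w=0.5)
    assert list(table["trace_id"]) == ["good"]
    assert [c for c in table.columns if c in FEATURE_NAMES] == FEATURE_NAMES
    assert any("short" in r.message for r in caplog.records)


def test_transformer_matches_function_and_sklearn_contract(rng):
    from sklearn.base import clone

    traces = [random_trace(rng, 100) for _ in range(4)]
    for i, t in enumerate(traces):
        t.trace_id, t.dataset = f"t{i}", "D"
    est = MobilityFeatureExtractor(window_duration_s=0.5)
    assert clone(est).get_params()["window_duration_s"] == 0.5
    out = est.fit([]).transform(traces)
    ref = extract_feature_table(traces, t_w=0.5)
    assert est.n_features_out_ == 12
    np.testing.assert_allclose(
        out[FEATURE_NAMES].to_numpy(), ref[FEATURE_NAMES].to_numpy()
    )
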