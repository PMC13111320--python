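"""Separable-conv cost identity, network construction, losses, adaptive class
weights, training capacity and stage-transition extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitiphen import classifier as clf
from vitiphen.classifier import (
    ClassWeightState,
    ConvCostSpec,
    LossConfig,
    NetworkSpec,
    build_network,
    compute_loss,
    conv_cost,
    transitions_from_stages,
    update_class_weights,
)


# ---------------------------------------------------------------- conv cost

def test_conv_cost_worked_example():
    z_n, z_s, ratio = conv_cost(ConvCostSpec(d_k=3, m=1, n=32, d_f=26))
    assert z_n == 194_688
    assert ratio == pytest.approx(1 / 32 + 1 / 9, abs=1e-12)


def test_identity_kernel_edge_case():
    _, _, ratio = conv_cost(ConvCostSpec(d_k=1, m=4, n=1, d_f=8))
    assert ratio == pytest.approx(2.0)


@given(
    st.integers(1, 7), st.integers(1, 64), st.integers(1, 128), st.integers(1, 64)
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_cost_ratio_closed_form(d_k, m, n, d_f):
    _, _, ratio = conv_cost(ConvCostSpec(d_k=d_k, m=m, n=n, d_f=d_f))
    assert ratio == pytest.approx(1 / n + 1 / d_k**2, abs=1e-12)


# ---------------------------------------------------------------- network

@pytest.fixture(scope="module")
def tiny_net():
    return build_network(
        NetworkSpec(width_multiplier=0.25, expansion=2, final_feature_width=32),
        dropout=0.3, kernel_size=3, seed=0,
    )


def test_forward_emits_probability_vectors(tiny_net):
    x = np.random.default_rng(0).random((5, 1, 26, 3))
    probs = tiny_net.predict_proba(x)
    assert probs.shape == (5, 4)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    zero = tiny_net.predict_proba(np.zeros((1, 1, 26, 3)))
    np.testing.assert_allclose(zero.sum(), 1.0, atol=1e-6)


def test_inference_deterministic(tiny_net):
    x = np.random.default_rng(1).random((3, 1, 26, 3))
    np.testing.assert_array_equal(tiny_net.predict_proba(x), tiny_net.predict_proba(x))


def test_full_width_parameter_count_under_one_million():
    net = build_network(NetworkSpec(), dropout=0.45, kernel_size=3, seed=0)
    assert net.param_count < 1_000_000
    assert net.param_count > 50_000  # it is still a 16-block trunk


def test_bad_input_shape_rejected(tiny_net):
    with pytest.raises(ValueError):
        tiny_net.forward(np.zeros((2, 1, 13, 3)))
    with pytest.raises(ValueError):
        build_network(NetworkSpec(), kernel_size=4)


# ---------------------------------------------------------------- losses

def test_uniform_weighted_equals_plain():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.ones(4), size=32)
    onehot = np.eye(4)[rng.integers(0, 4, 32)]
    plain = compute_loss(probs, onehot, LossConfig(mode="plain_ce", adaptive=False))
    weighted = compute_loss(
        probs, onehot,
        LossConfig(mode="weighted_ce", weights=np.full(4, 0.25), adaptive=False),
    )
    assert weighted == pytest.approx(0.25 * plain, abs=1e-9)  # uniform w scales by 1/4
    # with w = 1 the weighted loss equals the plain loss exactly
    ones = compute_loss(
        probs, onehot, LossConfig(mode="weighted_ce", weights=np.ones(4), adaptive=False)
    )
    assert ones == pytest.approx(plain, abs=1e-9)


def test_focal_zero_exponent_equals_plain():
    rng = np.random.default_rng(1)
    probs = rng.dirichlet(np.ones(4), size=16)
    onehot = np.eye(4)[rng.integers(0, 4, 16)]
    plain = compute_loss(probs, onehot, LossConfig(mode="plain_ce", adaptive=False))
    focal0 = compute_loss(probs, onehot, LossConfig(mode="focal", focal_exponent=0.0, adaptive=False))
    assert focal0 == pytest.approx(plain, abs=1e-9)


def test_uniform_prediction_loss_is_ln4():
    probs = np.full((8, 4), 0.25)
    onehot = np.eye(4)[np.zeros(8, dtype=int)]
    assert compute_loss(probs, onehot, LossConfig(mode="plain_ce", adaptive=False)) == pytest.approx(
        np.log(4), abs=1e-9
    )


def test_perfect_prediction_zero_loss():
    onehot = np.eye(4)[np.arange(4)]
    assert compute_loss(onehot, onehot, LossConfig(mode="plain_ce", adaptive=False)) == pytest.approx(
        0.0, abs=1e-9
    )


# ---------------------------------------------------------------- class weights

def test_equal_recalls_give_uniform_weights():
    conf = np.diag([5, 5, 5, 5])
    for mapping in ("identity", "cube", "exp", "exp100", "ten_y"):
        st_ = update_class_weights(conf, mapping)
        np.testing.assert_allclose(st_.weights, 0.25)


def test_exp_mapping_worked_example():
    conf = np.array([[0, 5, 0, 0], [0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5]])
    st_ = update_class_weights(conf, "exp")
    assert st_.weights[0] == pytest.approx(np.e / (np.e + 3), abs=1e-4)
    np.testing.assert_allclose(st_.weights[1:], (1 - np.e / (np.e + 3)) / 3, atol=1e-4)


def test_identity_mapping_already_normalized():
    # recalls 0.8, 0.8, 0.7, 0.7 -> Mr (0.2, 0.2, 0.3, 0.3), already summing to 1
    conf = np.array([[8, 2, 0, 0], [0, 8, 2, 0], [0, 0, 7, 3], [3, 0, 0, 7]])
    st_ = update_class_weights(conf, "identity")
    np.testing.assert_allclose(st_.weights, [0.2, 0.2, 0.3, 0.3], atol=1e-12)


def test_absent_class_carries_recall_forward():
    prev = ClassWeightState(
        recall=np.array([0.5, 1.0, 1.0, 1.0]),
        error_rate=np.array([0.5, 0.0, 0.0, 0.0]),
        weights=np.full(4, 0.25),
        epoch=1,
    )
    conf = np.array([[0, 0, 0, 0], [0, 4, 0, 0], [0, 0, 4, 0], [0, 0, 0, 4]])
    st_ = update_class_weights(conf, "exp", prev)
    assert st_.recall[0] == 0.5  # carried forward
    assert st_.weights.sum() == pytest.approx(1.0)


def test_weight_monotone_in_class_error():
    base = np.diag([10, 10, 10, 10]).astype(float)
    worse = base.copy()
    worse[0, 0] = 6
    worse[0, 1] = 4  # class 0 recall drops to 0.6
    for mapping in ("identity", "cube", "exp", "exp100", "ten_y"):
        w0 = update_class_weights(base, mapping).weights[0]
        w1 = update_class_weights(worse, mapping).weights[0]
        assert w1 > w0


# ---------------------------------------------------------------- training

def test_overfits_small_toy_set():
    """Capacity sanity: the network reaches 100% training accuracy on a
    50-sample toy problem given enough epochs."""
    rng = np.random.default_rng(3)
    x = 0.3 * rng.random((50, 1, 26, 3))
    y = rng.integers(0, 4, 50)
    for i, k in enumerate(y):  # class signature: an elevated band of rows
        x[i, 0, 6 * k : 6 * k + 6, :] += 0.5
    spec = NetworkSpec(width_multiplier=0.25, expansion=2, final_feature_width=32)
    theta = {"learning_rate": 5e-3, "batch_size": 16, "dropout": 0.0,
             "kernel_size": 3, "epochs": 60}
    model, history = clf.train_model(
        x, y, x, y, theta, LossConfig(mode="plain_ce", adaptive=False), seed=0, spec=spec
    )
    pred = model.predict_proba(x).argmax(axis=1)
    assert (pred == y).mean() == 1.0
    assert history[-1]["val_accuracy"] == 1.0


def test_training_loss_decreases_initially():
    rng = np.random.default_rng(4)
    x = rng.random((120, 1, 26, 3))
    y = (x[:, 0, :, 0].mean(axis=1) > 0.5).astype(int) + 2 * (
        x[:, 0, :, 2].mean(axis=1) > 0.5
    ).astype(int)
    spec = NetworkSpec(width_multiplier=0.25, expansion=2, final_feature_width=32)
    theta = {"learning_rate": 3e-3, "batch_size": 32, "dropout": 0.1,
             "kernel_size": 3, "epochs": 8}
    _, history = clf.train_model(
        x, y, x, y, theta, LossConfig(mode="plain_ce", adaptive=False), seed=0, spec=spec
    )
    losses = [h["train_loss"] for h in history]
    assert np.mean(losses[-3:]) < np.mean(losses[:3])


def test_missing_class_raises_named_error():
    x = np.random.default_rng(5).random((12, 1, 26, 3))
    y = np.array([0, 1, 2] * 4)  # class 3 (harvest) absent
    with pytest.raises(ValueError, match="harvest"):
        clf.train_model(x, y, x, y, {"learning_rate": 1e-3, "batch_size": 4,
                                     "dropout": 0.0, "kernel_size": 3, "epochs": 1})


def test_adaptive_weights_remain_probability_vector():
    rng = np.random.default_rng(6)
    x = rng.random((60, 1, 26, 3))
    y = rng.integers(0, 4, 60)
    spec = NetworkSpec(width_multiplier=0.25, expansion=2, final_feature_width=32)
    theta = {"learning_rate": 1e-3, "batch_size": 16, "dropout": 0.0,
             "kernel_size": 3, "epochs": 3}
    _, history = clf.train_model(
        x, y, x, y, theta, LossConfig(mode="weighted_ce", adaptive=True), seed=0, spec=spec
    )
    for h in history:
        assert np.isclose(sum(h["class_weights"]), 1.0)


# ---------------------------------------------------------------- transitions

def test_transition_onset_midpoint_example():
    stages = ["budburst", "budburst", "flowering", "flowering", "veraison", "harvest"] + [
        "harvest"
    ] * 20
    onsets = transitions_from_stages(stages)
    assert onsets["budburst"] == 8
    assert onsets["flowering"] == 36  # midpoint of interval 3
    assert onsets["veraison"] == 64
    assert onsets["harvest"] == 78


def test_transitions_monotonize_regressions():
    stages = ["flowering", "budburst", "flowering", "veraison", "flowering", "harvest"] + [
        "harvest"
    ] * 20
    onsets = transitions_from_stages(stages)
    # the budburst regression at interval 2 is absorbed by the running maximum
    assert "budburst" not in onsets
    assert onsets["flowering"] == 8


def test_degenerate_single_stage_sequence():
    onsets = transitions_from_stages(["flowering"] * 26)
    assert list(onsets) == ["flowering"]
    assert onsets["flowering"] == 8


def test_model_roundtrip_checkpoint(tmp_path, tiny_net):
    x = np.random.default_rng(9).random((4, 1, 26, 3))
    before = tiny_net.predict_proba(x)
    clf.save_model(tiny_net, str(tmp_path / "m"), extra={"note": 1})
    model, extra = clf.load_model(str(tmp_path / "m"))
    np.testing.assert_allclose(model.predict_proba(x), before, atol=1e-6)
    assert extra == {"note": 1}
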