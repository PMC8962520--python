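"""Enhancement network: contracts, loss, training behaviour."""

import math

import numpy as np
import pytest

from octenhance import (
    FrameStack, NetConfig, TrainConfig, acquire_frames, build_network,
    combined_loss, enhance, make_phantom, ssim, train,
)


def _tiny_dataset(n_stacks=6, n_frames=6, seed0=0, h=64, w=64):
    data = []
    for i in range(n_stacks):
        truth = make_phantom(h, w, seed=seed0 + i)
        stack = acquire_frames(truth, n_frames, (0.0, 0.0), 0.0,
                               seed=seed0 + 100 + i)
        data.append((stack, truth.clean))
    return data


# ------------------------------------------------------------ construction

def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        NetConfig(n_input_frames=0)
    with pytest.raises(ValueError):
        NetConfig(n_input_frames=21)
    with pytest.raises(ValueError):
        NetConfig(base_channels=2)
    with pytest.raises(ValueError):
        NetConfig(weighted_sum_mode="other")


@pytest.mark.parametrize("k", [1, 5])
def test_output_shape_and_range(k):
    model = build_network(NetConfig(n_input_frames=k, base_channels=4, seed=0))
    rng = np.random.default_rng(0)
    x = rng.random((1, k, 64, 64), dtype=np.float32)
    out = model.net.forward(x).data
    assert out.shape == (1, 1, 64, 64)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_fixed_weight_one_bypasses_network_exactly():
    model = build_network(NetConfig(
        n_input_frames=3, base_channels=4,
        weighted_sum_mode="fixed", fixed_weight=1.0, seed=1,
    ))
    rng = np.random.default_rng(1)
    frames = rng.random((3, 64, 64)).astype(np.float32)
    stack = FrameStack(frames=frames, aligned=True)
    out = enhance(model, stack)
    np.testing.assert_allclose(out, frames.mean(axis=0), atol=1e-7)


def test_identical_frames_give_order_invariant_output():
    model = build_network(NetConfig(n_input_frames=4, base_channels=4, seed=2))
    frame = make_phantom(64, 64, seed=3).clean.astype(np.float32)
    stack = FrameStack(frames=np.stack([frame] * 4), aligned=True)
    a = enhance(model, stack)
    b = enhance(model, stack)  # any permutation of identical frames
    np.testing.assert_array_equal(a, b)


def test_enhance_pads_non_multiple_of_eight_shapes():
    model = build_network(NetConfig(n_input_frames=2, base_channels=4, seed=4))
    rng = np.random.default_rng(5)
    frames = rng.random((2, 67, 93)).astype(np.float32)
    out = enhance(model, FrameStack(frames=frames, aligned=True))
    assert out.shape == (67, 93)


def test_enhance_requires_enough_surviving_frames():
    model = build_network(NetConfig(n_input_frames=5, base_channels=4, seed=0))
    frames = np.random.default_rng(0).random((3, 64, 64))
    with pytest.raises(ValueError):
        enhance(model, FrameStack(frames=frames, aligned=True))


# ------------------------------------------------------------------- loss

def test_combined_loss_reduces_to_bce_and_ssim_terms(phantom):
    rng = np.random.default_rng(6)
    pred = np.clip(phantom.clean + rng.normal(0, 0.05, phantom.clean.shape), 0, 1)
    target = phantom.clean
    eps = 1e-12
    p = np.clip(pred, eps, 1 - eps)
    bce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    assert combined_loss(pred, target, (1.0, 0.0)) == pytest.approx(bce)
    assert combined_loss(pred, target, (0.0, 1.0)) == pytest.approx(
        1.0 - ssim(pred, target))
    assert combined_loss(pred, target, (1.0, 1.0)) == pytest.approx(
        bce + 1.0 - ssim(pred, target))


def test_combined_loss_constant_half_hits_entropy_floor():
    half = np.full((32, 32), 0.5)
    loss = combined_loss(half, half, (1.0, 1.0))
    assert loss == pytest.approx(math.log(2.0), abs=1e-9)  # SSIM term is 0


def test_combined_loss_ssim_term_zero_for_identical_images(phantom):
    assert combined_loss(phantom.clean, phantom.clean, (0.0, 1.0)) == \
        pytest.approx(0.0, abs=1e-9)


def test_inverted_prediction_scores_worse_than_match():
    rng = np.random.default_rng(7)
    target = (rng.random((64, 64)) > 0.5).astype(float)
    eps = 1e-3
    good = np.clip(target, eps, 1 - eps)
    bad = np.clip(1.0 - target, eps, 1 - eps)
    assert combined_loss(bad, target) > combined_loss(good, target)


def test_combined_loss_validates_inputs(phantom):
    with pytest.raises(ValueError):
        combined_loss(phantom.clean, phantom.clean[:64])
    with pytest.raises(ValueError):
        combined_loss(phantom.clean + 2.0, phantom.clean)


def test_train_config_invariants():
    with pytest.raises(ValueError):
        TrainConfig(decay_factor=1.5)
    with pytest.raises(ValueError):
        TrainConfig(loss_weights=(0.0, 0.0))


# --------------------------------------------------------------- training

def test_training_reduces_loss_and_residual_weight_drifts_up():
    # Targets equal the mean of the inputs: the averaging solution (w = 1)
    # is optimal, so loss falls and the learnable blend weight rises.
    rng = np.random.default_rng(8)
    data = []
    for i in range(6):
        frames = np.clip(rng.normal(0.5, 0.15, (3, 64, 64)), 0, 1)
        stack = FrameStack(frames=frames, aligned=True)
        data.append((stack, frames.mean(axis=0)))
    model = build_network(NetConfig(n_input_frames=3, base_channels=4, seed=0))
    w0 = model.residual_weight
    model = train(model, data, TrainConfig(max_epochs=10, batch_size=3, seed=0))
    assert model.history[-1]["loss"] < model.history[0]["loss"]
    assert model.residual_weight > w0


def test_training_improves_enhancement_of_phantom_stacks():
    data = _tiny_dataset(6)
    model = build_network(NetConfig(n_input_frames=5, base_channels=4, seed=1))
    model = train(model, data, TrainConfig(max_epochs=8, batch_size=3, seed=1))
    truth = make_phantom(64, 64, seed=50)
    stack = acquire_frames(truth, 5, (0.0, 0.0), 0.0, seed=51)
    out = enhance(model, stack)
    best_single = max(ssim(f, truth.clean) for f in stack.frames)
    assert ssim(out, truth.clean) > best_single


def test_learning_rate_decays_after_patience_epochs_on_plateau():
    data = _tiny_dataset(2, h=64, w=64)
    model = build_network(NetConfig(n_input_frames=2, base_channels=4, seed=2))
    # Vanishingly small steps: the monitored loss never improves measurably,
    # so the decay rule fires exactly once after `patience_epochs` epochs.
    tc = TrainConfig(lr_init=1e-12, patience_epochs=10, max_epochs=12,
                     batch_size=2, seed=2)
    model = train(model, data, tc)
    lrs = [h["lr"] for h in model.history]
    assert lrs[9] == pytest.approx(1e-12)      # epoch 9: not yet decayed
    assert lrs[10] == pytest.approx(0.9e-12)   # decayed after 10 stale epochs
    assert lrs[12] == pytest.approx(0.9e-12)   # counter was reset


def test_training_is_deterministic_given_seeds():
    data = _tiny_dataset(3)
    runs = []
    for _ in range(2):
        model = build_network(NetConfig(n_input_frames=3, base_channels=4, seed=3))
        model = train(model, data, TrainConfig(max_epochs=3, batch_size=2, seed=3))
        runs.append([h["loss"] for h in model.history])
    assert runs[0] == runs[1]


def test_training_rejects_empty_or_short_datasets():
    model = build_network(NetConfig(n_input_frames=5, base_channels=4, seed=0))
    with pytest.raises(ValueError):
        train(model, [], TrainConfig())
    frames = np.random.default_rng(0).random((2, 64, 64))
    short = [(FrameStack(frames=frames, aligned=True), frames.mean(axis=0))]
    with pytest.raises(ValueError):
        train(model, short, TrainConfig())
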