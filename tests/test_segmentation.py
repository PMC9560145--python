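"""Residual UNet: shape contracts, loss semantics, training and inference."""

import numpy as np
import pytest

from cocoonct import nn
from cocoonct.phantom import generate_phantom
from cocoonct.preprocessing import ClipWindow, clip_normalize
from cocoonct.segmentation import (ModelSpec, TrainConfig, build_model, dice_loss,
                                   foreground_dice, load_checkpoint, predict_volume,
                                   save_checkpoint, train)
from conftest import clean_phantom_spec

#: Total trainable-parameter count of the production architecture (5 depths,
#: 16/32/64/128/256 filters).  Regression guard against silent drift.
DEFAULT_PARAMETER_COUNT = 5_737_155


def test_reduced_model_shape_contract():
    model = build_model(ModelSpec(depths=3, filters_per_depth=(8, 16, 32)), seed=0)
    x = np.zeros((1, 1, 32, 32, 32), dtype=np.float32)
    y = model.forward(x)
    assert y.shape == (1, 3, 32, 32, 32)


def test_default_model_accepts_96_cube_and_has_fixed_size():
    model = build_model(ModelSpec(), seed=0)
    assert model.n_parameters == DEFAULT_PARAMETER_COUNT
    y = model.forward(np.zeros((1, 1, 96, 96, 96), dtype=np.float32))
    assert y.shape == (1, 3, 96, 96, 96)


def test_model_init_deterministic_under_seed():
    a = build_model(ModelSpec.tiny(), seed=5)
    b = build_model(ModelSpec.tiny(), seed=5)
    for pa, pb in zip(a.params(), b.params()):
        np.testing.assert_array_equal(pa.val, pb.val)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(depths=3, filters_per_depth=(8, 16))
    with pytest.raises(ValueError):
        ModelSpec(depths=3, filters_per_depth=(8, 8, 16))


def test_dice_loss_perfect_prediction_is_zero(rng):
    labels = rng.integers(0, 3, size=(1, 4, 4, 4))
    target = nn.one_hot(labels, 3)
    assert dice_loss(target, target) == pytest.approx(0.0, abs=1e-4)


def test_dice_loss_maximally_wrong_approaches_one():
    labels = np.zeros((1, 4, 4, 4), dtype=int)
    labels[0, :2] = 1
    target = nn.one_hot(labels, 2)
    flipped = target[:, ::-1].copy()
    assert dice_loss(flipped, target, include_background=True) == pytest.approx(1.0, abs=1e-4)


def test_dice_loss_uniform_probabilities_on_balanced_grid():
    # 2x2x2 grid, half class 0 / half class 1, p = 0.5 everywhere:
    # per class: 2*sum(p*g)/(sum p + sum g) = 2*2/(4+4) = 0.5 -> loss 0.5
    labels = np.zeros((1, 2, 2, 2), dtype=int)
    labels[0, 1] = 1
    probs = np.full((1, 2, 2, 2, 2), 0.5)
    loss = dice_loss(probs, nn.one_hot(labels, 2), smooth=0.0, include_background=True)
    assert loss == pytest.approx(0.5, abs=1e-12)


def test_dice_loss_rejects_empty_input():
    with pytest.raises(ValueError):
        dice_loss(np.zeros((1, 2, 0, 0, 0)), np.zeros((1, 2, 0, 0, 0)))


def _tiny_phantom_pair(seed):
    spec = clean_phantom_spec(seed=seed, shape=(32, 32, 32), n_cocoons=3)
    hu, lab, _, truth = generate_phantom(spec)
    return hu, lab


def test_training_reduces_loss_and_is_deterministic():
    vols = [_tiny_phantom_pair(1), _tiny_phantom_pair(2)]
    cfg = TrainConfig(learning_rate=3e-3, epochs=4, batch_size=2, patches_per_volume=2,
                      seed=0, patch_size=32, val_interval=100)
    model, log = train(build_model(ModelSpec.tiny(), seed=0), vols, [], cfg)
    assert log[-1]["train_loss"] < log[0]["train_loss"]
    model2, log2 = train(build_model(ModelSpec.tiny(), seed=0), vols, [], cfg)
    assert log2[-1]["train_loss"] == pytest.approx(log[-1]["train_loss"], abs=0.0)


def test_training_preconditions():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError, match="at least one"):
        train(build_model(ModelSpec.tiny()), [], [], TrainConfig(epochs=1, patch_size=32))
    blank = (np.full((32, 32, 32), -1000.0, dtype=np.float32),
             np.zeros((32, 32, 32), dtype=np.uint8))
    with pytest.raises(ValueError, match="foreground"):
        train(build_model(ModelSpec.tiny()), [blank], [], TrainConfig(epochs=1, patch_size=32))


def test_predict_volume_probabilities_normalized_and_patch_consistent():
    hu, _ = _tiny_phantom_pair(3)
    model = build_model(ModelSpec.tiny(), seed=1)
    probs = predict_volume(model, hu, patch_size=32, overlap=0.0)
    assert probs.shape == (3, 32, 32, 32)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)
    # a volume exactly one patch wide with no overlap equals a single forward pass
    direct = model.predict_proba_patch(clip_normalize(hu))
    np.testing.assert_allclose(probs, direct, atol=1e-5)


def test_predict_volume_pads_and_crops_small_inputs():
    hu = np.full((20, 24, 28), -1000.0, dtype=np.float32)
    model = build_model(ModelSpec.tiny(), seed=1)
    probs = predict_volume(model, hu, patch_size=32, overlap=0.25)
    assert probs.shape == (3, 20, 24, 28)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_constant_input_prediction_periodic_in_interior():
    # stride-2 down/upsampling twice makes the tiny net shift-invariant
    # modulo a 4-voxel lattice: on constant input, interior probabilities
    # must agree between lattice-shifted voxels
    # (the patch must dwarf the receptive field so the centre is border-free)
    hu = np.full((96, 96, 96), -200.0, dtype=np.float32)
    model = build_model(ModelSpec.tiny(), seed=2)
    probs = predict_volume(model, hu, patch_size=96, overlap=0.0)
    center = probs[:, 48, 48, 48]
    for shift in ((4, 0, 0), (0, 4, 0), (0, 0, 4), (4, 4, 4), (-8, 4, 0)):
        other = probs[:, 48 + shift[0], 48 + shift[1], 48 + shift[2]]
        np.testing.assert_allclose(other, center, atol=1e-3)


def test_checkpoint_round_trip(tmp_path):
    hu, _ = _tiny_phantom_pair(4)
    model = build_model(ModelSpec.tiny(), seed=3)
    save_checkpoint(tmp_path / "model", model)
    loaded = load_checkpoint(tmp_path / "model.npz")
    a = model.predict_proba_patch(clip_normalize(hu))
    b = loaded.predict_proba_patch(clip_normalize(hu))
    np.testing.assert_array_equal(a, b)


def test_foreground_dice_definition():
    pred = np.zeros((4, 4, 4), dtype=int)
    true = np.zeros((4, 4, 4), dtype=int)
    pred[0, 0, :2] = 1
    true[0, 0, 1:3] = 2  # class disagreement is irrelevant to foreground dice
    assert foreground_dice(pred, true) == pytest.approx(0.5)
    assert foreground_dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))) == 1.0
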