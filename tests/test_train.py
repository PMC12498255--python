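"""SGD rule, training loop contracts, evaluation pipeline."""

from dataclasses import replace

import numpy as np
import pytest

from trunet.calibration import calibrated_config
from trunet.metrics import soft_dice_loss
from trunet.model import build_variant
from trunet.nn import Tensor, sgd_step
from trunet.nn import functional as F
from trunet.train import (Sample, TrainConfig, evaluate, make_dataset,
                          synthetic_split, train)


# -- the update rule --------------------------------------------------------

def test_sgd_step_hand_arithmetic():
    # theta = 1, L = theta^2, lr = 0.1, no momentum: theta' = 1 - 0.1*2 = 0.8
    theta, _ = sgd_step(np.array(1.0), np.array(2.0), lr=0.1)
    assert theta == pytest.approx(0.8)


def test_sgd_step_zero_gradient_is_identity():
    theta, _ = sgd_step(np.array(3.7), np.array(0.0), lr=0.5)
    assert theta == pytest.approx(3.7)


def test_sgd_step_momentum_two_step_recursion():
    # mu=0.9, constant gradient g: v1=g, v2=1.9g,
    # theta2 = theta0 - lr*g*(1 + 1.9)
    g = np.array(2.0)
    theta, v = sgd_step(np.array(1.0), g, lr=0.1, momentum=0.9)
    theta, v = sgd_step(theta, g, lr=0.1, velocity=v, momentum=0.9)
    assert theta == pytest.approx(1.0 - 0.1 * 2.0 * (1 + 1.9))


def test_sgd_step_rejects_non_finite_gradient():
    with pytest.raises(FloatingPointError):
        sgd_step(np.array(1.0), np.array(np.nan), lr=0.1)


# -- training loop ----------------------------------------------------------

def tiny_setup(seed=0, n_pullbacks=2, frames=6):
    cfg = calibrated_config(image_size=32, width_multiplier=0.0625,
                            sequence_length=3)
    model = build_variant(cfg, rng=np.random.default_rng(seed))
    dataset = synthetic_split(n_pullbacks, frames, 3, dict(image_size=32),
                              seed=seed)
    return model, dataset


def test_zero_learning_rate_freezes_weights():
    model, dataset = tiny_setup()
    before = {k: v.copy() for k, v in model.state_dict().items()
              if not k.endswith(("running_mean", "running_var"))}
    tc = TrainConfig(epochs=1, batch_size=4, learning_rate=0.0, seed=0)
    model, _ = train(model, dataset, tc)
    after = model.state_dict()
    for k, v in before.items():
        assert np.array_equal(after[k], v), k


def test_same_seed_gives_identical_history():
    histories = []
    for _ in range(2):
        model, dataset = tiny_setup(seed=1)
        tc = TrainConfig(epochs=2, batch_size=4, learning_rate=0.02, seed=5)
        _, h = train(model, dataset, tc, val_dataset=dataset[:2])
        histories.append(h)
    assert histories[0].train_loss == histories[1].train_loss
    assert histories[0].val_loss == histories[1].val_loss
    assert histories[0].val_js == histories[1].val_js


def test_training_reduces_dice_loss():
    model, dataset = tiny_setup(seed=2, n_pullbacks=3, frames=8)
    tc = TrainConfig(epochs=6, batch_size=4, learning_rate=0.02, seed=2)
    _, h = train(model, dataset, tc)
    assert len(h.train_loss) == 6
    assert all(0.0 <= l <= 1.0 for l in h.train_loss)     # Dice loss bounds
    assert h.train_loss[-1] < h.train_loss[0]


def test_gradient_sanity_finite_differences():
    """Autodiff gradient of the total Dice loss vs central differences at
    five random weights (64-bit, tiny model)."""
    cfg = calibrated_config(image_size=32, width_multiplier=0.0625,
                            sequence_length=2)
    model = build_variant(cfg, rng=np.random.default_rng(4), dtype=np.float64)
    model.eval()     # frozen BN statistics make the loss a clean function
    rng = np.random.default_rng(0)
    x = rng.random((1, 2, 1, 32, 32))
    y = (rng.random((1, 1, 32, 32)) > 0.6).astype(float)

    def loss_value():
        return float(soft_dice_loss(model(x), y).item())

    loss = soft_dice_loss(model(x), y)
    model.zero_grad()
    loss.backward()
    params = [p for p in model.parameters() if p.grad is not None
              and np.abs(p.grad).max() > 1e-8]
    picked = rng.choice(len(params), size=5, replace=False)
    eps = 1e-6
    for pi in picked:
        p = params[pi]
        flat_idx = int(np.argmax(np.abs(p.grad)))
        idx = np.unravel_index(flat_idx, p.shape)
        orig = p.data[idx]
        p.data[idx] = orig + eps
        fp = loss_value()
        p.data[idx] = orig - eps
        fm = loss_value()
        p.data[idx] = orig
        num = (fp - fm) / (2 * eps)
        assert num == pytest.approx(p.grad[idx], rel=1e-3, abs=1e-9)


def test_nan_loss_aborts():
    model, dataset = tiny_setup()
    for p in model.parameters():
        p.data[:] = np.nan
    tc = TrainConfig(epochs=1, batch_size=2, learning_rate=0.01, seed=0)
    with pytest.raises(FloatingPointError):
        train(model, dataset, tc)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=0)
    with pytest.raises(ValueError):
        TrainConfig(loss="bce")


# -- evaluation -------------------------------------------------------------

class _StubModel:
    """Predictor stub keyed by the target slice of each unit."""

    def __init__(self, mapping):
        self.mapping = mapping
        self.training = False

    def eval(self):
        return self

    def __call__(self, x):
        x = np.asarray(x)
        key = x[0, -1].tobytes()
        return Tensor(self.mapping[key][None, None].astype(np.float32))


def eval_dataset(seed=0):
    return synthetic_split(2, 6, 3, dict(image_size=32, blood_artifact_prob=0.4),
                           seed=seed)


def test_evaluate_oracle_predictor_scores_one():
    dataset = eval_dataset()
    mapping = {s.unit.target.astype(np.float32).tobytes():
               np.clip(s.mask.astype(np.float32), 0.01, 0.99) for s in dataset}
    report, df = evaluate(_StubModel(mapping), dataset)
    for k, v in report["all"].items():
        assert v == pytest.approx(1.0)
    if report["artifact"]:
        for v in report["artifact"].values():
            assert v == pytest.approx(1.0)


def test_evaluate_all_ones_predictor_recall_and_precision():
    dataset = eval_dataset(seed=3)
    mapping = {s.unit.target.astype(np.float32).tobytes():
               np.full(s.mask.shape, 0.9, dtype=np.float32) for s in dataset}
    report, df = evaluate(_StubModel(mapping), dataset)
    assert report["all"]["recall"] == pytest.approx(1.0)
    lumen_fraction = np.mean([s.mask.mean() for s in dataset])
    assert report["all"]["precision"] == pytest.approx(lumen_fraction)


def test_evaluate_subset_partition():
    dataset = eval_dataset(seed=4)
    mapping = {s.unit.target.astype(np.float32).tobytes():
               np.clip(s.mask.astype(np.float32), 0.01, 0.99) for s in dataset}
    report, df = evaluate(_StubModel(mapping), dataset)
    n_clean = int((~df["artifact"]).sum())
    assert report["n_images"] == report["n_artifact"] + n_clean


def test_make_dataset_one_sample_per_frame():
    from trunet.phantom import PhantomConfig, generate_pullback
    ph = generate_pullback(PhantomConfig(image_size=32, n_frames=5,
                                         base_radius=9.0, harmonic_amps=(1.5,),
                                         wall_thickness=3.0, catheter_radius=2.0,
                                         seed=0))
    samples = make_dataset([ph], T=3)
    assert len(samples) == 5
    assert all(s.unit.T == 3 for s in samples)
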