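"""Adversarial branch: contracts of the ops, exact loss decomposition, training."""

import numpy as np
import pytest

from cardioda import nn
from cardioda.gan_branch import (
    GanLossWeights,
    GanModelSpec,
    GanTrainer,
    TrainBatch,
    adversarial_loss,
    build_components,
    reconstruct,
    segment,
    segmentation_loss,
    total_loss,
    translate,
)

SIZE = 16


@pytest.fixture(scope="module")
def components():
    return build_components(GanModelSpec(input_size=SIZE, width=4), seed=0)


@pytest.fixture
def batch(rng):
    xs = rng.uniform(-1, 1, (2, 1, SIZE, SIZE)).astype(np.float32)
    ys = rng.integers(0, 7, (2, SIZE, SIZE))
    xt = rng.uniform(-1, 1, (3, 1, SIZE, SIZE)).astype(np.float32)
    yt = rng.integers(0, 7, (3, SIZE, SIZE))
    return TrainBatch(xs, ys, xt, yt, np.array([True, False, True]))


def test_translate_preserves_shape_and_tanh_range(components, rng):
    x = rng.uniform(-1, 1, (2, 1, SIZE, SIZE)).astype(np.float32)
    out = translate(components, x)
    assert out.shape == x.shape
    assert out.data.min() >= -1.0 and out.data.max() <= 1.0


def test_translate_rejects_wrong_size(components, rng):
    with pytest.raises(ValueError, match="16x16"):
        translate(components, rng.uniform(-1, 1, (1, 1, 8, 8)).astype(np.float32))


def test_zero_initialised_final_layer_outputs_zero(rng):
    comp = build_components(GanModelSpec(input_size=SIZE, width=4), seed=1)
    last = comp.g_st.net.modules[-1]
    last.weight.data[:] = 0
    last.bias.data[:] = 0
    out = translate(comp, rng.uniform(-1, 1, (1, 1, SIZE, SIZE)).astype(np.float32))
    assert np.all(out.data == 0.0)  # tanh(0)


def test_reconstruct_shape_and_range(components, rng):
    x = rng.uniform(-1, 1, (2, 1, SIZE, SIZE)).astype(np.float32)
    out = reconstruct(components, x)
    assert out.shape == x.shape
    assert np.abs(out.data).max() <= 1.0


def test_segment_probabilities_normalise(components, rng):
    x = rng.uniform(-1, 1, (2, 1, SIZE, SIZE)).astype(np.float32)
    probs = segment(components, x)
    assert probs.shape == (2, 7, SIZE, SIZE)
    assert np.abs(probs.data.sum(axis=1) - 1).max() < 1e-5
    assert set(np.unique(probs.data.argmax(axis=1))) <= set(range(7))


@pytest.mark.parametrize("d_out,is_real,expected", [
    (1.0, True, 0.0),
    (0.5, True, 0.25),
    (0.5, False, 0.25),
    (0.0, False, 0.0),
])
def test_adversarial_loss_least_squares(d_out, is_real, expected):
    d = nn.Tensor(np.full((2, 1, 4, 4), d_out, dtype=np.float32))
    assert adversarial_loss(d, is_real).item() == pytest.approx(expected)


def test_segmentation_loss_perfect_prediction_near_zero(rng):
    labels = rng.integers(0, 7, (1, 8, 8))
    logits = nn.Tensor(nn.one_hot(labels, 7) * 50.0)
    assert segmentation_loss(logits, labels).item() < 1e-3


def test_segmentation_loss_uniform_probs_ce_is_ln7(rng):
    labels = rng.integers(0, 7, (2, 8, 8))
    logits = nn.Tensor(np.zeros((2, 7, 8, 8), dtype=np.float32))
    ce = nn.softmax_cross_entropy(logits, labels)
    assert ce.item() == pytest.approx(np.log(7), rel=1e-5)


def test_segmentation_loss_permutation_invariant(rng):
    labels = rng.integers(0, 7, (1, 8, 8))
    logits_arr = rng.normal(0, 1, (1, 7, 8, 8)).astype(np.float32)
    base = segmentation_loss(nn.Tensor(logits_arr), labels).item()
    perm = rng.permutation(64)
    flat_logits = logits_arr.reshape(1, 7, 64)[:, :, perm].reshape(1, 7, 8, 8)
    flat_labels = labels.reshape(1, 64)[:, perm].reshape(1, 8, 8)
    assert segmentation_loss(nn.Tensor(flat_logits), flat_labels).item() == \
        pytest.approx(base, rel=1e-5)


def test_segmentation_loss_rejects_out_of_range_labels(components, rng):
    logits = nn.Tensor(rng.normal(0, 1, (1, 7, 8, 8)).astype(np.float32))
    with pytest.raises(ValueError, match="label"):
        segmentation_loss(logits, np.full((1, 8, 8), 9))


def test_total_loss_zero_weights_gives_zero(components, batch):
    comp_nofeat = build_components(
        GanModelSpec(input_size=SIZE, width=4, feature_discriminator=False), seed=0)
    w = GanLossWeights(0.0, 0.0, 0.0, 0.0)
    assert total_loss(batch, comp_nofeat, w).total == 0.0


def test_total_loss_unsupervised_reduction_exact(components, batch):
    unsup = TrainBatch(batch.source, batch.source_labels, batch.target)
    bd = total_loss(unsup, components, GanLossWeights())
    assert bd.terms["seg_tgt"] == 0.0


def test_total_loss_is_exact_weighted_sum(components, batch):
    bd = total_loss(batch, components, GanLossWeights())
    assert bd.total == pytest.approx(bd.weighted_sum(), abs=1e-6)


def test_supervised_mask_without_labels_rejected(rng):
    xs = rng.uniform(-1, 1, (1, 1, SIZE, SIZE)).astype(np.float32)
    ys = rng.integers(0, 7, (1, SIZE, SIZE))
    xt = rng.uniform(-1, 1, (1, 1, SIZE, SIZE)).astype(np.float32)
    with pytest.raises(ValueError, match="labels"):
        TrainBatch(xs, ys, xt, None, np.array([True]))


def test_train_step_deterministic_under_seed(batch):
    spec = GanModelSpec(input_size=SIZE, width=4)
    runs = []
    for _ in range(2):
        tr = GanTrainer(spec, seed=3)
        for _ in range(3):
            tr.train_step(batch)
        runs.append([p.data.copy() for p in tr.components.generator_params()])
    for a, b in zip(*runs):
        assert np.array_equal(a, b)


def test_generator_step_leaves_discriminators_unchanged(batch):
    tr = GanTrainer(GanModelSpec(input_size=SIZE, width=4), seed=0)
    before = [p.data.copy() for p in tr.components.discriminator_params()]
    bd = total_loss(batch, tr.components, tr.weights)
    bd.tensor.backward()
    tr.opt_g.step()  # generator-only update
    for a, b in zip(before, tr.components.discriminator_params()):
        assert np.array_equal(a, b.data)


def test_loss_decreases_over_training(batch):
    tr = GanTrainer(GanModelSpec(input_size=SIZE, width=4), seed=0)
    for _ in range(50):
        tr.train_step(batch)
    assert tr.history[-1]["total"] < tr.history[0]["total"]


def test_reconstruction_error_decreases_over_windows(rng):
    """Cycle-only training on one slice: L1 error falls across 10-step windows."""
    tr = GanTrainer(GanModelSpec(input_size=SIZE, width=4, feature_discriminator=False),
                    GanLossWeights(w_adv=0.0, w_cyc=1.0, w_seg_source=0.0,
                                   w_seg_target=0.0), seed=0)
    xs = rng.uniform(-1, 1, (1, 1, SIZE, SIZE)).astype(np.float32)
    ys = np.zeros((1, SIZE, SIZE), dtype=np.int64)
    batch = TrainBatch(xs, ys, xs.copy())
    for _ in range(30):
        tr.train_step(batch)
    cyc = [h["cyc"] for h in tr.history]
    windows = [np.mean(cyc[i:i + 10]) for i in (0, 10, 20)]
    assert windows[2] < windows[1] < windows[0]


def test_overfit_two_class_phantom_slices(noiseless_spec):
    """Supervised-only training on a binarised phantom slice pair reaches
    high foreground Dice (capacity smoke test, threshold frozen at 0.8)."""
    from cardioda.imaging_io import preprocess_case
    from cardioda.phantom import generate_phantom

    vol, lab = generate_phantom(noiseless_spec, "target")
    stack = preprocess_case(vol, lab, "gan", 32)
    sl = stack.slices[[6, 9]]
    la = (stack.label_slices[[6, 9]] > 0).astype(np.int64)
    tr = GanTrainer(GanModelSpec(input_size=32, width=8, feature_discriminator=False),
                    GanLossWeights(w_adv=0.0, w_cyc=0.0, w_seg_source=0.0,
                                   w_seg_target=1.0), seed=0)
    batch = TrainBatch(sl[:1][:, None] * 0, la[:1] * 0, sl[:, None], la,
                       np.array([True, True]))
    for _ in range(200):
        tr.train_step(batch)
    pred = tr.predict_slices(sl) > 0
    gt = la > 0
    dice = 2 * (pred & gt).sum() / (pred.sum() + gt.sum())
    assert dice > 0.8
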