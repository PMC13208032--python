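"""Translation networks and objective: oracles, contracts, training loop."""

import os

import numpy as np
import pytest

from doseup.models import patchgan_receptive_field
from doseup.nn import Tensor
from doseup.translator import (LossWeights, TrainConfig, build_models,
                               build_pyramid, contrastive_losses, edge_loss,
                               load_state, pyramid_l1, save_state, total_loss,
                               train_phase, translate)

TINY = dict(input_size=32, n_res_blocks=2, ngf=8, ndf=8, n_patches=16,
            batch_size=2)


@pytest.fixture(scope="module")
def tiny_dataset():
    rng = np.random.default_rng(0)
    return [(rng.random((32, 32)), rng.random((32, 32))) for _ in range(4)]


# -- defaults & architecture -------------------------------------------------

def test_committed_defaults():
    w = LossWeights()
    assert (w.lambda_adv, w.lambda_src, w.lambda_hdce, w.lambda_pyr,
            w.lambda_edge) == (1.0, 0.1, 0.2, 15.0, 2.0)
    assert w.scale_weights == (1.0, 1.0, 1.0, 1.0)
    c = TrainConfig()
    assert (c.lr, c.betas, c.epochs, c.batch_size, c.input_size,
            c.n_res_blocks, c.netf_channels, c.n_patches) == (
        2e-4, (0.5, 0.999), 40, 16, 256, 9, 256, 512)


def test_generator_shape_and_seeded_init(tiny_dataset):
    cfg = TrainConfig(**TINY)
    st1 = build_models(cfg, seed=7)
    st2 = build_models(cfg, seed=7)
    st3 = build_models(cfg, seed=8)
    assert st1.checksum() == st2.checksum()
    assert st1.checksum() != st3.checksum()
    out = translate(np.zeros((32, 32)), st1)
    assert out.shape == (32, 32)
    assert (out >= 0).all() and (out <= 1).all()


def test_patchgan_receptive_field_arithmetic():
    """The documented stack (4x4 kernels, strides 2,2,2,1,1) reaches 70 px."""
    assert patchgan_receptive_field() == 70


def test_discriminator_output_grid():
    cfg = TrainConfig(input_size=64, n_res_blocks=2, ngf=8, ndf=8)
    st = build_models(cfg, seed=0)
    pred = st.discriminator(Tensor(np.zeros((1, 1, 64, 64), np.float32)))
    # three stride-2 layers then two stride-1 valid-ish (pad 1, k 4)
    assert pred.shape == (1, 1, 6, 6)


# -- loss oracles ------------------------------------------------------------

def test_pyramid_l1_exact_and_constant():
    rng = np.random.default_rng(1)
    y = rng.random((16, 16))
    assert pyramid_l1(build_pyramid(y, y)) == 0.0
    w = LossWeights(scale_weights=(1.0, 0.0, 0.0, 0.0))
    levels = build_pyramid(y + 0.5, y)
    assert pyramid_l1(levels, w) == pytest.approx(0.5, abs=1e-12)


def test_pyramid_l1_matches_bruteforce():
    rng = np.random.default_rng(2)
    g, y = rng.random((8, 8)), rng.random((8, 8))
    val = pyramid_l1(build_pyramid(g, y), LossWeights())

    def pool(x):
        return x.reshape(x.shape[0] // 2, 2, x.shape[1] // 2, 2).mean((1, 3))

    acc, gs, ys = 0.0, g.copy(), y.copy()
    for s in range(4):
        acc += np.abs(gs - ys).mean()
        if s < 3:
            gs, ys = pool(gs), pool(ys)
    assert val == pytest.approx(acc, rel=1e-12)
    with pytest.raises(ValueError, match="level 1"):
        pyramid_l1([(g, y), (g, y[:4, :4]), (g, y), (g, y)], LossWeights())


def test_edge_loss_identity_offset_and_bruteforce():
    rng = np.random.default_rng(3)
    y = rng.random((8, 8))
    assert edge_loss(y, y) == 0.0
    assert edge_loss(y + 0.3, y) == pytest.approx(0.0, abs=1e-12)
    g = rng.random((8, 8))

    def brute(a, b):
        def fd(x, ax):
            return np.diff(x, axis=ax, append=np.take(x, [-1], axis=ax))

        def lap(x):
            xp = np.pad(x, 1, mode="edge")
            return xp[:-2, 1:-1] + xp[2:, 1:-1] + xp[1:-1, :-2] + xp[1:-1, 2:] - 4 * x

        return (np.abs(fd(a, 0) - fd(b, 0)).mean()
                + np.abs(fd(a, 1) - fd(b, 1)).mean()
                + np.abs(lap(a) - lap(b)).mean())

    assert edge_loss(g, y) == pytest.approx(brute(g, y), rel=1e-9)


def test_total_loss_weighting_and_linearity():
    ones = {k: 1.0 for k in ("adv", "src", "hdce", "pyr", "edge")}
    assert total_loss(ones) == pytest.approx(18.3)
    zero_w = LossWeights(lambda_adv=0, lambda_src=0, lambda_hdce=0,
                         lambda_pyr=0, lambda_edge=0)
    assert total_loss(ones, zero_w) == 0.0
    doubled = dict(ones, pyr=2.0)
    assert total_loss(doubled) - total_loss(ones) == pytest.approx(15.0)
    with pytest.raises(ValueError, match="pyr"):
        total_loss(dict(ones, pyr=float("nan")))


def test_src_zero_for_identical_relations_and_hand_oracle():
    rng = np.random.default_rng(4)
    f = rng.standard_normal((1, 3, 8))
    f /= np.linalg.norm(f, axis=-1, keepdims=True)
    cfg = TrainConfig()
    _, src = contrastive_losses([Tensor(f)], [Tensor(f.copy())], cfg)
    assert float(src.data) == pytest.approx(0.0, abs=1e-12)
    # hand-computed Jensen-Shannon between row softmaxes of 3x3 similarities
    g = rng.standard_normal((1, 3, 8))
    g /= np.linalg.norm(g, axis=-1, keepdims=True)
    _, src2 = contrastive_losses([Tensor(f)], [Tensor(g)], cfg)

    def row_softmax(s, tau):
        e = np.exp(s / tau - (s / tau).max(-1, keepdims=True))
        return e / e.sum(-1, keepdims=True)

    P = row_softmax(f[0] @ f[0].T, cfg.src_temperature)
    Q = row_softmax(g[0] @ g[0].T, cfg.src_temperature)
    M = (P + Q) / 2
    jsd = 0.5 * ((P * np.log((P + 1e-12) / (M + 1e-12))).sum(-1)
                 + (Q * np.log((Q + 1e-12) / (M + 1e-12))).sum(-1))
    assert float(src2.data) == pytest.approx(jsd.mean(), rel=1e-6)


def test_hdce_infinite_temperature_limit():
    """As temperature -> inf the loss approaches log of the negative count."""
    rng = np.random.default_rng(5)
    K = 6
    f = rng.standard_normal((1, K, 8))
    f /= np.linalg.norm(f, axis=-1, keepdims=True)
    hdce, _ = contrastive_losses([Tensor(f)], [Tensor(f.copy())],
                                 TrainConfig(temperature=1e9))
    assert float(hdce.data) == pytest.approx(np.log(K - 1), rel=1e-5)


# -- training loop contracts -------------------------------------------------

def test_training_deterministic_and_lr0(tiny_dataset):
    cfg = TrainConfig(**TINY, max_iterations=6, seed=3)
    _, log1 = train_phase(tiny_dataset, cfg)
    _, log2 = train_phase(tiny_dataset, cfg)
    assert [r["g_total"] for r in log1] == [r["g_total"] for r in log2]
    cfg0 = TrainConfig(**TINY, max_iterations=3, seed=3, lr=0.0)
    before = build_models(cfg0).checksum()
    after, _ = train_phase(tiny_dataset, cfg0)
    assert after.checksum() == pytest.approx(before, abs=1e-12)
    with pytest.raises(ValueError, match="empty"):
        train_phase([], cfg)


def test_checkpoint_round_trip(tmp_path, tiny_dataset):
    cfg = TrainConfig(**TINY, max_iterations=4, seed=9)
    st, _ = train_phase(tiny_dataset, cfg)
    path = os.path.join(tmp_path, "ckpt.npz")
    save_state(st, path)
    st2 = load_state(path)
    assert st2.checksum() == st.checksum()
    assert st2.provenance[-1]["event"] == "trained"
    x = np.asarray(tiny_dataset[0][0])
    assert (translate(x, st2) == translate(x, st)).all()


def test_finetune_does_not_mutate_checkpoint(tiny_dataset):
    cfg = TrainConfig(**TINY, max_iterations=3, seed=1, phase=1)
    st1, _ = train_phase(tiny_dataset, cfg)
    before = st1.checksum()
    cfg2 = TrainConfig(**TINY, max_iterations=3, seed=2, phase=2)
    st2, _ = train_phase(tiny_dataset, cfg2, init_from=st1)
    assert st1.checksum() == before
    assert any(p.get("event") == "init_from" for p in st2.provenance)


def test_identity_variant_passes_input_through():
    cfg = TrainConfig(**TINY, residual_output=True)
    st = build_models(cfg, seed=0)
    x = np.random.default_rng(6).random((32, 32))
    assert np.abs(translate(x, st) - x).max() < 1e-6


def test_translate_contracts(tiny_dataset):
    st = build_models(TrainConfig(**TINY), seed=0)
    with pytest.raises(ValueError, match="2-D"):
        translate(np.zeros((2, 32, 32)), st)
    with pytest.raises(ValueError, match="incompatible"):
        translate(np.zeros((30, 30)), st)
    out = translate(np.random.default_rng(1).random((32, 32)), st)
    assert out.min() >= 0.0 and out.max() <= 1.0
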