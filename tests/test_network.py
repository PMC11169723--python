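"""Stage-level oracle equivalence and structural invariants of the network.

Each stage is compared against an independent naive-loop implementation of
its defining equations; structural checks cover softmax normalisations,
causality, receptive fields, ablation wiring, determinism and checkpoints.
"""

import dataclasses

import numpy as np
import pytest

from ac4cpred.autodiff import Tensor
from ac4cpred.network import (Ac4cNet, MHSABlock, MHSAParams, ModelConfig,
                              SKCBlock, SKCParams, TCNParams, TCNStack,
                              ablation_matrix, build_model, causal_dilated_conv,
                              load_checkpoint, predict, save_checkpoint)


from oracles import naive_mhsa, naive_skc, naive_tcn_block, probe_receptive_field


# ---------------------------------------------------------------------------
# SKC
# ---------------------------------------------------------------------------

def test_skc_matches_naive_equations(rng):
    p = SKCParams(out_channels=6, branch_kernel_sizes=(3, 5, 7), reduction=2)
    block = SKCBlock(4, p, np.random.default_rng(3))
    block.store_attention = True
    x = rng.standard_normal((3, 4, 20)).astype(np.float32)
    got = block(Tensor(x)).data
    want, weights = naive_skc(x.astype(float), block)
    assert got.shape == (3, 6, 20)  # length preserved
    assert np.max(np.abs(got - want)) < 1e-5
    assert np.max(np.abs(block.last_attention - weights)) < 1e-5


def test_skc_single_branch_softmax_is_identity(rng):
    p = SKCParams(out_channels=5, branch_kernel_sizes=(3,), reduction=2)
    block = SKCBlock(2, p, np.random.default_rng(0))
    block.store_attention = True
    x = rng.standard_normal((2, 2, 15)).astype(np.float32)
    got = block(Tensor(x)).data
    branch = block.norm0(block.conv0(Tensor(x))).relu().data
    assert np.allclose(block.last_attention, 1.0)
    assert np.max(np.abs(got - branch)) < 1e-6


def test_skc_select_weights_are_probability_vectors(rng):
    block = SKCBlock(5, SKCParams(out_channels=8, branch_kernel_sizes=(3, 5)),
                     np.random.default_rng(1))
    block.store_attention = True
    for _ in range(100):
        x = rng.standard_normal((2, 5, 12)).astype(np.float32)
        block(Tensor(x))
        a = block.last_attention
        assert np.all(a > 0) and np.all(a < 1)
        assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# causal dilated convolution & TCN
# ---------------------------------------------------------------------------

def test_causal_conv_pointwise_case():
    y = causal_dilated_conv([1.0, -2.0, 3.0], [2.0], b=0.0, dilation=1)
    assert np.allclose(y, [2.0, -4.0, 6.0])


def test_causal_conv_impulse_response():
    x = np.zeros(6)
    x[0] = 1.0
    y = causal_dilated_conv(x, [0.7, -1.3], b=0.0, dilation=3)
    expected = np.zeros(6)
    expected[0] = 0.7   # w_0 * x_t
    expected[3] = -1.3  # w_1 * x_{t-3}
    assert np.allclose(y, expected)


def test_dilation_one_equals_plain_causal_convolution(rng):
    """Naive y_t = sum_i w_i x_{t-i} + b on 50 random inputs."""
    for _ in range(50):
        k = int(rng.integers(1, 5))
        n = int(rng.integers(k, 20))
        x = rng.standard_normal(n)
        w = rng.standard_normal(k)
        b = float(rng.standard_normal())
        got = causal_dilated_conv(x, w, b, dilation=1)
        want = np.array([b + sum(w[i] * (x[t - i] if t - i >= 0 else 0.0)
                                 for i in range(k)) for t in range(n)])
        assert np.max(np.abs(got - want)) < 1e-9


def test_causal_conv_ignores_future(rng):
    x = rng.standard_normal(30)
    w = rng.standard_normal(3)
    t0 = int(rng.integers(5, 25))
    y1 = causal_dilated_conv(x, w, 0.5, dilation=2)
    x2 = x.copy()
    x2[t0 + 1] += 10.0
    y2 = causal_dilated_conv(x2, w, 0.5, dilation=2)
    assert np.allclose(y1[: t0 + 1], y2[: t0 + 1])


def _stack_output(stack: TCNStack, x: np.ndarray) -> np.ndarray:
    stack.eval()
    return stack(Tensor(x.astype(np.float32))).data


@pytest.mark.parametrize("num_blocks", [1, 2, 3, 4])
def test_tcn_receptive_field_formula_matches_tap_structure(num_blocks):
    """1 + 2(k-1)(2^B - 1) equals the span of the instantiated tap pattern:
    each block holds two causal convolutions whose farthest tap reaches
    d*(k-1) steps back, with dilations read off the built stack."""
    for k in (2, 3, 5):
        p = TCNParams(kernel_size=k, num_blocks=num_blocks,
                      channels=tuple([3] * num_blocks))
        stack = TCNStack(2, p, np.random.default_rng(0))
        reach = 0
        for b in range(num_blocks):
            block = getattr(stack, f"block{b}")
            for conv in (block.conv1, block.conv2):
                assert conv.padding == "causal"
                reach += conv.dilation * (k - 1)
        assert 1 + reach == TCNStack.receptive_field(k, num_blocks)
        assert p.dilations == tuple(2 ** b for b in range(num_blocks))


@pytest.mark.parametrize("num_blocks", [1, 2, 3, 4])
def test_tcn_receptive_field_by_impulse_probing(num_blocks):
    """Perturbing input t' changes the last output iff it lies within the
    receptive field: exactly the last RF positions, nothing before."""
    k = 3
    length = 80
    rf = TCNStack.receptive_field(k, num_blocks)
    p = TCNParams(kernel_size=k, num_blocks=num_blocks,
                  channels=tuple([4] * num_blocks), dropout=0.0)
    stack = TCNStack(2, p, np.random.default_rng(8))
    changed = probe_receptive_field(stack, channels=2, length=length)
    t_out = length - 1
    assert changed == [t_out - rf + 1 <= t for t in range(length)]


def test_tcn_whole_stack_causality(rng):
    p = TCNParams(kernel_size=3, num_blocks=2, channels=(5, 5), dropout=0.0)
    stack = TCNStack(3, p, np.random.default_rng(2))
    x = rng.standard_normal((2, 3, 40))
    base = _stack_output(stack, x)
    t0 = 17
    xp = x.copy()
    xp[:, :, t0 + 1:] += rng.standard_normal(xp[:, :, t0 + 1:].shape)
    pert = _stack_output(stack, xp)
    assert np.allclose(base[:, :, : t0 + 1], pert[:, :, : t0 + 1], atol=1e-6)


def test_tcn_empty_stack_is_identity(rng):
    p = TCNParams(kernel_size=3, num_blocks=0, channels=())
    stack = TCNStack(4, p, np.random.default_rng(0))
    x = rng.standard_normal((2, 4, 10)).astype(np.float32)
    assert np.array_equal(_stack_output(stack, x), x)


def test_tcn_block_matches_naive_residual_equations(rng):
    """One block vs an explicit loop: two weight-normalised causal dilated
    convolutions with ReLU, plus the skip path, final ReLU."""
    from ac4cpred.network import TCNBlock

    block = TCNBlock(3, 4, kernel_size=2, dilation=2, dropout=0.0,
                     rng=np.random.default_rng(5))
    block.eval()
    x = rng.standard_normal((2, 3, 12)).astype(np.float32)
    got = block(Tensor(x)).data
    want = naive_tcn_block(x, block)
    assert np.max(np.abs(got - want)) < 1e-5


# ---------------------------------------------------------------------------
# MHSA
# ---------------------------------------------------------------------------

def test_mhsa_matches_naive_equations(rng):
    p = MHSAParams(model_dim=8, heads=2)
    block = MHSABlock(p, np.random.default_rng(4))
    x = rng.standard_normal((3, 8, 4)).astype(np.float32)  # (N, d, n=4)
    got = block(Tensor(x)).data
    want = naive_mhsa(x.transpose(0, 2, 1).astype(float), block)
    assert got.shape == x.shape
    assert np.max(np.abs(got - want.transpose(0, 2, 1))) < 1e-5


def test_mhsa_attention_rows_sum_to_one(rng):
    block = MHSABlock(MHSAParams(model_dim=6, heads=3), np.random.default_rng(1))
    block.store_attention = True
    for _ in range(20):
        x = rng.standard_normal((2, 6, 9)).astype(np.float32)
        block(Tensor(x))
        for a in block.last_attention:
            assert np.all(a >= 0)
            assert np.allclose(a.sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_permutation_equivariance(rng):
    """No positional term: permuting positions permutes outputs identically."""
    block = MHSABlock(MHSAParams(model_dim=8, heads=4), np.random.default_rng(9))
    x = rng.standard_normal((1, 8, 11)).astype(np.float32)
    perm = np.random.default_rng(3).permutation(11)
    out = block(Tensor(x)).data
    out_perm = block(Tensor(x[:, :, perm])).data
    assert np.max(np.abs(out[:, :, perm] - out_perm)) < 1e-5


def test_mhsa_rejects_indivisible_heads():
    with pytest.raises(ValueError, match="divide"):
        MHSAParams(model_dim=10, heads=4)


# ---------------------------------------------------------------------------
# assembled model
# ---------------------------------------------------------------------------

def test_full_model_scores_in_unit_interval(rng):
    model = build_model(ModelConfig.small(window_length=201, seed=0))
    X = rng.random((4, 5, 201)).astype(np.float32)
    s = predict(model, X)
    assert s.shape == (4,)
    assert np.all((s > 0) & (s < 1))


def test_all_seven_ablation_combinations_run(rng):
    assert len(ablation_matrix()) == 7
    X = rng.random((2, 5, 31)).astype(np.float32)
    for combo in ablation_matrix():
        cfg = ModelConfig.small(window_length=31, seed=1, **combo)
        s = predict(build_model(cfg), X)
        assert np.all((s > 0) & (s < 1))


def test_all_stages_disabled_is_an_error():
    with pytest.raises(ValueError, match="at least one"):
        ModelConfig(use_skc=False, use_tcn=False, use_mhsa=False)


def test_build_is_deterministic_given_seed():
    cfg = ModelConfig.small(window_length=51, seed=123)
    a = build_model(cfg)
    b = build_model(cfg)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        assert np.array_equal(pa.data, pb.data)


def test_predict_is_batch_size_independent(rng):
    model = build_model(ModelConfig.small(window_length=61, seed=2))
    X = rng.random((7, 5, 61)).astype(np.float32)
    together = predict(model, X)
    singly = np.concatenate([predict(model, X[i: i + 1]) for i in range(7)])
    assert np.max(np.abs(together - singly)) < 1e-6
    assert np.array_equal(predict(model, X), together)  # deterministic


def test_full_model_has_more_parameters_than_single_stage_ablations():
    full = build_model(ModelConfig.small(window_length=41, seed=0))
    n_full = full.num_parameters()
    assert n_full > 0
    for combo in ablation_matrix():
        if sum(combo.values()) == 1:
            small = build_model(ModelConfig.small(window_length=41, seed=0, **combo))
            assert small.num_parameters() < n_full


def test_checkpoint_round_trip(tmp_path, rng):
    model = build_model(ModelConfig.small(window_length=41, seed=7))
    X = rng.random((3, 5, 41)).astype(np.float32)
    before = predict(model, X)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert np.allclose(predict(loaded, X), before, atol=0)
    assert loaded.cfg == model.cfg


def test_checkpoint_records_encoder_and_rejects_mismatch(tmp_path, rng):
    from ac4cpred.network import check_encoder

    model = build_model(ModelConfig.small(window_length=41, seed=7, encoder="ncp"))
    save_checkpoint(model, tmp_path / "m.npz")
    loaded = load_checkpoint(tmp_path / "m.npz")
    assert loaded.cfg.encoder == "ncp"
    with pytest.raises(ValueError, match="encoder"):
        check_encoder(loaded, "onehot")


def test_embedding_encoder_forward(rng):
    cfg = ModelConfig.small(window_length=31, seed=3, encoder="embed")
    model = build_model(cfg)
    codes = rng.integers(0, 5, size=(4, 1, 31)).astype(np.float32)
    s = predict(model, codes)
    assert s.shape == (4,)
    assert np.all((s > 0) & (s < 1))
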