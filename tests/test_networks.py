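"""Network tests: attention against brute-force loops, residual algebra,
shape contracts, squeeze-excitation ablation, and complexity counting."""

import numpy as np
import pytest

from mmha.autodiff import Tensor
from mmha import nn
from mmha.networks import (ConcatFusionModel, EFEM, FEFEM, FusionModel,
                           ModelConfig, MultiHeadAttention, ResidualBlock,
                           TransformerBlock, UnimodalModel, attention,
                           count_params_flops, fuse_decision, reference_config,
                           scaled_config)


def tiny_cfg(**kw):
    base = dict(d_model=16, n_heads=2, n_blocks=1, mlp_ratio=2,
                efem_stem=4, efem_widths=(4, 8), efem_blocks=1,
                efem_expansion=2, fefem_widths=(4, 8), fefem_blocks=(1, 1),
                fefem_expansion=2, seed=0)
    base.update(kw)
    return ModelConfig(**base)


# ------------------------------------------------------------------ attention


def test_attention_single_key_returns_value():
    rng = np.random.default_rng(0)
    Q = Tensor(rng.standard_normal((3, 4)).astype(np.float32))
    K = Tensor(rng.standard_normal((1, 4)).astype(np.float32))
    V = Tensor(rng.standard_normal((1, 4)).astype(np.float32))
    out, w = attention(Q, K, V)
    assert np.allclose(out.data, np.repeat(V.data, 3, axis=0), atol=1e-6)
    assert np.allclose(w.data, 1.0)


def test_attention_equal_logits_gives_mean():
    rng = np.random.default_rng(1)
    Q = Tensor(np.zeros((2, 4), np.float32))      # orthogonal to all keys
    K = Tensor(rng.standard_normal((5, 4)).astype(np.float32))
    V = Tensor(rng.standard_normal((5, 4)).astype(np.float32))
    out, w = attention(Q, K, V)
    assert np.allclose(out.data, V.data.mean(0), atol=1e-6)
    assert np.allclose(w.data, 0.2, atol=1e-7)


def test_attention_matches_bruteforce_loop():
    rng = np.random.default_rng(2)
    Q = rng.standard_normal((3, 4))
    K = rng.standard_normal((5, 4))
    V = rng.standard_normal((5, 4))
    out, w = attention(Tensor(Q), Tensor(K), Tensor(V), d_k=4)
    # explicit exp/normalize/accumulate
    ref = np.zeros((3, 4))
    for i in range(3):
        logits = np.array([Q[i] @ K[j] / np.sqrt(4) for j in range(5)])
        e = np.exp(logits)
        p = e / e.sum()
        for j in range(5):
            ref[i] += p[j] * V[j]
    assert np.allclose(out.data, ref, atol=1e-6)
    assert np.allclose(w.data.sum(-1), 1.0, atol=1e-6)


def test_attention_rejects_bad_dk():
    with pytest.raises(ValueError):
        attention(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 3))),
                  Tensor(np.zeros((2, 3))), d_k=0)


def test_multi_head_two_heads_matches_manual():
    rng = np.random.default_rng(3)
    d, h, T, B = 8, 2, 5, 2
    mha = MultiHeadAttention(d, h, rng)
    Z = rng.standard_normal((B, T, d)).astype(np.float32)
    out, w = mha(Tensor(Z))
    assert out.shape == (B, T, d)
    assert np.allclose(w.data.sum(-1), 1.0, atol=1e-5)
    # manual per-head loop
    q = Z @ mha.wq.weight.data + mha.wq.bias.data
    k = Z @ mha.wk.weight.data + mha.wk.bias.data
    v = Z @ mha.wv.weight.data + mha.wv.bias.data
    dk = d // h
    heads = []
    for i in range(h):
        qi, ki, vi = (a[:, :, i * dk:(i + 1) * dk] for a in (q, k, v))
        s = qi @ ki.transpose(0, 2, 1) / np.sqrt(dk)
        e = np.exp(s - s.max(-1, keepdims=True))
        p = e / e.sum(-1, keepdims=True)
        heads.append(p @ vi)
    ref = np.concatenate(heads, axis=-1) @ mha.wo.weight.data + mha.wo.bias.data
    assert np.allclose(out.data, ref, atol=1e-5)


def test_multi_head_single_head_with_identity_output():
    rng = np.random.default_rng(4)
    d = 6
    mha = MultiHeadAttention(d, 1, rng)
    mha.wo.weight.data = np.eye(d, dtype=np.float32)
    mha.wo.bias.data = np.zeros(d, np.float32)
    Z = rng.standard_normal((1, 4, d)).astype(np.float32)
    out, _ = mha(Tensor(Z))
    q = Tensor(Z @ mha.wq.weight.data + mha.wq.bias.data)
    k = Tensor(Z @ mha.wk.weight.data + mha.wk.bias.data)
    v = Tensor(Z @ mha.wv.weight.data + mha.wv.bias.data)
    ref, _ = attention(q, k, v, d)
    assert np.allclose(out.data, ref.data, atol=1e-6)


def test_multi_head_rejects_indivisible():
    with pytest.raises(ValueError):
        MultiHeadAttention(10, 3, np.random.default_rng(0))


def test_preln_block_with_zeroed_branches_is_identity():
    rng = np.random.default_rng(5)
    blk = TransformerBlock(8, 2, 2, rng)
    blk.msa.wo.weight.data[:] = 0
    blk.msa.wo.bias.data[:] = 0
    blk.mlp.layers[2].weight.data[:] = 0
    blk.mlp.layers[2].bias.data[:] = 0
    x = rng.standard_normal((2, 5, 8)).astype(np.float32)
    out, _ = blk(Tensor(x))
    assert np.allclose(out.data, x, atol=1e-7)


# ------------------------------------------------------------------- encoders


def test_efem_shape_contract_and_finiteness():
    cfg = tiny_cfg(per_band_tokens=False)
    enc = EFEM(cfg, np.random.default_rng(0))
    out = enc(Tensor(np.zeros((2, 5, 32, 32), np.float32)))
    # 32 -> stem/2 = 16 -> two pooled stages: 4x4 map -> 16 tokens
    assert out.shape == (2, 16, 16)
    assert np.isfinite(out.data).all()
    with pytest.raises(ValueError):
        enc(Tensor(np.zeros((2, 3, 32, 32), np.float32)))


def test_efem_per_band_token_grouping():
    cfg = tiny_cfg(per_band_tokens=True)
    enc = EFEM(cfg, np.random.default_rng(0))
    out = enc(Tensor(np.random.randn(2, 5, 32, 32).astype(np.float32)))
    t = enc.tokens_per_band(32)
    assert out.shape == (2, 5 * t, 16)


def test_se_branch_is_not_identity():
    cfg = tiny_cfg()
    enc = EFEM(cfg, np.random.default_rng(0))
    enc.eval()
    x = Tensor(np.random.default_rng(1).standard_normal((1, 5, 32, 32))
               .astype(np.float32))
    normal = enc(x).data.copy()
    gates = [blk.se.gates(Tensor(np.random.randn(1, blk.se.fc2.bias.size, 4, 4)
                                 .astype(np.float32))).data
             for blk in enc.blocks]
    assert any(not np.allclose(g, 1.0, atol=1e-3) for g in gates)
    # bypassing SE (gates forced to 1) must change the encoder output
    for blk in enc.blocks:
        blk.se.forward = lambda t: t
    bypassed = enc(x).data
    assert not np.allclose(bypassed, normal, atol=1e-5)


def test_residual_block_zeroed_branch_is_projected_input():
    rng = np.random.default_rng(0)
    blk = ResidualBlock(8, 4, 8, 1, rng, bottleneck=True)
    blk.eval()
    final_bn = blk.body.layers[-1].layers[1]
    final_bn.weight.data[:] = 0
    final_bn.bias.data[:] = 0
    x = np.abs(rng.standard_normal((2, 8, 6, 6))).astype(np.float32)
    out = blk(Tensor(x))
    assert np.allclose(out.data, x, atol=1e-6)  # relu(x) = x for x >= 0


def test_fefem_shape_and_param_counting_oracle():
    cfg = tiny_cfg()
    enc = FEFEM(cfg, np.random.default_rng(0))
    out = enc(Tensor(np.zeros((2, 3, 32, 32), np.float32)))
    assert out.ndim == 3 and out.shape[0] == 2 and out.shape[2] == 16
    with pytest.raises(ValueError):
        enc(Tensor(np.zeros((2, 1, 32, 32), np.float32)))

    # layer-by-layer hand count for widths (4, 8), 1 bottleneck block each,
    # output expansion 2, d_model 16, conv bias-free + affine BN
    def conv_bn(cin, cout, k):
        return k * k * cin * cout + 2 * cout

    expected = conv_bn(3, 4, 7)                       # stem
    # stage 1: in 4 -> width 4 -> out 8, stride 1, with 1x1 projection
    expected += conv_bn(4, 4, 1) + conv_bn(4, 4, 3) + conv_bn(4, 8, 1) \
        + conv_bn(4, 8, 1)
    # stage 2: in 8 -> width 8 -> out 16, stride 2, with projection
    expected += conv_bn(8, 8, 1) + conv_bn(8, 8, 3) + conv_bn(8, 16, 1) \
        + conv_bn(8, 16, 1)
    # token projection: 1x1 conv (bias) 16 -> 16 then linear 16 -> 16
    expected += 16 * 16 + 16 + 16 * 16 + 16
    assert nn.count_params(enc) == expected


# --------------------------------------------------------------------- fusion


def test_fusion_depth_zero_ignores_inputs():
    cfg = tiny_cfg(n_blocks=0)
    model = FusionModel(cfg)
    model.eval()
    rng = np.random.default_rng(0)
    a, _ = model(Tensor(rng.standard_normal((2, 5, 32, 32)).astype(np.float32)),
                 Tensor(rng.standard_normal((2, 3, 32, 32)).astype(np.float32)))
    b, _ = model(Tensor(rng.standard_normal((2, 5, 32, 32)).astype(np.float32)),
                 Tensor(rng.standard_normal((2, 3, 32, 32)).astype(np.float32)))
    assert np.allclose(a.data, b.data, atol=1e-7)


def test_fusion_intra_modality_permutation_invariance():
    cfg = tiny_cfg()
    model = FusionModel(cfg)
    model.eval()
    rng = np.random.default_rng(0)
    eeg = rng.standard_normal((2, 10, 16)).astype(np.float32)
    face = rng.standard_normal((2, 4, 16)).astype(np.float32)
    base, _ = model.fuse_tokens(Tensor(eeg), Tensor(face))
    perm = rng.permutation(10)
    permuted, _ = model.fuse_tokens(Tensor(eeg[:, perm]), Tensor(face))
    assert np.allclose(base.data, permuted.data, atol=1e-5)


def test_fusion_attention_rows_sum_to_one():
    cfg = tiny_cfg(n_blocks=2)
    model = FusionModel(cfg)
    model.eval()
    rng = np.random.default_rng(0)
    logits, records = model(
        Tensor(rng.standard_normal((2, 5, 32, 32)).astype(np.float32)),
        Tensor(rng.standard_normal((2, 3, 32, 32)).astype(np.float32)))
    assert logits.shape == (2, 4)
    assert len(records) == 2
    for w in records:
        assert np.allclose(w.data.sum(-1), 1.0, atol=1e-5)
        assert (w.data >= 0).all()


def test_concat_fusion_contract_and_gradient_flow():
    cfg = tiny_cfg()
    model = ConcatFusionModel(cfg)
    rng = np.random.default_rng(0)
    eeg = Tensor(rng.standard_normal((2, 5, 32, 32)).astype(np.float32))
    face = Tensor(rng.standard_normal((2, 3, 32, 32)).astype(np.float32))
    out = model(eeg, face)
    assert out.shape == (2, 4)
    out2 = model(eeg, face)
    assert np.allclose(out.data, out2.data)  # deterministic

    # numeric gradient on one weight of each encoder (float64 for precision)
    from mmha.autodiff import cross_entropy_logits
    for p in model.parameters():
        p.data = p.data.astype(np.float64)
    eeg64 = Tensor(eeg.data.astype(np.float64))
    face64 = Tensor(face.data.astype(np.float64))
    y = np.array([0, 3])
    for conv in (model.efem.stem.layers[0].layers[0],
                 model.fefem.stem.layers[0].layers[0]):
        model.train()
        loss = cross_entropy_logits(model(eeg64, face64), y)
        loss.backward()
        g = conv.weight.grad[0, 0, 0, 0]
        assert g != 0
        eps = 1e-6
        orig = conv.weight.data[0, 0, 0, 0]
        conv.weight.data[0, 0, 0, 0] = orig + eps
        lp = float(cross_entropy_logits(model(eeg64, face64), y).data)
        conv.weight.data[0, 0, 0, 0] = orig - eps
        lm = float(cross_entropy_logits(model(eeg64, face64), y).data)
        conv.weight.data[0, 0, 0, 0] = orig
        assert np.isclose(g, (lp - lm) / (2 * eps), rtol=1e-4, atol=1e-9)
        for p in model.parameters():
            p.grad = None


def test_fuse_decision_examples():
    p = np.array([[0.25, 0.25, 0.25, 0.25]])
    assert np.allclose(fuse_decision(p, p), p)
    a = np.array([[0.6, 0.4, 0.0, 0.0]])
    b = np.array([[0.2, 0.8, 0.0, 0.0]])
    fused = fuse_decision(a, b)
    assert np.allclose(fused, [[0.4, 0.6, 0.0, 0.0]])
    assert np.allclose(fused.sum(-1), 1.0)
    with pytest.warns(UserWarning):
        fuse_decision(2 * a, b)


# ----------------------------------------------------------------- complexity


def test_param_counting_examples():
    rng = np.random.default_rng(0)
    conv = nn.Conv2d(3, 8, 1, rng, bias=True)
    assert nn.count_params(conv) == 3 * 8 + 8
    d = 16
    dw = nn.Conv2d(d, d, 3, rng, groups=d, bias=True)
    assert nn.count_params(dw) == 9 * d + d
    full = nn.Conv2d(d, d, 3, rng, bias=False)
    assert nn.count_params(full) == d * d * 9


def test_reference_model_budget_stable_across_seeds():
    n0 = nn.count_params(FusionModel(reference_config(seed=0)))
    n1 = nn.count_params(FusionModel(reference_config(seed=1)))
    assert n0 == n1


def test_count_macs_small_conv():
    rng = np.random.default_rng(0)
    model = nn.Sequential(nn.Conv2d(3, 4, 3, rng, padding=1),
                          nn.ReLU(), nn.GlobalAvgPool(), nn.Linear(4, 2, rng))
    p, macs = count_params_flops(model, (3, 8, 8))
    assert p == (3 * 4 * 9 + 4) + (4 * 2 + 2)
    assert macs == 4 * 8 * 8 * 3 * 9 + 2 * 4
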