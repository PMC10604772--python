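"""Transformer components: explicit-loop attention oracles, shape
contracts, identity-at-zero-init properties, and the composite loss."""

import numpy as np
import pytest

from nucleoseg.autodiff import Tensor
from nucleoseg.model import (
    DualTransformerBlock,
    LossWeights,
    ModelSpec,
    NucleusSegmenter,
    PatchEmbed,
    PatchExpanding,
    PatchMerging,
    SCAFusion,
    bce_with_logits,
    combine_loss,
    composite_loss,
    count_parameters,
    dice_loss,
    efficient_attention,
    sca_attention,
    standard_attention,
    transposed_attention,
)


# --------------------------------------------------------------------------
# explicit-loop oracles
# --------------------------------------------------------------------------
def softmax_np(x, axis):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def loop_efficient(q, k, v):
    n, dq = q.shape
    dk, dv = k.shape[1], v.shape[1]
    rq = np.stack([softmax_np(q[i], axis=0) for i in range(n)])
    rk = np.stack([softmax_np(k[:, c], axis=0) for c in range(dk)], axis=1)
    ctx = np.zeros((dk, dv))
    for c in range(dk):
        for e in range(dv):
            ctx[c, e] = sum(rk[j, c] * v[j, e] for j in range(n))
    out = np.zeros((n, dv))
    for i in range(n):
        for e in range(dv):
            out[i, e] = sum(rq[i, c] * ctx[c, e] for c in range(dq))
    return out


def loop_transposed(q, k, v, tau):
    n, d = q.shape
    qn = q / np.sqrt((q * q).sum(axis=0) + 1e-12)
    kn = k / np.sqrt((k * k).sum(axis=0) + 1e-12)
    ct = np.zeros((d, d))
    for c in range(d):
        for e in range(d):
            ct[c, e] = sum(kn[i, c] * qn[i, e] for i in range(n)) / tau
    ct = softmax_np(ct, axis=0)
    out = np.zeros((n, d))
    for i in range(n):
        for e in range(d):
            out[i, e] = sum(v[i, c] * ct[c, e] for c in range(d))
    return out


def loop_standard(q, k, v, bias=None):
    n, d = q.shape
    logits = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            logits[i, j] = sum(q[i, c] * k[j, c] for c in range(d)) / np.sqrt(d)
    if bias is not None:
        logits = logits + bias
    w = softmax_np(logits, axis=1)
    return w @ v


def loop_sca(q, k, v):
    n, d = q.shape
    rv = np.stack([softmax_np(v[:, c], axis=0) for c in range(d)], axis=1)
    rk = np.stack([softmax_np(k[:, c], axis=0) for c in range(d)], axis=1)
    ctx = rk.T @ q
    return rv @ ctx


@pytest.mark.parametrize("trial", range(10))
def test_efficient_attention_matches_loop_oracle(trial):
    rng = np.random.default_rng(100 + trial)
    n, d = int(rng.integers(2, 17)), int(rng.integers(2, 9))
    q, k, v = rng.normal(size=(3, n, d))
    out = efficient_attention(q, k, v).data
    assert np.allclose(out, loop_efficient(q, k, v), atol=1e-6)


@pytest.mark.parametrize("trial", range(10))
def test_transposed_attention_matches_loop_oracle(trial):
    rng = np.random.default_rng(200 + trial)
    n, d = int(rng.integers(2, 17)), int(rng.integers(2, 9))
    q, k, v = rng.normal(size=(3, n, d))
    tau = float(rng.uniform(0.5, 2.0))
    out = transposed_attention(q, k, v, tau).data
    assert np.allclose(out, loop_transposed(q, k, v, tau), atol=1e-6)


def test_standard_attention_oracle_and_degenerate_cases(rng):
    # N=1: softmax of a scalar is 1, output is V
    q = rng.normal(size=(1, 4)); v = rng.normal(size=(1, 4))
    assert np.allclose(standard_attention(q, q, v).data, v)
    # uniform zero queries: every row is the mean of V rows
    q0 = np.zeros((5, 4)); k = rng.normal(size=(5, 4)); v = rng.normal(size=(5, 4))
    assert np.allclose(standard_attention(q0, k, v).data, np.tile(v.mean(0), (5, 1)))
    # random case with a relative-position bias against the loop oracle
    q = rng.normal(size=(6, 4)); k = rng.normal(size=(6, 4)); v = rng.normal(size=(6, 3))
    b = rng.normal(size=(6, 6))
    assert np.allclose(standard_attention(q, k, v, b).data, loop_standard(q, k, v, b), atol=1e-6)


def test_sca_attention_matches_loop_oracle(rng):
    for _ in range(5):
        n, d = int(rng.integers(2, 12)), int(rng.integers(2, 7))
        q, k, v = rng.normal(size=(3, n, d))
        assert np.allclose(sca_attention(q, k, v).data, loop_sca(q, k, v), atol=1e-6)


def test_sca_constant_value_rows_collapse_to_context_mean(rng):
    """With all V rows equal, rho_v is uniform (1/N) over tokens, so
    every output row equals the column sums of the context
    rho_k(K)^T Q divided by N."""
    n, d = 7, 4
    q, k = rng.normal(size=(2, n, d))
    v = np.tile(rng.normal(size=(1, d)), (n, 1))
    out = sca_attention(q, k, v).data
    rk = softmax_np(k, axis=0)
    ctx = rk.T @ q
    assert np.allclose(out, np.tile(ctx.sum(axis=0) / n, (n, 1)), atol=1e-12)
    assert np.allclose(out, out[0], atol=1e-12)


# --------------------------------------------------------------------------
# attention operator properties
# --------------------------------------------------------------------------
@pytest.mark.parametrize("op", ["efficient", "transposed"])
def test_attention_permutation_equivariance(op, rng):
    n, d = 10, 6
    q, k, v = rng.normal(size=(3, n, d))
    perm = rng.permutation(n)
    if op == "efficient":
        out = efficient_attention(q, k, v).data
        out_p = efficient_attention(q[perm], k[perm], v[perm]).data
    else:
        out = transposed_attention(q, k, v, 1.3).data
        out_p = transposed_attention(q[perm], k[perm], v[perm], 1.3).data
    assert np.allclose(out[perm], out_p, atol=1e-10)


def test_efficient_attention_constant_values_pass_through(rng):
    """Both softmax factors are convex weights, so identical V rows are
    reproduced exactly."""
    n, d = 9, 5
    q, k = rng.normal(size=(2, n, d))
    vrow = rng.normal(size=d)
    out = efficient_attention(q, k, np.tile(vrow, (n, 1))).data
    assert np.allclose(out, np.tile(vrow, (n, 1)), atol=1e-10)


def test_transposed_attention_zero_values_and_scale_invariance(rng):
    n, d = 8, 4
    q, k = rng.normal(size=(2, n, d))
    assert np.allclose(transposed_attention(q, k, np.zeros((n, d)), 1.0).data, 0.0)
    # column-wise positive rescaling of Q is absorbed by the L2 normalization
    scale = rng.uniform(0.5, 3.0, size=d)
    v = rng.normal(size=(n, d))
    a = transposed_attention(q, k, v, 1.0).data
    b = transposed_attention(q * scale, k, v, 1.0).data
    assert np.allclose(a, b, atol=1e-9)


def test_attention_input_validation():
    bad = np.full((4, 4), np.nan)
    ok = np.zeros((4, 4))
    with pytest.raises(ValueError):
        efficient_attention(bad, ok, ok)
    with pytest.raises(ValueError):
        transposed_attention(ok, ok, ok, tau=0.0)


def test_efficient_attention_scales_to_many_tokens():
    """Linear-complexity contract: a token count whose N x N map would
    be tens of gigabytes runs instantly through the d x d context."""
    rng = np.random.default_rng(0)
    n, d = 50_000, 4
    q, k, v = rng.normal(size=(3, n, d))
    out = efficient_attention(q, k, v).data
    assert out.shape == (n, d) and np.isfinite(out).all()


# --------------------------------------------------------------------------
# structural modules
# --------------------------------------------------------------------------
def _randomize(module, rng, scale=0.05):
    for _, p in module.named_parameters():
        p.data = rng.normal(0.0, scale, size=p.data.shape)


def test_dual_block_is_identity_at_init(rng):
    block = DualTransformerBlock(8, 2, 2, np.random.default_rng(0))
    x = rng.normal(size=(2, 4, 4, 8))
    out = block(Tensor(x)).data
    assert np.allclose(out, x, atol=1e-12)


def test_dual_block_composition_matches_substeps(rng):
    block = DualTransformerBlock(8, 2, 2, np.random.default_rng(1))
    _randomize(block, rng)
    x = Tensor(rng.normal(size=(1, 4, 4, 8)))
    y = block.attn_spatial(x) + x
    y = block.ffn1(block.norm1(y)) + y
    z = block.attn_channel(y) + y
    expected = (block.ffn2(block.norm2(z)) + z).data
    assert np.allclose(block(x).data, expected, atol=1e-6)


def test_dual_block_preserves_shape(rng):
    block = DualTransformerBlock(12, 3, 4, np.random.default_rng(2))
    _randomize(block, rng)
    for shape in [(1, 4, 4, 12), (2, 8, 6, 12)]:
        assert block(Tensor(rng.normal(size=shape))).shape == shape


def test_patch_embed_shapes():
    spec = ModelSpec.tiny(base_dim=32)
    pe = PatchEmbed(spec, np.random.default_rng(0))
    out = pe(Tensor(np.zeros((1, 64, 64, 3))))
    assert out.shape == (1, 16, 16, 32)
    # full-size tile tokenizes to a 128x128 grid
    spec8 = ModelSpec.tiny(base_dim=8)
    pe8 = PatchEmbed(spec8, np.random.default_rng(0))
    out = pe8(Tensor(np.zeros((1, 512, 512, 3))))
    assert out.shape == (1, 128, 128, 8)


def test_patch_embed_deterministic(rng):
    spec = ModelSpec.tiny()
    pe = PatchEmbed(spec, np.random.default_rng(3))
    x = Tensor(rng.random((1, 32, 32, 3)))
    assert np.array_equal(pe(x).data, pe(x).data)


def test_patch_merging_shape_and_constant_preservation(rng):
    pm = PatchMerging(32, np.random.default_rng(0))
    assert pm(Tensor(np.zeros((1, 16, 16, 32)))).shape == (1, 8, 8, 64)
    # constructed weights: average the four neighbors, duplicated twice
    d = 4
    pm_small = PatchMerging(d, np.random.default_rng(0))
    w = np.zeros((4 * d, 2 * d))
    for blockrow in range(4):
        for i in range(d):
            w[blockrow * d + i, i] = 0.25
            w[blockrow * d + i, d + i] = 0.25
    pm_small.reduction.weight.data = w
    pm_small.reduction.bias.data = np.zeros(2 * d)
    const = np.tile(rng.normal(size=d), (1, 6, 6, 1))
    out = pm_small(Tensor(const)).data
    assert np.allclose(out[..., :d], const[:, :3, :3, :], atol=1e-12)
    assert np.allclose(out[..., d:], const[:, :3, :3, :], atol=1e-12)


def test_patch_merging_rejects_odd_grid():
    pm = PatchMerging(8, np.random.default_rng(0))
    with pytest.raises(ValueError):
        pm(Tensor(np.zeros((1, 5, 6, 8))))


def test_patch_expanding_shapes_and_roundtrip(rng):
    pe = PatchExpanding(64, np.random.default_rng(0))
    assert pe(Tensor(np.zeros((1, 8, 8, 64)))).shape == (1, 16, 16, 32)
    # expanding then merging restores the grid shape
    pm = PatchMerging(32, np.random.default_rng(1))
    x = Tensor(rng.normal(size=(1, 8, 8, 64)))
    assert pm(pe(x)).shape == x.shape
    with pytest.raises(ValueError):
        PatchExpanding(7, np.random.default_rng(0))


def test_sca_fusion_shape_and_mismatch(rng):
    sca = SCAFusion(32, 16, np.random.default_rng(0))
    x1 = Tensor(rng.normal(size=(1, 8, 8, 32)))
    x2 = Tensor(rng.normal(size=(1, 8, 8, 16)))
    assert sca(x1, x2).shape == (1, 8, 8, 16)
    with pytest.raises(ValueError):
        sca(x1, Tensor(rng.normal(size=(1, 4, 4, 16))))


# --------------------------------------------------------------------------
# full network
# --------------------------------------------------------------------------
@pytest.mark.parametrize("hw", [(32, 32), (64, 48), (96, 64)])
def test_forward_output_shape(hw):
    model = NucleusSegmenter(ModelSpec.tiny())
    h, w = hw
    out = model(np.zeros((h, w, 3)))
    assert out.shape == (1, h, w, 2)


def test_forward_rejects_indivisible_dims():
    model = NucleusSegmenter(ModelSpec.tiny())
    with pytest.raises(ValueError, match="16"):
        model(np.zeros((50, 64, 3)))


def test_forward_deterministic(rng):
    img = rng.random((32, 32, 3))
    m1 = NucleusSegmenter(ModelSpec.tiny(seed=7))
    m2 = NucleusSegmenter(ModelSpec.tiny(seed=7))
    assert np.array_equal(m1(img).data, m2(img).data)
    assert np.array_equal(m1(img).data, m1(img).data)


def test_backward_reaches_every_parameter(rng):
    model = NucleusSegmenter(ModelSpec.tiny(seed=1))
    _randomize(model, rng)  # activate zero-initialized branches too
    img = rng.random((1, 32, 32, 3))
    mask = (rng.random((1, 32, 32)) > 0.7).astype(int)
    loss = composite_loss(model(img), mask)
    loss.backward()
    grads = [p.grad for p in model.parameters()]
    assert all(g is not None and np.isfinite(g).all() for g in grads)
    nonzero = sum(1 for g in grads if np.any(g != 0))
    assert nonzero / len(grads) > 0.95


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(patch_stride=2)
    with pytest.raises(ValueError):
        ModelSpec(stage_depths=(2, 2), heads_per_stage=(1, 2, 4))
    with pytest.raises(ValueError):
        ModelSpec(base_dim=18)  # not divisible by 4


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------
def test_loss_weight_endpoints():
    w = LossWeights()
    assert combine_loss(1.0, 0.0, w) == pytest.approx(0.6)
    assert combine_loss(0.0, 1.0, w) == pytest.approx(0.4)
    with pytest.raises(ValueError):
        LossWeights(dice_weight=0.7, bce_weight=0.4)


def test_composite_loss_near_perfect_prediction(rng):
    mask = (rng.random((16, 16)) > 0.6).astype(int)
    scores = np.zeros((1, 16, 16, 2))
    scores[0, ..., 1] = np.where(mask == 1, 20.0, -20.0)
    loss = composite_loss(Tensor(scores), mask)
    assert 0.0 <= loss.item() <= 0.01


def test_composite_loss_worst_prediction_is_bounded(rng):
    mask = (rng.random((8, 8)) > 0.5).astype(int)
    scores = np.zeros((1, 8, 8, 2))
    scores[0, ..., 1] = np.where(mask == 1, -10.0, 10.0)  # confidently wrong
    loss = composite_loss(Tensor(scores), mask)
    assert loss.item() > 0.5  # near dice 0.6 + bce contribution


def test_composite_loss_rejects_nonbinary_mask():
    with pytest.raises(ValueError):
        composite_loss(Tensor(np.zeros((1, 4, 4, 2))), np.full((4, 4), 2))


def test_dice_bce_components(rng):
    z = Tensor(np.full((1, 4, 4), 50.0))
    ones = np.ones((1, 4, 4))
    assert dice_loss(z, ones).item() == pytest.approx(0.0, abs=1e-6)
    assert bce_with_logits(z, ones).item() == pytest.approx(0.0, abs=1e-6)


# --------------------------------------------------------------------------
# parameter counting
# --------------------------------------------------------------------------
def test_count_parameters_contract():
    spec = ModelSpec.tiny()
    assert count_parameters(spec) == count_parameters(spec)
    assert count_parameters(ModelSpec.tiny(base_dim=32)) > count_parameters(spec)


def test_linear_layer_hand_count():
    from nucleoseg.model import Linear

    lin = Linear(5, 7, np.random.default_rng(0))
    n = sum(p.data.size for _, p in lin.named_parameters())
    assert n == 5 * 7 + 7
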