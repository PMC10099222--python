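"""Window attention core: partition bookkeeping, shift masks, and oracle
equivalence of masked shifted-window attention with explicitly gathered
windows / dense attention."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrstnet import (
    SwinBlock, SwinBlockConfig, TokenGrid, WindowAttention, compute_attention_mask,
    cyclic_shift, swin_block_forward, window_partition, window_reverse,
    windowed_attention,
)
from hrstnet._tensor import Tensor
from hrstnet.swin import MASK_NEG


def grid(rng, dims, C=6, B=1):
    n = dims[0] * dims[1] * dims[2]
    return TokenGrid(Tensor(rng.standard_normal((B, n, C)).astype(np.float32)), dims)


# ---------------------------------------------------------------------------
# partition / reverse
# ---------------------------------------------------------------------------
def test_partition_counts(rng):
    g = grid(rng, (4, 4, 4))
    w, valid = window_partition(g, (2, 2, 2))
    assert w.shape[1:3] == (8, 8) and valid.all()
    w, valid = window_partition(g, (4, 4, 4))
    assert w.shape[1:3] == (1, 64) and valid.all()


def test_partition_padding_covers_each_token_once(rng):
    g = grid(rng, (6, 6, 6))
    w, valid = window_partition(g, (4, 4, 4))
    assert w.shape[1:3] == (8, 64)
    assert valid.sum() == 216
    # index bookkeeping oracle: partition a token-index grid with numpy and
    # verify every original token appears exactly once among valid slots
    idx = np.arange(216).reshape(6, 6, 6)
    idxp = np.pad(idx + 1, ((0, 2),) * 3)  # 1-based; 0 marks padding
    blocks = idxp.reshape(2, 4, 2, 4, 2, 4).transpose(0, 2, 4, 1, 3, 5)
    blocks = blocks.reshape(8, 64)
    assert np.array_equal(blocks != 0, valid)
    gathered = w.data[0, valid][np.argsort(blocks[valid])]
    np.testing.assert_array_equal(gathered, g.values.data[0])


def test_partition_invalid_window_raises(rng):
    with pytest.raises(ValueError):
        window_partition(grid(rng, (4, 4, 4)), (0, 2, 2))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(dims=st.tuples(*[st.integers(1, 6)] * 3),
       win=st.tuples(*[st.integers(1, 4)] * 3))
def test_partition_reverse_roundtrip(dims, win):
    rng = np.random.default_rng(hash((dims, win)) % 2 ** 31)
    g = grid(rng, dims, C=3)
    w, _ = window_partition(g, win)
    back = window_reverse(w, dims, win)
    np.testing.assert_array_equal(back.values.data, g.values.data)
    assert back.grid_dims == dims


def test_reverse_shape_mismatch_raises(rng):
    g = grid(rng, (4, 4, 4))
    w, _ = window_partition(g, (2, 2, 2))
    with pytest.raises(ValueError):
        window_reverse(w, (4, 4, 4), (4, 4, 4))


# ---------------------------------------------------------------------------
# cyclic shift
# ---------------------------------------------------------------------------
def test_cyclic_shift_identities(rng):
    g = grid(rng, (3, 4, 5))
    np.testing.assert_array_equal(cyclic_shift(g, (0, 0, 0)).values.data,
                                  g.values.data)
    np.testing.assert_array_equal(cyclic_shift(g, (3, 4, 5)).values.data,
                                  g.values.data)
    roundtrip = cyclic_shift(cyclic_shift(g, (1, 2, 3)), (-1, -2, -3))
    np.testing.assert_array_equal(roundtrip.values.data, g.values.data)


def test_cyclic_shift_1d_semantics(rng):
    # tokens [a, b, c, d] along one axis, shift 1 -> [b, c, d, a]
    g = grid(rng, (4, 1, 1), C=1)
    out = cyclic_shift(g, (1, 0, 0)).values.data[0, :, 0]
    np.testing.assert_array_equal(out, np.roll(g.values.data[0, :, 0], -1))


# ---------------------------------------------------------------------------
# attention masks
# ---------------------------------------------------------------------------
def test_mask_zero_when_unshifted_and_divisible():
    m = compute_attention_mask((4, 4, 4), (2, 2, 2), (0, 0, 0))
    assert (m == 0).all()


def test_mask_symmetric_within_windows():
    m = compute_attention_mask((6, 5, 7), (4, 4, 4), (2, 2, 2))
    np.testing.assert_array_equal(m, m.transpose(0, 2, 1))


def _segment(p: int, L: int, w: int, s: int) -> int:
    """Shift-mask segment of an original coordinate: the axis is cut at
    L - w and L - s (no cuts when the layer is unshifted)."""
    if s == 0:
        return 0
    return 0 if p < L - w else (1 if p < L - s else 2)


def test_mask_1d_brute_force():
    """1D grid length 4, window 2, shift 1: gather the shifted windows
    explicitly and mark pairs whose members come from different segments."""
    m = compute_attention_mask((4, 1, 1), (2, 1, 1), (1, 0, 0))
    rolled = np.roll(np.arange(4), -1)  # [1, 2, 3, 0]
    windows = rolled.reshape(2, 2)
    expect = np.zeros((2, 2, 2), dtype=np.float32)
    for wi, wtok in enumerate(windows):
        for a in range(2):
            for b in range(2):
                if _segment(wtok[a], 4, 2, 1) != _segment(wtok[b], 4, 2, 1):
                    expect[wi, a, b] = MASK_NEG
    np.testing.assert_array_equal(m, expect)


def _oracle_shifted_attention(g, attn, shift):
    """Brute-force oracle: roll the grid, gather windows explicitly, run
    plain numpy attention per window, blocking pairs whose original
    coordinates are not offset-preserving; then un-roll."""
    d, h, w = g.grid_dims
    C = g.embed_dim
    wd, wh, ww = attn.window_size
    x = g.values.data[0].reshape(d, h, w, C)
    pads = [(-d) % wd, (-h) % wh, (-w) % ww]
    xp = np.pad(x, ((0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
    D, H, W = xp.shape[:3]
    coords = np.stack(np.meshgrid(np.arange(D), np.arange(H), np.arange(W),
                                  indexing="ij"), -1)
    real = (coords[..., 0] < d) & (coords[..., 1] < h) & (coords[..., 2] < w)
    xs = np.roll(xp, tuple(-s for s in shift), (0, 1, 2))
    cs = np.roll(coords, tuple(-s for s in shift), (0, 1, 2))
    rs = np.roll(real, tuple(-s for s in shift), (0, 1, 2))

    qkvw = attn.qkv.weight.data
    qkvb = attn.qkv.bias.data
    projw, projb = attn.proj.weight.data, attn.proj.bias.data
    table = attn.relative_position_bias_table.data
    relidx = attn._rel_index.reshape(wd * wh * ww, wd * wh * ww)
    Hh, hd = attn.num_heads, attn.head_dim
    out = np.zeros_like(xs)
    for i0 in range(0, D, wd):
        for j0 in range(0, H, wh):
            for k0 in range(0, W, ww):
                blk = xs[i0:i0 + wd, j0:j0 + wh, k0:k0 + ww].reshape(-1, C)
                bc = cs[i0:i0 + wd, j0:j0 + wh, k0:k0 + ww].reshape(-1, 3)
                br = rs[i0:i0 + wd, j0:j0 + wh, k0:k0 + ww].reshape(-1)
                wpos = np.stack(np.meshgrid(np.arange(wd), np.arange(wh),
                                            np.arange(ww), indexing="ij"),
                                -1).reshape(-1, 3)
                qkv = blk @ qkvw + qkvb
                q, k, v = np.split(qkv, 3, axis=-1)
                segs = [tuple(_segment(bc[a][ax], (D, H, W)[ax],
                                       (wd, wh, ww)[ax], shift[ax])
                              for ax in range(3)) for a in range(len(blk))]
                res = np.zeros_like(blk)
                for head in range(Hh):
                    sl = slice(head * hd, (head + 1) * hd)
                    sc = (q[:, sl] / np.sqrt(hd)) @ k[:, sl].T
                    sc = sc + table[relidx, head]
                    for a in range(len(blk)):
                        for b in range(len(blk)):
                            if not (segs[a] == segs[b] and br[a] and br[b]):
                                sc[a, b] = -np.inf
                    sc = sc - sc.max(axis=-1, keepdims=True)
                    e = np.exp(sc)
                    p = e / np.maximum(e.sum(-1, keepdims=True), 1e-30)
                    res[:, sl] = p @ v[:, sl]
                out[i0:i0 + wd, j0:j0 + wh, k0:k0 + ww] = \
                    (res @ projw + projb).reshape(wd, wh, ww, C)
    out = np.roll(out, shift, (0, 1, 2))[:d, :h, :w]
    return out.reshape(-1, C)


@pytest.mark.parametrize("dims,window,shift", [
    ((4, 4, 4), (2, 2, 2), (1, 1, 1)),
    ((6, 5, 7), (4, 4, 4), (2, 2, 2)),
    ((8, 8, 8), (4, 4, 4), (2, 2, 2)),
    ((5, 4, 6), (3, 3, 3), (1, 1, 1)),
])
def test_masked_attention_equals_gathered_window_oracle(rng, dims, window, shift):
    C, heads = 6, 2
    g = grid(rng, dims, C=C)
    attn = WindowAttention(C, heads, window, rng)
    ours = windowed_attention(g, attn, shift).values.data[0]
    oracle = _oracle_shifted_attention(g, attn, shift)
    np.testing.assert_allclose(ours, oracle, atol=1e-5)


def test_global_window_reduces_to_dense_attention(rng):
    """window = grid, shift 0: equals dense full-grid attention."""
    dims, C, heads = (4, 4, 4), 8, 2
    g = grid(rng, dims, C=C)
    attn = WindowAttention(C, heads, dims, rng)
    ours = windowed_attention(g, attn, (0, 0, 0)).values.data[0]

    x = g.values.data[0]
    qkv = x @ attn.qkv.weight.data + attn.qkv.bias.data
    q, k, v = np.split(qkv, 3, -1)
    relidx = attn._rel_index.reshape(64, 64)
    out = np.zeros_like(x)
    for head in range(heads):
        sl = slice(head * 4, (head + 1) * 4)
        sc = (q[:, sl] / 2.0) @ k[:, sl].T
        sc += attn.relative_position_bias_table.data[relidx, head]
        e = np.exp(sc - sc.max(-1, keepdims=True))
        p = e / e.sum(-1, keepdims=True)
        out[:, sl] = p @ v[:, sl]
    dense = out @ attn.proj.weight.data + attn.proj.bias.data
    np.testing.assert_allclose(ours, dense, atol=1e-5)


def test_single_token_attention_is_value_projection(rng):
    C = 4
    g = grid(rng, (1, 1, 1), C=C)
    attn = WindowAttention(C, 2, (1, 1, 1), rng)
    out = windowed_attention(g, attn).values.data[0]
    x = g.values.data[0]
    v = (x @ attn.qkv.weight.data + attn.qkv.bias.data)[:, 2 * C:]
    np.testing.assert_allclose(out, v @ attn.proj.weight.data + attn.proj.bias.data,
                               atol=1e-5)


def test_head_divisibility_enforced(rng):
    with pytest.raises(ValueError):
        WindowAttention(7, 2, (2, 2, 2), rng)


# ---------------------------------------------------------------------------
# swin block
# ---------------------------------------------------------------------------
def test_swin_block_preserves_shape_and_is_deterministic(rng):
    cfg = SwinBlockConfig(depth=2, num_heads=2, window_size=(3, 3, 3))
    block = SwinBlock(6, cfg, np.random.default_rng(7))
    g = grid(rng, (5, 4, 6), C=6)
    a = swin_block_forward(g, block)
    b = swin_block_forward(g, block)
    assert a.grid_dims == g.grid_dims and a.values.shape == g.values.shape
    np.testing.assert_array_equal(a.values.data, b.values.data)


def test_swin_block_zeroed_weights_is_identity(rng):
    cfg = SwinBlockConfig(depth=2, num_heads=2, window_size=(2, 2, 2))
    block = SwinBlock(4, cfg, np.random.default_rng(7))
    for layer in block.layers:
        for lin in (layer.attn.qkv, layer.attn.proj, layer.mlp.fc1, layer.mlp.fc2):
            lin.weight.data[:] = 0
            lin.bias.data[:] = 0
        layer.attn.relative_position_bias_table.data[:] = 0
    g = grid(rng, (4, 4, 4), C=4)
    out = swin_block_forward(g, block)
    np.testing.assert_array_equal(out.values.data, g.values.data)


def test_block_config_validation():
    with pytest.raises(ValueError):
        SwinBlockConfig(window_size=(0, 2, 2))
    with pytest.raises(ValueError):
        SwinBlockConfig(window_size=(2, 2, 2), shift_size=(2, 0, 0))
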