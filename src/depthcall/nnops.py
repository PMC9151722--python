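"""Differentiable primitives used by the three networks.

Everything here is a pure function of (parameters, inputs) built from
``autograd.numpy`` operations, so gradients of any composition are
available via ``autograd``. Layout is channels-last: (batch, H, W, C)
for images and (batch, T, F) for sequences. Parameters are nested dicts
of float32 arrays created by the seeded ``init_*`` helpers.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as onp
from autograd.extend import defvjp, primitive

DTYPE = onp.float32


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def relu(x):
    return anp.maximum(x, 0.0)


def softmax(x):
    z = x - anp.max(x, axis=-1, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=-1, keepdims=True)


def dense(x, p):
    return anp.dot(x, p["W"]) + p["b"]


def _pad_hw(x, d):
    return onp.pad(x, ((0, 0), (d, d), (d, d), (0, 0)))


def _im2col(x, d):
    """Gather the 9 dilated-neighbourhood slices: (B,H,W,C) -> (B,H,W,9,C)."""
    B, H, Wd, C = x.shape
    xp = _pad_hw(x, d)
    cols = onp.empty((B, H, Wd, 9, C), dtype=x.dtype)
    for ki in range(3):
        for kj in range(3):
            cols[:, :, :, 3 * ki + kj, :] = xp[:, ki * d : ki * d + H, kj * d : kj * d + Wd, :]
    return cols


# bounded memo so a conv's W-VJP reuses the im2col built in its forward
# pass; callers that drive many graphs (the training loop) clear it per
# step via clear_conv_memo() so it never thrashes mid-backward
_conv_cols_memo: dict = {}
_CONV_MEMO_CAP = 160


def clear_conv_memo() -> None:
    _conv_cols_memo.clear()


def _im2col_cached(x, d):
    key = (id(x), d)
    hit = _conv_cols_memo.get(key)
    if hit is None or hit[0] is not x:
        cols = _im2col(x, d)
        if cols.nbytes > 32 * 2**20:  # don't hoard inference-sized batches
            return cols
        if len(_conv_cols_memo) >= _CONV_MEMO_CAP:
            _conv_cols_memo.clear()
        hit = (x, cols)
        _conv_cols_memo[key] = hit
    return hit[1]


@primitive
def conv2d_op(x, W, b, dilation=1):
    """3x3 'same' convolution with the given dilation, channels-last.

    A primitive with hand-written VJPs (im2col + one GEMM): autograd's
    generic slicing gradient (ufunc.at) is far too slow for the conv
    shift-and-accumulate pattern.
    """
    B, H, Wd, C = x.shape
    cout = W.shape[-1]
    cols = _im2col_cached(x, dilation)
    out = cols.reshape(B * H * Wd, 9 * C) @ W.reshape(9 * C, cout)
    return out.reshape(B, H, Wd, cout) + b


def _conv2d_vjp_x(ans, x, W, b, dilation=1):
    d = dilation
    B, H, Wd, C = x.shape

    def vjp(g):
        cout = W.shape[-1]
        g = onp.ascontiguousarray(g, dtype=x.dtype)
        dcols = g.reshape(B * H * Wd, cout) @ W.reshape(9 * C, cout).T
        dcols = dcols.reshape(B, H, Wd, 9, C)
        gp = onp.zeros((B, H + 2 * d, Wd + 2 * d, C), dtype=g.dtype)
        for ki in range(3):
            for kj in range(3):
                gp[:, ki * d : ki * d + H, kj * d : kj * d + Wd, :] += dcols[:, :, :, 3 * ki + kj, :]
        return gp[:, d : d + H, d : d + Wd, :]

    return vjp


def _conv2d_vjp_W(ans, x, W, b, dilation=1):
    B, H, Wd, C = x.shape

    def vjp(g):
        cols = _im2col_cached(x, dilation)
        cout = W.shape[-1]
        g = onp.ascontiguousarray(g, dtype=x.dtype)
        dW = cols.reshape(B * H * Wd, 9 * C).T @ g.reshape(B * H * Wd, cout)
        return dW.reshape(W.shape)

    return vjp


defvjp(
    conv2d_op,
    _conv2d_vjp_x,
    _conv2d_vjp_W,
    lambda ans, x, W, b, dilation=1: lambda g: g.sum(axis=(0, 1, 2)),
)


def conv2d(x, p, dilation=1):
    return conv2d_op(x, p["W"], p["b"], dilation)


def conv2d_reference(x, p, dilation=1):
    """Composed-autograd twin of :func:`conv2d` for gradient cross-checks."""
    d = dilation
    B, H, W, _ = x.shape
    xp = anp.pad(x, ((0, 0), (d, d), (d, d), (0, 0)), mode="constant")
    out = None
    for ki in range(3):
        for kj in range(3):
            term = anp.tensordot(
                xp[:, ki * d : ki * d + H, kj * d : kj * d + W, :],
                p["W"][ki, kj],
                axes=([3], [0]),
            )
            out = term if out is None else out + term
    return out + p["b"]


def conv1x1(x, p):
    return anp.tensordot(x, p["W"], axes=([3], [0])) + p["b"]


def maxpool2(x):
    """2x2 max pooling; odd spatial sizes are zero-padded to even first
    (inputs are post-rectifier, so padding never wins the max)."""
    B, H, W, C = x.shape
    if H % 2:
        x = anp.pad(x, ((0, 0), (0, 1), (0, 0), (0, 0)), mode="constant")
        H += 1
    if W % 2:
        x = anp.pad(x, ((0, 0), (0, 0), (0, 1), (0, 0)), mode="constant")
        W += 1
    x = anp.reshape(x, (B, H // 2, 2, W // 2, 2, C))
    return anp.max(anp.max(x, axis=4), axis=2)


def upsample2(x, p):
    """Learned 2x transposed convolution (kernel 2, stride 2)."""
    B, H, W, _ = x.shape
    cout = p["W"].shape[-1]
    y = anp.tensordot(x, p["W"], axes=([3], [0])) + p["b"]  # (B,H,W,2,2,Cout)
    y = anp.transpose(y, (0, 1, 3, 2, 4, 5))
    return anp.reshape(y, (B, 2 * H, 2 * W, cout))


def crop(x, h, w):
    return x[:, :h, :w, :]


def _np_sigmoid(x):
    return 0.5 * (onp.tanh(0.5 * x) + 1.0)


def _lstm_run(x, Wx, Wh, b, reverse):
    """Plain-numpy LSTM pass; returns hidden states (in input time
    order) and the per-step cache needed for backpropagation."""
    B, T, _ = x.shape
    H = Wh.shape[0]
    xw = onp.tensordot(x, Wx, axes=([2], [0])) + b  # (B,T,4H)
    h = onp.zeros((B, H), dtype=x.dtype)
    c = onp.zeros((B, H), dtype=x.dtype)
    hs = onp.empty((B, T, H), dtype=x.dtype)
    cache = []
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        z = xw[:, t, :] + h @ Wh
        i = _np_sigmoid(z[:, :H])
        f = _np_sigmoid(z[:, H : 2 * H])
        g = onp.tanh(z[:, 2 * H : 3 * H])
        o = _np_sigmoid(z[:, 3 * H :])
        c_prev, h_prev = c, h
        c = f * c_prev + i * g
        tc = onp.tanh(c)
        h = o * tc
        hs[:, t, :] = h
        cache.append((t, i, f, g, o, c_prev, tc, h_prev))
    return hs, cache


@primitive
def lstm_states(x, Wx, Wh, b, reverse=False):
    """Per-step hidden states of a single-direction LSTM, as a primitive
    with a hand-written backward pass (see :func:`_lstm_vjps`)."""
    return _lstm_run(x, Wx, Wh, b, reverse)[0]


def _lstm_backward(g, x, Wx, Wh, b, reverse):
    g = onp.ascontiguousarray(g, dtype=x.dtype)
    _, cache = _lstm_run(x, Wx, Wh, b, reverse)
    B, T, _ = x.shape
    H = Wh.shape[0]
    dxw = onp.empty((B, T, 4 * H), dtype=x.dtype)
    dWh = onp.zeros_like(Wh)
    dh = onp.zeros((B, H), dtype=x.dtype)
    dc = onp.zeros((B, H), dtype=x.dtype)
    for t, i, f, gg, o, c_prev, tc, h_prev in reversed(cache):
        dh_t = g[:, t, :] + dh
        do = dh_t * tc
        dc = dc + dh_t * o * (1.0 - tc * tc)
        di = dc * gg
        df = dc * c_prev
        dg = dc * i
        dz = onp.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - gg * gg), do * o * (1 - o)],
            axis=1,
        )
        dxw[:, t, :] = dz
        dWh += h_prev.T @ dz
        dh = dz @ Wh.T
        dc = dc * f
    dx = onp.tensordot(dxw, Wx, axes=([2], [1]))
    dWx = onp.tensordot(x, dxw, axes=([0, 1], [0, 1]))
    db = dxw.sum(axis=(0, 1))
    return dx, dWx, dWh, db


# one-entry memo: autograd calls the per-argument VJPs of a node back to
# back with the same upstream gradient, so a single BPTT pass serves all four
_lstm_bw_memo: dict = {}


def _lstm_backward_cached(g, x, Wx, Wh, b, reverse):
    key = (id(g), id(x), id(Wx), reverse)
    hit = _lstm_bw_memo.get(key)
    if hit is None or hit[0] is not g:
        _lstm_bw_memo.clear()
        hit = (g, _lstm_backward(g, x, Wx, Wh, b, reverse))
        _lstm_bw_memo[key] = hit
    return hit[1]


def _lstm_vjp(argnum):
    def vjp_maker(ans, x, Wx, Wh, b, reverse=False):
        return lambda g: _lstm_backward_cached(g, x, Wx, Wh, b, reverse)[argnum]

    return vjp_maker


defvjp(lstm_states, *(_lstm_vjp(k) for k in range(4)))


def lstm_layer(x, p, reverse=False):
    """Single-direction LSTM over (B, T, F); returns per-step hidden
    states (B, T, H) in input time order and the final hidden state."""
    hs = lstm_states(x, p["Wx"], p["Wh"], p["b"], reverse)
    final = hs[:, 0, :] if reverse else hs[:, -1, :]
    return hs, final


def lstm_layer_reference(x, p, reverse=False):
    """Composed-autograd twin of :func:`lstm_layer` for gradient checks."""
    B, T, _ = x.shape
    H = p["Wh"].shape[0]
    xw = anp.tensordot(x, p["Wx"], axes=([2], [0])) + p["b"]
    h = anp.zeros((B, H), dtype=DTYPE)
    c = anp.zeros((B, H), dtype=DTYPE)
    hs = []
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        z = xw[:, t, :] + anp.dot(h, p["Wh"])
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = anp.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c = f * c + i * g
        h = o * anp.tanh(c)
        hs.append(h)
    if reverse:
        hs = hs[::-1]
    return anp.stack(hs, axis=1), h


def bilstm_layer(x, p):
    """Bidirectional layer: concatenated per-step states and the pair of
    final states (forward-final, backward-final)."""
    fwd_seq, fwd_h = lstm_layer(x, p["fwd"], reverse=False)
    bwd_seq, bwd_h = lstm_layer(x, p["bwd"], reverse=True)
    return anp.concatenate([fwd_seq, bwd_seq], axis=2), (fwd_h, bwd_h)


# ---------------------------------------------------------------------------
# seeded initialization (uniform fan-in)


def _uniform(rng, shape, fan_in):
    limit = 1.0 / onp.sqrt(max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def init_dense(rng, fan_in, fan_out):
    return {"W": _uniform(rng, (fan_in, fan_out), fan_in),
            "b": onp.zeros(fan_out, dtype=DTYPE)}


def init_conv(rng, cin, cout):
    return {"W": _uniform(rng, (3, 3, cin, cout), 9 * cin),
            "b": onp.zeros(cout, dtype=DTYPE)}


def init_conv1x1(rng, cin, cout):
    return {"W": _uniform(rng, (cin, cout), cin),
            "b": onp.zeros(cout, dtype=DTYPE)}


def init_upsample(rng, cin, cout):
    return {"W": _uniform(rng, (cin, 2, 2, cout), cin),
            "b": onp.zeros(cout, dtype=DTYPE)}


def init_lstm(rng, fan_in, hidden):
    b = onp.zeros(4 * hidden, dtype=DTYPE)
    b[hidden : 2 * hidden] = 1.0  # forget-gate bias: keep memory alive at init
    return {
        "Wx": _uniform(rng, (fan_in, 4 * hidden), fan_in),
        "Wh": _uniform(rng, (hidden, 4 * hidden), hidden),
        "b": b,
    }


def init_bilstm(rng, fan_in, hidden):
    return {"fwd": init_lstm(rng, fan_in, hidden),
            "bwd": init_lstm(rng, fan_in, hidden)}
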