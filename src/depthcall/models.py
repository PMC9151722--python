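"""The three networks: generator G, discriminator D, caller C.

G is an encoder-decoder with skip connections and dilated convolutions
that maps a 33x32 low-depth pileup image to a predicted high-depth
image of the same size. D scores a (candidate, conditioning) image pair
with a probability that the candidate is a real high-depth image. C is
a two-layer bidirectional LSTM over the 33-step sequence formed by
concatenating the projected and observed images along the feature axis,
ending in four softmax heads (21 genotype pairs, 3 zygosities, two
33-way allele-length changes).

All forwards are pure, deterministic functions of (params, input);
parameters are nested dicts of float32 arrays with seeded init.
"""

from __future__ import annotations

import json

import autograd.numpy as anp
import numpy as onp

from . import nnops as nn

IMAGE_SHAPE = (33, 32)
HEAD_SIZES = {"gt21": 21, "zygosity": 3, "len1": 33, "len2": 33}

_ENC_CHANNELS = (16, 32, 64)
_LSTM_HIDDEN = 128
_FC_SIZES = (192, 96)

#: fixed count-to-feature scale for the caller input. Pileup counts grow
#: with depth (tens of reads); feeding them raw saturates the recurrent
#: gates and stalls learning, so the caller sees counts / 10.
CALLER_INPUT_SCALE = 0.1

_PROB_EPS = 1e-7


def _check_images(x, name="images"):
    x = onp.asarray(x, dtype=nn.DTYPE) if not hasattr(x, "_value") else x
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != IMAGE_SHAPE:
        raise ValueError(f"{name} must have shape (n, 33, 32), got {x.shape}")
    return x


# ---------------------------------------------------------------------------
# generator


def init_generator(seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed)
    p: dict = {}
    cin = 1
    for i, c in enumerate(_ENC_CHANNELS, start=1):
        p[f"enc{i}a"] = nn.init_conv(rng, cin, c)
        p[f"enc{i}b"] = nn.init_conv(rng, c, c)
        cin = c
    p["botta"] = nn.init_conv(rng, 64, 64)
    p["bottb"] = nn.init_conv(rng, 64, 64)
    dec_channels = (64, 32, 16)
    skip_channels = (64, 32, 16)
    cin = 64
    for i, (c, skip) in enumerate(zip(dec_channels, skip_channels), start=1):
        p[f"up{i}"] = nn.init_upsample(rng, cin, c)
        p[f"dec{i}a"] = nn.init_conv(rng, c + skip, c)
        p[f"dec{i}b"] = nn.init_conv(rng, c, c)
        cin = c
    p["out"] = nn.init_conv1x1(rng, 16, 1)
    return p


def _conv_block(x, pa, pb):
    x = nn.relu(nn.conv2d(x, pa, dilation=1))
    return nn.relu(nn.conv2d(x, pb, dilation=2))


def _encoder(x, p, prefix="enc"):
    """Three (conv, dilated conv, 2x pool) stages; returns pooled output
    and the pre-pool feature maps for skip connections."""
    skips = []
    for i in range(1, 4):
        x = _conv_block(x, p[f"{prefix}{i}a"], p[f"{prefix}{i}b"])
        skips.append(x)
        x = nn.maxpool2(x)
    return x, skips


def generator_forward(params: dict, images):
    """Project a batch of low-depth images to predicted high-depth images."""
    x = _check_images(images)
    squeeze = onp.ndim(images) == 2
    h = anp.reshape(x, x.shape + (1,))
    h, skips = _encoder(h, params)
    h = _conv_block(h, params["botta"], params["bottb"])
    for i, skip in enumerate(reversed(skips), start=1):
        h = nn.upsample2(h, params[f"up{i}"])
        h = nn.crop(h, skip.shape[1], skip.shape[2])
        h = anp.concatenate([h, skip], axis=3)
        h = _conv_block(h, params[f"dec{i}a"], params[f"dec{i}b"])
    h = nn.conv1x1(h, params["out"])  # linear: counts are unbounded above
    out = anp.reshape(h, x.shape)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# discriminator


def init_discriminator(seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed)
    p: dict = {}
    cin = 2
    for i, c in enumerate(_ENC_CHANNELS, start=1):
        p[f"enc{i}a"] = nn.init_conv(rng, cin, c)
        p[f"enc{i}b"] = nn.init_conv(rng, c, c)
        cin = c
    p["head"] = nn.init_dense(rng, 64, 1)
    return p


def discriminator_forward(params: dict, candidate, conditioning):
    """Probability in (0, 1) that ``candidate`` is a real high-depth image,
    conditioned on the low-depth image it should correspond to.

    Channel order of the stacked input is (candidate, conditioning).
    """
    cand = _check_images(candidate, "candidate")
    cond = _check_images(conditioning, "conditioning")
    if cand.shape != cond.shape:
        raise ValueError("candidate and conditioning batches differ in shape")
    squeeze = onp.ndim(candidate) == 2
    h = anp.stack([cand, cond], axis=3)
    h, _ = _encoder(h, params)
    h = anp.mean(h, axis=(1, 2))  # global average pooling -> (B, 64)
    logit = nn.dense(h, params["head"])[:, 0]
    # squash the logit smoothly: keeps the probability strictly inside
    # (0, 1) while the gradient never vanishes exactly (a hard clip can
    # deadlock adversarial training once D saturates)
    prob = nn.sigmoid(15.0 * anp.tanh(anp.clip(logit, -60.0, 60.0) / 15.0))
    return prob[0] if squeeze else prob


# ---------------------------------------------------------------------------
# caller


def init_caller(seed: int = 0) -> dict:
    rng = onp.random.default_rng(seed)
    p = {
        "lstm1": nn.init_bilstm(rng, 64, _LSTM_HIDDEN),
        "lstm2": nn.init_bilstm(rng, 2 * _LSTM_HIDDEN, _LSTM_HIDDEN),
        "fc1": nn.init_dense(rng, 2 * _LSTM_HIDDEN, _FC_SIZES[0]),
        "fc2": nn.init_dense(rng, _FC_SIZES[0], _FC_SIZES[1]),
    }
    for head, k in HEAD_SIZES.items():
        p[f"head_{head}"] = nn.init_dense(rng, _FC_SIZES[1], k)
    return p


def caller_forward(params: dict, generated, low) -> dict:
    """Predict the four variant-attribute distributions from the
    (projected, observed) image pair. Returns a dict of simplex arrays
    keyed ``gt21``, ``zygosity``, ``len1``, ``len2``."""
    gen = _check_images(generated, "generated")
    obs = _check_images(low, "low")
    if gen.shape != obs.shape:
        raise ValueError("generated and low batches differ in shape")
    squeeze = onp.ndim(generated) == 2
    seq = CALLER_INPUT_SCALE * anp.concatenate([gen, obs], axis=2)  # (B, 33, 64)
    seq, _ = nn.bilstm_layer(seq, params["lstm1"])
    seq, _ = nn.bilstm_layer(seq, params["lstm2"])
    # read out the candidate column's state: at the window center both
    # directions have consumed the whole window, and the variant signal
    # stays localized instead of being diluted across 33 steps
    h = seq[:, seq.shape[1] // 2, :]  # (B, 256)
    h = nn.relu(nn.dense(h, params["fc1"]))
    h = nn.relu(nn.dense(h, params["fc2"]))
    out = {}
    for head in HEAD_SIZES:
        probs = nn.softmax(nn.dense(h, params[f"head_{head}"]))
        out[head] = probs[0] if squeeze else probs
    return out


# ---------------------------------------------------------------------------
# checkpoints


def _flatten_tree(tree, prefix=""):
    flat = {}
    for key in sorted(tree):
        val = tree[key]
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            flat.update(_flatten_tree(val, name + "/"))
        else:
            flat[name] = val
    return flat


def _unflatten_tree(flat):
    tree: dict = {}
    for name, val in flat.items():
        parts = name.split("/")
        node = tree
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = val
    return tree


def save_params(path, params: dict, meta: dict | None = None) -> None:
    """Single-file checkpoint: arrays plus a JSON metadata header."""
    flat = _flatten_tree(params)
    header = json.dumps(meta or {})
    onp.savez(path, __meta__=onp.frombuffer(header.encode(), dtype=onp.uint8), **flat)


def load_params(path) -> tuple[dict, dict]:
    with onp.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode()) if "__meta__" in data else {}
        flat = {k: data[k] for k in data.files if k != "__meta__"}
    return _unflatten_tree(flat), meta
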