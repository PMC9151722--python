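"""Losses and the alternating two-optimizer training procedure.

One step has two phases. Phase 1 updates the generator and caller
jointly under

    total = lambda1 * mse(G(I), I_gt)
          + lambda2 * sum of focal losses over the four caller heads
          + lambda3 * mean(-log D(G(I), I))

with the discriminator frozen. Phase 2 then updates the discriminator
under mean(-(log D(I_gt, I) + log(1 - D(G(I), I)))) with the generator
output treated as a constant. Both Adam optimizers take exactly one
step per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as onp
from autograd import value_and_grad
from autograd.misc import flatten

from . import models, nnops
from .pileup import GT_SYMBOLS, genotype_class_table, gt21_index

LOG_EPS = 1e-7


@dataclass
class LossWeights:
    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.1
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    batch_size: int = 256
    epochs: int = 5
    seed: int = 0
    log_clamp_eps: float = LOG_EPS
    adversarial: bool = True  # False: drop the adversarial term and D updates
    caller_only: bool = False  # True: train C on (I, I) alone, G untouched
    augment: bool = False  # label-consistent augmentation of each batch

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class LossRecord:
    l_g: float = 0.0
    l_c: float = 0.0
    l_adver: float = 0.0
    l_total: float = 0.0
    l_d: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


class TrainingDiverged(RuntimeError):
    pass


def _to_float(x) -> float:
    # unwrap autograd boxes captured inside a traced objective
    while hasattr(x, "_value"):
        x = x._value
    return float(x)


# ---------------------------------------------------------------------------
# losses


def _clamp(p, eps=LOG_EPS):
    return anp.clip(p, eps, 1.0)


def focal_loss(probs, target, gamma: float = 2.0, eps: float = LOG_EPS):
    """Mean over the batch of -(1 - p_t)^gamma * log(p_t).

    ``probs`` is (K,) or (B, K); ``target`` an index or (B,) indices.
    gamma = 0 recovers plain cross-entropy.
    """
    probs2 = probs if anp.ndim(probs) == 2 else anp.reshape(probs, (1, -1))
    targets = onp.atleast_1d(onp.asarray(target, dtype=onp.int64))
    K = probs2.shape[1]
    if (targets < 0).any() or (targets >= K).any():
        raise ValueError(f"target out of range for {K} classes")
    onehot = onp.eye(K, dtype=onp.float32)[targets]
    p_t = _clamp(anp.sum(probs2 * onehot, axis=1), eps)
    return anp.mean(-((1.0 - p_t) ** gamma) * anp.log(p_t))


def caller_loss(pred: dict, labels, gamma: float = 2.0):
    """Equally-weighted sum of the four per-head focal losses.

    ``labels`` is (B, 4) of (gt21, zygosity, len1, len2) indices.
    """
    labels = onp.atleast_2d(onp.asarray(labels, dtype=onp.int64))
    total = 0.0
    for i, head in enumerate(("gt21", "zygosity", "len1", "len2")):
        total = total + focal_loss(pred[head], labels[:, i], gamma)
    return total


def generator_loss(generated, target):
    """Mean over batch and pixels of the squared projection error."""
    return anp.mean((generated - target) ** 2)


def adversarial_g_loss(d_fake, eps: float = LOG_EPS):
    return anp.mean(-anp.log(_clamp(d_fake, eps)))


def discriminator_loss(d_real, d_fake, eps: float = LOG_EPS):
    return anp.mean(-(anp.log(_clamp(d_real, eps)) + anp.log(_clamp(1.0 - d_fake, eps))))


# ---------------------------------------------------------------------------
# augmentation

_GT_TABLE = genotype_class_table()


def _gt21_permutation(base_perm) -> onp.ndarray:
    """Map each genotype-pair class through a permutation of the four
    base symbols (Ins/Del are fixed points)."""
    relabel = {GT_SYMBOLS[i]: GT_SYMBOLS[int(base_perm[i])] for i in range(4)}
    out = onp.empty(len(_GT_TABLE), dtype=onp.int64)
    for k, (a, b) in enumerate(_GT_TABLE):
        out[k] = gt21_index(relabel.get(a, a), relabel.get(b, b))
    return out


def augment_batch(low, high, labels, rng):
    """Label-consistent batch augmentation.

    Per batch: permute the four base identities (same permutation on
    both strands and both images, with the gt21 label remapped), mirror
    the position axis half the time, and apply a mild multiplicative
    depth jitter. Zygosity and length labels are invariant under all
    three. This emulates data abundance at desk scale, where the
    handful of simulated variant sites would otherwise be memorized.
    """
    B = low.shape[0]
    width = low.shape[1]
    low = low.reshape(B, width, 8, 4).copy()
    high = high.reshape(B, width, 8, 4).copy()
    labels = labels.copy()

    perm = rng.permutation(4)
    row_perm = onp.concatenate([perm, perm + 4])
    inv = onp.argsort(row_perm)
    low = low[:, :, inv, :]
    high = high[:, :, inv, :]
    labels[:, 0] = _gt21_permutation(perm)[labels[:, 0]]

    if rng.random() < 0.5:
        low = low[:, ::-1]
        high = high[:, ::-1]

    scale = rng.uniform(0.8, 1.25)
    low = low * scale
    high = high * scale

    return (
        onp.ascontiguousarray(low.reshape(B, width, 32), dtype=onp.float32),
        onp.ascontiguousarray(high.reshape(B, width, 32), dtype=onp.float32),
        labels,
    )


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Plain Adam over a flattened parameter tree."""

    def __init__(self, learning_rate: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = None
        self.v = None
        self.t = 0

    def step(self, params, grads):
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        flat_g = flat_g.astype(flat_p.dtype, copy=False)
        if self.m is None:
            self.m = onp.zeros_like(flat_p)
            self.v = onp.zeros_like(flat_p)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * flat_g
        self.v = self.beta2 * self.v + (1 - self.beta2) * flat_g**2
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        new_flat = flat_p - self.lr * mhat / (onp.sqrt(vhat) + self.eps)
        return unflatten(new_flat.astype(flat_p.dtype))


# ---------------------------------------------------------------------------
# training


def _batch_arrays(batch) -> tuple[onp.ndarray, onp.ndarray, onp.ndarray]:
    """Accept either a dict of arrays or a list of TrainingExample."""
    if isinstance(batch, dict):
        return (
            onp.asarray(batch["low"], dtype=onp.float32),
            onp.asarray(batch["high"], dtype=onp.float32),
            onp.asarray(batch["labels"], dtype=onp.int64),
        )
    low = onp.stack([ex.low_image.data for ex in batch]).astype(onp.float32)
    high = onp.stack([ex.high_image.data for ex in batch]).astype(onp.float32)
    labels = onp.asarray([ex.label.as_tuple() for ex in batch], dtype=onp.int64)
    return low, high, labels


def _check_finite(record: LossRecord, batch_info: str) -> None:
    vals = record.as_dict()
    if not all(onp.isfinite(v) for v in vals.values()):
        raise TrainingDiverged(f"non-finite loss {vals} on batch {batch_info}")


def train_step(
    batch,
    g_params: dict,
    c_params: dict,
    d_params: dict,
    weights: LossWeights,
    g_opt: Adam,
    d_opt: Adam,
    config: TrainConfig | None = None,
):
    """One alternating step; returns updated (g, c, d) params and a LossRecord."""
    config = config or TrainConfig()
    low, high, labels = _batch_arrays(batch)
    if low.shape[0] == 0:
        raise ValueError("empty batch")
    nnops.clear_conv_memo()
    lam3 = weights.lambda3 if config.adversarial else 0.0
    parts: dict = {}

    if config.caller_only:
        def c_obj(cp):
            pred = models.caller_forward(cp, low, low)
            l_c = caller_loss(pred, labels, weights.gamma)
            parts.update(l_g=0.0, l_c=l_c, l_adver=0.0)
            return weights.lambda2 * l_c

        total, grads = value_and_grad(c_obj)(c_params)
        c_params = g_opt.step(c_params, grads)
        record = LossRecord(
            l_g=0.0,
            l_c=_to_float(parts["l_c"]),
            l_adver=0.0,
            l_total=_to_float(total),
            l_d=0.0,
        )
        _check_finite(record, f"size={low.shape[0]}")
        return g_params, c_params, d_params, record

    def gc_obj(gc):
        gen = models.generator_forward(gc["g"], low)
        parts["gen"] = gen
        l_g = generator_loss(gen, high)
        pred = models.caller_forward(gc["c"], gen, low)
        l_c = caller_loss(pred, labels, weights.gamma)
        if lam3 > 0:
            d_fake = models.discriminator_forward(d_params, gen, low)
            l_adv = adversarial_g_loss(d_fake, config.log_clamp_eps)
        else:
            l_adv = 0.0
        parts.update(l_g=l_g, l_c=l_c, l_adver=l_adv)
        return weights.lambda1 * l_g + weights.lambda2 * l_c + lam3 * l_adv

    total, grads = value_and_grad(gc_obj)({"g": g_params, "c": c_params})
    updated = g_opt.step({"g": g_params, "c": c_params}, grads)
    g_params, c_params = updated["g"], updated["c"]

    l_d = 0.0
    if config.adversarial:
        # fake images for D come from the phase-1 forward pass (pre-update
        # G) — the standard minimax ordering; G's output is detached so no
        # gradient reaches the generator
        gen_val = parts["gen"]
        while hasattr(gen_val, "_value"):
            gen_val = gen_val._value
        gen_const = onp.asarray(gen_val, dtype=onp.float32)

        def d_obj(dp):
            d_real = models.discriminator_forward(dp, high, low)
            d_fake = models.discriminator_forward(dp, gen_const, low)
            return discriminator_loss(d_real, d_fake, config.log_clamp_eps)

        l_d, d_grads = value_and_grad(d_obj)(d_params)
        d_params = d_opt.step(d_params, d_grads)

    l_g, l_c, l_adver = (_to_float(parts[k]) for k in ("l_g", "l_c", "l_adver"))
    record = LossRecord(
        l_g=l_g,
        l_c=l_c,
        l_adver=l_adver,
        # recompute in double precision so the decomposition identity of
        # the record holds exactly (the float32 graph value may differ ~1e-7)
        l_total=weights.lambda1 * l_g + weights.lambda2 * l_c + lam3 * l_adver,
        l_d=_to_float(l_d),
    )
    _check_finite(record, f"size={low.shape[0]}")
    return g_params, c_params, d_params, record


@dataclass
class FitResult:
    g_params: dict
    c_params: dict
    d_params: dict
    history: list[LossRecord] = field(default_factory=list)
    zygosity_accuracy: list[float] = field(default_factory=list)


def zygosity_accuracy(c_params, g_params, low, labels, caller_only=False, batch_size=256):
    """Training-set argmax accuracy of the zygosity head."""
    correct = 0
    for i in range(0, low.shape[0], batch_size):
        chunk = low[i : i + batch_size]
        gen = chunk if caller_only else models.generator_forward(g_params, chunk)
        pred = models.caller_forward(c_params, onp.asarray(gen), chunk)
        correct += int((onp.argmax(pred["zygosity"], axis=1) == labels[i : i + batch_size, 1]).sum())
    return correct / low.shape[0]


def fit(
    dataset,
    weights: LossWeights | None = None,
    config: TrainConfig | None = None,
    init_seed: int | None = None,
    checkpoint_dir=None,
    max_steps_per_epoch: int | None = None,
    track_accuracy: bool = False,
) -> FitResult:
    """Train on a dataset (dict of low/high/labels arrays or a list of
    TrainingExample), shuffling with the config seed each epoch."""
    weights = weights or LossWeights()
    config = config or TrainConfig()
    low, high, labels = _batch_arrays(dataset)
    n = low.shape[0]
    if n == 0:
        raise ValueError("empty dataset")

    seed = config.seed if init_seed is None else init_seed
    g_params = models.init_generator(seed)
    c_params = models.init_caller(seed + 1)
    d_params = models.init_discriminator(seed + 2)
    g_opt = Adam(config.learning_rate)
    d_opt = Adam(config.learning_rate)

    result = FitResult(g_params, c_params, d_params)
    aug_rng = onp.random.default_rng(config.seed + 991)
    for epoch in range(config.epochs):
        order = onp.random.default_rng(config.seed + epoch).permutation(n)
        records = []
        steps = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            b_low, b_high, b_labels = low[idx], high[idx], labels[idx]
            if config.augment:
                b_low, b_high, b_labels = augment_batch(b_low, b_high, b_labels, aug_rng)
            batch = {"low": b_low, "high": b_high, "labels": b_labels}
            g_params, c_params, d_params, rec = train_step(
                batch, g_params, c_params, d_params, weights, g_opt, d_opt, config
            )
            records.append(rec)
            steps += 1
            if max_steps_per_epoch is not None and steps >= max_steps_per_epoch:
                break
        mean_rec = LossRecord(
            **{
                k: float(onp.mean([r.as_dict()[k] for r in records]))
                for k in records[0].as_dict()
            }
        )
        result.history.append(mean_rec)
        if track_accuracy:
            result.zygosity_accuracy.append(
                zygosity_accuracy(c_params, g_params, low, labels, config.caller_only)
            )
        if checkpoint_dir is not None:
            meta = {"epoch": epoch, "seed": seed}
            for name, p in (("g", g_params), ("c", c_params), ("d", d_params)):
                models.save_params(f"{checkpoint_dir}/{name}_epoch{epoch}.npz", p, meta)
    result.g_params, result.c_params, result.d_params = g_params, c_params, d_params
    return result
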