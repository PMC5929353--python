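"""Convolutional Hit/Maybe/Miss classifier in pure NumPy.

Four (configurable) stages of convolution (kernel 3, stride 2, zero
padding) -> batch normalization -> ReLU -> 2x2 max pooling feed a flattened
feature vector into one fully connected layer and a SoftMax over the three
classes.  Edge rounding is ceil for the strided convolution and floor for
pooling, the unique simple convention under which the default 720-pixel
input yields the 8x45x45 stage-2 stack and a 288-long feature vector.

Both the forward pass and reverse-mode gradients (back-propagation) are
implemented here so the package has no deep-learning framework dependency;
training is plain mini-batch SGD on cross-entropy with class-balanced
batches and an exponentially decaying learning rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from braggscreen.io_formats import AnnotationTable, Label

__all__ = [
    "CNNArchitecture",
    "NetworkWeights",
    "TrainConfig",
    "shape_chain",
    "init_weights",
    "forward",
    "loss_and_grads",
    "decide_label",
    "softmax",
    "cross_entropy_loss",
    "make_balanced_batches",
    "lr_schedule",
    "sgd_step",
    "train",
    "predict",
    "save_weights",
    "load_weights",
]

BN_EPS = 1e-5
BN_MOMENTUM = 0.1
PROB_FLOOR = 1e-12
WEIGHTS_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CNNArchitecture:
    """Network hyper-shape.  Defaults reproduce the 288-feature extractor."""

    input_size: int = 720
    kernel_size: int = 3
    stride: int = 2
    pool_size: int = 2
    channels_per_stage: tuple[int, ...] = (4, 8, 16, 32)
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be odd and positive")
        if self.stride < 1 or self.pool_size < 1:
            raise ValueError("stride and pool_size must be positive")
        if not self.channels_per_stage:
            raise ValueError("need at least one stage")

    @property
    def n_features(self) -> int:
        channels, edge = shape_chain(self)[-1]
        return channels * edge * edge

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_size": self.input_size,
                "kernel_size": self.kernel_size,
                "stride": self.stride,
                "pool_size": self.pool_size,
                "channels_per_stage": list(self.channels_per_stage),
                "n_classes": self.n_classes,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CNNArchitecture":
        d = json.loads(text)
        d["channels_per_stage"] = tuple(d["channels_per_stage"])
        return cls(**d)


def shape_chain(arch: CNNArchitecture) -> list[tuple[int, int]]:
    """(channels, edge) after each stage; conv edge = ceil(n/s), pool = floor."""
    edge = arch.input_size
    chain: list[tuple[int, int]] = []
    for i, channels in enumerate(arch.channels_per_stage):
        conv_edge = -(-edge // arch.stride)  # ceil
        pool_edge = conv_edge // arch.pool_size
        if pool_edge < 1:
            raise ValueError(
                f"stage {i + 1}: edge collapsed to {pool_edge} "
                f"(input_size {arch.input_size} too small for "
                f"{len(arch.channels_per_stage)} stages)"
            )
        chain.append((channels, pool_edge))
        edge = pool_edge
    return chain


@dataclass
class NetworkWeights:
    """Learnable parameters plus batch-norm running statistics."""

    conv: list[np.ndarray]  # per stage: (C_out, C_in, k, k)
    gamma: list[np.ndarray]  # BN scale, (C_out,)
    beta: list[np.ndarray]  # BN shift, (C_out,)
    run_mean: list[np.ndarray]
    run_var: list[np.ndarray]
    fc_w: np.ndarray  # (n_classes, n_features)
    fc_b: np.ndarray  # (n_classes,)

    def learnables(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i in range(len(self.conv)):
            out[f"conv{i}"] = self.conv[i]
            out[f"gamma{i}"] = self.gamma[i]
            out[f"beta{i}"] = self.beta[i]
        out["fc_w"] = self.fc_w
        out["fc_b"] = self.fc_b
        return out

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            conv=[a.copy() for a in self.conv],
            gamma=[a.copy() for a in self.gamma],
            beta=[a.copy() for a in self.beta],
            run_mean=[a.copy() for a in self.run_mean],
            run_var=[a.copy() for a in self.run_var],
            fc_w=self.fc_w.copy(),
            fc_b=self.fc_b.copy(),
        )


def init_weights(arch: CNNArchitecture, rng: np.random.Generator) -> NetworkWeights:
    """Variance-scaled symmetric random init (He fan-in scaling)."""
    shape_chain(arch)  # validates the architecture
    k = arch.kernel_size
    conv, gamma, beta, rmean, rvar = [], [], [], [], []
    c_in = 1
    for c_out in arch.channels_per_stage:
        std = np.sqrt(2.0 / (c_in * k * k))
        conv.append(rng.normal(0.0, std, (c_out, c_in, k, k)))
        gamma.append(np.ones(c_out))
        beta.append(np.zeros(c_out))
        rmean.append(np.zeros(c_out))
        rvar.append(np.ones(c_out))
        c_in = c_out
    n_f = arch.n_features
    fc_w = rng.normal(0.0, np.sqrt(1.0 / n_f), (arch.n_classes, n_f))
    fc_b = np.zeros(arch.n_classes)
    return NetworkWeights(conv, gamma, beta, rmean, rvar, fc_w, fc_b)


# ---------------------------------------------------------------------------
# Layer primitives (forward + backward)


def _im2col(x: np.ndarray, k: int, s: int) -> tuple[np.ndarray, tuple]:
    """(N, C, H, W) -> (N, Ho*Wo, C*k*k) patches for a zero-padded strided conv."""
    n, c, h, w = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    windows = windows[:, :, ::s, ::s, :, :]  # (N, C, Ho, Wo, k, k)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, ho, wo, pad)


def _col_index(meta: tuple, k: int, s: int) -> np.ndarray:
    """Flat indices (Ho*Wo, C*k*k) into the padded (C, Hp, Wp) image."""
    n, c, h, w, ho, wo, pad = meta
    hp, wp = h + 2 * pad, w + 2 * pad
    r0 = (np.arange(ho) * s)[:, None, None, None, None]
    c0 = (np.arange(wo) * s)[None, :, None, None, None]
    ch = np.arange(c)[None, None, :, None, None]
    kr = np.arange(k)[None, None, None, :, None]
    kc = np.arange(k)[None, None, None, None, :]
    idx = (ch * hp + r0 + kr) * wp + (c0 + kc)
    return idx.reshape(ho * wo, c * k * k)


def _col2im(dcols: np.ndarray, meta: tuple, k: int, s: int) -> np.ndarray:
    """Scatter-add column gradients back to image space."""
    n, c, h, w, ho, wo, pad = meta
    hp, wp = h + 2 * pad, w + 2 * pad
    idx = _col_index(meta, k, s)
    per_image = c * hp * wp
    offsets = (np.arange(n) * per_image)[:, None, None]
    flat_idx = (idx[None, :, :] + offsets).ravel()
    acc = np.bincount(flat_idx, weights=dcols.ravel(), minlength=n * per_image)
    dxp = acc.reshape(n, c, hp, wp)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def _conv_forward(x, kernels, stride):
    c_out = kernels.shape[0]
    k = kernels.shape[-1]
    cols, meta = _im2col(x, k, stride)
    wmat = kernels.reshape(c_out, -1)
    out = cols @ wmat.T  # (N, Ho*Wo, C_out)
    n, _, _, _, ho, wo, _ = meta
    out = out.transpose(0, 2, 1).reshape(n, c_out, ho, wo)
    return out, (cols, meta, kernels.shape)


def _bn_forward(x, gamma, beta, run_mean, run_var, mode):
    axes = (0, 2, 3)
    if mode == "train":
        mu = x.mean(axis=axes)
        var = x.var(axis=axes)
        run_mean *= 1.0 - BN_MOMENTUM
        run_mean += BN_MOMENTUM * mu
        run_var *= 1.0 - BN_MOMENTUM
        run_var += BN_MOMENTUM * var
    else:
        mu, var = run_mean, run_var
    ivar = 1.0 / np.sqrt(var + BN_EPS)
    xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, ivar, gamma, mode)


def _bn_backward(dout, cache):
    xhat, ivar, gamma, mode = cache
    dgamma = np.sum(dout * xhat, axis=(0, 2, 3))
    dbeta = np.sum(dout, axis=(0, 2, 3))
    g = gamma[None, :, None, None]
    iv = ivar[None, :, None, None]
    if mode == "train":
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dxhat = dout * g
        dx = (
            iv
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            )
        )
    else:
        dx = dout * g * iv
    return dx, dgamma, dbeta


def _pool_forward(x, p):
    n, c, h, w = x.shape
    ho, wo = h // p, w // p
    xc = x[:, :, : ho * p, : wo * p]
    patches = xc.reshape(n, c, ho, p, wo, p).transpose(0, 1, 2, 4, 3, 5)
    patches = patches.reshape(n, c, ho, wo, p * p)
    arg = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape, p)


def _pool_backward(dout, cache):
    arg, xshape, p = cache
    n, c, h, w = xshape
    ho, wo = h // p, w // p
    dpatches = np.zeros((n, c, ho, wo, p * p))
    np.put_along_axis(dpatches, arg[..., None], dout[..., None], axis=-1)
    dpatches = dpatches.reshape(n, c, ho, wo, p, p).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(xshape)
    dx[:, :, : ho * p, : wo * p] = dpatches.reshape(n, c, ho * p, wo * p)
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise SoftMax, shift-invariant in the logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Full network


def _forward_impl(weights, arch, x, mode):
    """Shared forward pass; returns activations plus per-layer caches."""
    if x.ndim == 2:
        x = x[None]
    n = x.shape[0]
    if x.shape[-1] != arch.input_size or x.shape[-2] != arch.input_size:
        raise ValueError(
            f"expected {arch.input_size}x{arch.input_size} images, got {x.shape}"
        )
    h = x.reshape(n, 1, arch.input_size, arch.input_size).astype(np.float64)
    caches = []
    for i in range(len(arch.channels_per_stage)):
        z, conv_cache = _conv_forward(h, weights.conv[i], arch.stride)
        b, bn_cache = _bn_forward(
            z, weights.gamma[i], weights.beta[i],
            weights.run_mean[i], weights.run_var[i], mode,
        )
        r = np.maximum(b, 0.0)
        h, pool_cache = _pool_forward(r, arch.pool_size)
        caches.append((conv_cache, bn_cache, b, pool_cache))
    feats = h.reshape(n, -1)
    logits = feats @ weights.fc_w.T + weights.fc_b
    probs = softmax(logits)
    return feats, logits, probs, caches, h.shape


def forward(
    weights: NetworkWeights,
    arch: CNNArchitecture,
    image_batch: np.ndarray,
    mode: str = "eval",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the network on an (N, H, W) batch.

    Returns (feature vectors, logits, classification vectors).  Batch-norm
    uses batch statistics in ``train`` mode (and updates the running
    statistics) and the stored running statistics in ``eval`` mode, which is
    fully deterministic.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    feats, logits, probs, _, _ = _forward_impl(weights, arch, image_batch, mode)
    return feats, logits, probs


def cross_entropy_loss(probs: np.ndarray, targets: Sequence[int]) -> float:
    """Mean negative log probability of the target class."""
    probs = np.atleast_2d(probs)
    targets = np.asarray(targets, dtype=int)
    if probs.shape[0] == 0:
        raise ValueError("empty batch")
    p_t = probs[np.arange(len(targets)), targets]
    return float(-np.mean(np.log(np.maximum(p_t, PROB_FLOOR))))


def loss_and_grads(
    weights: NetworkWeights,
    arch: CNNArchitecture,
    image_batch: np.ndarray,
    targets: Sequence[int],
    mode: str = "train",
    need_input_grad: bool = False,
):
    """Cross-entropy loss, parameter gradients and optionally d(loss)/d(input).

    Gradients are the mean over the batch of per-example loss gradients,
    obtained by reverse-mode differentiation through every layer.
    """
    targets = np.asarray(targets, dtype=int)
    feats, logits, probs, caches, map_shape = _forward_impl(
        weights, arch, image_batch, mode
    )
    n = probs.shape[0]
    loss = cross_entropy_loss(probs, targets)

    onehot = np.zeros_like(probs)
    onehot[np.arange(n), targets] = 1.0
    dlogits = (probs - onehot) / n

    grads: dict[str, np.ndarray] = {
        "fc_w": dlogits.T @ feats,
        "fc_b": dlogits.sum(axis=0),
    }
    dh = (dlogits @ weights.fc_w).reshape(map_shape)
    for i in reversed(range(len(arch.channels_per_stage))):
        conv_cache, bn_cache, pre_relu, pool_cache = caches[i]
        dr = _pool_backward(dh, pool_cache)
        db = dr * (pre_relu > 0.0)
        dz, dgamma, dbeta = _bn_backward(db, bn_cache)
        cols, meta, kshape = conv_cache
        nb, _, _, _, ho, wo, _ = meta
        c_out = kshape[0]
        dmat = dz.reshape(nb, c_out, ho * wo).transpose(0, 2, 1)
        grads[f"conv{i}"] = np.einsum("npo,npk->ok", dmat, cols).reshape(kshape)
        grads[f"gamma{i}"] = dgamma
        grads[f"beta{i}"] = dbeta
        if i > 0 or need_input_grad:
            dcols = dmat @ weights.conv[i].reshape(c_out, -1)
            dh = _col2im(dcols, meta, arch.kernel_size, arch.stride)
    for g in grads.values():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
    dx = dh.reshape(-1, arch.input_size, arch.input_size) if need_input_grad else None
    return loss, grads, probs, dx


# ---------------------------------------------------------------------------
# Decision rule


def decide_label(y: Sequence[float]) -> tuple[Label, Label]:
    """(binary, three-class) hard labels from a classification vector.

    Binary: Hit-like iff p_hit + p_maybe >= p_miss (ties retain the frame).
    Three-class: argmax with ties broken Hit > Maybe > Miss.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"expected a length-3 vector, got shape {y.shape}")
    binary = Label.HIT if y[0] + y[1] >= y[2] else Label.MISS
    three = Label(int(np.argmax(y)))  # argmax returns the first max: Hit>Maybe>Miss
    return binary, three


# ---------------------------------------------------------------------------
# Training utilities


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the published protocol)."""

    batch_size: int = 64
    batches_per_epoch: int = 100
    epochs: int = 120
    lr_start: float = 0.1
    lr_end: float = 0.0001
    seed: int = 0
    balanced_batches: bool = True
    momentum: float = 0.0
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.batches_per_epoch, self.epochs) < 1:
            raise ValueError("batch_size, batches_per_epoch, epochs must be >= 1")
        if self.lr_start < 0 or self.lr_end < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.lr_start > 0 and self.lr_end > self.lr_start:
            raise ValueError("lr_end must not exceed lr_start")


def lr_schedule(config: TrainConfig, epoch: int) -> float:
    """Exponential decay from lr_start (epoch 0) to lr_end (last epoch)."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if config.epochs == 1 or config.lr_start == 0:
        return config.lr_start
    frac = epoch / (config.epochs - 1)
    return config.lr_start * (config.lr_end / config.lr_start) ** frac


def make_balanced_batches(
    table: AnnotationTable,
    batch_size: int,
    rng: np.random.Generator,
    n_batches: int = 1,
) -> list[list[str]]:
    """Frame-id batches with per-class counts differing by at most one.

    Classes with too few frames are resampled with replacement.  The
    remainder (batch_size mod n_classes) is rotated across classes so no
    class is systematically favored.
    """
    by_class: dict[Label, list[str]] = {lab: [] for lab in Label}
    for fid, lab in zip(table.df["frame_id"], table.df["label"]):
        by_class[Label(lab)].append(fid)
    for lab in Label:
        if not by_class[lab]:
            raise ValueError(f"class {lab} absent from the table (balanced mode)")
    classes = list(Label)
    base, rem = divmod(batch_size, len(classes))
    batches: list[list[str]] = []
    for j in range(n_batches):
        counts = {lab: base for lab in classes}
        for i in range(rem):
            counts[classes[(j + i) % len(classes)]] += 1
        batch: list[str] = []
        for lab in classes:
            pool = by_class[lab]
            k = counts[lab]
            pick = rng.choice(len(pool), size=k, replace=len(pool) < k)
            batch.extend(pool[i] for i in pick)
        perm = rng.permutation(len(batch))
        batches.append([batch[i] for i in perm])
    return batches


def _sample_batches(
    table: AnnotationTable, batch_size: int, rng: np.random.Generator, n_batches: int
) -> list[list[str]]:
    ids = table.frame_ids
    return [
        [ids[i] for i in rng.choice(len(ids), size=min(batch_size, len(ids)), replace=False)]
        for _ in range(n_batches)
    ]


def sgd_step(
    weights: NetworkWeights,
    grads: dict[str, np.ndarray],
    lr: float,
    velocity: dict[str, np.ndarray] | None = None,
    momentum: float = 0.0,
    weight_decay: float = 0.0,
) -> NetworkWeights:
    """In-place vanilla SGD update ``w <- w - lr * grad`` (momentum optional)."""
    params = weights.learnables()
    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {name}")
        p = params[name]
        if weight_decay:
            g = g + weight_decay * p
        if momentum and velocity is not None:
            v = velocity.setdefault(name, np.zeros_like(p))
            v *= momentum
            v += g
            g = v
        p -= lr * g
    return weights


def train(
    images: np.ndarray,
    frame_ids: Sequence[str],
    table: AnnotationTable,
    arch: CNNArchitecture,
    config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_frame_ids: Sequence[str] | None = None,
    val_table: AnnotationTable | None = None,
) -> tuple[NetworkWeights, pd.DataFrame]:
    """Train the classifier; returns weights and a per-epoch history table.

    *images* is the (N, edge, edge) array of preprocessed frames aligned
    with *frame_ids*; labels come from *table*.  The optional validation set
    is evaluated (eval mode) after each epoch and never used for gradient
    updates.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    weights = init_weights(arch, rng)
    index = {fid: i for i, fid in enumerate(frame_ids)}
    label_of = {
        fid: int(Label(lab))
        for fid, lab in zip(table.df["frame_id"], table.df["label"])
    }
    missing = [fid for fid in label_of if fid not in index]
    if missing:
        raise ValueError(f"annotated frames missing from the stack: {missing[:5]}")
    velocity: dict[str, np.ndarray] = {}
    history = []
    for epoch in range(config.epochs):
        lr = lr_schedule(config, epoch)
        if config.balanced_batches:
            batches = make_balanced_batches(
                table, config.batch_size, rng, config.batches_per_epoch
            )
        else:
            batches = _sample_batches(
                table, config.batch_size, rng, config.batches_per_epoch
            )
        losses, correct, seen = [], 0, 0
        for batch_ids in batches:
            idx = [index[fid] for fid in batch_ids]
            targets = [label_of[fid] for fid in batch_ids]
            x = images[idx]
            loss, grads, probs, _ = loss_and_grads(
                weights, arch, x, targets, mode="train"
            )
            if lr > 0:
                sgd_step(
                    weights, grads, lr, velocity,
                    momentum=config.momentum, weight_decay=config.weight_decay,
                )
            losses.append(loss)
            correct += int(np.sum(np.argmax(probs, axis=1) == np.asarray(targets)))
            seen += len(targets)
        row = {
            "epoch": epoch,
            "lr": lr,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / seen,
        }
        if val_images is not None and val_table is not None:
            val_pred = predict(weights, arch, val_images, val_frame_ids)
            v_targets = np.array(
                [int(val_table.label_of(fid)) for fid in val_pred["frame_id"]]
            )
            v_probs = val_pred[["p_hit", "p_maybe", "p_miss"]].to_numpy()
            row["val_loss"] = cross_entropy_loss(v_probs, v_targets)
            row["val_acc"] = float(
                np.mean(np.argmax(v_probs, axis=1) == v_targets)
            )
        history.append(row)
    return weights, pd.DataFrame(history)


def predict(
    weights: NetworkWeights,
    arch: CNNArchitecture,
    images: np.ndarray,
    frame_ids: Sequence[str] | None = None,
    batch_size: int = 64,
) -> pd.DataFrame:
    """Eval-mode classification of a stack of preprocessed images.

    Returns a table with columns frame_id, p_hit, p_maybe, p_miss, binary,
    three_class.  Results are independent of batch order.
    """
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    n = images.shape[0]
    if frame_ids is None:
        frame_ids = [f"f{i:05d}" for i in range(n)]
    rows = []
    for start in range(0, n, batch_size):
        x = images[start: start + batch_size]
        _, _, probs = forward(weights, arch, x, mode="eval")
        for j, p in enumerate(probs):
            binary, three = decide_label(p)
            rows.append(
                {
                    "frame_id": frame_ids[start + j],
                    "p_hit": p[0],
                    "p_maybe": p[1],
                    "p_miss": p[2],
                    "binary": str(binary) if binary == Label.MISS else "HitLike",
                    "three_class": str(three),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weight container


def save_weights(path, weights: NetworkWeights, arch: CNNArchitecture) -> None:
    """Versioned binary container with the architecture record embedded."""
    payload = {
        "format_version": np.array(WEIGHTS_FORMAT_VERSION),
        "arch_json": np.array(arch.to_json()),
        "fc_w": weights.fc_w,
        "fc_b": weights.fc_b,
        "n_stages": np.array(len(weights.conv)),
    }
    for i in range(len(weights.conv)):
        payload[f"conv{i}"] = weights.conv[i]
        payload[f"gamma{i}"] = weights.gamma[i]
        payload[f"beta{i}"] = weights.beta[i]
        payload[f"run_mean{i}"] = weights.run_mean[i]
        payload[f"run_var{i}"] = weights.run_var[i]
    np.savez(path, **payload)


def load_weights(path) -> tuple[NetworkWeights, CNNArchitecture]:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["format_version"])
        if version != WEIGHTS_FORMAT_VERSION:
            raise ValueError(f"unsupported weights format version {version}")
        arch = CNNArchitecture.from_json(str(z["arch_json"]))
        n_stages = int(z["n_stages"])
        weights = NetworkWeights(
            conv=[z[f"conv{i}"] for i in range(n_stages)],
            gamma=[z[f"gamma{i}"] for i in range(n_stages)],
            beta=[z[f"beta{i}"] for i in range(n_stages)],
            run_mean=[z[f"run_mean{i}"] for i in range(n_stages)],
            run_var=[z[f"run_var{i}"] for i in range(n_stages)],
            fc_w=z["fc_w"],
            fc_b=z["fc_b"],
        )
    return weights, arch
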