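"""Naive double-loop reference implementations used as independent oracles.

These deliberately avoid the vectorized/stride-trick code paths of the
package so that agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np


def conv2d_naive(x: np.ndarray, kernels: np.ndarray, stride: int) -> np.ndarray:
    """Zero-padded strided convolution; x (C, H, W), kernels (Co, C, k, k)."""
    c_out, c_in, k, _ = kernels.shape
    _, h, w = x.shape
    pad = k // 2
    xp = np.zeros((c_in, h + 2 * pad, w + 2 * pad))
    xp[:, pad: pad + h, pad: pad + w] = x
    ho = -(-h // stride)
    wo = -(-w // stride)
    out = np.zeros((c_out, ho, wo))
    for o in range(c_out):
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for c in range(c_in):
                    for a in range(k):
                        for b in range(k):
                            acc += (
                                kernels[o, c, a, b]
                                * xp[c, i * stride + a, j * stride + b]
                            )
                out[o, i, j] = acc
    return out


def maxpool_naive(x: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping max pooling with floor edge handling; x (C, H, W)."""
    c, h, w = x.shape
    ho, wo = h // p, w // p
    out = np.zeros((c, ho, wo))
    for ch in range(c):
        for i in range(ho):
            for j in range(wo):
                out[ch, i, j] = x[ch, i * p: (i + 1) * p, j * p: (j + 1) * p].max()
    return out


def bin_naive(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-sum binning with high-end trimming."""
    h, w = image.shape
    ho, wo = h // factor, w // factor
    out = np.zeros((ho, wo))
    for i in range(ho):
        for j in range(wo):
            acc = 0.0
            for a in range(factor):
                for b in range(factor):
                    acc += image[i * factor + a, j * factor + b]
            out[i, j] = acc
    return out


def global_norm_naive(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = [image[i, j] for i in range(image.shape[0])
            for j in range(image.shape[1]) if mask[i, j]]
    mu = sum(vals) / len(vals)
    var = sum((v - mu) ** 2 for v in vals) / len(vals)
    sigma = np.sqrt(var)
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            if mask[i, j]:
                out[i, j] = (image[i, j] - mu) / sigma
    return out


def lcn_naive(
    image: np.ndarray, mask: np.ndarray, window: int, epsilon: float
) -> np.ndarray:
    """Local contrast normalization with symmetric (edge-repeating)
    reflection padding of both image and mask."""
    pad = window // 2
    ip = np.pad(image.astype(float), pad, mode="symmetric")
    mp = np.pad(mask.astype(bool), pad, mode="symmetric")
    h, w = image.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            vals = []
            for a in range(window):
                for b in range(window):
                    if mp[i + a, j + b]:
                        vals.append(ip[i + a, j + b])
            if not vals:
                continue
            n = len(vals)
            mean = sum(vals) / n
            var = sum(v * v for v in vals) / n - mean * mean
            sigma = np.sqrt(max(var, 0.0))
            out[i, j] = (image[i, j] - mean) / max(sigma, epsilon)
    return out


def success_rate_naive(truth_labels, pred_labels) -> float:
    """Binary (Hit-or-Maybe vs Miss) agreement fraction; labels are ints
    with Miss == 2."""
    ok = 0
    for t, p in zip(truth_labels, pred_labels):
        if (int(t) == 2) == (int(p) == 2):
            ok += 1
    return ok / len(truth_labels)
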