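"""Minimal NumPy neural-network primitives shared by the classifier and the
GAN discriminator: a multi-width convolutional text network with max pooling
and a softmax head, plus an Adam optimizer.

The convolution follows the "full-width kernel" formulation: a kernel of
height m spans m consecutive embedding rows and the whole embedding width,
producing a 1-D feature map of length rows - m + 1 that is max-pooled to a
single scalar per kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Adam:
    """Adam over a dict of parameter arrays (updated in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TextCnnParams:
    embedding: np.ndarray  # (V, N); row per vocabulary index
    kernels: dict[int, np.ndarray]  # height -> (m*N, k)
    biases: dict[int, np.ndarray]  # height -> (k,)
    fc_w: np.ndarray  # (total_k, C)
    fc_b: np.ndarray  # (C,)

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {"embedding": self.embedding, "fc_w": self.fc_w, "fc_b": self.fc_b}
        for m in self.kernels:
            out[f"K{m}"] = self.kernels[m]
            out[f"b{m}"] = self.biases[m]
        return out


def init_text_cnn(
    vocab_size: int,
    embed_dim: int,
    kernel_heights: tuple[int, ...],
    kernels_per_height: int,
    n_classes: int,
    rng: np.random.Generator,
    embedding: np.ndarray | None = None,
) -> TextCnnParams:
    if embedding is None:
        embedding = rng.uniform(-0.05, 0.05, size=(vocab_size, embed_dim))
    else:
        embedding = np.array(embedding, dtype=float)
    kernels, biases = {}, {}
    for m in kernel_heights:
        fan_in = m * embed_dim
        kernels[m] = rng.normal(scale=1.0 / np.sqrt(fan_in), size=(fan_in, kernels_per_height))
        biases[m] = np.zeros(kernels_per_height)
    total = kernels_per_height * len(kernel_heights)
    fc_w = rng.normal(scale=1.0 / np.sqrt(total), size=(total, n_classes))
    fc_b = np.zeros(n_classes)
    return TextCnnParams(embedding, kernels, biases, fc_w, fc_b)


def _windows(X: np.ndarray, m: int) -> np.ndarray:
    """(B, L, N) -> (B, L-m+1, m*N) stride-1 row windows."""
    B, L, N = X.shape
    view = np.lib.stride_tricks.sliding_window_view(X, m, axis=1)  # (B, L-m+1, N, m)
    return view.transpose(0, 1, 3, 2).reshape(B, L - m + 1, m * N)


@dataclass
class _ForwardCache:
    X: np.ndarray
    win: dict[int, np.ndarray]
    pre: dict[int, np.ndarray]
    argmax: dict[int, np.ndarray]
    pooled: np.ndarray
    dropout_mask: np.ndarray | None
    probs: np.ndarray


def text_cnn_forward(
    params: TextCnnParams,
    X: np.ndarray,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> _ForwardCache:
    """Forward pass on a batch of embedding matrices X (B, L, N).

    Per kernel: ReLU(conv) -> max pool to one scalar; pooled scalars are
    concatenated, (inverted) dropout is applied when training, then a fully
    connected softmax head produces class probabilities.
    """
    B = X.shape[0]
    heights = sorted(params.kernels)
    win, pre, argmax, pooled_parts = {}, {}, {}, []
    for m in heights:
        w = _windows(X, m)
        z = relu(w @ params.kernels[m] + params.biases[m])  # (B, L', k)
        am = z.argmax(axis=1)  # (B, k)
        win[m], pre[m], argmax[m] = w, z, am
        pooled_parts.append(np.take_along_axis(z, am[:, None, :], axis=1)[:, 0, :])
    pooled = np.concatenate(pooled_parts, axis=1)  # (B, total_k)
    mask = None
    feat = pooled
    if dropout > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        mask = (rng.random(pooled.shape) >= dropout) / (1.0 - dropout)
        feat = pooled * mask
    probs = softmax(feat @ params.fc_w + params.fc_b)
    return _ForwardCache(X, win, pre, argmax, pooled, mask, probs)


def text_cnn_backward(
    params: TextCnnParams,
    cache: _ForwardCache,
    dlogits: np.ndarray,
    token_ids: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Backward pass given d(loss)/d(logits); returns grads keyed like
    ``TextCnnParams.as_dict``.  When ``token_ids`` (B, L) is given, the
    input gradient is scattered into the embedding table."""
    B = dlogits.shape[0]
    heights = sorted(params.kernels)
    k_per = params.biases[heights[0]].shape[0]

    feat = cache.pooled if cache.dropout_mask is None else cache.pooled * cache.dropout_mask
    grads: dict[str, np.ndarray] = {
        "fc_w": feat.T @ dlogits,
        "fc_b": dlogits.sum(axis=0),
    }
    dfeat = dlogits @ params.fc_w.T
    if cache.dropout_mask is not None:
        dfeat = dfeat * cache.dropout_mask

    dX = np.zeros_like(cache.X)
    for hi, m in enumerate(heights):
        dpool = dfeat[:, hi * k_per : (hi + 1) * k_per]  # (B, k)
        z = cache.pre[m]
        dz = np.zeros_like(z)
        np.put_along_axis(dz, cache.argmax[m][:, None, :], dpool[:, None, :], axis=1)
        dz *= z > 0  # ReLU mask (and max of an all-zero map has zero pre-grad)
        w = cache.win[m]
        grads[f"K{m}"] = np.einsum("blf,blk->fk", w, dz)
        grads[f"b{m}"] = dz.sum(axis=(0, 1))
        dwin = dz @ params.kernels[m].T  # (B, L', m*N)
        N = cache.X.shape[2]
        Lp = dwin.shape[1]
        dwin = dwin.reshape(B, Lp, m, N)
        for r in range(m):
            dX[:, r : r + Lp, :] += dwin[:, :, r, :]
    if token_ids is not None:
        demb = np.zeros_like(params.embedding)
        np.add.at(demb, token_ids.reshape(-1), dX.reshape(-1, dX.shape[2]))
        grads["embedding"] = demb
    else:
        grads["_dX"] = dX
    return grads


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and d(loss)/d(logits) for softmax outputs."""
    B = probs.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(B), labels] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B
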