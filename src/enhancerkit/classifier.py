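"""Multi-width convolutional classifier of embedded DNA word sequences and
the two-layer prediction scheme (enhancer vs non-enhancer, then strong vs
weak for called enhancers).

Default architecture: kernel heights {2, 3, 4} x embedding width, 128
kernels per height, one max-pooled scalar per kernel concatenated into a
128 x 3 = 384 feature vector, dropout, then a fully connected softmax over
two classes.  The embedding layer is initialized from pretrained skip-gram
vectors and fine-tuned unless frozen.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from enhancerkit.embed import EmbeddingMatrix, SkipGramModel
from enhancerkit.nn import (
    Adam,
    TextCnnParams,
    cross_entropy_grad,
    init_text_cnn,
    relu,
    text_cnn_backward,
    text_cnn_forward,
)


@dataclass
class CnnConfig:
    kernel_heights: tuple[int, ...] = (2, 3, 4)
    kernels_per_height: int = 128
    embed_dim: int = 300
    n_classes: int = 2
    dropout: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0
    embedding_trainable: bool = True

    @property
    def fc_width(self) -> int:
        return self.kernels_per_height * len(self.kernel_heights)


def conv_forward(x: np.ndarray | EmbeddingMatrix, kernel: np.ndarray, bias: float, height: int) -> np.ndarray:
    """One kernel's feature map: z_i = ReLU(sum(W ⊙ x[i:i+m]) + b), stride 1.

    ``kernel`` is (m, N); output length = rows - m + 1."""
    if isinstance(x, EmbeddingMatrix):
        x = x.rows
    rows, width = x.shape
    m, kw = kernel.shape
    if m != height:
        raise ValueError("kernel height mismatch")
    if kw != width:
        raise ValueError("kernel width must equal the embedding width")
    if rows < m:
        raise ValueError(f"input has {rows} rows < kernel height {m}")
    out = np.empty(rows - m + 1)
    for i in range(rows - m + 1):
        out[i] = np.sum(kernel * x[i : i + m]) + bias
    return relu(out)


def max_pool(feature_map: np.ndarray) -> float:
    """The maximum element of a non-empty feature map."""
    feature_map = np.asarray(feature_map)
    if feature_map.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(feature_map.max())


@dataclass
class CnnClassifier:
    params: TextCnnParams
    config: CnnConfig
    max_words: int
    train_log: list = field(default_factory=list)

    def _check(self, X: np.ndarray) -> None:
        if X.ndim != 3 or X.shape[1] != self.max_words or X.shape[2] != self.config.embed_dim:
            raise ValueError(
                f"expected input (B, {self.max_words}, {self.config.embed_dim}),"
                f" got {X.shape}"
            )

    def pooled_features(self, X: np.ndarray) -> np.ndarray:
        """The concatenated max-pooled feature vectors (B, fc_width)."""
        self._check(X)
        return text_cnn_forward(self.params, X).pooled

    def predict_proba(self, X: np.ndarray | list[EmbeddingMatrix]) -> np.ndarray:
        X = _stack(X)
        self._check(X)
        return text_cnn_forward(self.params, X).probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        # ties at exactly 0.5 resolve to the positive class
        return (probs[:, 1] >= 0.5).astype(int)

    def save(self, path: Path | str) -> None:
        arrays = dict(self.params.as_dict())
        meta = json.dumps(
            {"config": asdict(self.config), "max_words": self.max_words}
        )
        with open(path, "wb") as fh:
            np.savez(fh, meta=meta, **arrays)

    @classmethod
    def load(cls, path: Path | str) -> "CnnClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg_raw = meta["config"]
            cfg_raw["kernel_heights"] = tuple(cfg_raw["kernel_heights"])
            config = CnnConfig(**cfg_raw)
            kernels = {m: data[f"K{m}"].copy() for m in config.kernel_heights}
            biases = {m: data[f"b{m}"].copy() for m in config.kernel_heights}
            params = TextCnnParams(
                embedding=data["embedding"].copy(),
                kernels=kernels,
                biases=biases,
                fc_w=data["fc_w"].copy(),
                fc_b=data["fc_b"].copy(),
            )
            return cls(params=params, config=config, max_words=meta["max_words"])


def cnn_forward(x: np.ndarray | EmbeddingMatrix, model: CnnClassifier) -> np.ndarray:
    """Class probabilities for a single embedding matrix."""
    if isinstance(x, EmbeddingMatrix):
        x = x.rows
    return model.predict_proba(x[None, :, :])[0]


def _stack(X) -> np.ndarray:
    if isinstance(X, np.ndarray):
        return X
    return np.stack([m.rows if isinstance(m, EmbeddingMatrix) else m for m in X])


def train_classifier(
    train_set,
    config: CnnConfig | None = None,
    embedding_model: SkipGramModel | None = None,
    token_ids: np.ndarray | None = None,
) -> CnnClassifier:
    """Train the CNN on (EmbeddingMatrix, label) pairs by minimizing
    cross-entropy with Adam.

    With ``token_ids`` (B, L) and ``embedding_model`` given, the network owns
    an embedding table initialized from the skip-gram input vectors and
    fine-tunes it when ``config.embedding_trainable``; otherwise the supplied
    matrices are treated as fixed inputs.  Early stopping monitors a
    deterministic validation split.  Fully seed-deterministic.
    """
    config = config or CnnConfig()
    pairs = list(train_set)
    if not pairs:
        raise ValueError("empty training set")
    labels = np.array([int(lbl) for _, lbl in pairs])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    X = _stack([m for m, _ in pairs])
    B, L, N = X.shape
    if N != config.embed_dim:
        raise ValueError(f"embedding width {N} != config.embed_dim {config.embed_dim}")

    rng = np.random.default_rng(config.seed)
    use_embedding_table = token_ids is not None and embedding_model is not None
    if use_embedding_table:
        params = init_text_cnn(
            embedding_model.vocabulary.size,
            N,
            config.kernel_heights,
            config.kernels_per_height,
            config.n_classes,
            rng,
            embedding=embedding_model.W,
        )
    else:
        params = init_text_cnn(
            1, N, config.kernel_heights, config.kernels_per_height,
            config.n_classes, rng,
        )

    order = rng.permutation(B)
    n_val = int(round(config.validation_fraction * B))
    val_idx, trn_idx = order[:n_val], order[n_val:]
    if len(trn_idx) == 0 or len(np.unique(labels[trn_idx])) < 2:
        trn_idx, val_idx = order, order[:0]

    param_dict = params.as_dict()
    trainable = dict(param_dict)
    if not (use_embedding_table and config.embedding_trainable):
        trainable.pop("embedding", None)
    opt = Adam(trainable, lr=config.learning_rate)

    model = CnnClassifier(params=params, config=config, max_words=L)
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(config.epochs):
        perm = rng.permutation(trn_idx)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, len(perm), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            if use_embedding_table:
                xb = params.embedding[token_ids[idx]]
            else:
                xb = X[idx]
            cache = text_cnn_forward(params, xb, dropout=config.dropout, rng=rng)
            loss, dlogits = cross_entropy_grad(cache.probs, labels[idx])
            grads = text_cnn_backward(
                params,
                cache,
                dlogits,
                token_ids=token_ids[idx] if use_embedding_table else None,
            )
            grads.pop("_dX", None)
            opt.step({k: g for k, g in grads.items() if k in trainable})
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if len(val_idx):
            xv = params.embedding[token_ids[val_idx]] if use_embedding_table else X[val_idx]
            probs = text_cnn_forward(params, xv).probs
            vloss, _ = cross_entropy_grad(probs, labels[val_idx])
            entry["val_loss"] = vloss
            if vloss < best_val - 1e-6:
                best_val, since_best = vloss, 0
                best_state = {k: v.copy() for k, v in param_dict.items()}
            else:
                since_best += 1
        model.train_log.append(entry)
        if len(val_idx) and since_best >= config.patience:
            break
    if best_state is not None:
        for k, v in best_state.items():
            param_dict[k][...] = v
    return model


@dataclass
class TwoLayerPredictor:
    layer1: CnnClassifier  # enhancer vs non-enhancer
    layer2: CnnClassifier  # strong vs weak


@dataclass
class TwoLayerCall:
    sequence_id: str
    call: str  # non_enhancer | weak_enhancer | strong_enhancer
    p_enhancer: float
    p_strong: float | None  # None when layer 2 was not invoked


def predict_two_layer(
    matrices: list[EmbeddingMatrix], predictor: TwoLayerPredictor
) -> list[TwoLayerCall]:
    """Layer 1 gates at P(enhancer) >= 0.5; called enhancers go to layer 2,
    graded strong at P(strong) >= 0.5 (ties resolve to the positive class)."""
    X = _stack(matrices)
    p1 = predictor.layer1.predict_proba(X)[:, 1]
    out: list[TwoLayerCall] = []
    enhancer_idx = [i for i, p in enumerate(p1) if p >= 0.5]
    p2_map: dict[int, float] = {}
    if enhancer_idx:
        X2 = X[enhancer_idx]
        p2 = predictor.layer2.predict_proba(X2)[:, 1]
        p2_map = dict(zip(enhancer_idx, p2))
    for i, mat in enumerate(matrices):
        sid = mat.source_id if isinstance(mat, EmbeddingMatrix) else str(i)
        if i not in p2_map:
            out.append(TwoLayerCall(sid, "non_enhancer", float(p1[i]), None))
        else:
            p_strong = float(p2_map[i])
            call = "strong_enhancer" if p_strong >= 0.5 else "weak_enhancer"
            out.append(TwoLayerCall(sid, call, float(p1[i]), p_strong))
    return out


def write_predictions(calls: list[TwoLayerCall], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("id\tcall\tp_enhancer\tp_strong\n")
        for c in calls:
            p2 = "" if c.p_strong is None else f"{c.p_strong:.6f}"
            fh.write(f"{c.sequence_id}\t{c.call}\t{c.p_enhancer:.6f}\t{p2}\n")
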