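"""Skip-gram word embeddings with negative sampling, trained from segmented
DNA corpora, plus per-sequence embedding matrices for the CNN.

The model keeps an input-vector table ``W`` (V x N, row j = center vector of
word j) and a context-vector table ``U`` (N x V, column j = context vector
of word j).  Training maximizes, per (center w, context q) pair,

    log sigma(h . theta_q) + sum_t log sigma(-h . theta_t)

over ``m`` negative words t drawn from the unigram^0.75 noise distribution,
by stochastic gradient ascent with a linearly decayed learning rate.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from enhancerkit.tokenize import Vocabulary, WordSequence


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def log_sigmoid(x):
    # log sigma(x) = -softplus(-x), stable for both signs
    return np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))


@dataclass
class SgnsTrainConfig:
    window: int = 4  # context words per center, split across both sides
    negatives: int = 10
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    noise_power: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.negatives < 1:
            raise ValueError("negatives must be >= 1")
        if self.window < 2 or self.window % 2:
            raise ValueError("window must be an even count >= 2")


@dataclass
class SkipGramModel:
    W: np.ndarray  # (V, N) input vectors
    U: np.ndarray  # (N, V) context vectors
    vocabulary: Vocabulary
    config: SgnsTrainConfig | None = None
    train_log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        V = self.vocabulary.size
        if self.W.shape[0] != V or self.U.shape[1] != V:
            raise ValueError("W/U shapes inconsistent with vocabulary size")
        if self.W.shape[1] != self.U.shape[0]:
            raise ValueError("W and U embedding dimensions differ")
        if not (np.isfinite(self.W).all() and np.isfinite(self.U).all()):
            raise ValueError("model parameters must be finite")

    @property
    def dim(self) -> int:
        return self.W.shape[1]

    def hidden(self, word: str) -> np.ndarray:
        """h = xW: the input vector of the center word."""
        return self.W[self.vocabulary.index(word)]

    def save(self, path: Path | str) -> None:
        payload = {
            "vocabulary": json.dumps(self.vocabulary.word_to_index),
            "config": json.dumps(asdict(self.config) if self.config else None),
        }
        with open(path, "wb") as fh:
            np.savez(fh, W=self.W, U=self.U, meta=json.dumps(payload))

    @classmethod
    def load(cls, path: Path | str) -> "SkipGramModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            vocab = Vocabulary(word_to_index=json.loads(meta["vocabulary"]))
            cfg_raw = json.loads(meta["config"])
            cfg = SgnsTrainConfig(**cfg_raw) if cfg_raw else None
            return cls(W=data["W"].copy(), U=data["U"].copy(), vocabulary=vocab, config=cfg)


@dataclass
class EmbeddingMatrix:
    """A sequence's word vectors stacked vertically, zero-padded to max_words."""

    rows: np.ndarray  # (max_words, N)
    word_count: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.word_count > self.rows.shape[0]:
            raise ValueError("word_count exceeds matrix rows")


def softmax_probability(model: SkipGramModel, center_word: str, j: int | None = None):
    """Full-softmax output probabilities P_j = exp(h.U_j) / sum_k exp(h.U_k).

    Returns the full V-vector, or the single probability when ``j`` is given.
    Computed with max-subtraction for stability.
    """
    h = model.hidden(center_word)
    logits = h @ model.U
    logits = logits - logits.max()
    ex = np.exp(logits)
    probs = ex / ex.sum()
    if j is None:
        return probs
    if not 0 <= j < model.vocabulary.size:
        raise KeyError(f"word index {j} out of range")
    return float(probs[j])


def sgns_objective(model: SkipGramModel, center: str, context: str, negatives) -> float:
    """log sigma(h.theta_q) + sum_t log sigma(-h.theta_t) for one pair."""
    h = model.hidden(center)
    q = model.vocabulary.index(context)
    val = float(log_sigmoid(h @ model.U[:, q]))
    for t in negatives:
        ti = model.vocabulary.index(t) if isinstance(t, str) else int(t)
        if ti == q:
            raise ValueError("negative sample equals the context word")
        val += float(log_sigmoid(-(h @ model.U[:, ti])))
    return val


def sgns_pair_objective(h: np.ndarray, theta: np.ndarray) -> float:
    """Pair objective for center vector h and context columns theta
    (column 0 = the true context word, remaining columns = negatives)."""
    dots = h @ theta
    return float(log_sigmoid(dots[0]) + log_sigmoid(-dots[1:]).sum())


def sgns_pair_gradient(h: np.ndarray, theta: np.ndarray):
    """Analytic ascent gradients (d/dh, d/dtheta) of the pair objective."""
    dots = h @ theta
    g = -sigmoid(dots)
    g[0] += 1.0  # (label - sigma): 1 for the positive column, 0 for negatives
    return theta @ g, np.outer(h, g)


class NoiseDistribution:
    """Unigram^power noise distribution over a corpus vocabulary."""

    def __init__(self, corpus, vocabulary: Vocabulary, power: float = 0.75):
        counts = np.zeros(vocabulary.size)
        for ws in corpus:
            for w in ws:
                counts[vocabulary.index(w)] += 1
        weights = np.power(counts, power, where=counts > 0, out=np.zeros_like(counts))
        total = weights.sum()
        if total == 0:
            raise ValueError("corpus is empty")
        self.probs = weights / total
        self.cum = np.cumsum(self.probs)
        self.vocabulary = vocabulary

    def draw(self, exclude: int, m: int, rng: np.random.Generator) -> np.ndarray:
        """m i.i.d. draws, redrawing any that equal the excluded index."""
        if np.count_nonzero(self.probs) == 1 and self.probs[exclude] > 0:
            raise ValueError("cannot draw negatives: vocabulary of size 1")
        out = np.searchsorted(self.cum, rng.random(m), side="right")
        while True:
            bad = out == exclude
            if not bad.any():
                return out
            out[bad] = np.searchsorted(self.cum, rng.random(int(bad.sum())), side="right")


def draw_negatives(
    word: str,
    noise: NoiseDistribution,
    config: SgnsTrainConfig,
    rng: np.random.Generator,
) -> list[str]:
    words = noise.vocabulary.words()
    idx = noise.vocabulary.index(word)
    return [words[i] for i in noise.draw(idx, config.negatives, rng)]


def _context_pairs(ids: list[int], half: int):
    for c, w in enumerate(ids):
        lo = max(0, c - half)
        hi = min(len(ids), c + half + 1)
        for k in range(lo, hi):
            if k != c:
                yield w, ids[k]


def train_skipgram(
    corpus,
    vocabulary: Vocabulary,
    config: SgnsTrainConfig | None = None,
    dim: int = 300,
) -> SkipGramModel:
    """Train SGNS embeddings by per-pair stochastic gradient ascent.

    W and U start uniform in [-0.5/N, 0.5/N); one positive pair is formed for
    the center word with each of window/2 words to the left and right
    (truncated at sequence boundaries).  The summed pair objective is logged
    per epoch.  Deterministic for a fixed seed.
    """
    config = config or SgnsTrainConfig()
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(config.seed)
    V, N = vocabulary.size, dim
    scale = 0.5 / N
    W = rng.uniform(-scale, scale, size=(V, N))
    U = rng.uniform(-scale, scale, size=(N, V))

    encoded = [[vocabulary.index(w) for w in ws] for ws in corpus]
    noise = NoiseDistribution(corpus, vocabulary, config.noise_power)
    half = config.window // 2
    pairs = np.array(
        [pair for ids in encoded for pair in _context_pairs(ids, half)],
        dtype=np.int64,
    ).reshape(-1, 2)
    n_pairs_per_epoch = len(pairs)
    total_pairs = max(1, n_pairs_per_epoch * config.epochs)

    train_log = []
    seen = 0
    m = config.negatives
    for epoch in range(config.epochs):
        # negatives drawn in bulk for the whole epoch (i.i.d. from the noise
        # distribution, rejecting the true context word by redraw)
        negs = np.searchsorted(noise.cum, rng.random((n_pairs_per_epoch, m)), side="right")
        while True:
            bad = negs == pairs[:, 1:2]
            n_bad = int(bad.sum())
            if not n_bad:
                break
            negs[bad] = np.searchsorted(noise.cum, rng.random(n_bad), side="right")
        objective = 0.0
        cols = np.empty(m + 1, dtype=np.int64)
        for p in range(n_pairs_per_epoch):
            w, q = pairs[p]
            alpha = config.learning_rate * (1.0 - seen / total_pairs)
            alpha = max(alpha, config.min_learning_rate)
            seen += 1
            h = W[w].copy()
            cols[0] = q
            cols[1:] = negs[p]
            theta = U[:, cols]  # (N, m+1)
            # objective and gradient share one set of dot products
            dots = h @ theta
            dots[1:] *= -1.0
            objective += float(log_sigmoid(dots).sum())
            g = sigmoid(-dots)  # = label - sigma(h.theta) with signs folded in
            g[1:] *= -1.0
            W[w] = h + alpha * (theta @ g)
            np.add.at(U, (slice(None), cols), np.outer(h, alpha * g))
        train_log.append(objective)
    return SkipGramModel(W=W, U=U, vocabulary=vocabulary, config=config, train_log=train_log)


def mean_pooled_vector(words, model: SkipGramModel) -> np.ndarray:
    """Debug-only mean of a sequence's word vectors.

    Pooled encodings are deliberately not offered as classifier inputs (the
    stacked embedding matrix is); this export exists for inspection."""
    if isinstance(words, WordSequence):
        words = words.words
    words = list(words)
    if not words:
        return np.zeros(model.dim)
    idx = [model.vocabulary.index(w) for w in words]
    return model.W[idx].mean(axis=0)


def embed_sequence(
    words, model: SkipGramModel, max_words: int, source_id: str = ""
) -> EmbeddingMatrix:
    """Look up each word's input vector; rows beyond word_count are zero."""
    if isinstance(words, WordSequence):
        source_id = source_id or words.source_id
        words = words.words
    words = list(words)
    if len(words) > max_words:
        raise ValueError(
            f"sequence {source_id!r} has {len(words)} words > max_words={max_words}"
        )
    rows = np.zeros((max_words, model.dim))
    for i, w in enumerate(words):
        rows[i] = model.W[model.vocabulary.index(w)]
    return EmbeddingMatrix(rows=rows, word_count=len(words), source_id=source_id)
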