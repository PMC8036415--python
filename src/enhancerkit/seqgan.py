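"""Sequence GAN for data augmentation.

An autoregressive gated-recurrent generator emits dinucleotide tokens; a
convolutional discriminator scores token sequences as real vs generated.
The generator is warm-started by maximum-likelihood pretraining and then
updated by policy gradient, with intermediate-state rewards estimated by
Monte-Carlo rollouts under a frozen copy of the generator.  Generated
sequences are detokenized to DNA and filtered for redundancy with a greedy
identity clustering that stands in for CD-HIT.
"""

from __future__ import annotations

import itertools
import json
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from enhancerkit.nn import Adam, TextCnnParams, init_text_cnn, softmax, text_cnn_backward, text_cnn_forward
from enhancerkit.seq_io import DnaSequence
from enhancerkit.tokenize import WordSequence, non_overlapped_2gram

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
MONONUCLEOTIDES = list("ACGT")


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class RolloutConfig:
    n_rollouts: int = 16

    def __post_init__(self) -> None:
        if self.n_rollouts < 1:
            raise ValueError("n_rollouts must be >= 1")


@dataclass
class GanTrainConfig:
    pretrain_epochs: int = 20
    adv_rounds: int = 10
    g_steps: int = 1
    d_steps: int = 1
    g_learning_rate: float = 0.01
    d_learning_rate: float = 1e-3
    pretrain_learning_rate: float = 1e-2
    batch_size: int = 32
    seed: int = 0
    class_tag: str = "non_enhancer"

    def __post_init__(self) -> None:
        for name in ("pretrain_epochs", "adv_rounds", "d_steps", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.g_steps < 0:
            raise ValueError("g_steps must be >= 0")


# ---------------------------------------------------------------------------
# Generator: single-layer GRU policy over tokens
# ---------------------------------------------------------------------------


class GeneratorPolicy:
    """Autoregressive GRU over a token vocabulary with a start token.

    ``tokens`` are the emittable symbols (dinucleotides by default); the
    start token is appended internally and never emitted.  ``horizon`` is
    the number of tokens per generated sequence (100 for 200-bp DNA).
    """

    def __init__(
        self,
        tokens: list[str] | None = None,
        horizon: int = 100,
        hidden_size: int = 64,
        embed_dim: int = 32,
        seed: int = 0,
    ):
        self.tokens = list(tokens) if tokens is not None else list(DINUCLEOTIDES)
        self.horizon = horizon
        self.hidden_size = hidden_size
        self.embed_dim = embed_dim
        self.V = len(self.tokens)
        self.start_id = self.V
        rng = np.random.default_rng(seed)
        H, D, V = hidden_size, embed_dim, self.V
        s = 0.1
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(scale=s, size=(V + 1, D)),
            "Wz": rng.normal(scale=s, size=(D, H)),
            "Wr": rng.normal(scale=s, size=(D, H)),
            "Wh": rng.normal(scale=s, size=(D, H)),
            "Uz": rng.normal(scale=s, size=(H, H)),
            "Ur": rng.normal(scale=s, size=(H, H)),
            "Uh": rng.normal(scale=s, size=(H, H)),
            "bz": np.zeros(H),
            "br": np.zeros(H),
            "bh": np.zeros(H),
            "Wo": rng.normal(scale=s, size=(H, V)),
            "bo": np.zeros(V),
        }

    # -- core recurrence ----------------------------------------------------

    def initial_hidden(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.hidden_size))

    def step(self, token_ids: np.ndarray, h_prev: np.ndarray, cache: bool = False):
        """One GRU step: returns (h, logits[, cache])."""
        p = self.params
        x = p["E"][token_ids]
        z = _sigmoid(x @ p["Wz"] + h_prev @ p["Uz"] + p["bz"])
        r = _sigmoid(x @ p["Wr"] + h_prev @ p["Ur"] + p["br"])
        hc = np.tanh(x @ p["Wh"] + (r * h_prev) @ p["Uh"] + p["bh"])
        h = (1.0 - z) * h_prev + z * hc
        logits = h @ p["Wo"] + p["bo"]
        if cache:
            return h, logits, (token_ids, x, h_prev, z, r, hc, h)
        return h, logits

    def step_probs(self, token_ids: np.ndarray, h_prev: np.ndarray):
        h, logits = self.step(token_ids, h_prev)
        return h, softmax(logits)

    def conditional_probs(self, prefix: list[int] | np.ndarray) -> np.ndarray:
        """G(y | prefix) as a probability vector over the token vocabulary."""
        h = self.initial_hidden(1)
        inp = np.array([self.start_id])
        probs = None
        for tok in [None, *list(prefix)]:
            if tok is not None:
                inp = np.array([int(tok)])
            h, probs = self.step_probs(inp, h)
        return probs[0]

    def forward_sequences(self, token_ids: np.ndarray):
        """Teacher-forced forward over (B, T) targets.

        Returns (logits (B,T,V), caches) with inputs shifted right by the
        start token."""
        B, T = token_ids.shape
        h = self.initial_hidden(B)
        inputs = np.concatenate(
            [np.full((B, 1), self.start_id, dtype=np.int64), token_ids[:, :-1]], axis=1
        )
        logits = np.empty((B, T, self.V))
        caches = []
        for t in range(T):
            h, lg, c = self.step(inputs[:, t], h, cache=True)
            logits[:, t] = lg
            caches.append(c)
        return logits, caches

    def backward_sequences(self, caches, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT: gradients of a scalar loss given d(loss)/d(logits) (B,T,V)."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        T = dlogits.shape[1]
        dh_next = np.zeros((dlogits.shape[0], self.hidden_size))
        for t in range(T - 1, -1, -1):
            token_ids, x, h_prev, z, r, hc, h = caches[t]
            dl = dlogits[:, t]
            grads["Wo"] += h.T @ dl
            grads["bo"] += dl.sum(axis=0)
            dh = dh_next + dl @ p["Wo"].T
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)
            dhc_pre = dhc * (1.0 - hc * hc)
            grads["Wh"] += x.T @ dhc_pre
            grads["bh"] += dhc_pre.sum(axis=0)
            grads["Uh"] += (r * h_prev).T @ dhc_pre
            dx = dhc_pre @ p["Wh"].T
            drh = dhc_pre @ p["Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            grads["Wz"] += x.T @ dz_pre
            grads["bz"] += dz_pre.sum(axis=0)
            grads["Uz"] += h_prev.T @ dz_pre
            grads["Wr"] += x.T @ dr_pre
            grads["br"] += dr_pre.sum(axis=0)
            grads["Ur"] += h_prev.T @ dr_pre
            dx += dz_pre @ p["Wz"].T + dr_pre @ p["Wr"].T
            dh_prev += dz_pre @ p["Uz"].T + dr_pre @ p["Ur"].T
            np.add.at(grads["E"], token_ids, dx)
            dh_next = dh_prev
        return grads

    # -- sampling -----------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        prefix: np.ndarray | None = None,
        h0: np.ndarray | None = None,
        keep_hidden: bool = False,
    ):
        """Sample n sequences of `horizon` tokens; optionally continue a
        (n, t) prefix from hidden state h0.  Returns ids (n, horizon) or
        (ids, per-step hidden states) when keep_hidden."""
        T = self.horizon
        if prefix is None:
            prefix = np.empty((n, 0), dtype=np.int64)
        t0 = prefix.shape[1]
        ids = np.empty((n, T), dtype=np.int64)
        ids[:, :t0] = prefix
        if h0 is None:
            h = self.initial_hidden(n)
            inp = np.full(n, self.start_id, dtype=np.int64)
            for t in range(t0):
                h, _ = self.step(inp, h)
                inp = prefix[:, t]
        else:
            h = h0
            inp = prefix[:, -1] if t0 else np.full(n, self.start_id, dtype=np.int64)
        hiddens = []
        for t in range(t0, T):
            h, probs = self.step_probs(inp, h)
            u = rng.random((n, 1))
            cum = probs.cumsum(axis=1)
            inp = (cum > u).argmax(axis=1)
            # float-rounding guard: if cum never exceeded u, take the last token
            short = cum[:, -1] <= u[:, 0]
            if short.any():
                inp[short] = self.V - 1
            ids[:, t] = inp
            if keep_hidden:
                hiddens.append(h)
        return (ids, hiddens) if keep_hidden else ids

    def copy(self) -> "GeneratorPolicy":
        clone = GeneratorPolicy(
            tokens=self.tokens,
            horizon=self.horizon,
            hidden_size=self.hidden_size,
            embed_dim=self.embed_dim,
        )
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def sync_from(self, other: "GeneratorPolicy") -> None:
        for k in self.params:
            self.params[k][...] = other.params[k]

    def nll(self, token_ids: np.ndarray) -> float:
        logits, _ = self.forward_sequences(token_ids)
        probs = softmax(logits)
        B, T = token_ids.shape
        picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], token_ids]
        return -float(np.mean(np.log(picked + 1e-12)))

    def save(self, path: Path | str) -> None:
        meta = json.dumps(
            {
                "tokens": self.tokens,
                "horizon": self.horizon,
                "hidden_size": self.hidden_size,
                "embed_dim": self.embed_dim,
            }
        )
        with open(path, "wb") as fh:
            np.savez(fh, meta=meta, **self.params)

    @classmethod
    def load(cls, path: Path | str) -> "GeneratorPolicy":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            gen = cls(
                tokens=meta["tokens"],
                horizon=meta["horizon"],
                hidden_size=meta["hidden_size"],
                embed_dim=meta["embed_dim"],
            )
            for k in gen.params:
                gen.params[k] = data[k].copy()
            return gen


# ---------------------------------------------------------------------------
# Discriminator: convolutional real-vs-generated classifier
# ---------------------------------------------------------------------------


class Discriminator:
    """Multi-width CNN over token embeddings; ``score`` is P(real) in (0, 1)."""

    def __init__(
        self,
        vocab_size: int = 16,
        embed_dim: int = 16,
        kernel_heights: tuple[int, ...] = (2, 3),
        kernels_per_height: int = 16,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.vocab_size = vocab_size
        self.params: TextCnnParams = init_text_cnn(
            vocab_size, embed_dim, kernel_heights, kernels_per_height, 2, rng
        )

    def score(self, token_ids: np.ndarray) -> np.ndarray:
        """P(real) for a batch of token-id sequences (B, T)."""
        token_ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
        X = self.params.embedding[token_ids]
        probs = text_cnn_forward(self.params, X).probs
        return np.clip(probs[:, 1], 1e-12, 1.0 - 1e-12)

    def train_step(
        self, real: np.ndarray, fake: np.ndarray, opt: Adam
    ) -> float:
        """One gradient step on -E_R[log D] - E_G[log(1-D)]; returns the loss."""
        ids = np.concatenate([real, fake], axis=0)
        labels = np.concatenate(
            [np.ones(len(real), dtype=int), np.zeros(len(fake), dtype=int)]
        )
        X = self.params.embedding[ids]
        cache = text_cnn_forward(self.params, X)
        probs = np.clip(cache.probs, 1e-12, 1.0 - 1e-12)
        n_r, n_f = len(real), len(fake)
        loss = -float(np.log(probs[:n_r, 1]).mean()) - float(
            np.log(probs[n_r:, 0]).mean()
        )
        dlogits = cache.probs.copy()
        dlogits[np.arange(len(ids)), labels] -= 1.0
        dlogits[:n_r] /= n_r
        dlogits[n_r:] /= n_f
        grads = text_cnn_backward(self.params, cache, dlogits, token_ids=ids)
        opt.step(grads)
        return loss


def discriminator_loss(
    discriminator, real_batch: np.ndarray, fake_batch: np.ndarray
) -> float:
    """-E_R[log D(R)] - E_G[log(1 - D(G))]."""
    if len(real_batch) == 0 or len(fake_batch) == 0:
        raise ValueError("batches must be non-empty")
    d_real = discriminator.score(real_batch)
    d_fake = discriminator.score(fake_batch)
    return -float(np.mean(np.log(d_real))) - float(np.mean(np.log1p(-d_fake)))


# ---------------------------------------------------------------------------
# Pretraining, action values, policy gradient, adversarial loop
# ---------------------------------------------------------------------------


def pretrain_generator(
    real_token_seqs: np.ndarray,
    generator: GeneratorPolicy,
    config: GanTrainConfig,
) -> list[float]:
    """Teacher-forced maximum-likelihood warm start; returns per-epoch NLL."""
    real = np.asarray(real_token_seqs, dtype=np.int64)
    if real.size == 0:
        raise ValueError("empty pretraining corpus")
    if real.shape[1] != generator.horizon:
        raise ValueError("sequences must match the generator horizon")
    rng = np.random.default_rng(config.seed)
    opt = Adam(generator.params, lr=config.pretrain_learning_rate)
    log = []
    B_total, T = real.shape
    for epoch in range(config.pretrain_epochs):
        perm = rng.permutation(B_total)
        for lo in range(0, B_total, config.batch_size):
            batch = real[perm[lo : lo + config.batch_size]]
            logits, caches = generator.forward_sequences(batch)
            probs = softmax(logits)
            B = batch.shape[0]
            dlogits = probs.copy()
            dlogits[
                np.arange(B)[:, None], np.arange(T)[None, :], batch
            ] -= 1.0
            dlogits /= B * T
            grads = generator.backward_sequences(caches, dlogits)
            opt.step(grads)
        log.append(generator.nll(real))
    return log


def action_value(
    state: np.ndarray,
    action: int,
    generator: GeneratorPolicy,
    discriminator,
    rollout_cfg: RolloutConfig,
    rng: np.random.Generator,
    rollout_policy: GeneratorPolicy | None = None,
) -> float:
    """Q(state, action): discriminator output at t = T (exact, no sampling);
    otherwise the mean score of N rollout completions of state + action."""
    state = np.asarray(state, dtype=np.int64).reshape(-1)
    prefix = np.concatenate([state, [action]])
    t = len(prefix)
    T = generator.horizon
    if t > T:
        raise ValueError("state + action exceed the horizon")
    if t == T:
        return float(discriminator.score(prefix[None, :])[0])
    policy = rollout_policy or generator
    N = rollout_cfg.n_rollouts
    tiled = np.tile(prefix, (N, 1))
    completions = policy.sample(N, rng, prefix=tiled)
    return float(discriminator.score(completions).mean())


def _full_action_values(
    samples: np.ndarray,
    hiddens: list[np.ndarray],
    rollout_policy: GeneratorPolicy,
    discriminator,
    rollout_cfg: RolloutConfig,
    rng: np.random.Generator,
    V: int,
) -> np.ndarray:
    """Q(prefix, a) for every action a at every prefix of a sampled batch.

    Returns (B, T, V).  The terminal position uses the discriminator output
    directly; earlier positions average N rollout completions per action."""
    B, T = samples.shape
    N = rollout_cfg.n_rollouts
    actions = np.tile(np.arange(V, dtype=np.int64), B)[:, None]  # (B*V, 1)
    Q = np.empty((B, T, V))
    full = np.concatenate([np.repeat(samples[:, : T - 1], V, axis=0), actions], axis=1)
    Q[:, T - 1, :] = discriminator.score(full).reshape(B, V)
    for pos in range(T - 1):
        prefix = np.concatenate(
            [np.repeat(samples[:, :pos], V, axis=0), actions], axis=1
        )
        prefix = np.repeat(prefix, N, axis=0)  # (B*V*N, pos+1)
        h0 = np.repeat(np.repeat(hiddens[pos], V, axis=0), N, axis=0)
        completions = rollout_policy.sample(B * V * N, rng, prefix=prefix, h0=h0)
        scores = discriminator.score(completions).reshape(B, V, N)
        Q[:, pos, :] = scores.mean(axis=2)
    return Q


def generator_gradient(
    generator: GeneratorPolicy,
    discriminator,
    rollout_cfg: RolloutConfig,
    batch: int,
    rng: np.random.Generator,
    rollout_policy: GeneratorPolicy | None = None,
):
    """Policy-gradient ascent estimate over sampled prefixes, summing over
    all actions at each position:

        (1/B) sum_b sum_t sum_y  grad G(y | Y_{1:t-1})  *  Q(Y_{1:t-1}, y)

    Returns (grads, diagnostics).  Unbiased for the expected terminal
    reward; exactly zero (up to float noise) when Q is constant, because
    sum_y grad G(y | s) = grad 1 = 0."""
    rollout_policy = rollout_policy or generator
    samples, hiddens = generator.sample(batch, rng, keep_hidden=True)
    Q = _full_action_values(
        samples, hiddens, rollout_policy, discriminator, rollout_cfg, rng, generator.V
    )
    logits, caches = generator.forward_sequences(samples)
    probs = softmax(logits)
    B = samples.shape[0]
    # dJ/dlogit_j = p_j * (Q_j - sum_y p_y Q_y); vanishes for constant Q
    baseline = (probs * Q).sum(axis=2, keepdims=True)
    dJ = probs * (Q - baseline) / B
    loss_grads = generator.backward_sequences(caches, -dJ)
    grads = {k: -v for k, v in loss_grads.items()}  # ascent direction
    mean_reward = float(discriminator.score(samples).mean())
    diagnostics = {"mean_reward": mean_reward, "mean_q": float(Q.mean())}
    return grads, diagnostics


def adversarial_train(
    real_token_seqs: np.ndarray,
    generator: GeneratorPolicy,
    discriminator: Discriminator,
    config: GanTrainConfig,
    rollout_cfg: RolloutConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[dict]:
    """Alternate policy-gradient generator updates and discriminator updates.

    The rollout policy is a frozen copy of the generator, synchronized before
    each block of generator steps.  Returns the per-round training log."""
    rollout_cfg = rollout_cfg or RolloutConfig()
    rng = rng or np.random.default_rng(config.seed)
    real = np.asarray(real_token_seqs, dtype=np.int64)
    rollout_policy = generator.copy()
    d_opt = Adam(discriminator.params.as_dict(), lr=config.d_learning_rate)
    log: list[dict] = []
    for rnd in range(config.adv_rounds):
        # discriminator first, so generator rewards are informative
        d_loss = None
        for _ in range(config.d_steps):
            fake = generator.sample(config.batch_size, rng)
            idx = rng.choice(len(real), size=min(len(real), config.batch_size), replace=False)
            d_loss = discriminator.train_step(real[idx], fake, d_opt)
        mean_reward = None
        for _ in range(config.g_steps):
            rollout_policy.sync_from(generator)
            grads, diag = generator_gradient(
                generator,
                discriminator,
                rollout_cfg,
                config.batch_size,
                rng,
                rollout_policy=rollout_policy,
            )
            mean_reward = diag["mean_reward"]
            if not np.isfinite(mean_reward):
                raise RuntimeError("adversarial training diverged (NaN reward)")
            for k, g in grads.items():
                generator.params[k] += config.g_learning_rate * g
        if mean_reward is None:
            fake = generator.sample(config.batch_size, rng)
            mean_reward = float(discriminator.score(fake).mean())
        log.append({"round": rnd, "mean_reward": mean_reward, "d_loss": d_loss})
    return log


# ---------------------------------------------------------------------------
# Tokenization bridges and generation
# ---------------------------------------------------------------------------


def sequences_to_token_ids(sequences, tokens: list[str] | None = None) -> np.ndarray:
    """Pre-segment DNA sequences with the non-overlapped 2-gram scheme and
    encode them as token-id rows (all sequences must tokenize to equal length)."""
    tokens = tokens or DINUCLEOTIDES
    index = {t: i for i, t in enumerate(tokens)}
    rows = []
    for seq in sequences:
        ws = seq if isinstance(seq, WordSequence) else non_overlapped_2gram(seq)
        rows.append([index[w] for w in ws.words])
    arr = np.asarray(rows, dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError("sequences tokenize to unequal lengths")
    return arr


def detokenize(token_ids: np.ndarray, tokens: list[str] | None = None) -> str:
    tokens = tokens or DINUCLEOTIDES
    return "".join(tokens[i] for i in token_ids)


def generate_sequences(
    generator: GeneratorPolicy,
    n: int,
    class_tag: str,
    rng: np.random.Generator,
) -> list[DnaSequence]:
    """Sample n token sequences and detokenize them into DNA records whose
    ids encode the class and index (``<class>|generated|<i>``)."""
    ids = generator.sample(n, rng)
    out = []
    for i in range(n):
        residues = detokenize(ids[i], generator.tokens)
        out.append(DnaSequence(id=f"{class_tag}|generated|{i}", residues=residues))
    return out


# ---------------------------------------------------------------------------
# Redundancy filter (internal CD-HIT stand-in)
# ---------------------------------------------------------------------------

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


def pairwise_identity(a: str | np.ndarray, b: str | np.ndarray, cutoff: float = 0.0) -> float:
    """Identity = matches in the best ungapped sliding alignment / shorter
    length.  Shifts whose overlap cannot reach ``cutoff`` are skipped."""
    a = _encode(a) if isinstance(a, str) else a
    b = _encode(b) if isinstance(b, str) else b
    la, lb = len(a), len(b)
    shorter = min(la, lb)
    min_overlap = max(1, int(np.ceil(cutoff * shorter)))
    best = 0
    for shift in range(-(lb - min_overlap), la - min_overlap + 1):
        a0, b0 = max(0, shift), max(0, -shift)
        ov = min(la - a0, lb - b0)
        if ov < min_overlap:
            continue
        matches = int((a[a0 : a0 + ov] == b[b0 : b0 + ov]).sum())
        if matches > best:
            best = matches
    return best / shorter


def _max_identity_vs_pool(arr: np.ndarray, pool: np.ndarray, cutoff: float) -> float:
    """Best sliding-alignment identity of ``arr`` against every row of an
    equal-length pool (n, L), vectorized over the pool; early-exits at the
    first shift reaching the cutoff."""
    L = len(arr)
    min_overlap = max(1, int(np.ceil(cutoff * L)))
    best = 0.0
    for shift in range(-(L - min_overlap), L - min_overlap + 1):
        a0, b0 = max(0, shift), max(0, -shift)
        ov = L - abs(shift)
        matches = (arr[a0 : a0 + ov] == pool[:, b0 : b0 + ov]).sum(axis=1)
        m = float(matches.max()) / L
        if m > best:
            best = m
            if best >= cutoff:
                return best
    return best


def _kmer_set(arr: np.ndarray, k: int) -> set:
    if len(arr) < k:
        return {arr.tobytes()}
    view = np.lib.stride_tricks.sliding_window_view(arr, k)
    return {v.tobytes() for v in view}


def redundancy_filter(
    sequences: list[DnaSequence],
    cutoff: float = 0.80,
    reference: list[DnaSequence] | None = None,
    kmer_prefilter: bool = True,
    k: int = 8,
    engine: str = "internal",
) -> list[DnaSequence]:
    """Greedy incremental clustering in input order: a sequence is discarded
    when its identity to any retained (or reference) sequence reaches the
    cutoff.

    The k-mer prefilter skips pairs sharing no k-mer; it is a speed heuristic
    that is safe for near-duplicates (which always share k-mers at the
    aligned offset) but can in principle pass an adversarial pair, so the
    retained-set guarantee is "no pair of k-mer-sharing sequences at >=
    cutoff identity".  ``engine='cdhit'`` shells out to cd-hit-est instead.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must lie in (0, 1]")
    if engine == "cdhit":
        return _cdhit_filter(sequences, cutoff)
    kept: list[DnaSequence] = []
    pool: list[tuple[np.ndarray, set]] = []
    for ref in reference or []:
        arr = _encode(ref.residues)
        pool.append((arr, _kmer_set(arr, k) if kmer_prefilter else set()))
    for seq in sequences:
        arr = _encode(seq.residues)
        kmers = _kmer_set(arr, k) if kmer_prefilter else set()
        candidates = [
            other
            for other, other_kmers in pool
            if not kmer_prefilter or (kmers & other_kmers)
        ]
        redundant = False
        if candidates:
            same_len = [c for c in candidates if len(c) == len(arr)]
            if same_len:
                pool_mat = np.stack(same_len)
                if _max_identity_vs_pool(arr, pool_mat, cutoff) >= cutoff:
                    redundant = True
            if not redundant:
                for other in candidates:
                    if len(other) == len(arr):
                        continue
                    if pairwise_identity(arr, other, cutoff=cutoff) >= cutoff:
                        redundant = True
                        break
        if not redundant:
            kept.append(seq)
            pool.append((arr, kmers))
    return kept


def _cdhit_filter(sequences: list[DnaSequence], cutoff: float) -> list[DnaSequence]:
    exe = shutil.which("cd-hit-est")
    if exe is None:
        raise FileNotFoundError("cd-hit-est not found on PATH")
    import tempfile

    from enhancerkit.seq_io import write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        inp, out = f"{tmp}/in.fasta", f"{tmp}/out.fasta"
        with open(inp, "w") as fh:
            for s in sequences:
                fh.write(f">{s.id}\n{s.residues}\n")
        subprocess.run(
            [exe, "-i", inp, "-o", out, "-c", str(cutoff), "-n", "5"],
            check=True,
            capture_output=True,
        )
        kept_ids = set()
        with open(out) as fh:
            for line in fh:
                if line.startswith(">"):
                    kept_ids.add(line[1:].strip().split()[0])
    return [s for s in sequences if s.id in kept_ids]
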