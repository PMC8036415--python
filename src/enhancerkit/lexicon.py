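"""Statistics-based DNA word segmentation.

A unigram dictionary (word → probability) is learned from a corpus in three
stages: a byte-pair-encoding seed, EM fitting of the word probabilities to
maximize the marginal likelihood over all segmentations, and iterative
pruning of low-loss words until the dictionary reaches its target size.
Sequences are then segmented by the maximum-probability path (Viterbi).

The four mononucleotides are protected members of every dictionary, which
guarantees that every A/C/G/T sequence is segmentable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from enhancerkit.seq_io import DnaSequence
from enhancerkit.tokenize import Scheme, WordSequence

PROTECTED = ("A", "C", "G", "T")
_PROB_FLOOR = 1e-300
_NEG_INF = -np.inf


@dataclass
class LexiconTrainConfig:
    target_size: int = 150
    keep_fraction: float = 0.70
    seed_size: int = 1000
    max_word_length: int = 8
    em_tol: float = 1e-6
    em_max_iter: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_fraction < 1.0:
            raise ValueError("keep_fraction must lie in (0, 1)")
        if self.target_size < 4:
            raise ValueError("target_size must be at least 4 (mononucleotides)")


@dataclass
class UnigramDictionary:
    """A word → probability table; probabilities sum to one."""

    entries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for base in PROTECTED:
            if base not in self.entries:
                raise ValueError(f"mononucleotide {base!r} missing from dictionary")
        for w, p in self.entries.items():
            if p <= 0.0:
                raise ValueError(f"word {w!r} has non-positive probability {p}")
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def words(self) -> list[str]:
        return list(self.entries)

    def probability(self, word: str) -> float:
        return self.entries[word]

    def max_word_length(self) -> int:
        return max(len(w) for w in self.entries)

    @classmethod
    def from_counts(cls, counts: dict[str, float]) -> "UnigramDictionary":
        total = sum(counts.values())
        probs = {w: c / total for w, c in counts.items()}
        return cls(entries=_floor_and_renormalize(probs))

    def to_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for w in sorted(self.entries):
                fh.write(f"{w}\t{self.entries[w]:.15g}\n")

    @classmethod
    def from_tsv(cls, path: Path | str) -> "UnigramDictionary":
        entries: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                word, prob = line.rstrip("\n").split("\t")
                entries[word] = float(prob)
        return cls(entries=entries)


def _floor_and_renormalize(probs: dict[str, float]) -> dict[str, float]:
    floored = False
    out = {}
    for w, p in probs.items():
        if p < _PROB_FLOOR:
            p = _PROB_FLOOR
            floored = True
        out[w] = p
    if floored:
        warnings.warn("dictionary probabilities floored at 1e-300", RuntimeWarning)
    total = sum(out.values())
    return {w: p / total for w, p in out.items()}


# ---------------------------------------------------------------------------
# Lattice: vectorized word-match tables shared by forward/backward passes.
# ---------------------------------------------------------------------------


class _CorpusLattice:
    """Word-match tables for a corpus under a fixed word set.

    ``match[i, pos, l-1]`` is the dictionary index of ``seq_i[pos:pos+l]``
    or -1 when that substring is not a word.  All recursions below are
    vectorized across sequences.
    """

    def __init__(self, corpus: list[str], words: list[str]):
        self.words = list(words)
        self.word_index = {w: i for i, w in enumerate(self.words)}
        self.max_len = max(len(w) for w in self.words)
        self.seq_lens = np.array([len(s) for s in corpus], dtype=np.int64)
        self.n = len(corpus)
        self.L = int(self.seq_lens.max()) if self.n else 0
        match = np.full((self.n, self.L, self.max_len), -1, dtype=np.int64)
        for i, s in enumerate(corpus):
            for pos in range(len(s)):
                for l in range(1, min(self.max_len, len(s) - pos) + 1):
                    idx = self.word_index.get(s[pos : pos + l], -1)
                    match[i, pos, l - 1] = idx
        self.match = match

    def log_probs(self, dictionary: UnigramDictionary) -> np.ndarray:
        return np.array(
            [math.log(dictionary.entries[w]) for w in self.words], dtype=np.float64
        )

    def forward(self, logp: np.ndarray, exclude: int = -2) -> tuple[np.ndarray, np.ndarray]:
        """Log-space forward sums; returns (alpha, per-sequence log-likelihood).

        ``alpha[i, pos]`` = log of the summed probability of all partial
        segmentations of sequence i covering residues [0, pos).  ``exclude``
        masks one word index (used for pruning-loss evaluation); its
        probability mass is renormalized out via the caller's logp shift.
        """
        alpha = np.full((self.n, self.L + 1), _NEG_INF)
        alpha[:, 0] = 0.0
        for pos in range(self.L):
            src = alpha[:, pos]
            if not np.any(np.isfinite(src)):
                continue
            for l in range(1, self.max_len + 1):
                if pos + l > self.L:
                    break
                ids = self.match[:, pos, l - 1]
                valid = ids >= 0
                if exclude >= 0:
                    valid &= ids != exclude
                if not valid.any():
                    continue
                cand = np.where(valid, src + logp[np.maximum(ids, 0)], _NEG_INF)
                alpha[:, pos + l] = np.logaddexp(alpha[:, pos + l], cand)
        ll = alpha[np.arange(self.n), self.seq_lens]
        return alpha, ll

    def candidate_lls(
        self, logp: np.ndarray, cand_ids: np.ndarray, shifts: np.ndarray
    ) -> np.ndarray:
        """Corpus log-likelihood with one word removed, for many candidates.

        ``shifts[k]`` = log(1 - p(candidate k)) renormalizes the remaining
        probability mass.  Candidates are processed in chunks so the forward
        recursion vectorizes over (candidate, sequence) jointly.
        """
        out = np.empty(len(cand_ids))
        bytes_per_cand = self.n * (self.L + 1) * 8
        chunk = max(1, min(len(cand_ids), int(2e8 // max(bytes_per_cand, 1))))
        for lo in range(0, len(cand_ids), chunk):
            cids = cand_ids[lo : lo + chunk][:, None]  # (K, 1)
            shf = shifts[lo : lo + chunk][:, None]
            K = cids.shape[0]
            alpha = np.full((K, self.n, self.L + 1), _NEG_INF)
            alpha[:, :, 0] = 0.0
            for pos in range(self.L):
                src = alpha[:, :, pos]
                for l in range(1, self.max_len + 1):
                    if pos + l > self.L:
                        break
                    ids = self.match[:, pos, l - 1]
                    base_valid = ids >= 0
                    if not base_valid.any():
                        continue
                    w = np.where(base_valid, logp[np.maximum(ids, 0)], _NEG_INF)
                    cand = src + (w[None, :] - shf)
                    cand[ids[None, :] == cids] = _NEG_INF
                    np.logaddexp(
                        alpha[:, :, pos + l], cand, out=alpha[:, :, pos + l]
                    )
            ll = alpha[:, np.arange(self.n), self.seq_lens]  # (K, n)
            totals = np.where(
                np.isfinite(ll).all(axis=1), ll.sum(axis=1), _NEG_INF
            )
            out[lo : lo + chunk] = totals
        return out

    def backward(self, logp: np.ndarray) -> np.ndarray:
        beta = np.full((self.n, self.L + 1), _NEG_INF)
        beta[np.arange(self.n), self.seq_lens] = 0.0
        for pos in range(self.L - 1, -1, -1):
            acc = np.full(self.n, _NEG_INF)
            for l in range(1, self.max_len + 1):
                if pos + l > self.L:
                    break
                ids = self.match[:, pos, l - 1]
                valid = ids >= 0
                if not valid.any():
                    continue
                cand = np.where(
                    valid, beta[:, pos + l] + logp[np.maximum(ids, 0)], _NEG_INF
                )
                acc = np.logaddexp(acc, cand)
            beta[:, pos] = acc
            # positions past a sequence's end keep their sentinel values
            done = pos >= self.seq_lens
            beta[done, pos] = np.where(
                pos == self.seq_lens[done], 0.0, _NEG_INF
            )
        return beta

    def expected_counts(self, logp: np.ndarray) -> tuple[np.ndarray, float]:
        """E-step: posterior expected usage count of each word, plus total L."""
        alpha, ll = self.forward(logp)
        beta = self.backward(logp)
        counts = np.zeros(len(self.words))
        for l in range(1, self.max_len + 1):
            ids = self.match[:, : self.L - l + 1, l - 1] if self.L - l + 1 > 0 else None
            if ids is None:
                continue
            npos = ids.shape[1]
            a = alpha[:, :npos]
            b = beta[:, l : l + npos]
            valid = ids >= 0
            if not valid.any():
                continue
            post = (
                a
                + np.where(valid, logp[np.maximum(ids, 0)], 0.0)
                + b
                - ll[:, None]
            )
            w = np.where(valid & np.isfinite(post), np.exp(post), 0.0)
            counts += np.bincount(
                ids[valid], weights=w[valid], minlength=len(self.words)
            )
        return counts, float(ll.sum())


def _corpus_strings(corpus) -> list[str]:
    out = []
    for item in corpus:
        out.append(item.residues if isinstance(item, DnaSequence) else str(item))
    return out


# ---------------------------------------------------------------------------
# BPE seeding
# ---------------------------------------------------------------------------


def bpe_seed(corpus, config: LexiconTrainConfig | None = None) -> UnigramDictionary:
    """Seed dictionary from iterative most-frequent-adjacent-pair merges.

    Starting from the four mononucleotides, the most frequent adjacent symbol
    pair (ties broken by lexicographically smallest merged string) is merged
    until ``seed_size`` distinct words exist, skipping merges that would
    exceed ``max_word_length``.  Initial probabilities are proportional to
    add-one-smoothed post-merge symbol counts (smoothing keeps intermediate
    symbols that were fully absorbed by later merges at positive probability).
    """
    config = config or LexiconTrainConfig()
    seqs = _corpus_strings(corpus)
    if sum(len(s) for s in seqs) < 2:
        raise ValueError("corpus must contain at least 2 nucleotides")

    symbols = list(PROTECTED)  # id -> string; ids may alias equal strings
    sym_of = {s: i for i, s in enumerate(symbols)}
    words: set[str] = set(PROTECTED)

    parts = []
    for s in seqs:
        parts.append(np.array([sym_of[c] for c in s], dtype=np.int64))
        parts.append(np.array([-1], dtype=np.int64))  # sequence separator
    arr = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)

    while len(words) < config.seed_size:
        left, right = arr[:-1], arr[1:]
        lens = np.array([len(s) for s in symbols], dtype=np.int64)
        valid = (left >= 0) & (right >= 0)
        if valid.any():
            merged_len = np.zeros(valid.shape, dtype=np.int64)
            merged_len[valid] = lens[left[valid]] + lens[right[valid]]
            valid &= merged_len <= config.max_word_length
        if not valid.any():
            break
        m = len(symbols)
        codes = left[valid] * m + right[valid]
        uniq, cnts = np.unique(codes, return_counts=True)
        best = cnts.max()
        cand = uniq[cnts == best]
        merged_strings = [symbols[c // m] + symbols[c % m] for c in cand]
        pick = min(range(len(merged_strings)), key=merged_strings.__getitem__)
        code = int(cand[pick])
        l_id, r_id = code // m, code % m
        new_string = merged_strings[pick]

        new_id = len(symbols)
        symbols.append(new_string)
        words.add(new_string)

        # greedy non-overlapping left-to-right replacement
        positions = np.nonzero((left == l_id) & (right == r_id) & valid)[0]
        kept: list[int] = []
        last = -2
        for p in positions:
            if p == last + 1:
                continue
            kept.append(int(p))
            last = int(p)
        kept_arr = np.array(kept, dtype=np.int64)
        arr[kept_arr] = new_id
        arr = np.delete(arr, kept_arr + 1)

    # post-merge symbol counts, aggregated per word string
    counts: dict[str, float] = {w: 1.0 for w in words}  # add-one smoothing
    occ = np.bincount(arr[arr >= 0], minlength=len(symbols))
    for sym_id, c in enumerate(occ):
        if c and symbols[sym_id] in counts:
            counts[symbols[sym_id]] += float(c)
    return UnigramDictionary.from_counts(counts)


# ---------------------------------------------------------------------------
# Marginal likelihood, EM, pruning, Viterbi
# ---------------------------------------------------------------------------


def marginal_log_likelihood(corpus, dictionary: UnigramDictionary) -> float:
    """Sum over sequences of log of the summed probability of all
    segmentations, computed by a log-space forward recursion."""
    seqs = _corpus_strings(corpus)
    lattice = _CorpusLattice(seqs, dictionary.words())
    _, ll = lattice.forward(lattice.log_probs(dictionary))
    if not np.all(np.isfinite(ll)):
        raise ValueError("corpus contains an unsegmentable sequence")
    return float(ll.sum())


def em_fit(
    corpus,
    dictionary: UnigramDictionary,
    config: LexiconTrainConfig | None = None,
    _lattice: _CorpusLattice | None = None,
) -> tuple[UnigramDictionary, list[float]]:
    """Fit word probabilities by EM on the marginal segmentation likelihood.

    E-step: expected word counts from forward-backward posteriors over each
    sequence's full segmentation lattice; M-step: counts normalized.  Stops
    on relative log-likelihood change < ``em_tol`` or ``em_max_iter``.
    Returns the fitted dictionary and the per-iteration log-likelihood trace
    (non-decreasing up to numerical slack).
    """
    config = config or LexiconTrainConfig()
    seqs = _corpus_strings(corpus)
    lattice = _lattice or _CorpusLattice(seqs, dictionary.words())
    probs = dict(dictionary.entries)
    trace: list[float] = []
    prev = None
    for _ in range(config.em_max_iter):
        logp = np.array([math.log(probs[w]) for w in lattice.words])
        counts, ll = lattice.expected_counts(logp)
        trace.append(ll)
        new = {w: counts[i] for i, w in enumerate(lattice.words)}
        probs = _floor_and_renormalize(new)
        if prev is not None and abs(ll - prev) <= config.em_tol * abs(prev):
            break
        prev = ll
    return UnigramDictionary(entries=probs), trace


def prune_step(
    corpus,
    dictionary: UnigramDictionary,
    config: LexiconTrainConfig | None = None,
    min_keep: int | None = None,
) -> UnigramDictionary:
    """Remove low-loss words, keeping the top ``keep_fraction`` plus the
    protected mononucleotides.

    ``loss_i = L(dict) - L(dict without word i, renormalized)``, evaluated
    against the currently fitted probabilities (no per-candidate EM refit).
    Ties are broken by higher probability, then lexicographically.
    ``min_keep`` clamps the number of retained non-protected words from
    below, used to land exactly on the target size.
    """
    config = config or LexiconTrainConfig()
    seqs = _corpus_strings(corpus)
    lattice = _CorpusLattice(seqs, dictionary.words())
    logp = lattice.log_probs(dictionary)
    _, base_ll = lattice.forward(logp)
    base = float(base_ll.sum())

    cand = [
        (idx, w, dictionary.entries[w])
        for idx, w in enumerate(lattice.words)
        if w not in PROTECTED
    ]
    cand_ids = np.array([c[0] for c in cand], dtype=np.int64)
    # p_w clamped away from 1 so the renormalization shift stays finite when
    # one word has absorbed nearly all probability mass
    shifts = np.array([math.log1p(-min(c[2], 1.0 - 1e-15)) for c in cand])
    lls = lattice.candidate_lls(logp, cand_ids, shifts)
    losses: list[tuple[float, float, str]] = []
    for (idx, w, p_w), ll in zip(cand, lls):
        # -inf marks a removal that makes some sequence unsegmentable
        loss = math.inf if not np.isfinite(ll) else base - float(ll)
        losses.append((loss, p_w, w))

    n_nonprot = len(losses)
    n_keep = math.ceil(config.keep_fraction * n_nonprot)
    n_keep = min(n_keep, n_nonprot - 1)  # always drop at least one word
    if min_keep is not None:
        n_keep = max(n_keep, min_keep)
    n_keep = max(n_keep, 0)
    ranked = sorted(losses, key=lambda t: (-t[0], -t[1], t[2]))
    kept = {w for _, _, w in ranked[:n_keep]}
    new_probs = {
        w: p for w, p in dictionary.entries.items() if w in kept or w in PROTECTED
    }
    total = sum(new_probs.values())
    return UnigramDictionary(entries={w: p / total for w, p in new_probs.items()})


def learn_dictionary(
    corpus, config: LexiconTrainConfig | None = None
) -> UnigramDictionary:
    """BPE seed → iterate {EM fit, prune} until the target size → final EM.

    The last prune clamps the kept count so the result has exactly
    ``target_size`` words.  Deterministic for a given (corpus, config).
    """
    config = config or LexiconTrainConfig()
    if config.target_size > config.seed_size:
        raise ValueError("target_size must not exceed seed_size")
    dictionary = bpe_seed(corpus, config)
    while dictionary.size > config.target_size:
        dictionary, _ = em_fit(corpus, dictionary, config)
        remaining = config.target_size - len(PROTECTED)
        n_nonprot = dictionary.size - len(PROTECTED)
        min_keep = remaining if math.ceil(config.keep_fraction * n_nonprot) < remaining else None
        dictionary = prune_step(corpus, dictionary, config, min_keep=min_keep)
    dictionary, _ = em_fit(corpus, dictionary, config)
    return dictionary


def viterbi_segment(seq: DnaSequence, dictionary: UnigramDictionary) -> WordSequence:
    """Maximum-probability segmentation by left-to-right dynamic programming.

    Ties are broken by fewer words, then by the lexicographically smallest
    word sequence.  The protected mononucleotides guarantee a path exists.
    """
    r = seq.residues
    L = len(r)
    max_len = dictionary.max_word_length()
    entries = dictionary.entries
    # best[pos] = (score, n_words, words tuple) for residues[0:pos]
    best: list[tuple[float, int, tuple[str, ...]] | None] = [None] * (L + 1)
    best[0] = (0.0, 0, ())
    for pos in range(L):
        cur = best[pos]
        if cur is None:
            continue
        score, n_words, words = cur
        for l in range(1, min(max_len, L - pos) + 1):
            w = r[pos : pos + l]
            p = entries.get(w)
            if p is None:
                continue
            cand = (score + math.log(p), n_words + 1, words + (w,))
            old = best[pos + l]
            if (
                old is None
                or cand[0] > old[0]
                or (cand[0] == old[0] and cand[1] < old[1])
                or (cand[0] == old[0] and cand[1] == old[1] and cand[2] < old[2])
            ):
                best[pos + l] = cand
    final = best[L]
    assert final is not None, "protected mononucleotides guarantee a path"
    return WordSequence(words=final[2], source_id=seq.id, scheme=Scheme.STATISTICAL.value)
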