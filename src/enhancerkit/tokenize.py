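"""Deterministic n-gram word segmentation of DNA sequences.

Three schemes are provided:

* ``ov3`` — overlapped 3-gram: a width-3 window moved with stride 1.
* ``nov3`` — non-overlapped 3-gram: a width-3 window moved with stride 3
  from start offsets 1, 2 and 3 (1-based); the leading fragment of offsets
  2 and 3 and any trailing fragment are emitted as 1- or 2-letter words, so
  the dictionary holds 4 + 16 + 64 = 84 words.
* ``nov2`` — non-overlapped 2-gram, used to pre-segment sequences for the
  sequence GAN; odd lengths emit a trailing mononucleotide.

The statistical scheme (``stat``) has a learned dictionary; see
:mod:`enhancerkit.lexicon`.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path

from enhancerkit.seq_io import DnaSequence

_BASES = "ACGT"


class Scheme(str, enum.Enum):
    OVERLAPPED_3GRAM = "ov3"
    NON_OVERLAPPED_3GRAM = "nov3"
    NON_OVERLAPPED_2GRAM = "nov2"
    STATISTICAL = "stat"


@dataclass(frozen=True)
class WordSequence:
    """An ordered list of word tokens produced from one sequence."""

    words: tuple[str, ...]
    source_id: str
    scheme: str

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


@dataclass
class Vocabulary:
    """A dense bijection between words and integer indices in [0, V)."""

    word_to_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_words(cls, words: list[str]) -> "Vocabulary":
        if len(set(words)) != len(words):
            raise ValueError("vocabulary words must be unique")
        return cls(word_to_index={w: i for i, w in enumerate(words)})

    @property
    def size(self) -> int:
        return len(self.word_to_index)

    def __len__(self) -> int:
        return len(self.word_to_index)

    def __contains__(self, word: str) -> bool:
        return word in self.word_to_index

    def index(self, word: str) -> int:
        try:
            return self.word_to_index[word]
        except KeyError:
            raise KeyError(f"word {word!r} not in vocabulary") from None

    def words(self) -> list[str]:
        out = [""] * len(self.word_to_index)
        for w, i in self.word_to_index.items():
            out[i] = w
        return out

    def encode(self, words) -> list[int]:
        return [self.index(w) for w in words]

    def to_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            for w, i in sorted(self.word_to_index.items(), key=lambda kv: kv[1]):
                fh.write(f"{w}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: Path | str) -> "Vocabulary":
        mapping: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                word, idx = line.rstrip("\n").split("\t")
                mapping[word] = int(idx)
        indices = sorted(mapping.values())
        if indices != list(range(len(mapping))):
            raise ValueError("vocabulary indices must be dense 0..V-1")
        return cls(word_to_index=mapping)


def _require_length(seq: DnaSequence, minimum: int) -> None:
    if len(seq) < minimum:
        raise ValueError(
            f"sequence {seq.id!r} has length {len(seq)} < {minimum}"
        )


def overlapped_3gram(seq: DnaSequence) -> WordSequence:
    """Stride-1 trinucleotide words: word i = residues[i..i+2], L-2 words."""
    _require_length(seq, 3)
    r = seq.residues
    words = tuple(r[i : i + 3] for i in range(len(r) - 2))
    return WordSequence(words=words, source_id=seq.id, scheme=Scheme.OVERLAPPED_3GRAM.value)


def non_overlapped_3gram(seq: DnaSequence) -> tuple[WordSequence, WordSequence, WordSequence]:
    """Stride-3 segmentation from 1-based start offsets 1, 2 and 3.

    Offset k emits a leading fragment of length k-1 (when k > 1), then full
    trinucleotides, then any trailing fragment; concatenating each offset's
    words reconstructs the sequence.
    """
    _require_length(seq, 3)
    r = seq.residues
    out = []
    for k in (1, 2, 3):
        words: list[str] = []
        lead = k - 1
        if lead:
            words.append(r[:lead])
        pos = lead
        while pos + 3 <= len(r):
            words.append(r[pos : pos + 3])
            pos += 3
        if pos < len(r):
            words.append(r[pos:])
        out.append(
            WordSequence(
                words=tuple(words),
                source_id=seq.id,
                scheme=f"{Scheme.NON_OVERLAPPED_3GRAM.value}:offset{k}",
            )
        )
    return tuple(out)


def non_overlapped_3gram_concat(seq: DnaSequence) -> WordSequence:
    """The three offset segmentations concatenated in offset order 1‖2‖3.

    This keeps one word sequence (hence one embedding matrix) per input.
    """
    parts = non_overlapped_3gram(seq)
    words = tuple(itertools.chain.from_iterable(p.words for p in parts))
    return WordSequence(words=words, source_id=seq.id, scheme=Scheme.NON_OVERLAPPED_3GRAM.value)


def non_overlapped_2gram(seq: DnaSequence) -> WordSequence:
    """Stride-2 dinucleotide words; odd lengths get a trailing mononucleotide."""
    _require_length(seq, 2)
    r = seq.residues
    words = [r[i : i + 2] for i in range(0, len(r) - 1, 2)]
    if len(r) % 2:
        words.append(r[-1])
    return WordSequence(words=tuple(words), source_id=seq.id, scheme=Scheme.NON_OVERLAPPED_2GRAM.value)


def _enumerate_ngrams(n: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=n)]


def build_vocabulary(scheme: Scheme | str, dictionary=None) -> Vocabulary:
    """The word dictionary of a segmentation scheme.

    ``ov3`` → 64 trinucleotides; ``nov3`` → 4 + 16 + 64 = 84 words (sorted by
    length then lexicographically); ``nov2`` → 16 dinucleotides; ``stat`` →
    the words of the supplied learned dictionary.
    """
    scheme = Scheme(scheme)
    if scheme is Scheme.OVERLAPPED_3GRAM:
        return Vocabulary.from_words(_enumerate_ngrams(3))
    if scheme is Scheme.NON_OVERLAPPED_3GRAM:
        return Vocabulary.from_words(
            _enumerate_ngrams(1) + _enumerate_ngrams(2) + _enumerate_ngrams(3)
        )
    if scheme is Scheme.NON_OVERLAPPED_2GRAM:
        return Vocabulary.from_words(_enumerate_ngrams(2))
    if dictionary is None:
        raise ValueError("statistical scheme requires a learned dictionary")
    return Vocabulary.from_words(sorted(dictionary.words()))


def segment(seq: DnaSequence, scheme: Scheme | str, dictionary=None) -> WordSequence:
    """Dispatch to the scheme's segmenter (nov3 uses offset concatenation)."""
    scheme = Scheme(scheme)
    if scheme is Scheme.OVERLAPPED_3GRAM:
        return overlapped_3gram(seq)
    if scheme is Scheme.NON_OVERLAPPED_3GRAM:
        return non_overlapped_3gram_concat(seq)
    if scheme is Scheme.NON_OVERLAPPED_2GRAM:
        return non_overlapped_2gram(seq)
    from enhancerkit.lexicon import viterbi_segment

    if dictionary is None:
        raise ValueError("statistical scheme requires a learned dictionary")
    return viterbi_segment(seq, dictionary)


def write_word_file(word_seqs, path: Path | str) -> None:
    """One line per sequence: id then whitespace-joined words."""
    with open(path, "w") as fh:
        for ws in word_seqs:
            fh.write(ws.source_id + "\t" + " ".join(ws.words) + "\n")


def read_word_file(path: Path | str, scheme: str = "file") -> list[WordSequence]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            seq_id, _, rest = line.partition("\t")
            out.append(
                WordSequence(words=tuple(rest.split()), source_id=seq_id, scheme=scheme)
            )
    return out
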