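"""Benchmark-shaped synthetic datasets.

The simulator emulates the statistical structure of the 200-bp enhancer
benchmark: a negative class with elevated A/T frequency, a positive class
with near-uniform composition, and enhancer strength encoded as the dosage
of planted motif words (strong sequences carry more occurrences than weak
ones).  Motif words are drawn from the simulation seed so downstream tests
cannot overfit to a fixed motif.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from enhancerkit.seq_io import (
    Dataset,
    DnaSequence,
    EnhancerLabel,
    LabeledRecord,
    StrengthLabel,
)
from enhancerkit.tokenize import WordSequence

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_non: int = 1484
    n_strong: int = 742
    n_weak: int = 742
    length: int = 200
    at_bias: tuple[float, float, float, float] = (0.30, 0.20, 0.20, 0.30)  # A,C,G,T
    positive_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_words: list[str] | None = None  # default: drawn from the seed
    n_motifs: int = 2
    motif_length: int = 8
    strong_dosage: int = 6
    weak_dosage: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for comp in (self.at_bias, self.positive_composition):
            arr = np.asarray(comp)
            if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid composition {comp}")
        if self.strong_dosage < 0 or self.weak_dosage < 0:
            raise ValueError("dosages must be non-negative")
        if self.strong_dosage <= self.weak_dosage:
            raise ValueError("strong_dosage must exceed weak_dosage")


def benchmark_preset(seed: int = 0, scale: float = 1.0) -> SimulationConfig:
    """The 1484 non / 742 strong / 742 weak shape, optionally scaled down."""
    return SimulationConfig(
        n_non=max(2, round(1484 * scale)),
        n_strong=max(1, round(742 * scale)),
        n_weak=max(1, round(742 * scale)),
        seed=seed,
    )


def _random_seq(rng: np.random.Generator, length: int, comp) -> str:
    return "".join(rng.choice(_BASES, size=length, p=np.asarray(comp)))


def _plant_motifs(
    residues: str, motifs: list[str], dosage: int, rng: np.random.Generator
) -> str:
    """Overwrite `dosage` non-overlapping windows with motif words.

    Placements are drawn by distributing the leftover length randomly into
    the gaps around the motifs, which samples non-overlapping positions
    without rejection even when the packing is tight."""
    if dosage == 0:
        return residues
    L = len(residues)
    chosen = [motifs[int(rng.integers(len(motifs)))] for _ in range(dosage)]
    used = sum(len(m) for m in chosen)
    if used > L:
        raise ValueError("dosage x motif length exceeds sequence length")
    gaps = rng.multinomial(L - used, np.full(dosage + 1, 1.0 / (dosage + 1)))
    chars = list(residues)
    pos = 0
    for gap, motif in zip(gaps, chosen):
        pos += int(gap)
        chars[pos : pos + len(motif)] = motif
        pos += len(motif)
    return "".join(chars)


def simulate_dataset(config: SimulationConfig | None = None) -> Dataset:
    """Draw the synthetic two-layer dataset described in the module docstring."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    motifs = config.motif_words
    if motifs is None:
        motifs = [
            _random_seq(rng, config.motif_length, (0.25, 0.25, 0.25, 0.25))
            for _ in range(config.n_motifs)
        ]
    records = []
    for i in range(config.n_non):
        residues = _random_seq(rng, config.length, config.at_bias)
        records.append(
            LabeledRecord(
                sequence=DnaSequence(id=f"non{i}", residues=residues),
                enhancer_label=EnhancerLabel.NON_ENHANCER,
            )
        )
    for label, dosage, n, tag in (
        (StrengthLabel.STRONG, config.strong_dosage, config.n_strong, "strong"),
        (StrengthLabel.WEAK, config.weak_dosage, config.n_weak, "weak"),
    ):
        for i in range(n):
            residues = _random_seq(rng, config.length, config.positive_composition)
            residues = _plant_motifs(residues, motifs, dosage, rng)
            records.append(
                LabeledRecord(
                    sequence=DnaSequence(id=f"{tag}{i}", residues=residues),
                    enhancer_label=EnhancerLabel.ENHANCER,
                    strength_label=label,
                )
            )
    return Dataset(records=records)


def simulate_token_corpus(
    vocab_size: int,
    n: int,
    length: int,
    seed: int = 0,
    cooccur_pairs: dict[tuple[str, str], float] | None = None,
    composition: np.ndarray | None = None,
) -> list[WordSequence]:
    """Abstract token sequences (words ``w0..w{V-1}``) for embedding and GAN
    unit tests.

    ``cooccur_pairs`` maps (P, Q) to the probability that Q immediately
    follows each emission of P; ``composition`` overrides the uniform token
    distribution.
    """
    rng = np.random.default_rng(seed)
    words = [f"w{i}" for i in range(vocab_size)]
    probs = (
        np.full(vocab_size, 1.0 / vocab_size)
        if composition is None
        else np.asarray(composition, dtype=float)
    )
    if len(probs) != vocab_size or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a length-V probability vector")
    follow = {p: (q, prob) for (p, q), prob in (cooccur_pairs or {}).items()}
    out = []
    for i in range(n):
        toks: list[str] = []
        while len(toks) < length:
            if toks and toks[-1] in follow:
                q, prob = follow[toks[-1]]
                if rng.random() < prob:
                    toks.append(q)
                    continue
            toks.append(words[int(rng.integers(vocab_size)) if composition is None
                              else int(rng.choice(vocab_size, p=probs))])
        out.append(WordSequence(words=tuple(toks[:length]), source_id=f"t{i}", scheme="synthetic"))
    return out
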