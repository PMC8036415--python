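"""Evaluation: confusion metrics (Acc/Sn/Sp/MCC), leakage-safe stratified
k-fold cross-validation with optional GAN augmentation, and real-vs-generated
sequence analytics (nucleotide composition and trinucleotide physicochemical
profiles).

Only real records are ever evaluated; generated records may join training
folds but a leakage audit asserts they never reach a test fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from enhancerkit.classifier import CnnConfig, train_classifier
from enhancerkit.embed import SgnsTrainConfig, embed_sequence, train_skipgram
from enhancerkit.lexicon import LexiconTrainConfig, learn_dictionary
from enhancerkit.seq_io import (
    Dataset,
    DnaSequence,
    EnhancerLabel,
    LabeledRecord,
    Layer,
    Provenance,
    StrengthLabel,
)
from enhancerkit.seqgan import (
    Discriminator,
    GanTrainConfig,
    GeneratorPolicy,
    RolloutConfig,
    adversarial_train,
    generate_sequences,
    pretrain_generator,
    redundancy_filter,
    sequences_to_token_ids,
)
from enhancerkit.tokenize import Scheme, build_vocabulary, segment


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sn: float
    sp: float
    mcc: float
    mcc_undefined: bool = False  # denominator was zero; mcc reported as 0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Acc, Sn, Sp and MCC from a confusion table.

    A zero MCC denominator is reported as MCC = 0 with ``mcc_undefined``."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return MetricSet(acc, sn, sp, 0.0, mcc_undefined=True)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricSet(acc, sn, sp, mcc)


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    folds: list[list[str]]
    seed: int
    stratified: bool


def make_cv_plan(
    dataset: Dataset, k: int = 10, seed: int = 0, stratified: bool = True
) -> CvPlan:
    """Disjoint, exhaustive folds over the real records, stratified by the
    layer's binary class; deterministic for a given seed."""
    records = dataset.real_records()
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    if stratified:
        groups: dict[int, list[str]] = {}
        for rec in records:
            groups.setdefault(dataset.binary_label(rec), []).append(rec.id)
        for label in sorted(groups):
            ids = groups[label]
            if k > len(ids):
                raise ValueError(f"k={k} exceeds class size {len(ids)}")
            order = rng.permutation(len(ids))
            for pos, idx in enumerate(order):
                folds[pos % k].append(ids[idx])
    else:
        ids = [r.id for r in records]
        if k > len(ids):
            raise ValueError(f"k={k} exceeds dataset size {len(ids)}")
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            folds[pos % k].append(ids[idx])
    return CvPlan(folds=folds, seed=seed, stratified=stratified)


# ---------------------------------------------------------------------------
# Fold pipeline: segment -> embed -> CNN (optionally GAN-augmented)
# ---------------------------------------------------------------------------


@dataclass
class CvPipelineConfig:
    """Everything one fold needs to fit a classifier from raw records."""

    scheme: Scheme | str = Scheme.OVERLAPPED_3GRAM
    embed_dim: int = 32
    sgns: SgnsTrainConfig = field(
        default_factory=lambda: SgnsTrainConfig(window=4, negatives=5, epochs=2)
    )
    embed_corpus: str = "positives"  # or "all"
    cnn: CnnConfig | None = None
    lexicon: LexiconTrainConfig | None = None  # for the statistical scheme
    augment: bool = False
    n_generate: int = 200  # per class
    gan: GanTrainConfig = field(
        default_factory=lambda: GanTrainConfig(
            pretrain_epochs=2, adv_rounds=1, g_steps=1, d_steps=1, batch_size=16
        )
    )
    rollout: RolloutConfig = field(default_factory=lambda: RolloutConfig(n_rollouts=2))
    gan_hidden: int = 16
    gan_embed_dim: int = 8
    redundancy_cutoff: float = 0.80
    fast: bool = False  # fit dictionary/embeddings once on all records
    seed: int = 0

    def resolved_cnn(self) -> CnnConfig:
        if self.cnn is not None:
            return self.cnn
        # desk-scale defaults: small nets, no early stopping (validation
        # splits of a handful of records stop training far too early)
        return CnnConfig(
            embed_dim=self.embed_dim,
            kernels_per_height=32,
            epochs=60,
            batch_size=16,
            dropout=0.25,
            learning_rate=1e-2,
            validation_fraction=0.0,
            seed=self.seed,
        )


def _class_tag(rec: LabeledRecord) -> str:
    if rec.enhancer_label is EnhancerLabel.NON_ENHANCER:
        return "non_enhancer"
    return "strong" if rec.strength_label is StrengthLabel.STRONG else "weak"


def _augment_records(
    train_records: list[LabeledRecord], cfg: CvPipelineConfig, fold_seed: int
) -> list[LabeledRecord]:
    """Train one GAN per class on the fold's training records and return
    redundancy-filtered generated records."""
    by_class: dict[str, list[LabeledRecord]] = {}
    for rec in train_records:
        by_class.setdefault(_class_tag(rec), []).append(rec)
    out: list[LabeledRecord] = []
    for tag in sorted(by_class):
        recs = by_class[tag]
        token_ids = sequences_to_token_ids([r.sequence for r in recs])
        horizon = token_ids.shape[1]
        gen = GeneratorPolicy(
            horizon=horizon,
            hidden_size=cfg.gan_hidden,
            embed_dim=cfg.gan_embed_dim,
            seed=fold_seed,
        )
        disc = Discriminator(
            vocab_size=gen.V, embed_dim=cfg.gan_embed_dim, kernels_per_height=8,
            seed=fold_seed + 1,
        )
        gan_cfg = replace(cfg.gan, seed=fold_seed, class_tag=tag)
        pretrain_generator(token_ids, gen, gan_cfg)
        rng = np.random.default_rng(fold_seed)
        adversarial_train(token_ids, gen, disc, gan_cfg, cfg.rollout, rng)
        seqs = generate_sequences(gen, cfg.n_generate, f"{tag}_f{fold_seed}", rng)
        seqs = redundancy_filter(seqs, cutoff=cfg.redundancy_cutoff)
        for s in seqs:
            if tag == "non_enhancer":
                enh, strength = EnhancerLabel.NON_ENHANCER, StrengthLabel.NOT_APPLICABLE
            else:
                enh = EnhancerLabel.ENHANCER
                strength = StrengthLabel.STRONG if tag == "strong" else StrengthLabel.WEAK
            out.append(
                LabeledRecord(
                    sequence=s,
                    enhancer_label=enh,
                    strength_label=strength,
                    provenance=Provenance.GENERATED,
                )
            )
    return out


class FoldModel:
    """Segmentation context + embeddings + classifier fitted on one fold."""

    def __init__(
        self,
        cfg: CvPipelineConfig,
        dataset: Dataset,
        train_records: list[LabeledRecord],
        fold_seed: int,
        shared: dict | None = None,
    ):
        self.cfg = cfg
        self.dataset = dataset
        shared = shared or {}
        self.trained_on_ids = {r.id for r in train_records}

        if cfg.augment:
            generated = _augment_records(train_records, cfg, fold_seed)
            train_records = list(train_records) + generated

        scheme = Scheme(cfg.scheme)
        if scheme is Scheme.STATISTICAL:
            self.dictionary = shared.get("dictionary") or learn_dictionary(
                [r.sequence for r in train_records if r.provenance is Provenance.REAL],
                cfg.lexicon or LexiconTrainConfig(target_size=40, seed_size=100),
            )
            self.vocab = build_vocabulary(scheme, self.dictionary)
        else:
            self.dictionary = None
            self.vocab = build_vocabulary(scheme)
        self.scheme = scheme

        words_train = [
            segment(r.sequence, scheme, self.dictionary) for r in train_records
        ]
        if "max_words" in shared:
            self.max_words = shared["max_words"]
        else:
            longest = max(len(w) for w in words_train)
            self.max_words = (
                int(longest * 1.1) + 1 if scheme is Scheme.STATISTICAL else longest
            )

        if "embedding" in shared:
            self.embedding = shared["embedding"]
        else:
            if cfg.embed_corpus == "all":
                corpus = words_train
            elif cfg.embed_corpus == "real_positives":
                corpus = [
                    ws
                    for ws, r in zip(words_train, train_records)
                    if self.dataset.binary_label(r) == 1
                    and r.provenance is Provenance.REAL
                ]
            else:  # "positives": positive-class sequences incl. generated
                corpus = [
                    ws
                    for ws, r in zip(words_train, train_records)
                    if self.dataset.binary_label(r) == 1
                ]
            sgns = replace(cfg.sgns, seed=fold_seed)
            self.embedding = train_skipgram(corpus, self.vocab, sgns, dim=cfg.embed_dim)

        pairs = [
            (
                embed_sequence(ws, self.embedding, self.max_words),
                self.dataset.binary_label(r),
            )
            for ws, r in zip(words_train, train_records)
        ]
        cnn_cfg = replace(cfg.resolved_cnn(), seed=fold_seed, embed_dim=cfg.embed_dim)
        self.classifier = train_classifier(pairs, cnn_cfg)

    def predict(self, records: list[LabeledRecord]) -> np.ndarray:
        mats = [
            embed_sequence(
                segment(r.sequence, self.scheme, self.dictionary),
                self.embedding,
                self.max_words,
            )
            for r in records
        ]
        X = np.stack([m.rows for m in mats])
        return self.classifier.predict(X)


@dataclass
class CvResult:
    pooled: MetricSet
    per_fold: pd.DataFrame
    counts: ConfusionCounts
    audit: dict


class LeakageError(RuntimeError):
    pass


def run_cv(
    dataset: Dataset,
    cfg: CvPipelineConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold CV with per-fold fitting of every pipeline stage.

    Generated sequences join training folds only; metrics pool the held-out
    real records.  A leakage audit aborts the run if a generated record or a
    test record ever enters the wrong side of a fold."""
    cfg = cfg or CvPipelineConfig()
    plan = make_cv_plan(dataset, k=k, seed=seed)
    by_id = {r.id: r for r in dataset.real_records()}

    shared: dict | None = None
    if cfg.fast:
        warm = FoldModel(cfg, dataset, dataset.real_records(), fold_seed=seed, shared=None)
        shared = {
            "embedding": warm.embedding,
            "max_words": warm.max_words,
            "dictionary": warm.dictionary,
        }

    total = ConfusionCounts(0, 0, 0, 0)
    rows = []
    fold_logs = []
    for fold_idx, test_ids in enumerate(plan.folds):
        test_set = set(test_ids)
        train_records = [r for r in dataset.real_records() if r.id not in test_set]
        test_records = [by_id[i] for i in test_ids]
        model = FoldModel(
            cfg, dataset, train_records, fold_seed=seed * 1000 + fold_idx, shared=shared
        )
        if model.trained_on_ids & test_set:
            raise LeakageError(f"fold {fold_idx}: test records used in training")
        for rec in test_records:
            if rec.provenance is not Provenance.REAL:
                raise LeakageError(f"fold {fold_idx}: generated record in test fold")
        preds = model.predict(test_records)
        labels = np.array([dataset.binary_label(r) for r in test_records])
        counts = ConfusionCounts(
            tp=int(((preds == 1) & (labels == 1)).sum()),
            fp=int(((preds == 1) & (labels == 0)).sum()),
            tn=int(((preds == 0) & (labels == 0)).sum()),
            fn=int(((preds == 0) & (labels == 1)).sum()),
        )
        total = total + counts
        m = compute_metrics(counts)
        rows.append(
            {
                "fold": fold_idx,
                "n": counts.total,
                "acc": m.acc,
                "sn": m.sn,
                "sp": m.sp,
                "mcc": m.mcc,
            }
        )
        fold_logs.append(
            {"fold": fold_idx, "test_ids": list(test_ids), "train_ids": sorted(model.trained_on_ids)}
        )

    audit = audit_fold_logs(fold_logs, {r.id for r in dataset.real_records()})
    if total.total != len(dataset.real_records()):
        raise LeakageError("evaluated-record count differs from real-record count")
    return CvResult(
        pooled=compute_metrics(total),
        per_fold=pd.DataFrame(rows),
        counts=total,
        audit=audit,
    )


def audit_fold_logs(fold_logs: list[dict], real_ids: set[str]) -> dict:
    """Independent re-check of fold logs: folds partition the real ids and no
    fold's training set intersects its test set."""
    seen: set[str] = set()
    for entry in fold_logs:
        test = set(entry["test_ids"])
        if test & seen:
            raise LeakageError("folds are not disjoint")
        if test & set(entry["train_ids"]):
            raise LeakageError("train/test overlap inside a fold")
        if not test <= real_ids:
            raise LeakageError("non-real record in a test fold")
        seen |= test
    if seen != real_ids:
        raise LeakageError("folds do not cover every real record")
    return {"n_folds": len(fold_logs), "n_records": len(seen), "passed": True}


# ---------------------------------------------------------------------------
# Composition and physicochemical profiles
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class PropertyTable:
    """64 trinucleotides x named physicochemical property columns."""

    values: dict[str, np.ndarray]
    names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != 64:
            raise ValueError(f"property table has {len(self.values)} rows, needs 64")
        for tri, row in self.values.items():
            if len(row) != len(self.names) or not np.isfinite(row).all():
                raise ValueError(f"bad property row for {tri!r}")

    @classmethod
    def from_tsv(cls, path) -> "PropertyTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        names = list(df.columns)
        values = {tri: row.to_numpy(dtype=float) for tri, row in df.iterrows()}
        return cls(values=values, names=names)


def load_default_property_table() -> PropertyTable:
    """The bundled trinucleotide table: nearest-neighbor duplex
    thermodynamics plus composition fractions (a documented stand-in; any
    5-column table can replace it)."""
    ref = resources.files("enhancerkit.data") / "trinucleotide_properties.tsv"
    with resources.as_file(ref) as path:
        return PropertyTable.from_tsv(path)


def composition_profile(sequences) -> np.ndarray:
    """Pooled A/C/G/T frequencies over all sequences (sums to 1)."""
    seqs = [s.residues if isinstance(s, DnaSequence) else str(s) for s in sequences]
    if not seqs:
        raise ValueError("no sequences")
    counts = np.zeros(4)
    for s in seqs:
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    return counts / counts.sum()


def physchem_profile(sequences, table: PropertyTable) -> np.ndarray:
    """Mean of each property over every overlapping trinucleotide window."""
    seqs = [s.residues if isinstance(s, DnaSequence) else str(s) for s in sequences]
    total = np.zeros(len(table.names))
    n = 0
    for s in seqs:
        for i in range(len(s) - 2):
            tri = s[i : i + 3]
            if tri not in table.values:
                raise KeyError(f"trinucleotide {tri!r} missing from property table")
            total += table.values[tri]
            n += 1
    if n == 0:
        raise ValueError("no trinucleotide windows (sequences shorter than 3?)")
    return total / n


def compare_real_generated(real, generated, table: PropertyTable | None = None) -> pd.DataFrame:
    """Plot-ready table of composition and property profiles for both sets
    plus absolute differences (4 composition rows + one row per property)."""
    table = table or load_default_property_table()
    comp_r, comp_g = composition_profile(real), composition_profile(generated)
    prop_r, prop_g = physchem_profile(real, table), physchem_profile(generated, table)
    rows = []
    for i, b in enumerate(BASES):
        rows.append(
            {
                "kind": "composition",
                "feature": b,
                "real": comp_r[i],
                "generated": comp_g[i],
                "abs_difference": abs(comp_r[i] - comp_g[i]),
            }
        )
    for i, name in enumerate(table.names):
        rows.append(
            {
                "kind": "property",
                "feature": name,
                "real": prop_r[i],
                "generated": prop_g[i],
                "abs_difference": abs(prop_r[i] - prop_g[i]),
            }
        )
    return pd.DataFrame(rows)


def write_comparison_report(df: pd.DataFrame, path: Path | str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
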