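"""Reading, writing and validation of labeled DNA sequence datasets.

Sequences are plain A/C/G/T strings (uppercased on input, ambiguity codes
rejected).  Class labels are conveyed either by per-class FASTA files (one
label for the whole file) or by a TSV labels table with columns
``id<TAB>enhancer_label<TAB>strength_label``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

_ALPHABET = frozenset("ACGT")
_FASTA_LINE_WIDTH = 60


class EnhancerLabel(str, enum.Enum):
    ENHANCER = "enhancer"
    NON_ENHANCER = "non_enhancer"


class StrengthLabel(str, enum.Enum):
    STRONG = "strong"
    WEAK = "weak"
    NOT_APPLICABLE = "not_applicable"


class Provenance(str, enum.Enum):
    REAL = "real"
    GENERATED = "generated"


class Layer(str, enum.Enum):
    FIRST = "first"
    SECOND = "second"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input or invalid residues."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence over the four-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise FastaParseError(
                f"sequence {self.id!r} contains non-ACGT characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledRecord:
    """A DNA sequence with two-layer class labels and provenance."""

    sequence: DnaSequence
    enhancer_label: EnhancerLabel
    strength_label: StrengthLabel = StrengthLabel.NOT_APPLICABLE
    provenance: Provenance = Provenance.REAL

    def __post_init__(self) -> None:
        if (
            self.enhancer_label is EnhancerLabel.NON_ENHANCER
            and self.strength_label is not StrengthLabel.NOT_APPLICABLE
        ):
            raise ValueError(
                f"record {self.sequence.id!r}: strength label "
                f"{self.strength_label.value!r} requires enhancer_label=enhancer"
            )

    @property
    def id(self) -> str:
        return self.sequence.id


@dataclass
class Dataset:
    """An ordered collection of labeled records, optionally bound to a layer.

    For ``layer=first`` the binary target is enhancer vs non-enhancer; for
    ``layer=second`` only enhancers are present and the target is strong vs
    weak.
    """

    records: list[LabeledRecord] = field(default_factory=list)
    layer: Layer | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in dataset")
            seen.add(rec.id)
        if self.layer is Layer.SECOND:
            for rec in self.records:
                if rec.enhancer_label is not EnhancerLabel.ENHANCER:
                    raise ValueError(
                        "second-layer dataset must contain only enhancers"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LabeledRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> LabeledRecord:
        return self.records[i]

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def real_records(self) -> list[LabeledRecord]:
        return [r for r in self.records if r.provenance is Provenance.REAL]

    def binary_label(self, rec: LabeledRecord) -> int:
        """1 for the positive class of the bound layer, 0 otherwise."""
        if self.layer is None:
            raise ValueError("dataset is not bound to a layer")
        if self.layer is Layer.FIRST:
            return int(rec.enhancer_label is EnhancerLabel.ENHANCER)
        return int(rec.strength_label is StrengthLabel.STRONG)


@dataclass(frozen=True)
class LabelSpec:
    """How to assign class labels to the records of one FASTA file.

    Either fixed labels for the whole file, or a ``table_path`` pointing at a
    TSV with ``id<TAB>enhancer_label<TAB>strength_label`` rows.
    """

    enhancer_label: EnhancerLabel | None = None
    strength_label: StrengthLabel = StrengthLabel.NOT_APPLICABLE
    provenance: Provenance = Provenance.REAL
    table_path: Path | str | None = None


def _read_labels_table(path: Path | str) -> dict[str, tuple[EnhancerLabel, StrengthLabel]]:
    table: dict[str, tuple[EnhancerLabel, StrengthLabel]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            seq_id, enh, strength = parts
            table[seq_id] = (EnhancerLabel(enh), StrengthLabel(strength))
    return table


def read_fasta(path: Path | str, label_spec: LabelSpec) -> Dataset:
    """Read a FASTA file into a :class:`Dataset`.

    Residues are uppercased; any character outside {A,C,G,T} (including N)
    raises :class:`FastaParseError` naming the offending record.  Duplicate
    ids raise ``ValueError``.
    """
    path = Path(path)
    table = _read_labels_table(label_spec.table_path) if label_spec.table_path else None

    records: list[LabeledRecord] = []
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(
                f"{path}:1: expected FASTA header starting with '>', "
                f"got {first.strip()!r}"
            )
        fh.seek(0)
        for header, seq in SimpleFastaParser(fh):
            seq_id = header.split()[0] if header.split() else ""
            if not seq_id:
                raise FastaParseError(f"{path}: empty FASTA header")
            dna = DnaSequence(id=seq_id, residues=seq.upper())
            if table is not None:
                if seq_id not in table:
                    raise ValueError(
                        f"{path}: id {seq_id!r} missing from labels table"
                    )
                enh, strength = table[seq_id]
            else:
                if label_spec.enhancer_label is None:
                    raise ValueError(
                        "label_spec must set enhancer_label or table_path"
                    )
                enh, strength = label_spec.enhancer_label, label_spec.strength_label
            records.append(
                LabeledRecord(
                    sequence=dna,
                    enhancer_label=enh,
                    strength_label=strength,
                    provenance=label_spec.provenance,
                )
            )
    return Dataset(records=records)


def write_fasta(records: Iterable[LabeledRecord] | Dataset, path: Path | str) -> None:
    """Write records as FASTA, 60 characters per body line.

    Round-trips exactly through :func:`read_fasta` (ids and residues)."""
    recs = list(records.records if isinstance(records, Dataset) else records)
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.sequence.id}\n")
            body = rec.sequence.residues
            for i in range(0, len(body), _FASTA_LINE_WIDTH):
                fh.write(body[i : i + _FASTA_LINE_WIDTH] + "\n")


def write_labels_table(records: Iterable[LabeledRecord] | Dataset, path: Path | str) -> None:
    recs = list(records.records if isinstance(records, Dataset) else records)
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(
                f"{rec.id}\t{rec.enhancer_label.value}\t{rec.strength_label.value}\n"
            )


def build_layer_dataset(
    records: Iterable[LabeledRecord] | Dataset, layer: Layer | str
) -> Dataset:
    """Assemble the dataset for one layer of the two-layer scheme.

    First layer keeps everything (enhancer vs non-enhancer target); second
    layer keeps only enhancers (strong vs weak target).
    """
    layer = Layer(layer)
    recs = list(records.records if isinstance(records, Dataset) else records)
    if layer is Layer.FIRST:
        return Dataset(records=recs, layer=layer)
    enhancers = [
        r for r in recs if r.enhancer_label is EnhancerLabel.ENHANCER
    ]
    if not enhancers:
        raise ValueError("second layer requested but dataset has no enhancers")
    for r in enhancers:
        if r.strength_label is StrengthLabel.NOT_APPLICABLE:
            raise ValueError(
                f"record {r.id!r} lacks a strength label required for layer 2"
            )
    return Dataset(records=enhancers, layer=layer)


def relabel_provenance(record: LabeledRecord, provenance: Provenance) -> LabeledRecord:
    return replace(record, provenance=provenance)
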