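"""Peptide FASTA reading/writing, labeled-dataset assembly and splitting.

Datasets follow the positive/negative FASTA-pair convention used by public
anticancer-peptide benchmarks: one file of experimentally supported ACPs
(label 1) and one file of non-ACPs (label 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.model_selection import train_test_split

from .tables import ALPHABET

logger = logging.getLogger(__name__)

_CANONICAL = frozenset(ALPHABET)


class SequenceValidationError(ValueError):
    """Raised when a sequence contains a non-canonical residue."""

    def __init__(self, residue: str, position: int, context: str = ""):
        self.residue = residue
        self.position = position  # 1-based
        where = f" in {context!r}" if context else ""
        super().__init__(
            f"non-canonical residue {residue!r} at position {position}{where}; "
            f"allowed alphabet is {ALPHABET}"
        )


def validate_sequence(seq: str, context: str = "") -> str:
    """Return the canonical (stripped, upper-cased) form of ``seq``.

    Raises :class:`SequenceValidationError` identifying the first offending
    character and its 1-based position if any residue falls outside the
    20-letter alphabet, and ``ValueError`` on an empty sequence.
    """
    canonical = "".join(seq.split()).upper()
    if not canonical:
        raise ValueError("empty sequence" + (f" for {context!r}" if context else ""))
    for pos, ch in enumerate(canonical, start=1):
        if ch not in _CANONICAL:
            raise SequenceValidationError(ch, pos, context)
    return canonical


@dataclass(frozen=True)
class Peptide:
    """A validated peptide: identifier, canonical sequence, optional label."""

    id: str
    seq: str
    label: int | None = None  # 1 = ACP, 0 = non-ACP

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled peptides."""

    peptides: list[Peptide]
    name: str = ""

    def __post_init__(self) -> None:
        for p in self.peptides:
            if p.label not in (0, 1):
                raise ValueError(f"peptide {p.id!r} has no binary label")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    @property
    def n_positive(self) -> int:
        return sum(p.label == 1 for p in self.peptides)

    @property
    def n_negative(self) -> int:
        return sum(p.label == 0 for p in self.peptides)

    def class_counts(self) -> tuple[int, int]:
        """(#positive, #negative)."""
        return self.n_positive, self.n_negative


@dataclass(frozen=True)
class SplitSpec:
    """How to partition a labeled dataset into train/validation folds."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def read_fasta(path: str | Path, skip_invalid: bool = False) -> list[Peptide]:
    """Read a FASTA file into unlabeled :class:`Peptide` records.

    Order is preserved and sequences are validated/upper-cased. With
    ``skip_invalid`` records with non-canonical residues are dropped with a
    logged warning instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        if not raw:
            raise ValueError(f"record {record.id!r} in {path} has an empty sequence")
        try:
            seq = validate_sequence(raw, context=record.id)
        except SequenceValidationError:
            if skip_invalid:
                logger.warning("skipping invalid record %r in %s", record.id, path)
                continue
            raise
        peptides.append(Peptide(id=record.id, seq=seq))
    if not peptides:
        raise ValueError(f"no sequence records in {path}")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides to a FASTA file (one line per sequence)."""
    records = [
        SeqRecord(Seq(p.seq), id=p.id, description="") for p in peptides
    ]
    SeqIO.write(records, str(Path(path)), "fasta-2line")


def _dedupe_ids(
    peptides: Sequence[Peptide], on_duplicate: str
) -> list[Peptide]:
    seen: dict[str, int] = {}
    out: list[Peptide] = []
    for p in peptides:
        if p.id in seen:
            if on_duplicate == "error":
                raise ValueError(f"duplicate peptide id {p.id!r}")
            seen[p.id] += 1
            new_id = f"{p.id}_{seen[p.id]}"
            logger.warning("duplicate id %r renamed to %r", p.id, new_id)
            out.append(replace(p, id=new_id))
        else:
            seen[p.id] = 0
            out.append(p)
    return out


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    name: str = "",
    skip_invalid: bool = False,
    on_duplicate: str = "rename",
) -> LabeledDataset:
    """Assemble a labeled dataset from a positive/negative FASTA pair.

    Positives get label 1, negatives label 0. Duplicate identifiers across
    the two files are auto-suffixed with a warning by default
    (``on_duplicate="error"`` to fail instead).
    """
    if on_duplicate not in ("rename", "error"):
        raise ValueError(f"unknown duplicate policy {on_duplicate!r}")
    positives = [
        replace(p, label=1) for p in read_fasta(pos_path, skip_invalid=skip_invalid)
    ]
    negatives = [
        replace(p, label=0) for p in read_fasta(neg_path, skip_invalid=skip_invalid)
    ]
    if not positives:
        raise ValueError("no positive samples")
    if not negatives:
        raise ValueError("no negative samples")
    peptides = _dedupe_ids(positives + negatives, on_duplicate)
    ds = LabeledDataset(peptides=peptides, name=name or Path(pos_path).stem)
    logger.info(
        "loaded %s: %d positives, %d negatives", ds.name, ds.n_positive, ds.n_negative
    )
    return ds


def split(
    dataset: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledDataset, LabeledDataset]:
    """Partition a dataset into train/validation folds.

    Deterministic under ``spec.seed``; stratified by label by default so the
    class ratio is preserved to within one sample per class.
    """
    labels = [p.label for p in dataset]
    if spec.stratified and (sum(labels) == 0 or sum(labels) == len(labels)):
        raise ValueError("stratified split needs at least one member of each class")
    idx = list(range(len(dataset)))
    train_idx, val_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=labels if spec.stratified else None,
        shuffle=True,
    )
    train = LabeledDataset(
        [dataset.peptides[i] for i in sorted(train_idx)], name=f"{dataset.name}-train"
    )
    val = LabeledDataset(
        [dataset.peptides[i] for i in sorted(val_idx)], name=f"{dataset.name}-val"
    )
    return train, val
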