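"""Peptide sequence I/O, validation and dataset-hygiene checks.

Reads and writes FASTA plus a two-column label table, validates sequences
against the 20-letter amino-acid alphabet, and checks the curation property
that no two peptides share >= 70% global-alignment identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import Align

#: The 20 standard one-letter amino-acid codes, in fixed alphabetical order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

ANTI = "ANTI"
NON_ANTI = "NON_ANTI"
LABELS = (ANTI, NON_ANTI)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class PeptideRecord:
    """A single peptide: unique id plus an uppercase amino-acid sequence."""

    id: str
    sequence: str


@dataclass
class ValidationVerdict:
    valid: bool
    reason: str | None = None


@dataclass
class LabeledDataset:
    """Peptide records together with a binary activity label per id.

    Invariants: record ids are unique and the label map keys coincide
    exactly with the record ids; labels take values "ANTI" or "NON_ANTI".
    """

    records: list[PeptideRecord]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate record id {dup!r}")
        if set(ids) != set(self.labels):
            missing = set(ids) ^ set(self.labels)
            raise ValueError(f"record ids and label ids disagree: {sorted(missing)}")
        bad = {v for v in self.labels.values()} - set(LABELS)
        if bad:
            raise ValueError(f"unknown label values {sorted(bad)}; expected {LABELS}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_vector(self) -> list[str]:
        """Labels in record order."""
        return [self.labels[r.id] for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts = {ANTI: 0, NON_ANTI: 0}
        for v in self.labels.values():
            counts[v] += 1
        return counts


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Parse a FASTA file into peptide records.

    Sequences are uppercased and whitespace-stripped; the id is the first
    whitespace-delimited token of the header. Raises :class:`FastaParseError`
    naming the line number for a sequence line before any header or an
    entry with no sequence.
    """
    path = Path(path)
    records: list[PeptideRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"line {header_line}: entry {header!r} has no sequence")
        records.append(PeptideRecord(id=header, sequence=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.upper())
        flush()
    return records


def write_fasta(records: Iterable[PeptideRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence line per record)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a label table: CSV/TSV with header columns id,label."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None or {"id", "label"} - set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns 'id' and 'label'")
        for row in reader:
            labels[row["id"]] = row["label"]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label"])
        for pid, lab in labels.items():
            writer.writerow([pid, lab])


def labels_from_headers(records: Iterable[PeptideRecord]) -> dict[str, str]:
    """Fallback label convention: id suffix "|ANTI" or "|NON_ANTI"."""
    labels = {}
    for rec in records:
        if "|" not in rec.id:
            raise ValueError(f"record {rec.id!r} has no '|LABEL' suffix")
        _, lab = rec.id.rsplit("|", 1)
        labels[rec.id] = lab
    return labels


def validate_record(record: PeptideRecord) -> ValidationVerdict:
    """Verdict on sequence nomenclature: 20-letter alphabet, length >= 2."""
    seq = record.sequence
    if len(seq) < 2:
        return ValidationVerdict(False, f"length {len(seq)} < 2")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_SET:
            return ValidationVerdict(False, f"invalid character {ch!r} at position {pos}")
    return ValidationVerdict(True)


def filter_valid(dataset: LabeledDataset) -> tuple[LabeledDataset, list[tuple[str, str]]]:
    """Drop records that fail :func:`validate_record`.

    Returns the cleaned dataset and a rejection log of (id, reason) pairs.
    Raises if nothing survives, since an empty dataset is unusable downstream.
    """
    kept: list[PeptideRecord] = []
    log: list[tuple[str, str]] = []
    for rec in dataset.records:
        verdict = validate_record(rec)
        if verdict.valid:
            kept.append(rec)
        else:
            log.append((rec.id, verdict.reason or "invalid"))
    if not kept:
        raise ValueError("all records invalid; empty dataset is unusable")
    labels = {r.id: dataset.labels[r.id] for r in kept}
    return LabeledDataset(records=kept, labels=labels), log


def _aligner() -> Align.PairwiseAligner:
    # Needleman-Wunsch with match=1, mismatch=0, linear gap -1.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: PeptideRecord, b: PeptideRecord) -> float:
    """Fraction of identical aligned positions under global alignment.

    Identity = matches / alignment length (gap columns included in the
    length), so it lies in [0, 1] and equals 1 only for identical sequences.
    """
    aln = _aligner().align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def max_identity_check(
    dataset: LabeledDataset, threshold: float = 0.70
) -> list[tuple[str, str, float]]:
    """All unordered record pairs with identity >= threshold (inclusive).

    An empty report means the dataset satisfies the curation rule that no
    two peptides are 70%-or-more identical.
    """
    if len(dataset) < 2:
        raise ValueError("need at least 2 records to compare")
    offenders = []
    recs = dataset.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            ident = pairwise_identity(recs[i], recs[j])
            if ident >= threshold:
                offenders.append((recs[i].id, recs[j].id, ident))
    return offenders
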