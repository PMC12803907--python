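"""Protein sequence I/O: FASTA reading/writing, validation, deduplication, labels.

Input corpora are plain amino-acid FASTA files, optionally accompanied by a
two-column TSV (``id<TAB>family``) assigning each sequence to a transcription-
factor family. Validation keeps only sequences over the 20-letter standard
alphabet (a permissive mode tolerates ambiguity codes such as B/J/O/U/X/Z, whose
residues simply never contribute a valid k-mer window downstream), and exact
duplicate sequences are collapsed to their first occurrence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered. This string is the
#: canonical alphabet for validation and for k-mer vocabulary ordering.
STANDARD_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD_SET = frozenset(STANDARD_ALPHABET)


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed (sequence data before any header)."""


class LabelTableError(ValueError):
    """Raised for an invalid id->family label table (e.g. duplicate ids)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with an identifier and an optional family label."""

    id: str
    sequence: str
    family: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")


@dataclass
class LabeledCorpus:
    """An ordered, deduplicated collection of :class:`ProteinRecord`.

    ``families`` lists the distinct non-absent family labels in order of first
    appearance; unlabeled records (e.g. non-TF background) carry ``family=None``.
    """

    records: list[ProteinRecord] = field(default_factory=list)

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            if rec.family is not None and rec.family not in seen:
                seen[rec.family] = None
        return list(seen)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labeled(self) -> "LabeledCorpus":
        """Sub-corpus of records that carry a family label (order preserved)."""
        return LabeledCorpus([r for r in self.records if r.family is not None])

    def subset(self, ids: Iterable[str]) -> "LabeledCorpus":
        wanted = set(ids)
        return LabeledCorpus([r for r in self.records if r.id in wanted])


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into a list of :class:`ProteinRecord`.

    The id is the header token before the first whitespace. Sequences are
    upper-cased and a single terminal stop symbol ``'*'`` is stripped.
    An empty file yields an empty list with a warning; sequence data before
    any ``'>'`` header raises :class:`FastaParseError` naming the line.
    """
    path = Path(path)
    # Locate the first non-blank line so malformed input is reported by line
    # number; SimpleFastaParser would silently skip a headerless preamble.
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file", stacklevel=2)
            return []

    records: list[ProteinRecord] = []
    with path.open() as handle:
        for title, seq in SimpleFastaParser(handle):
            seq = seq.upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            records.append(ProteinRecord(id=title.split()[0], sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, sequences wrapped at 60 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with Path(path).open("w") as handle:
        SeqIO.write(seqs, handle, "fasta")


def validate_and_dedup(
    records: Sequence[ProteinRecord], permissive: bool = False
) -> tuple[LabeledCorpus, dict[str, int]]:
    """Drop records with invalid residues and collapse exact duplicate sequences.

    By default only the 20 standard amino acids are accepted; with
    ``permissive=True`` any alphabetic residue is kept (ambiguity codes then
    contribute no valid k-mer windows downstream). An internal ``'*'`` is
    always invalid. Among identical sequence strings the first occurrence wins;
    conflicting family labels on duplicates are logged.

    Returns the corpus plus counts ``{"kept", "dropped_invalid", "merged_duplicates"}``.
    """
    kept: list[ProteinRecord] = []
    first_by_seq: dict[str, ProteinRecord] = {}
    n_invalid = 0
    n_merged = 0
    for rec in records:
        bad = _invalid_residues(rec.sequence, permissive)
        if bad:
            n_invalid += 1
            logger.warning(
                "dropping record %s: invalid character %r", rec.id, sorted(bad)[0]
            )
            continue
        prior = first_by_seq.get(rec.sequence)
        if prior is not None:
            n_merged += 1
            if rec.family is not None and prior.family is not None and rec.family != prior.family:
                logger.warning(
                    "duplicate sequence %s/%s with conflicting families %s/%s; keeping %s",
                    prior.id, rec.id, prior.family, rec.family, prior.family,
                )
            continue
        first_by_seq[rec.sequence] = rec
        kept.append(rec)
    if records and not kept:
        warnings.warn("all records invalid; returning empty corpus", stacklevel=2)
    counts = {"kept": len(kept), "dropped_invalid": n_invalid, "merged_duplicates": n_merged}
    return LabeledCorpus(kept), counts


def _invalid_residues(sequence: str, permissive: bool) -> set[str]:
    if permissive:
        return {c for c in sequence if not c.isalpha()}
    return set(sequence) - _STANDARD_SET


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``id<TAB>family`` into a mapping. Duplicate ids error."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if list(table.columns[:2]) != ["id", "family"]:
        raise LabelTableError(
            f"{path}: expected header 'id<TAB>family', got {list(table.columns)}"
        )
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise LabelTableError(f"{path}: duplicate ids in label table: {dupes}")
    return dict(zip(table["id"], table["family"]))


def write_label_table(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(labels), "family": [labels[i] for i in labels]}
    ).to_csv(path, sep="\t", index=False)


def attach_labels(
    corpus: LabeledCorpus, labels: Mapping[str, str]
) -> tuple[LabeledCorpus, list[str]]:
    """Attach family labels to corpus records by id.

    Records present in the table get their family set; others remain
    unlabeled. Returns the relabeled corpus and the list of orphan label ids
    (present in the table but absent from the corpus), which is also warned
    about.
    """
    corpus_ids = set(corpus.ids)
    orphans = [i for i in labels if i not in corpus_ids]
    if orphans:
        warnings.warn(
            f"{len(orphans)} label id(s) not present in corpus: {orphans[:10]}",
            stacklevel=2,
        )
    new_records = [
        replace(rec, family=labels[rec.id]) if rec.id in labels else rec
        for rec in corpus.records
    ]
    return LabeledCorpus(new_records), orphans
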