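"""Readers/writers and canonical in-memory records for the S1-domain pipeline.

All coordinates in files and in :class:`DomainAnnotation` are 1-based inclusive,
the convention used for residue ranges of protein features.  Sequences are
upper-case strings over the 20 standard amino acids plus ``X``; the ambiguous
codes B, Z, U and O are mapped to ``X`` with a warning because public database
records may contain them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues, in the fixed index order used throughout
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: full alphabet including the unknown-residue symbol
ALPHABET = AMINO_ACIDS + "X"
#: ambiguity codes silently collapsed to X
_AMBIGUOUS = {"B", "Z", "U", "O"}

DOMAINS_OF_LIFE = ("Archaea", "Bacteria", "Eukaryota")

#: residue -> integer index (X == 20), used by the alignment kernels
RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}


class SeqIOError(ValueError):
    """Raised for malformed sequence, taxonomy or domain-table input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identity and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record with empty id")
        if not self.sequence:
            raise SeqIOError(f"protein {self.id!r} has an empty sequence")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in RESIDUE_INDEX]
        if bad:
            pos, c = bad[0]
            raise SeqIOError(
                f"protein {self.id!r}: non-amino-acid character {c!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        """Protein size in amino-acid residues (a.a.r.)."""
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyLabel:
    """Taxonomic assignment of one protein: domain of life, phylum, class."""

    id: str
    domain_of_life: str
    phylum: str = ""
    class_: str = ""

    def __post_init__(self) -> None:
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise SeqIOError(
                f"{self.id!r}: unknown domain of life {self.domain_of_life!r} "
                f"(expected one of {', '.join(DOMAINS_OF_LIFE)})"
            )


@dataclass(frozen=True)
class DomainAnnotation:
    """One detected S1 repeat: ordinal position (N->C) and residue range."""

    protein_id: str
    domain_index: int  # 1..k counted from the N terminus
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise SeqIOError(
                f"{self.protein_id!r} domain {self.domain_index}: invalid range "
                f"{self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("*", "")
    if any(c in _AMBIGUOUS for c in seq):
        logger.warning("record %s: ambiguous residues (B/Z/U/O) mapped to X", rec_id)
        seq = "".join("X" if c in _AMBIGUOUS else c for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes the record id;
    sequences are upper-cased, stop symbols ``*`` are stripped, and the
    ambiguity codes B/Z/U/O are mapped to X with a warning.

    Raises
    ------
    SeqIOError
        If the file is empty, an id occurs twice, or a sequence contains
        characters outside the amino-acid alphabet.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=_clean_sequence(str(rec.seq), rec.id),
                description=rec.description,
            )
        )
    if not records:
        raise SeqIOError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = _BioSeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_aligned_fasta(path: str | Path) -> list[str]:
    """Read an aligned FASTA (seed alignment): equal-length rows over residues + '-'."""
    rows = [str(rec.seq).upper() for rec in _BioSeqIO.parse(str(path), "fasta")]
    if not rows:
        raise SeqIOError(f"no aligned sequences found in {path}")
    if len({len(r) for r in rows}) != 1:
        raise SeqIOError(f"ragged alignment in {path}: unequal row lengths")
    return rows


_TAXONOMY_COLUMNS = ["id", "domain_of_life", "phylum", "class"]


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyLabel]:
    """Read a TSV taxonomy table (id, domain_of_life, phylum, class) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"taxonomy table {path} missing columns: {', '.join(missing)}")
    df = df.rename(columns={"class": "class_"})
    labels: dict[str, TaxonomyLabel] = {}
    for row in df.itertuples(index=False):
        lab = TaxonomyLabel(
            id=row.id,
            domain_of_life=row.domain_of_life,
            phylum=row.phylum,
            class_=row.class_,
        )
        labels[lab.id] = lab
    return labels


def write_taxonomy(labels: Mapping[str, TaxonomyLabel] | Iterable[TaxonomyLabel],
                   path: str | Path) -> None:
    if isinstance(labels, Mapping):
        labels = list(labels.values())
    df = pd.DataFrame(
        [(l.id, l.domain_of_life, l.phylum, l.class_) for l in labels],
        columns=_TAXONOMY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


_DOMAIN_COLUMNS = ["protein_id", "domain_index", "start", "end", "score"]


def _check_annotations(annotations: Iterable[DomainAnnotation]) -> list[DomainAnnotation]:
    anns = list(annotations)
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for a in anns:
        by_protein.setdefault(a.protein_id, []).append(a)
    for pid, rows in by_protein.items():
        rows = sorted(rows, key=lambda a: a.start)
        for prev, cur in zip(rows, rows[1:]):
            if cur.start <= prev.end:
                raise SeqIOError(
                    f"overlapping domain annotations for {pid!r}: "
                    f"{prev.start}..{prev.end} and {cur.start}..{cur.end}"
                )
        indices = sorted(a.domain_index for a in rows)
        if indices != list(range(1, len(rows) + 1)):
            raise SeqIOError(f"domain indices for {pid!r} not consecutive from 1: {indices}")
    return anns


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV domain table; validates ranges, overlap and index numbering."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _DOMAIN_COLUMNS if c not in df.columns]
    if missing:
        raise SeqIOError(f"domain table {path} missing columns: {', '.join(missing)}")
    anns = [
        DomainAnnotation(
            protein_id=row.protein_id,
            domain_index=int(row.domain_index),
            start=int(row.start),
            end=int(row.end),
            score=float(row.score),
        )
        for row in df.itertuples(index=False)
    ]
    return _check_annotations(anns)


def write_domain_table(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    """Write annotations as TSV; the write->read round trip is exact."""
    anns = _check_annotations(annotations)
    anns.sort(key=lambda a: (a.protein_id, a.start))
    df = pd.DataFrame(
        [(a.protein_id, a.domain_index, a.start, a.end, repr(a.score)) for a in anns],
        columns=_DOMAIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def encode_sequence(seq: str):
    """Map a residue string to the integer index array used by the DP kernels."""
    import numpy as np

    return np.array([RESIDUE_INDEX[c] for c in seq], dtype=np.int64)
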