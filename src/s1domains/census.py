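"""Census of S1-domain repeat counts across the three domains of life.

For every (domain of life, repeat count) class the census reports how many
proteins fall in it, the minimum and maximum protein size (a.a.r.) and the ids
of the extreme proteins — the structure of a repeat-distribution table.
Absolute counts from any particular database release are deliberately not a
reproduction goal; the census is validated against generated ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .seqio import DomainAnnotation, ProteinRecord, TaxonomyLabel

logger = logging.getLogger(__name__)

_CENSUS_COLUMNS = [
    "domain_of_life", "n_domains", "count",
    "min_len", "max_len", "shortest_id", "longest_id",
]


@dataclass(frozen=True)
class CensusRow:
    domain_of_life: str
    n_domains: int
    count: int
    min_len: int
    max_len: int
    shortest_id: str
    longest_id: str

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("census row with zero proteins")
        if self.min_len > self.max_len:
            raise ValueError("census row with min_len > max_len")


@dataclass
class CensusTable:
    """Rows keyed by (domain_of_life, n_domains), sorted."""

    rows: list[CensusRow]

    def __getitem__(self, key: tuple[str, int]) -> CensusRow:
        for row in self.rows:
            if (row.domain_of_life, row.n_domains) == key:
                return row
        raise KeyError(key)

    def total(self) -> int:
        return sum(r.count for r in self.rows)


def build_census(
    records: list[ProteinRecord],
    annotations: list[DomainAnnotation],
    taxonomy: dict[str, TaxonomyLabel],
) -> CensusTable:
    """Group proteins by (domain of life, repeat count) with size extremes.

    Proteins with zero detected domains are excluded (their number is
    logged); a protein without a taxonomy label is an error.  Ties for the
    shortest/longest protein go to the lexicographically smaller id.
    """
    counts: dict[str, int] = {}
    for ann in annotations:
        counts[ann.protein_id] = counts.get(ann.protein_id, 0) + 1

    cells: dict[tuple[str, int], list[ProteinRecord]] = {}
    n_zero = 0
    for rec in sorted(records, key=lambda r: r.id):
        k = counts.get(rec.id, 0)
        if k == 0:
            n_zero += 1
            continue
        if rec.id not in taxonomy:
            raise ValueError(f"protein {rec.id!r} has no taxonomy label")
        cells.setdefault((taxonomy[rec.id].domain_of_life, k), []).append(rec)
    if n_zero:
        logger.info("census: %d proteins with no detected domain excluded", n_zero)

    rows = []
    for (dol, k), recs in sorted(cells.items()):
        shortest = min(recs, key=lambda r: (r.length, r.id))
        max_len = max(r.length for r in recs)
        longest = min((r for r in recs if r.length == max_len), key=lambda r: r.id)
        rows.append(
            CensusRow(
                domain_of_life=dol,
                n_domains=k,
                count=len(recs),
                min_len=shortest.length,
                max_len=longest.length,
                shortest_id=shortest.id,
                longest_id=longest.id,
            )
        )
    return CensusTable(rows=rows)


def census_to_tsv(table: CensusTable, path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in table.rows], columns=_CENSUS_COLUMNS)
    df = df.sort_values(["domain_of_life", "n_domains"])
    df.to_csv(path, sep="\t", index=False)


def census_from_tsv(path: str | Path) -> CensusTable:
    df = pd.read_csv(path, sep="\t", dtype={"domain_of_life": str})
    rows = [
        CensusRow(
            domain_of_life=r.domain_of_life,
            n_domains=int(r.n_domains),
            count=int(r.count),
            min_len=int(r.min_len),
            max_len=int(r.max_len),
            shortest_id=str(r.shortest_id),
            longest_id=str(r.longest_id),
        )
        for r in df.itertuples(index=False)
    ]
    return CensusTable(rows=rows)
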