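"""Per-position domain sets, cross-group identity matrices and correspondences.

This is the core comparative step: multidomain proteins of a taxon group are
sliced into their ordinal domain positions (first, second, ... counted N->C),
and for two groups the mean percent identity between every position of one and
every position of the other is tabulated.  The argmax of each row calls the
best-corresponding domain pair — the signal used to trace organellar domains
back to a specific repeat position of their bacterial relatives.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import pairwise
from .seqio import DomainAnnotation, ProteinRecord, TaxonomyLabel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupFilter:
    """Selection of proteins for one domain group.

    ``k`` is the required repeat count: proteins whose annotated domain count
    differs are excluded (with a warning), matching the observation that the
    repeat count is a fixed characteristic of a phylum-level group.
    """

    name: str
    k: int
    domains_of_life: tuple[str, ...] | None = None
    phyla: tuple[str, ...] | None = None
    classes: tuple[str, ...] | None = None
    name_pattern: str | None = None  # regex matched against the description

    def matches(self, record: ProteinRecord, label: TaxonomyLabel | None) -> bool:
        if self.domains_of_life is not None:
            if label is None or label.domain_of_life not in self.domains_of_life:
                return False
        if self.phyla is not None:
            if label is None or label.phylum not in self.phyla:
                return False
        if self.classes is not None:
            if label is None or label.class_ not in self.classes:
                return False
        if self.name_pattern is not None:
            if not re.search(self.name_pattern, record.description):
                return False
        return True


@dataclass
class DomainGroup:
    """Domain sequences of one taxon group, keyed by ordinal position 1..k."""

    name: str
    n_positions: int
    members: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sorted(self.members) != list(range(1, self.n_positions + 1)):
            raise ValueError(
                f"group {self.name!r}: positions must be contiguous 1..{self.n_positions}"
            )
        for pos, seqs in self.members.items():
            if not seqs or any(not s for s in seqs):
                raise ValueError(f"group {self.name!r} position {pos}: empty member sequence")

    def n_members(self) -> int:
        return len(self.members[1])


@dataclass
class IdentityMatrix:
    """Mean identity between domain position i of group A and j of group B."""

    group_a: str
    group_b: str
    values: np.ndarray  # (m, n) fractions in [0, 1]
    counts: np.ndarray  # (m, n) number of aligned pairs per cell

    def __post_init__(self) -> None:
        if self.values.shape != self.counts.shape:
            raise ValueError("values and counts must have the same shape")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("identity values must be within [0, 1]")
        if np.any(self.counts < 1):
            raise ValueError("every matrix cell needs at least one aligned pair")


def extract_domains(
    records: list[ProteinRecord],
    annotations: list[DomainAnnotation],
    taxonomy: dict[str, TaxonomyLabel],
    group_filter: GroupFilter,
) -> DomainGroup:
    """Slice selected proteins into per-position domain sequence sets.

    Proteins passing the filter but with an annotated domain count different
    from ``group_filter.k`` are excluded with a warning.  Member lists are
    ordered by protein id so the output is independent of input order.
    """
    by_record = {r.id: r for r in records}
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        if ann.protein_id not in by_record:
            raise ValueError(f"annotation refers to unknown protein {ann.protein_id!r}")
        by_protein.setdefault(ann.protein_id, []).append(ann)

    k = group_filter.k
    members: dict[int, list[str]] = {pos: [] for pos in range(1, k + 1)}
    n_selected = 0
    for pid in sorted(by_protein):
        record = by_record[pid]
        if not group_filter.matches(record, taxonomy.get(pid)):
            continue
        anns = sorted(by_protein[pid], key=lambda a: a.start)
        if len(anns) != k:
            logger.warning(
                "%s: %d domains found, group %r requires %d — excluded",
                pid, len(anns), group_filter.name, k,
            )
            continue
        n_selected += 1
        for ann in anns:
            if ann.end > record.length:
                raise ValueError(f"{pid!r}: annotation {ann.start}..{ann.end} beyond length")
            members[ann.domain_index].append(record.sequence[ann.start - 1 : ann.end])
    if n_selected == 0:
        raise ValueError(f"no proteins matched group filter {group_filter.name!r} with k={k}")
    return DomainGroup(name=group_filter.name, n_positions=k, members=members)


def identity_matrix(a: DomainGroup, b: DomainGroup, **align_kwargs) -> IdentityMatrix:
    """Position-by-position mean identity grid between two domain groups.

    Off-diagonal cells (and every cell when the groups differ) are the mean
    identity over all A x B sequence pairs; when ``a is b`` the diagonal is
    the within-position mean over unordered pairs.
    """
    m, n = a.n_positions, b.n_positions
    values = np.zeros((m, n))
    counts = np.zeros((m, n), dtype=int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            try:
                if a is b and i == j:
                    seqs = a.members[i]
                    if len(seqs) < 2:
                        values[i - 1, j - 1] = 1.0 if len(seqs) == 1 else 0.0
                        counts[i - 1, j - 1] = 1
                    else:
                        values[i - 1, j - 1] = pairwise.group_identity(seqs, **align_kwargs)
                        counts[i - 1, j - 1] = len(seqs) * (len(seqs) - 1) // 2
                else:
                    values[i - 1, j - 1] = pairwise.cross_group_identity(
                        a.members[i], b.members[j], **align_kwargs
                    )
                    counts[i - 1, j - 1] = len(a.members[i]) * len(b.members[j])
            except Exception as exc:
                raise RuntimeError(
                    f"identity computation failed at cell ({i}, {j}) of "
                    f"{a.name!r} x {b.name!r}: {exc}"
                ) from exc
    return IdentityMatrix(group_a=a.name, group_b=b.name, values=values, counts=counts)


def best_correspondence(m: IdentityMatrix) -> list[tuple[int, int, float]]:
    """Row-wise argmax of the identity matrix: the best domain correspondences.

    For each position of group A, reports the group-B position(s) with maximal
    mean identity.  Ties are all reported, smallest column first.
    """
    if m.values.size == 0:
        raise ValueError("empty identity matrix")
    out: list[tuple[int, int, float]] = []
    for i in range(m.values.shape[0]):
        row = m.values[i]
        best = row.max()
        for j in np.flatnonzero(row == best):
            out.append((i + 1, int(j) + 1, float(best)))
    return out


def length_repeat_correlation(
    records: list[ProteinRecord], annotations: list[DomainAnnotation]
) -> float:
    """Spearman rank correlation between protein size and repeat count.

    Ties are midranked.  If either variable is constant the correlation is
    undefined; 0.0 is returned with a warning.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 proteins for a rank correlation")
    counts_by_protein: dict[str, int] = {}
    for ann in annotations:
        counts_by_protein[ann.protein_id] = counts_by_protein.get(ann.protein_id, 0) + 1
    lengths = [r.length for r in records]
    counts = [counts_by_protein.get(r.id, 0) for r in records]
    if len(set(lengths)) == 1 or len(set(counts)) == 1:
        logger.warning("constant lengths or domain counts: correlation undefined, returning 0")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(lengths, counts)
    return float(rho)


def identity_matrix_to_tsv(m: IdentityMatrix, path) -> None:
    """Write the matrix as TSV, cells as percent with one decimal."""
    import pandas as pd

    df = pd.DataFrame(
        np.round(m.values * 100.0, 1),
        index=[f"{m.group_a}:{i+1}" for i in range(m.values.shape[0])],
        columns=[f"{m.group_b}:{j+1}" for j in range(m.values.shape[1])],
    )
    df.to_csv(path, sep="\t")


def correspondence_to_tsv(pairs: list[tuple[int, int, float]], m: IdentityMatrix, path) -> None:
    """Write best correspondences as TSV; tied rows carry a ``tied`` flag."""
    import pandas as pd

    from collections import Counter

    per_row = Counter(i for i, _, _ in pairs)
    df = pd.DataFrame(
        [
            (m.group_a, i, m.group_b, j, round(v * 100.0, 1), "tied" if per_row[i] > 1 else "")
            for i, j, v in pairs
        ],
        columns=["group_a", "position_a", "group_b", "position_b", "identity_pct", "note"],
    )
    df.to_csv(path, sep="\t", index=False)
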