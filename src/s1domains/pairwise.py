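"""Global pairwise alignment and the percent-identity statistics.

Every identity number downstream (identity matrices, distances, trees) is the
fraction of aligned columns in which both sequences carry a residue and the
residues are equal.  Alignments are optimal Needleman–Wunsch with affine gaps
(gap of length L costs ``open + (L-1)*extend``) and a deterministic traceback:
on score ties the diagonal move is preferred, then the gap consuming the first
sequence ("up"), then the gap consuming the second ("left").

Defaults are Clustal-like: BLOSUM62, gap open 10, gap extend 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from . import _align
from .seqio import ALPHABET, encode_sequence

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: identity denominator conventions (see :func:`percent_identity`)
DENOM_RESIDUE_COLUMNS = "both-residues"
DENOM_ALIGNMENT_LENGTH = "columns"


def load_matrix(name_or_path: str | Path = DEFAULT_MATRIX) -> np.ndarray:
    """Load a substitution matrix as a 21x21 array over ``ALPHABET``.

    ``name_or_path`` is either a named matrix shipped with Biopython
    ("BLOSUM62", "PAM250", ...) or a path to a file in NCBI matrix text
    format.
    """
    name = str(name_or_path)
    if Path(name).is_file():
        mat = substitution_matrices.read(name)
    else:
        mat = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out


@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal global alignment of two sequences."""

    a_aligned: str
    b_aligned: str
    score: float
    n_identical: int
    n_aligned_cols: int

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings have unequal lengths")


def alignment_from_strings(a_aligned: str, b_aligned: str, score: float = 0.0) -> PairwiseAlignment:
    """Build a :class:`PairwiseAlignment` from already-aligned strings."""
    n_ident = sum(1 for x, y in zip(a_aligned, b_aligned) if x == y and x != "-")
    n_cols = sum(1 for x, y in zip(a_aligned, b_aligned) if x != "-" and y != "-")
    return PairwiseAlignment(a_aligned, b_aligned, score, n_ident, n_cols)


def global_align(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gap penalties."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if matrix is None:
        matrix = _BLOSUM62
    M, IX, IY = _align.gotoh_global(
        encode_sequence(a), encode_sequence(b), matrix, float(gap_open), float(gap_extend)
    )
    a_aln, b_aln, score = _align.traceback_global(a, b, M, IX, IY, gap_open, gap_extend)
    n_ident = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
    n_cols = sum(1 for x, y in zip(a_aln, b_aln) if x != "-" and y != "-")
    return PairwiseAlignment(a_aln, b_aln, score, n_ident, n_cols)


def percent_identity(
    aln: PairwiseAlignment, denominator: str = DENOM_RESIDUE_COLUMNS
) -> float:
    """Identity fraction in [0, 1] of a pairwise alignment.

    With the default ``both-residues`` denominator only columns where both
    sequences carry residues count; with ``columns`` the full alignment
    length (gap columns included) is the denominator.  Returns 0.0 for an
    alignment with no residue columns.
    """
    if denominator == DENOM_RESIDUE_COLUMNS:
        denom = aln.n_aligned_cols
    elif denominator == DENOM_ALIGNMENT_LENGTH:
        denom = len(aln.a_aligned)
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return aln.n_identical / denom


def pair_identity(a: str, b: str, **kwargs) -> float:
    """Align two sequences globally and return their percent identity."""
    denominator = kwargs.pop("denominator", DENOM_RESIDUE_COLUMNS)
    return percent_identity(global_align(a, b, **kwargs), denominator)


def group_identity(seqs: list[str], **kwargs) -> float:
    """Mean percent identity over all unordered pairs of a sequence set."""
    if len(seqs) < 2:
        raise ValueError("group identity needs at least 2 sequences")
    vals = [pair_identity(a, b, **kwargs) for a, b in combinations(seqs, 2)]
    return float(np.mean(vals))


def cross_group_identity(seqs_a: list[str], seqs_b: list[str], **kwargs) -> float:
    """Mean percent identity over all A x B pairs (within-group pairs excluded)."""
    if not seqs_a or not seqs_b:
        raise ValueError("both groups must be non-empty")
    vals = [pair_identity(a, b, **kwargs) for a, b in product(seqs_a, seqs_b)]
    return float(np.mean(vals))


_BLOSUM62 = load_matrix(DEFAULT_MATRIX)
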