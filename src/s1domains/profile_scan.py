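"""Position-specific scoring profile for the S1 domain and tandem-repeat detection.

A profile is built from a seed alignment of S1 domains as per-column log-odds
scores, ``ln((count_a + pc * bg_a) / ((n_col + pc) * bg_a))``, where ``count_a``
is the number of seed sequences showing residue ``a`` in the column, ``n_col``
the number of residues observed in the column, ``bg`` the background residue
distribution and ``pc`` a pseudocount.  ``X`` scores zero everywhere.

Repeats are detected by iterated best-local-hit search: profile-to-sequence
local alignment with affine gaps, accept the best hit if its score per profile
column reaches the cutoff, mask its residues, repeat.  Hits are reported
N-terminus to C-terminus with ordinal indices 1..k, mirroring the
"first/second/third domain" language used for multidomain proteins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from . import _align
from .seqio import (
    ALPHABET,
    AMINO_ACIDS,
    DomainAnnotation,
    ProteinRecord,
    encode_sequence,
)

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0
#: minimum normalized (per-column) hit score; calibrated so that random
#: sequences yield no hits while true domains up to ~0.5 substitutions/site
#: from the seed consensus are retained (see docs/methods.md)
DEFAULT_CUTOFF = 1.0
DEFAULT_PSEUDOCOUNT = 2.0

_GAP_CHARS = {"-", "."}


def uniform_background() -> dict[str, float]:
    """Uniform background distribution over the 20 standard residues."""
    return {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class ScoringProfile:
    """Position-specific log-odds scoring model for one domain family."""

    scores: np.ndarray  # (length, 21) over ALPHABET order; X column == 0
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != len(ALPHABET):
            raise ValueError("profile scores must be (length, 21)")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    @property
    def columns(self) -> list[dict[str, float]]:
        """Per-column residue -> score mappings (including X)."""
        return [
            {aa: float(self.scores[i, k]) for k, aa in enumerate(ALPHABET)}
            for i in range(self.length)
        ]


@dataclass(frozen=True)
class DomainHit:
    """One detected S1 repeat in a protein (1-based inclusive coordinates)."""

    protein_id: str
    start: int
    end: int
    raw_score: float
    norm_score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def build_profile(
    seed_alignment: list[str],
    background: dict[str, float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    cutoff: float = DEFAULT_CUTOFF,
) -> ScoringProfile:
    """Build a scoring profile from an aligned set of domain sequences.

    Alignment columns in which more than half of the sequences carry a gap are
    dropped.  Exact duplicate seed sequences are collapsed (with a warning) so
    that the effective sequence count reflects distinct sequences only.
    """
    if not seed_alignment:
        raise ValueError("empty seed alignment")
    if len({len(s) for s in seed_alignment}) != 1:
        raise ValueError("ragged seed alignment: sequences have unequal lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    rows = []
    seen: set[str] = set()
    for s in seed_alignment:
        s = s.upper()
        if s in seen:
            logger.warning("duplicate seed sequence collapsed in profile construction")
            continue
        seen.add(s)
        rows.append(s)
    if background is None:
        background = uniform_background()
    bg = np.array([background[aa] for aa in AMINO_ACIDS])
    n_rows = len(rows)
    width = len(rows[0])
    cols: list[np.ndarray] = []
    for j in range(width):
        column = [r[j] for r in rows]
        n_gap = sum(1 for c in column if c in _GAP_CHARS)
        if n_gap > 0.5 * n_rows:
            continue
        counts = np.zeros(20)
        for c in column:
            if c in _GAP_CHARS or c == "X":
                continue
            try:
                counts[AMINO_ACIDS.index(c)] += 1
            except ValueError as exc:
                raise ValueError(f"invalid residue {c!r} in seed alignment") from exc
        n_col = counts.sum()
        col_scores = np.log((counts + pseudocount * bg) / ((n_col + pseudocount) * bg))
        cols.append(col_scores)
    if not cols:
        raise ValueError("all alignment columns were gap-dominated")
    scores = np.zeros((len(cols), len(ALPHABET)))
    scores[:, :20] = np.asarray(cols)
    # X column stays 0
    return ScoringProfile(
        scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        cutoff=cutoff,
    )


def _best_hit(profile: ScoringProfile, seq_idx: np.ndarray, masked: np.ndarray):
    """Best local alignment of the profile to the unmasked sequence regions.

    Returns (start, end, raw_score) with 1-based inclusive sequence
    coordinates, or None if no positive-scoring alignment exists.
    """
    M, IX, IY = _align.profile_local(
        profile.scores, seq_idx, masked, profile.gap_open, profile.gap_extend
    )
    raw = float(M.max())
    if raw <= 0:
        return None
    # deterministic end cell: smallest sequence index, then profile column
    ends = np.argwhere(M == raw)
    end_i, end_j = (int(ends[0][0]), int(ends[0][1]))
    start_i, _ = _align.traceback_local(
        M, IX, IY, end_i, end_j, profile.gap_open, profile.gap_extend
    )
    return start_i, end_i, raw


def scan_sequence(profile: ScoringProfile, record: ProteinRecord) -> list[DomainHit]:
    """Detect all non-overlapping repeats of the profile in one protein.

    Greedy iterated masking: the best-scoring local hit is accepted if its
    per-column score reaches ``profile.cutoff`` and its span is within
    [0.5 L, 1.5 L] of the profile length L; its residues are then masked and
    the search repeats.  Hits are returned sorted by start position.
    """
    seq_idx = encode_sequence(record.sequence)
    masked = np.zeros(len(record.sequence), dtype=np.bool_)
    L = profile.length
    hits: list[DomainHit] = []
    while True:
        found = _best_hit(profile, seq_idx, masked)
        if found is None:
            break
        start, end, raw = found
        norm = raw / L
        if norm < profile.cutoff:
            break
        span = end - start + 1
        if not (0.5 * L <= span <= 1.5 * L):
            logger.warning(
                "%s: hit %d..%d rejected, span %d outside [%.0f, %.0f]",
                record.id, start, end, span, 0.5 * L, 1.5 * L,
            )
            break
        hits.append(
            DomainHit(
                protein_id=record.id, start=start, end=end,
                raw_score=raw, norm_score=norm,
            )
        )
        masked[start - 1 : end] = True
    hits.sort(key=lambda h: h.start)
    return hits


def hits_to_annotations(hits: list[DomainHit]) -> list[DomainAnnotation]:
    """Convert hits of one protein to ordinal annotations (1..k, N->C)."""
    ordered = sorted(hits, key=lambda h: h.start)
    return [
        DomainAnnotation(
            protein_id=h.protein_id,
            domain_index=i + 1,
            start=h.start,
            end=h.end,
            score=h.norm_score,
        )
        for i, h in enumerate(ordered)
    ]


def scan_to_annotations(profile: ScoringProfile, record: ProteinRecord) -> list[DomainAnnotation]:
    return hits_to_annotations(scan_sequence(profile, record))


def count_domains(record: ProteinRecord, profile: ScoringProfile) -> int:
    """Number of S1 repeats detected in a protein."""
    return len(scan_sequence(profile, record))
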