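"""Generator of bead-on-a-string multidomain protein families with known truth.

The model mirrors the assumed history of tandem S1 repeats: a single ancestral
domain (default 80 residues, within the 70–150 residue range typical of the
OB-fold) is duplicated into ``k`` ordinal positions per group; a fixed subset
of positions (default 30%) is frozen, standing for the conserved fold and
RNA-binding site, while the remaining sites substitute freely.  Each taxon
group diverges from the family root, its domain-position lineages diverge
independently from the group ancestor, and each protein's domains diverge
from their position ancestor — so within-protein paralogy exists.  An
optional *transfer* makes every domain position of a target ("organellar")
group descend from one chosen position of a source ("bacterial") group, the
endosymbiosis scenario whose recovery the analysis is meant to test.

A group's ``divergence`` d is the expected number of substitutions per free
site from the group ancestor to a tip domain, split evenly between the
position branch (d/2) and the protein branch (d/2); the group ancestor sits
d/2 from the family root.  Domains contain no indels, so true coordinates are
exact; linkers are drawn independently per protein (variable length and
composition), which is what exercises the scanner's tolerance to spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phylo
from .seqio import (
    AMINO_ACIDS,
    DomainAnnotation,
    ProteinRecord,
    TaxonomyLabel,
)

DEFAULT_DOMAIN_LEN = 80
DEFAULT_LINKER_RANGE = (10, 30)
DEFAULT_FROZEN_FRACTION = 0.3


@dataclass(frozen=True)
class GroupSpec:
    """One taxon group of multidomain proteins."""

    name: str
    n_proteins: int
    k: int  # number of tandem domains per protein
    divergence: float  # expected substitutions per free site, ancestor -> tip
    domain_of_life: str = "Bacteria"
    phylum: str = ""
    class_: str = ""

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.k < 1:
            raise ValueError(f"group {self.name!r}: n_proteins and k must be >= 1")
        if self.divergence < 0:
            raise ValueError(f"group {self.name!r}: divergence must be >= 0")


@dataclass(frozen=True)
class TransferSpec:
    """Endosymbiotic seeding of a target group from one source domain position."""

    source_group: str
    source_position: int
    target_group_name: str
    extra_divergence: float = 0.1

    def __post_init__(self) -> None:
        if self.extra_divergence < 0:
            raise ValueError("extra_divergence must be >= 0")


@dataclass
class SyntheticSpec:
    """Full description of one synthetic family."""

    groups: list[GroupSpec]
    seed: int
    domain_len: int = DEFAULT_DOMAIN_LEN
    linker_len_range: tuple[int, int] = DEFAULT_LINKER_RANGE
    conservation: np.ndarray | None = None  # per-position weights in [0, 1]
    frozen_fraction: float = DEFAULT_FROZEN_FRACTION
    transfer: TransferSpec | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.groups:
            raise ValueError("spec contains no groups")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.domain_len < 10:
            raise ValueError("domain_len too small")
        lo, hi = self.linker_len_range
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid linker length range {self.linker_len_range}")
        if self.conservation is not None:
            w = np.asarray(self.conservation, dtype=float)
            if w.shape != (self.domain_len,):
                raise ValueError("conservation must have one weight per domain position")
            if np.any((w < 0) | (w > 1)):
                raise ValueError("conservation weights must be within [0, 1]")
        if not 0 <= self.frozen_fraction <= 1:
            raise ValueError("frozen_fraction must be within [0, 1]")
        if self.transfer is not None:
            by_name = {g.name: g for g in self.groups}
            t = self.transfer
            if t.source_group not in by_name:
                raise ValueError(f"transfer source group {t.source_group!r} not in spec")
            if t.target_group_name not in by_name:
                raise ValueError(f"transfer target group {t.target_group_name!r} not in spec")
            if t.source_group == t.target_group_name:
                raise ValueError("transfer source and target groups must differ")
            if not 1 <= t.source_position <= by_name[t.source_group].k:
                raise ValueError(
                    f"transfer source position {t.source_position} outside "
                    f"1..{by_name[t.source_group].k}"
                )


@dataclass
class SyntheticTruth:
    """Generated data plus everything a test needs to verify recovery."""

    records: list[ProteinRecord]
    annotations: list[DomainAnnotation]
    taxonomy: dict[str, TaxonomyLabel]
    source_map: dict[int, int] | None  # target position -> source position
    true_tree: str  # Newick over group names
    ancestor: str  # family root domain sequence
    conservation: np.ndarray  # per-position weights used


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Sequence drawn uniformly from the 20 standard residues."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_sequence(
    seq: str,
    divergence: float,
    conservation: np.ndarray | None,
    rng: np.random.Generator,
) -> str:
    """Substitute each site with probability ``(1 - exp(-divergence)) * (1 - w)``.

    ``w`` is the site's conservation weight; fully conserved sites (w == 1)
    never change.  Substitutions draw uniformly from the 19 other residues;
    length is always preserved.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    if divergence == 0:
        return seq
    n = len(seq)
    if conservation is None:
        w = np.zeros(n)
    else:
        w = np.asarray(conservation, dtype=float)
        if w.shape != (n,):
            raise ValueError("conservation length does not match sequence")
    p_sub = (1.0 - np.exp(-divergence)) * (1.0 - w)
    hit = rng.random(n) < p_sub
    out = list(seq)
    for i in np.flatnonzero(hit):
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    return random_sequence(int(rng.integers(lo, hi + 1)), rng)


def _group_tree_newick(spec: SyntheticSpec) -> str:
    """Schematic group-level topology: the transfer target nests with its source."""
    nodes: dict[str, phylo.Node] = {
        g.name: phylo.Node(label=g.name) for g in spec.groups
    }
    children: list[tuple[phylo.Node, float]] = []
    if spec.transfer is not None:
        t = spec.transfer
        pair = phylo.Node(
            children=[
                (nodes.pop(t.source_group), 0.0),
                (nodes.pop(t.target_group_name), t.extra_divergence),
            ]
        )
        children.append((pair, 0.0))
    for g in spec.groups:
        if g.name in nodes:
            children.append((nodes[g.name], g.divergence / 2.0))
    root = children[0][0] if len(children) == 1 else phylo.Node(children=children)
    return phylo.to_newick(phylo.PhyloTree(root=root))


def generate_family(spec: SyntheticSpec) -> SyntheticTruth:
    """Generate the family described by ``spec`` with full ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    root = random_sequence(spec.domain_len, rng)
    if spec.conservation is not None:
        conservation = np.asarray(spec.conservation, dtype=float)
    else:
        conservation = np.zeros(spec.domain_len)
        n_frozen = int(round(spec.frozen_fraction * spec.domain_len))
        frozen = rng.choice(spec.domain_len, size=n_frozen, replace=False)
        conservation[frozen] = 1.0

    by_name = {g.name: g for g in spec.groups}
    # group ancestors, then per-position ancestors
    group_anc: dict[str, str] = {}
    pos_anc: dict[str, dict[int, str]] = {}
    for g in spec.groups:
        if spec.transfer is not None and g.name == spec.transfer.target_group_name:
            continue  # seeded from the source group below
        group_anc[g.name] = mutate_sequence(root, g.divergence / 2.0, conservation, rng)
        pos_anc[g.name] = {
            p: mutate_sequence(group_anc[g.name], g.divergence / 2.0, conservation, rng)
            for p in range(1, g.k + 1)
        }

    source_map: dict[int, int] | None = None
    if spec.transfer is not None:
        t = spec.transfer
        target = by_name[t.target_group_name]
        seed_domain = pos_anc[t.source_group][t.source_position]
        group_anc[target.name] = seed_domain
        pos_anc[target.name] = {
            p: mutate_sequence(seed_domain, t.extra_divergence, conservation, rng)
            for p in range(1, target.k + 1)
        }
        source_map = {p: t.source_position for p in range(1, target.k + 1)}

    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    taxonomy: dict[str, TaxonomyLabel] = {}
    lo, hi = spec.linker_len_range
    for g in spec.groups:
        for i in range(g.n_proteins):
            pid = f"{g.name}_{i + 1:02d}"
            parts: list[str] = []
            pos = 0
            flank = _linker(rng, lo, hi)
            parts.append(flank)
            pos += len(flank)
            for p in range(1, g.k + 1):
                domain = mutate_sequence(
                    pos_anc[g.name][p], g.divergence / 2.0, conservation, rng
                )
                annotations.append(
                    DomainAnnotation(
                        protein_id=pid,
                        domain_index=p,
                        start=pos + 1,
                        end=pos + len(domain),
                    )
                )
                parts.append(domain)
                pos += len(domain)
                tail = _linker(rng, lo, hi)
                parts.append(tail)
                pos += len(tail)
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence="".join(parts),
                    description=f"synthetic {g.name} protein with {g.k} S1 domains",
                )
            )
            taxonomy[pid] = TaxonomyLabel(
                id=pid,
                domain_of_life=g.domain_of_life,
                phylum=g.phylum,
                class_=g.class_,
            )

    return SyntheticTruth(
        records=records,
        annotations=annotations,
        taxonomy=taxonomy,
        source_map=source_map,
        true_tree=_group_tree_newick(spec),
        ancestor=root,
        conservation=conservation,
    )


def seed_alignment_from_truth(
    truth: SyntheticTruth, n: int = 8, divergence: float = 0.1, seed: int = 0
) -> list[str]:
    """Build a gapless seed alignment of close homologs of the family root.

    Stands in for a curated S1 seed alignment when testing the scanner on
    generated families.
    """
    rng = np.random.default_rng(seed)
    return [
        mutate_sequence(truth.ancestor, divergence, truth.conservation, rng)
        for _ in range(n)
    ]


@dataclass(frozen=True)
class CensusGroupSpec:
    """One census row to synthesize: repeat count, protein count, size span."""

    domain_of_life: str
    k: int
    count: int
    min_len: int
    max_len: int
    phylum: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("census group needs count >= 1")
        if self.min_len > self.max_len:
            raise ValueError("census group with min_len > max_len")


def generate_census_fixture(
    spec_list: list[CensusGroupSpec],
    seed: int,
    domain_len: int = 70,
    divergence: float = 0.2,
) -> SyntheticTruth:
    """Generate a mixed-taxonomy dataset whose census is known exactly.

    Protein sizes within each (domain of life, k) class interpolate linearly
    from ``min_len`` to ``max_len``; the first and last protein of a class
    realize the extremes exactly.  Requires ``min_len >= k * domain_len`` so
    the domains fit.
    """
    if not spec_list:
        raise ValueError("empty census spec")
    for cs in spec_list:
        if cs.min_len < cs.k * domain_len:
            raise ValueError(
                f"census group {cs.domain_of_life}/k={cs.k}: min_len {cs.min_len} "
                f"cannot hold {cs.k} domains of {domain_len} residues"
            )
    rng = np.random.default_rng(seed)
    root = random_sequence(domain_len, rng)
    conservation = np.zeros(domain_len)
    frozen = rng.choice(domain_len, size=int(round(0.3 * domain_len)), replace=False)
    conservation[frozen] = 1.0

    records: list[ProteinRecord] = []
    annotations: list[DomainAnnotation] = []
    taxonomy: dict[str, TaxonomyLabel] = {}
    for cs in spec_list:
        for i in range(cs.count):
            if cs.count == 1:
                total = cs.min_len
            else:
                frac = i / (cs.count - 1)
                total = int(round(cs.min_len + frac * (cs.max_len - cs.min_len)))
            pid = f"{cs.domain_of_life[:3].upper()}{cs.k}_{i + 1:03d}"
            extra = total - cs.k * domain_len
            # distribute non-domain residues over the k+1 flanks/linkers
            cuts = np.sort(rng.integers(0, extra + 1, size=cs.k)) if cs.k else []
            seg_lens = np.diff(np.concatenate(([0], cuts, [extra])))
            parts: list[str] = []
            pos = 0
            for p in range(1, cs.k + 1):
                flank = random_sequence(int(seg_lens[p - 1]), rng)
                parts.append(flank)
                pos += len(flank)
                domain = mutate_sequence(root, divergence, conservation, rng)
                annotations.append(
                    DomainAnnotation(
                        protein_id=pid, domain_index=p,
                        start=pos + 1, end=pos + domain_len,
                    )
                )
                parts.append(domain)
                pos += domain_len
            parts.append(random_sequence(int(seg_lens[-1]), rng))
            seq = "".join(parts)
            assert len(seq) == total
            records.append(
                ProteinRecord(id=pid, sequence=seq,
                              description=f"synthetic census protein k={cs.k}")
            )
            taxonomy[pid] = TaxonomyLabel(
                id=pid, domain_of_life=cs.domain_of_life, phylum=cs.phylum
            )
    return SyntheticTruth(
        records=records,
        annotations=annotations,
        taxonomy=taxonomy,
        source_map=None,
        true_tree=";",
        ancestor=root,
        conservation=conservation,
    )
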