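"""Distances from percent identities and neighbor-joining trees.

Identity fractions are converted to evolutionary distances either as
p-distances (``d = 1 - identity``) or with the Kimura correction for protein
sequences (``d = -ln(1 - p - 0.2 p^2)`` with ``p = 1 - identity``), the
default, which approximates multiple substitutions per site the way classic
distance-tree software does.  Trees are built with the Saitou–Nei
neighbor-joining algorithm using the Studier–Keppler Q criterion; branch
lengths are in substitutions per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import pairwise

P_DISTANCE = "p"
KIMURA = "kimura"


def identity_to_distance(p_identity: float, correction: str = KIMURA) -> float:
    """Convert an identity fraction in [0, 1] to an evolutionary distance."""
    if not 0.0 <= p_identity <= 1.0:
        raise ValueError(f"identity {p_identity} outside [0, 1]")
    p = 1.0 - p_identity
    if correction == P_DISTANCE:
        return p
    if correction == KIMURA:
        arg = 1.0 - p - 0.2 * p * p
        if arg <= 0.0:
            raise ValueError(
                f"Kimura correction undefined for identity {p_identity:.3f} "
                f"(corrected argument {arg:.3f} <= 0)"
            )
        return -math.log(arg)
    raise ValueError(f"unknown distance correction {correction!r}")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if n < 2:
            raise ValueError("distance matrix needs at least 2 taxa")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(self.d < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")


def distance_matrix_from_sequences(
    labels: list[str],
    seqs: list[str],
    correction: str = KIMURA,
    **align_kwargs,
) -> DistanceMatrix:
    """All-vs-all pairwise identity converted to a distance matrix."""
    if len(labels) != len(seqs):
        raise ValueError("labels and sequences differ in number")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise.pair_identity(seqs[i], seqs[j], **align_kwargs)
            d[i, j] = d[j, i] = identity_to_distance(ident, correction)
    return DistanceMatrix(labels=list(labels), d=d)


@dataclass
class Node:
    """Tree node; leaves carry a label, internal nodes children with edge lengths."""

    label: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out

    def min_leaf(self) -> str:
        return min(self.leaf_labels())


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary internal root."""

    root: Node

    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaf_labels())

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (should reproduce an additive input)."""
        labels = self.leaf_labels()
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}  # type: ignore[dict-item]
            below: dict[str, float] = {}
            child_maps = []
            for child, length in node.children:
                cmap = {lab: dist + length for lab, dist in walk(child).items()}
                child_maps.append(cmap)
            for a_i in range(len(child_maps)):
                for b_i in range(a_i + 1, len(child_maps)):
                    for la, da in child_maps[a_i].items():
                        for lb, db in child_maps[b_i].items():
                            d[index[la], index[lb]] = d[index[lb], index[la]] = da + db
            for cmap in child_maps:
                below.update(cmap)
            return below

        walk(self.root)
        return DistanceMatrix(labels=labels, d=d)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted tree, each as its smaller-named side."""
        all_leaves = frozenset(self.root.leaf_labels())
        splits: set[frozenset[str]] = set()

        def walk(node: Node) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])  # type: ignore[list-item]
            below: set[str] = set()
            for child, _ in node.children:
                side = walk(child)
                below |= side
                other = all_leaves - side
                if 2 <= len(side) <= len(all_leaves) - 2:
                    splits.add(min(side, frozenset(other), key=lambda s: (len(s), sorted(s))))
            return frozenset(below)

        walk(self.root)
        return splits


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the Studier–Keppler Q criterion.

    Ties in Q are broken by the lexicographically smallest (min leaf, max
    leaf) label pair of the candidate nodes.  Negative branch lengths are
    clamped to zero with the deficit moved to the sister branch, preserving
    the joined pair's total distance.
    """
    n = len(dm.labels)
    nodes: list[Node] = [Node(label=lab) for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    def tie_key(i: int, j: int) -> tuple[str, str]:
        a, b = nodes[i].min_leaf(), nodes[j].min_leaf()
        return (a, b) if a <= b else (b, a)

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, tie_key(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (len(active) - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
            li = max(li, 0.0)
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances of the new node to the remaining ones
        new_index = i
        for k in active:
            if k in (i, j):
                continue
            d[new_index, k] = d[k, new_index] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes[new_index] = parent
        active.remove(j)

    if len(active) == 2:
        i, j = active
        total = d[i, j]
        root = Node(children=[(nodes[i], total / 2.0), (nodes[j], total / 2.0)])
        return PhyloTree(root=root)

    i, j, k = active
    li = max(0.0, 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = max(0.0, 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return PhyloTree(root=root)


def _format_length(x: float) -> str:
    return f"{x:.6g}"


def to_newick(tree: PhyloTree) -> str:
    """Serialize with deterministic child order (smallest contained leaf label)."""

    def render(node: Node) -> str:
        if node.is_leaf:
            return node.label  # type: ignore[return-value]
        parts = sorted(node.children, key=lambda cl: cl[0].min_leaf())
        inner = ",".join(f"{render(c)}:{_format_length(l)}" for c, l in parts)
        return f"({inner})"

    return render(tree.root) + ";"


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(path, sep="\t")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(labels=[str(c) for c in df.columns], d=df.to_numpy(dtype=float))
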