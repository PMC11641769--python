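"""End-to-end recovery experiments on generated endosymbiosis families.

One replicate generates a three-group family — a "bacterial" source group
(k = 3), an unrelated bacterial outgroup (k = 3) and an "organellar" target
group (k = 2) whose domains all descend from one chosen source position —
then runs the full pipeline (profile scan, per-position identity matrix,
best correspondence, NJ tree) and scores whether the truth was recovered:

* does every row argmax of the target-vs-source identity matrix point at the
  true source position;
* are domain counts detected exactly;
* do the organellar leaves nest inside the source group's clade of the NJ
  tree (rooted at the outgroup).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import domain_compare, phylo, profile_scan, synthetic_data
from .seqio import DomainAnnotation

SOURCE = "Cyanolike"
OUTGROUP = "Otherbact"
TARGET = "Organellar"


def endosymbiosis_spec(
    seed: int,
    n_proteins: int = 5,
    divergence: float = 0.3,
    source_position: int = 3,
    extra_divergence: float = 0.1,
    target_k: int = 2,
) -> synthetic_data.SyntheticSpec:
    """Study conditions for the organellar-origin recovery experiment."""
    return synthetic_data.SyntheticSpec(
        groups=[
            synthetic_data.GroupSpec(
                name=SOURCE, n_proteins=n_proteins, k=3, divergence=divergence,
                domain_of_life="Bacteria", phylum="Cyanobacteria",
            ),
            synthetic_data.GroupSpec(
                name=OUTGROUP, n_proteins=n_proteins, k=3, divergence=divergence,
                domain_of_life="Bacteria", phylum="Chloroflexi",
            ),
            synthetic_data.GroupSpec(
                name=TARGET, n_proteins=n_proteins, k=target_k, divergence=divergence,
                domain_of_life="Eukaryota", phylum="Streptophyta",
            ),
        ],
        transfer=synthetic_data.TransferSpec(
            source_group=SOURCE,
            source_position=source_position,
            target_group_name=TARGET,
            extra_divergence=extra_divergence,
        ),
        seed=seed,
    )


@dataclass
class ReplicateResult:
    count_fraction: float  # fraction of proteins with detected count == truth
    source_position_recovered: bool  # all argmax rows == true source position
    organellar_nested: bool  # organellar leaves inside the source clade
    identity_matrix: domain_compare.IdentityMatrix
    tree: phylo.PhyloTree

    @property
    def counts_exact(self) -> bool:
        return self.count_fraction == 1.0


def _group_annotations(annotations: list[DomainAnnotation]) -> dict[str, list[DomainAnnotation]]:
    out: dict[str, list[DomainAnnotation]] = {}
    for a in annotations:
        out.setdefault(a.protein_id, []).append(a)
    return out


def organellar_nested(
    tree: phylo.PhyloTree,
    target_leaves: set[str],
    source_leaves: set[str],
    outgroup_leaves: set[str],
) -> bool:
    """True when the smallest split containing all target leaves but no
    outgroup leaf consists solely of target + source leaves."""
    all_leaves = frozenset(tree.root.leaf_labels())
    candidates = []
    for split in tree.bipartitions():
        for side in (split, all_leaves - split):
            if target_leaves <= side and not (outgroup_leaves & side):
                candidates.append(side)
    if not candidates:
        return False
    smallest = min(candidates, key=len)
    return smallest <= (target_leaves | source_leaves)


def run_replicate(
    seed: int,
    n_proteins: int = 5,
    divergence: float = 0.3,
    source_position: int = 3,
    use_scanner: bool = True,
) -> ReplicateResult:
    """Generate one family and measure truth recovery end to end."""
    spec = endosymbiosis_spec(
        seed, n_proteins=n_proteins, divergence=divergence,
        source_position=source_position,
    )
    truth = synthetic_data.generate_family(spec)
    rng = np.random.default_rng(seed)

    if use_scanner:
        seed_aln = synthetic_data.seed_alignment_from_truth(
            truth, n=8, divergence=0.1, seed=int(rng.integers(2**31)),
        )
        profile = profile_scan.build_profile(seed_aln)
        annotations: list[DomainAnnotation] = []
        n_exact = 0
        true_by_protein = _group_annotations(truth.annotations)
        for rec in truth.records:
            anns = profile_scan.scan_to_annotations(profile, rec)
            annotations.extend(anns)
            n_exact += len(anns) == len(true_by_protein[rec.id])
        count_fraction = n_exact / len(truth.records)
    else:
        annotations = truth.annotations
        count_fraction = 1.0

    groups = {}
    for name, k in ((SOURCE, 3), (OUTGROUP, 3), (TARGET, 2)):
        groups[name] = domain_compare.extract_domains(
            truth.records,
            annotations,
            truth.taxonomy,
            domain_compare.GroupFilter(name=name, k=k, name_pattern=f"synthetic {name} "),
        )

    matrix = domain_compare.identity_matrix(groups[TARGET], groups[SOURCE])
    pairs = domain_compare.best_correspondence(matrix)
    recovered = (
        len(pairs) == groups[TARGET].n_positions
        and all(j == source_position for _, j, _ in pairs)
    )

    # NJ tree over one representative domain per protein
    labels: list[str] = []
    seqs: list[str] = []
    leaf_sets: dict[str, set[str]] = {SOURCE: set(), OUTGROUP: set(), TARGET: set()}
    rep_position = {SOURCE: source_position, OUTGROUP: source_position, TARGET: 1}
    by_protein = _group_annotations(annotations)
    rec_by_id = {r.id: r for r in truth.records}
    for name in (SOURCE, OUTGROUP, TARGET):
        want = rep_position[name]
        for pid in sorted(by_protein):
            if not pid.startswith(name + "_"):
                continue
            anns = sorted(by_protein[pid], key=lambda a: a.start)
            if len(anns) < want:
                continue
            a = anns[want - 1]
            label = f"{pid}_d{want}"
            labels.append(label)
            seqs.append(rec_by_id[pid].sequence[a.start - 1 : a.end])
            leaf_sets[name].add(label)
    tree = phylo.neighbor_joining(
        phylo.distance_matrix_from_sequences(labels, seqs)
    )
    nested = organellar_nested(
        tree, leaf_sets[TARGET], leaf_sets[SOURCE], leaf_sets[OUTGROUP]
    )

    return ReplicateResult(
        count_fraction=count_fraction,
        source_position_recovered=recovered,
        organellar_nested=nested,
        identity_matrix=matrix,
        tree=tree,
    )


def run_benchmark(
    seed: int,
    n_replicates: int = 100,
    n_proteins: int = 5,
    divergence: float = 0.3,
    source_position: int = 3,
    use_scanner: bool = True,
) -> dict[str, float]:
    """Recovery rates over seeded replicates (fractions in [0, 1])."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31, size=n_replicates)
    n_pos = n_clade = 0
    count_fracs = []
    for s in rep_seeds:
        res = run_replicate(
            int(s), n_proteins=n_proteins, divergence=divergence,
            source_position=source_position, use_scanner=use_scanner,
        )
        n_pos += res.source_position_recovered
        n_clade += res.organellar_nested
        count_fracs.append(res.count_fraction)
    return {
        "source_position_recovery": n_pos / n_replicates,
        "count_accuracy": float(np.mean(count_fracs)),
        "clade_recovery": n_clade / n_replicates,
        "n_replicates": n_replicates,
    }
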