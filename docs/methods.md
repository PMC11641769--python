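# Methods

## The analysis in brief

The package quantifies how tandem S1-domain repeats relate across taxon
groups. Proteins are scanned for repeats with a position-specific profile;
proteins of a group are sliced into ordinal domain positions (1..k, N→C);
mean percent identities between positions of two groups form an identity
matrix whose row argmax calls the best-corresponding domain pair; identities
are converted to distances and summarized as a neighbor-joining tree. A
seeded simulator provides families with known repeat coordinates, known
source position of an "organellar" group, and known group topology, so every
stage can be validated against truth.

## Profile scanning

A scoring profile is built from a seed alignment of S1 domains. Column
scores are log-odds against a background distribution (uniform over the 20
residues by default):

    score(a) = ln( (count_a + pc · bg_a) / ((n_col + pc) · bg_a) )

with `count_a` the number of seed sequences carrying residue `a` in the
column, `n_col` the residues observed in the column, and pseudocount
`pc = 2` by default (a compromise between sharp match scores and a bounded
penalty for unseen residues; with eight seed sequences the consensus column
scores ≈ 2.8 and an unseen residue ≈ −1.6). Columns that are more than half
gaps are dropped; exact duplicate seed sequences are collapsed so the
effective count reflects distinct sequences; `X` scores 0 everywhere.

Repeats are found by iterated best-local-hit search: profile-to-sequence
local alignment (affine gaps, open 11 / extend 1), accept the best hit if
its **normalized score** — raw score divided by profile length — reaches the
cutoff, mask the hit's residues, repeat. Greedy masking is deterministic and
adequate for linker-separated repeats; ties in the DP traceback prefer the
diagonal, then the sequence-gap, then the profile-gap move. Accepted hits
must span between 0.5× and 1.5× the profile length.

**Cutoff.** The default cutoff is 1.0 (mean log-odds per profile column).
The choice follows from the score scale: with a ln-based profile, uniform
background and ~30% conserved sites, a true domain at 0.5 substitutions/site
from the seed consensus has an expected per-column score of about 1.4–1.7,
while the best random-sequence excursion normalized by full profile length
stays far below 1 (random residues score ≈ −1.1 per column on average, so a
raw score of 80 over an 80-column profile is unreachable by chance). A
cutoff near 2 would be ~74% of the maximal self-score and demonstrably
rejects true domains beyond ~0.25 substitutions/site; 1.0 retains domains
to ~0.6 substitutions/site at ≥3 standard errors of margin while keeping
random 200-mers hit-free.

## Percent identity and alignment

Global alignments are Needleman–Wunsch with affine gaps (a gap of length L
costs `open + (L−1)·extend`), BLOSUM62, open 10 / extend 0.5 — Clustal-like
defaults. Identity is `n_identical / n_aligned_columns` where only columns
with residues on both sides count; the alignment-length denominator is
available as an option since published identity percentages rarely state
their convention, and on closely related sequences the two differ by only a
few points. Group identity is the mean over all unordered pairs of
**pairwise** global alignments rather than a joint multiple alignment: it
removes a heuristic external dependency, is exactly reproducible, and on
sets that are ≥40% identical tracks MSA-derived identities within the
few-point tolerance used everywhere here.

## Identity matrices and correspondences

Matrix cells are means of pairwise identities (not identities of consensus
sequences). When a group is compared with itself the diagonal holds the
within-position mean over unordered pairs. Proteins whose detected repeat
count differs from the group's required k are excluded with a warning — the
repeat count is treated as a hard characteristic of a group, matching how
phylum-level repeat counts behave. Row argmaxes are reported with all ties,
smallest column first.

## Distances and trees

Identity fractions become distances with either `d = 1 − p_identity` or the
Kimura protein correction `d = −ln(1 − p − 0.2p²)`, the default (the
correction used by classic distance-tree software when no model is given;
it is undefined for identities below ~15%, which the implementation reports
as an error rather than truncating). Neighbor joining follows Saitou–Nei
with the Studier–Keppler Q criterion; Q ties are broken by the
lexicographically smallest (min leaf, max leaf) pair so relabeling never
changes the result; negative branch-length estimates are clamped to zero
with the deficit moved to the sister branch, preserving the joined pair's
total distance. Newick serialization orders children by their smallest
contained leaf label and prints lengths to six significant digits, making
output byte-deterministic. Branch lengths are labeled substitutions per
site.

## The simulator

One ancestral domain (default 80 residues) is drawn from the background; a
random 30% of positions are frozen, standing for the conserved β-barrel and
RNA-binding surface, while the loops vary. Substitution is Poisson-like:
each free site changes with probability `1 − exp(−d)` to a uniformly chosen
different residue. A group with divergence `d` places its ancestor `d/2`
from the family root, its position ancestors `d/2` from the group ancestor
(so positions within a protein are true paralogs), and each protein's
domains `d/2` from their position ancestor. An endosymbiotic transfer makes
every position ancestor of the target group a copy of one chosen source
position ancestor at `extra_divergence` (default 0.1). Domains contain no
indels, keeping true coordinates exact; linkers (10–30 residues) are drawn
independently per protein, which is what varies repeat spacing. The
benchmark's study conditions are: source and outgroup k = 3, target k = 2,
five proteins per group, divergence 0.3, transfer from source position 3.

What the simulator does **not** emulate: insertions/deletions inside
domains, site-rate heterogeneity beyond frozen/free, composition bias,
domain gain/loss within a group, or horizontal transfer networks. Passing
the recovery benchmarks therefore shows the pipeline is correct and well
calibrated under the assumed repeat-evolution model, not that it matches
any particular database-wide survey.

## Census

The census groups proteins by (domain of life, detected repeat count) and
reports counts, size extremes and extreme-protein ids; ties on size go to
the lexicographically smaller id. Absolute counts of any real database
release depend on that release and are not reproduction goals; the census
fixture generator instead realizes requested per-class counts and exact
size extremes (sizes interpolate linearly between the requested minimum and
maximum), so agreement can be checked exactly.

## Problem sizes and determinism

The recovery benchmark uses 100 replicates of 15 proteins each (~45 domains
per replicate scanned, ~250 pairwise alignments for matrices and trees),
which characterizes the recovery rates to a few percent while completing in
seconds; all randomness flows from a single integer seed through
`numpy.random.default_rng`, and derived seeds stay below 2³¹. The dynamic
programming kernels are numba-compiled; the first call in a process pays a
one-time compilation cost of a few seconds.

## Known limitations

* Real-data identity checks need user-supplied sequence files and a real S1
  seed alignment; a profile built from synthetic seeds cannot detect real
  S1 domains.
* The scanner's greedy masking can miss a repeat whose best local hit
  marginally fails the span filter; no joint decoding of overlapping
  candidates is attempted.
* Group identity by all-pairs global alignment is not identical to an MSA
  percent-identity matrix; differences are within a few percentage points
  on closely related sets but can grow for deeply diverged ones.
* Kimura-corrected distances saturate near 85% difference; very distant
  domain pairs should use p-distances.
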