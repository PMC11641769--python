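# s1domains

Tools for the comparative analysis of tandem **RNA-binding S1 domain**
repeats in proteins. The S1 domain is an OB-fold β-barrel of roughly 70–90
residues that occurs in 1–15 tandem copies ("beads on a string") in bacterial,
archaeal and eukaryotic RNA-binding proteins — ribosomal protein S1 (RpS1),
PNPase, RNase E, NusA, elongation factor Ts and others. Because chloroplasts
and mitochondria descend from engulfed Cyanobacteria and Alphaproteobacteria,
the per-position similarity of organellar S1 domains to specific repeat
positions of their bacterial relatives is an evolutionary marker of
symbiogenesis, and that is the analysis this package implements:

1. **Detect and count** S1 repeats in protein sequences with a
   position-specific scoring profile built from a seed alignment
   (log-odds per column, local alignment with affine gaps, greedy
   iterated masking of accepted hits).
2. **Census** the repeat-count distribution per domain of life, with
   minimum/maximum protein sizes and the extreme records, plus the
   Spearman correlation between protein size and repeat count.
3. **Compare domain positions**: slice k-domain proteins of two taxon
   groups into ordinal positions (1..k, N→C) and tabulate the mean percent
   identity between every position pair,

   `M[i, j] = mean over sequence pairs of  n_identical / n_aligned_columns`

   from global Needleman–Wunsch alignments (BLOSUM62, gap open 10,
   extend 0.5). The row argmax calls the best domain correspondence —
   e.g. "the first organellar domain corresponds to the third bacterial
   domain".
4. **Build trees**: identities become distances (`d = 1 − p` or the Kimura
   protein correction `d = −ln(1 − p − 0.2p²)`) and trees are built with
   Saitou–Nei neighbor joining (Studier–Keppler Q criterion), written as
   Newick.
5. **Generate ground truth**: a seeded simulator of multidomain families —
   an ancestral domain duplicated into positions, group-specific
   divergence, conserved sites, random linkers, and an optional
   "endosymbiotic transfer" that seeds an organellar group from one chosen
   bacterial domain position — so every stage of the pipeline is testable
   offline against known truth.

## Worked example

Simulate an endosymbiosis benchmark family (a 3-domain "Cyanolike" source
group, an unrelated 3-domain outgroup, and a 2-domain "Organellar" group
seeded from source position 3), scan it, and ask which source position the
organellar domains correspond to:

```sh
s1domains simulate --seed 42 --out-dir demo
s1domains scan demo/proteins.fasta \
    --seed-alignment demo/seed_alignment.fasta --out demo/domains.tsv
s1domains idmatrix demo/proteins.fasta \
    --domains demo/domains.tsv --taxonomy demo/taxonomy.tsv \
    --group-a Organellar --k-a 2 --pattern-a Organellar \
    --group-b Cyanolike  --k-b 3 --pattern-b Cyanolike \
    --out demo/idmatrix.tsv
```

`demo/idmatrix.tsv` (mean percent identity, organellar positions × source
positions):

```
            Cyanolike:1  Cyanolike:2  Cyanolike:3
Organellar:1       62.9         59.5         72.3
Organellar:2       67.8         61.0         77.4
```

Both organellar positions are most identical to source position 3 (72.3%
and 77.4%, the row maxima) — `s1domains correspond` reports exactly that —
which is the generated truth: the organellar group was seeded from the
third source domain. The ~10-point margin over the other columns reflects
the extra divergence separating domain-position lineages within a group.

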