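# structforge

Tooling for building machine-learning-ready protein structure datasets with
**homology-insulated** train/validation splits.

Protein sequences are not independent samples: evolutionary relatedness means
a naive random split leaks information from training into validation, and the
leak persists far below the twilight zone of pairwise sequence identity.
`structforge` implements a curation pipeline that takes structures, sequences
and multiple sequence alignments and produces:

* normalized per-chain entries with missing-residue **mask records**,
  backbone (N, Cα, C′) coordinates, and experimental metadata;
* Henikoff-weighted evolutionary profiles (**PSSMs**) with per-column
  information content, including the substitution of unknown/modified
  residues by the most probable profile residue and the rule that drops any
  entry whose profile contains a run of more than three zero-information
  columns;
* a **temporal reset**: entries are restricted to those publicly released
  strictly before a historical cutoff date (the start dates of CASP 7–12
  ship as ready-made cutoffs);
* the iterative **validation ladder**: cluster the pool by transitive closure
  at 10% sequence identity, draw 32 clusters (ignoring clusters of more than
  100 members), keep one exemplar per drawn cluster and remove the rest,
  then recluster the remainder at 20, 30, 40, 50, 70 and 90% — what survives
  is the training pool;
* training-set **thinnings** at 30/50/70/90/95/100% identity with an 80%
  mutual-coverage requirement below 100%, so single domains are not grouped
  with the multi-domain proteins that contain them;
* a unified, human-readable **text record** per entry (sequence + PSSM +
  tertiary coordinates + mask);
* an **assessment** module measuring the maximum detectable sequence
  identity of every held-out entry to the training set.

## The core procedure

Clustering follows the transitive-closure ("clustering mode 1") convention:
entries are nodes, significant pairwise matches (E ≤ 0.001) with identity ≥ t
are edges, and clusters are connected components — remote homologs are linked
through chains of intermediate sequences. Validation clustering deliberately
imposes *no* coverage requirement: a short protein matching a subpart of a
longer one counts as related, which overestimates identity and is the
conservative direction when guarding against leakage.

Exemplars avoid cluster boundaries. The cluster medoid (maximum summed
identity to the other members) is used as bait for a tight sub-cluster of
entries ≥ 95% identical to it that cover ≥ 90% of its length; from the
intersection with the original cluster, the winner maximizes, in order,

```
structure quality = 1/resolution − R-value   (the PDB's criterion)
release date                                  (newer is better)
length                                        (longer is better)
```

Pairwise identity comes from a pluggable backend: the built-in backend is
Smith-Waterman local alignment (BLOSUM62, gap open 11 / extend 1) with a
calibrated Karlin–Altschul E-value, and a tab-separated adapter ingests
externally computed all-against-all score tables (e.g. profile–profile
alignments of MSAs, which is how homology below ~20% identity is detected in
practice).

## Worked example

Everything is scriptable from Python, but the `forge` CLI covers the whole
pipeline. Starting from a synthetic corpus of 40 independent families
(123 entries):

```bash
forge synth --n-families 40 --members 2,4 --length 200,250 --seed 11 --out corpus
printf 'clusters_per_level: 4\nseed: 1\n' > cfg.yaml
forge split --entries corpus/structures.tsv --config cfg.yaml --out split
```

```
validation 10%: 4 exemplars
validation 20%: 4 exemplars
validation 30%: 4 exemplars
validation 40%: 4 exemplars
validation 50%: 4 exemplars
validation 70%: 4 exemplars
validation 90%: 4 exemplars
training pool: 37 entries
```

Each ladder level drew 4 clusters, kept their exemplars as that level's
validation set, and removed the other cluster members; the 37 entries never
drawn form the training pool. Thinning the training pool:

```bash
forge thin --entries corpus/structures.tsv --training split/split_manifest.tsv \
           --table split/scores.tsv --out thinnings.tsv
```

```
thinning 30%: 12 entries
thinning 50%: 12 entries
thinning 70%: 12 entries
thinning 90%: 12 entries
thinning 95%: 12 entries
thinning 100%: 37 entries
```

The 37 training entries span 12 families whose members are 95–99% identical,
so every level below 100% keeps one exemplar per family; at 100% only exact
duplicates collapse. Finally, measuring insulation:

```bash
forge assess --entries corpus/structures.tsv --train split/split_manifest.tsv \
             --table split/scores.tsv --out assess
```

```
group  n  min  q1  median  q3  max
   10  4  0.0 0.0     0.0 0.0  0.0
   20  4  0.0 0.0     0.0 0.0  0.0
   ...
   90  4  0.0 0.0     0.0 0.0  0.0
```

Every validation exemplar shows 0% maximum identity to the training set: the
families were generated independently, and the significance cutoff (E ≤
0.001) correctly reports no detectable homology — the property that makes the
low-identity validation sets usable as proxies for novel-fold prediction
targets.

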