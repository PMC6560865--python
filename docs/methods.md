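# Methods

This note documents the models, conventions and numerical choices behind
`structforge`, and what the synthetic test corpora do and do not establish
about behavior on real data.

## Structure ingestion

An entry is one *physical* polypeptide chain. mmCIF inputs are parsed with
gemmi; logical chains (label asym units) belonging to the same author chain
are concatenated in residue-number order, with numbering gaps filled by `'X'`
residues masked unresolved. Physically distinct chains become separate
entries, and only the first model of a multi-model file is used. A residue is
*resolved* iff all three backbone atoms (N, Cα, C′) are present; unresolved
positions carry the placeholder coordinate (0, 0, 0), and the mask is the
authoritative signal — consumers must never infer resolution from
coordinates. Coordinates are stored in picometers (mmCIF ångströms × 100),
which keeps integral values exact in text serialization.

Inclusion requires length ≥ 2 and at most 90% unresolved residues; both
bounds are strict in the exclusion direction (exactly 90% unresolved still
passes). The temporal filter keeps entries released *strictly before* the
cutoff date — "available prior to" a date excludes the date itself — and the
six CASP 7–12 start dates are provided as constants and accepted verbatim in
`YYYY/M/D` form. The release date of an mmCIF entry is the earliest revision
date present. Entries missing a release date are rejected with a warning by
default (a strict mode raises instead).

The >90%-unresolved filter is applied after chain merging, i.e. on the
physical chain: merging is part of normalization and the filter is defined on
entries, not on file-level fragments.

Domain boundaries are supplied as a table (chain id, start, end; 1-based
inclusive) rather than parsed from a domain database; extraction slices
sequence, mask and coordinates and inherits metadata.

## Profiles

Profiles are weighted per-column amino-acid frequency tables over the query
columns of an MSA.

* **Redundancy filtering** is greedy in input order (Hobohm-1): the query is
  always retained, and a row is dropped iff its identity to some already
  retained row *exceeds* the ceiling (default 90%). Row identity counts
  matches over columns where both rows are non-gap.
* **Henikoff position-based weights**: in each column a residue of type *t*
  receives 1/(r·s), with *r* the number of distinct types in the column and
  *s* the count of type *t*; gaps take no share; row weights are normalized
  to sum to 1. Duplicating a row provably never increases another row's
  weight, which is the property the weighting exists for.
* **Frequencies and information**: no pseudocounts. Letters outside the
  20-letter alphabet (`'X'`) are excluded from both numerator and
  denominator, so every position's frequencies sum to 1 unless the column
  has no residue mass at all, in which case it is flagged zero-information.
  Information content is `log2(20) − H(column)` bits, clamped at 0 — a
  background-free convention under which "zero information" means exactly
  "empty or uniform column". Zero is detected with an absolute tolerance of
  1e-12, since the entropy of a numerically uniform column is not exactly
  log2(20).
* **Unknown-residue substitution** replaces `'X'` with the argmax residue of
  the profile column, ties broken alphabetically (so an all-zero column
  resolves to `'A'`); the operation is idempotent. An entry is dropped
  outright when its profile contains a run of *more than three* consecutive
  zero-information positions (a run of exactly three survives).

## Pairwise identity and significance

The built-in backend aligns sequences with Smith-Waterman (or global
Needleman-Wunsch on request) under BLOSUM62 with affine gaps, open 11 /
extend 1. Identity is matches over alignment columns excluding gap-gap
pairs — the permissive denominator, consistent with the deliberate
overestimation discussed below. Coverage of a sequence is the span from its
first to last aligned residue divided by its length. No coverage floor is
applied by the pairwise operation; callers impose one where appropriate.

Significance uses Karlin–Altschul statistics, `E = K·m·n·exp(−λS)`. Gapped
λ and K cannot be computed analytically, so they were estimated once by
maximum-likelihood Gumbel fit to optimal local scores of random length-200
sequence pairs under this scoring scheme (the same simulation approach used
to calibrate database-search tools): λ = 0.214, K = 0.022. Note the aligner
charges a length-k gap `11 + (k−1)·1`, marginally cheaper than the BLAST
convention's `11 + k`, which is why published BLAST constants are not reused.
The fitted tail reproduces the nominal rate (P ≈ 0.001 of a chance pair
passing E ≤ 0.001) within a factor of ~3 across lengths 100–400. A pair with
no positive-scoring local alignment has identity 0 and E = ∞.

For all-against-all graph construction the backend first enumerates candidate
pairs sharing at least one exact 5-mer — the standard seeding heuristic of
database search. At the within-family identities the backend is designed for
(≥ 30%, lengths ≥ 100) a shared 5-mer is essentially guaranteed, while ~99%
of unrelated pairs are skipped; detection of homology far below that regime
is the job of profile–profile comparison, which enters through the score-table
adapter, not through this backend. Seeding can be disabled (`seed_kmer=None`)
for exhaustive behavior, which the oracle tests use.

The score-table adapter reads 6-column tab-separated tables (query, target,
identity, coverage_q, coverage_t, evalue) and keeps rows with E ≤ 0.001 by
default; absent pairs are non-edges, duplicates and symmetric rows collapse.

## Clustering and splits

Clusters at threshold *t* are connected components of the graph restricted to
edges with identity ≥ *t* (and, when requested, mutual coverage ≥ the floor),
computed with networkx; this is the transitive-closure behavior that lets
remote homologs cluster through intermediates. Output order is canonical
(clusters sorted by smallest member id), making every downstream draw a
function of the seed alone.

The validation ladder processes thresholds 10, 20, 30, 40, 50, 70, 90% in
ascending order. At each level the remaining entries are clustered with *no*
coverage requirement; clusters larger than 100 members are excluded *before*
sampling; 32 candidates (or all, with a warning, when fewer exist — small
corpora must not abort) are drawn uniformly without replacement by a seeded
`random.Random`; each drawn cluster contributes its exemplar to the
validation set and its other members to the removed set, giving the analytic
removal bound of 32 × 100 = 3200 entries per level. Entries never drawn form
the training pool, and the three parts partition the input by construction
(verified at runtime).

Exemplar selection uses the medoid as bait, builds the tight set (identity ≥
95% to the bait, alignment covering ≥ 90% of the bait's length — coverage is
measured on the bait), intersects it with the cluster (the bait guarantees
non-emptiness), and ranks candidates by structure quality `1/resolution −
R-value`, then newer release date, then greater length, then smallest id.
Entries missing resolution or R-value receive −∞ quality: the criterion is
undefined for them, and conservative demotion means they never displace a
structure with measured quality. The tight set is computed against the same
backend/graph as the surrounding run; at 95% identity the sequence- and
profile-based notions of identity coincide for practical purposes.

Thinnings below 100% cluster the training pool at the level's identity with a
0.80 mutual-coverage floor and keep one exemplar per cluster (same selection
criteria); the coverage floor is what prevents a single domain from being
absorbed by a multi-domain protein containing it (their alignment covers only
the domain's share of the longer chain). At 100% clusters are groups of
byte-identical sequences. Because each level's edge set is a subset of the
previous level's, thinning sizes are monotone in the level.

## Assessment

For each held-out entry the maximum identity over significant hits (E ≤
0.001) to the training set is reported; an entry with no significant hit is
recorded as 0% with an explicit no-hit flag rather than as missing, so that
group medians over hit-free groups are 0 — "no detectable homology" is a
measured outcome, not absent data. Group summaries are five-number summaries
(min, quartiles, median, max) computed with numpy percentiles.

## Synthetic corpora

The generator produces families from independent random ancestors (uniform
over the 20 amino acids) with descendants point-substituted to a target
identity drawn from the within-family range; substitution-only mutation makes
the target identity an exact mutation count, and measured pairwise identities
land within ±3 points of target at lengths ≥ 200 (local alignment may trim a
mismatched terminus). Defaults: 40 families of 2–5 members, within-family
identity 95–99% (high enough that families stay intact at the 90% ladder
level through their ancestor hub), lengths 200–300, release dates uniform
over 2004–2008 (straddling the first CASP cutoff), resolutions uniform in
[1, 4] Å and R-values in [0.15, 0.35] (typical crystallographic ranges),
missing-residue fraction 0–10% in 1–3 contiguous fragments. An optional
deletion mode introduces alignment gaps. Coordinates are smooth helix-like
curves in picometers — they exercise masks, units and serialization, not
stereochemistry. Each entry's MSA is its family in the ancestor coordinate
frame with the entry as query. Generation is a pure function of the spec
(numpy `default_rng(seed)`), so identical specs yield byte-identical output.

What the synthetic corpora *do not* emulate: realistic amino-acid
composition, site-rate variation, phylogenetic correlation, indel-rich
alignments, genuinely remote (10–30%) homologous pairs, and the heavy-tailed
family-size distribution of real structure collections. Consequently the
passing tests establish the correctness of the combinatorial and statistical
machinery — clustering, ladders, exemplar ranking, insulation accounting —
not the sensitivity of any particular alignment method on real remote
homologs, which is delegated to external profile–profile tools via the score
table adapter.

The ladder-scale suite uses 260 families (~770 entries): seven levels consume
up to 224 clusters, and ≥ 40 candidates remain at the final level, so every
level can draw its full 32 clusters and a residual training pool survives.

## Degenerate inputs and tie-breaks

Empty entry sets, empty clusters, empty training pools and empty alignments
raise; zero candidate clusters at a ladder level produce an empty validation
set with a warning. All argmax/selection operations end in a lexicographic id
tie-break, and sampling orders candidates canonically first, so every output
is deterministic given (input, seed) across platforms. Record serialization
prints frequencies to 5 decimals and coordinates to 0.1 pm; written records
re-serialize byte-identically after a read.

## Known limitations

* The profile–profile comparison that detects homology below ~20% identity
  is not reimplemented; the pipeline consumes its scores through the table
  adapter. The built-in sequence backend is intended for fixtures, thinnings
  and high-identity operations.
* E-value calibration was performed at lengths 100–400 and uniform residue
  composition; extreme lengths or biased composition will shift the
  effective significance level.
* mmCIF support is the subset needed for curation (atom records, first
  model, entity/asym mapping, resolution, R-value, release date); altloc
  variants beyond the first and non-polymer entities are ignored.
* Secondary structure is carried through records when provided but never
  computed.
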