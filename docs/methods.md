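# Methods

## Model and procedure

**Phylostrata.** The query species' lineage is the ordered root→tip path in
a user-supplied taxonomy (NCBI-taxdump dialect or a 3-column TSV). Position
1 is the taxonomy root; the last position `L` is the query itself. Smaller
numbers are older age classes — the convention standard in
phylostratigraphy, where "young" lineage-specific genes carry the highest
class numbers. Every node present in the supplied file is used; callers who
want only ranked nodes prune the file, which keeps granularity explicit
rather than hidden in a filter.

**Gene age per orthogroup.** For each orthogroup containing the query
species, the age class is

```
psnum(group) = min over member species s ≠ query of lca(query, s)
```

where `lca` returns the deepest lineage position that is an ancestor-or-self
of `s`. The minimum makes the class the *oldest* supported ancestor: one
member branching at the root is enough to date the group to class 1. A group
containing only the query gets the tip class `L`. All query genes of one
group inherit the same class. A gene listed in several groups (possible in
eggNOG-style inputs) keeps the oldest class, with a warning — the
conservative choice, since the alternative would let a spurious young group
overwrite strong deep homology.

**Continuity score.** The score quantifies species completeness between the
group's LCA and the query tip. Position `p ∈ [psnum, L−1]` counts as
*occupied* when some member species' LCA with the query is exactly `p`
(the LCA position itself counts by construction); the score is
`|occupied| / (L − psnum)`, and 1.0 for query-only groups (vacuously
complete). This binary-occupancy definition is this package's own: it is 1
exactly for gap-free groups and decreases with the number of lineage nodes
lacking any detectable ortholog, which is the property one wants when
flagging candidate horizontal transfers. Counting species per node instead
of binary occupancy would conflate sampling density with continuity. Scores
are printed with 4 decimals for stable files; the in-memory value is exact.

**TEI.** `TEI_c = Σ e_ic·ps_i / Σ e_ic` over the genes present in the age
mapping. Two conventions matter:

* genes absent from the mapping are excluded from numerator *and*
  denominator — treating them as class 0 would silently bias every cell
  old;
* a cell whose mapped expression sums to zero gets NaN, not 0 — empty cells
  exist in real filtered scRNA objects and 0 would read as "infinitely
  old".

Defined values are therefore always within `[min ps, max ps]`, TEI is
invariant to scaling any cell's counts by `k > 0`, and no library-size
normalization is applied internally (callers keep control over what the
grouped summaries average).

**Partial TEI** replaces the numerator sum with its restriction to one age
class, keeping the global denominator, so the strata × cells matrix sums
column-wise to the TEI vector exactly (up to float addition order; tests
require 1e−9 relative).

**Grouped relative expression** (`get_rematrix`) runs: optional elementwise
transform (`none`/`log1p`/`sqrt` — a deliberately minimal set, both options
preserve sparsity and cover the common variance-stabilizing choices) → mean
per gene over each group's cells → mean over each class's genes → optional
per-class min–max scaling across groups. Averaging cells before genes keeps
gene-rich classes from dominating. A class constant across groups cannot be
min–max scaled; it becomes all-zero and is reported in `constant_strata`
rather than producing NaNs or a fake signal.

**Binning** (`get_bins`) turns any finite per-gene metric into integer
classes 1..n. Quantile binning (default) gives near-equal counts; uniform
binning gives equal widths. Values tied at a boundary all go to the lower
bin, which makes the assignment deterministic and order-independent. If all
values coincide, every gene lands in bin 1 regardless of `n_bins`.
Non-finite values are dropped and reported.

## Sparse contract

TEI, partial TEI and grouped means are computed as sparse matrix–vector or
sparse–sparse-indicator products plus row sums: cost and memory are
proportional to the number of nonzero counts, and a dense cells × genes
array is never formed. When every matrix gene is mapped, the column
subsetting step is skipped entirely to avoid a full copy — the common case
on large matrices. The test suite exercises this path at 100,000 cells ×
20,000 genes (1% density, ~2·10⁷ nonzeros) and requires completion within
60 s on one CPU; observed runtime is well under one second for the index
itself.

## Synthetic data

The `simulate` module generates the study inputs every test runs on:

* **Taxonomies** — random rooted trees with a requested leaf (species)
  count and depth bound; at depth 2 the tree is exactly a root with leaf
  children.
* **Orthogroups** — each group's species composition is sampled so its true
  LCA class follows a requested spectrum: one anchor species branching
  exactly at the target class plus random extras branching no deeper, so
  the class is exact by construction and recorded as ground truth.
* **Counts** — Poisson draws with rates `base_rate · exp(direction · bias ·
  z)` where `z` is the standardized age class and `direction` is −1/0/+1
  for old-biased/neutral/young-biased cell groups (defaults: base rate 2.0,
  bias 0.8, alternating old/young labels). These defaults give clearly
  separated but overlapping group TEI distributions at a few dozen cells —
  a realistic effect size for stage-level contrasts. Counts are integers,
  matching the raw-count regime the pipeline starts from; transformed
  regimes are exercised through `get_rematrix`'s tags.

Ground truth is computed by oracles that share no code with the production
modules: explicit parent-walk path intersection for ages, and a dense
per-cell python loop for TEI. What the generator does **not** emulate:
dropout beyond Poisson zeros, overdispersion, batch effects, doublets, or
realistic gene-count distributions. Passing tests therefore demonstrate
algorithmic correctness on sparse count data, not robustness to real scRNA
noise structure.

All generators are seeded (default 0), use no global random state, and
regenerate byte-identical files per seed.

## Numerical and design choices

* Unknown taxids are hard errors; merged/deleted-taxid remapping is out of
  scope — silent remapping hides fixture and input bugs.
* Orthomap rows are sorted by (PSnum, Orthogroup, seqID) so written files
  are byte-stable; CLI writes are atomic (temp-then-rename).
* Version stripping removes only one trailing `.digits` run
  (`ENST0001.3 → ENST0001`, `GENE.X` untouched); identifier resolution
  order is exact seqID → versionless → transcript→gene translation, and an
  identifier that still fails is reported, never guessed. When versionless
  collapsing maps one name onto two age classes, the older class wins with
  a warning.
* Only the `gene_name` GTF attribute is honored for display names; GTF
  coordinates and features other than attribute extraction are ignored.
* Unplaced query genes (in no orthogroup) are omitted from the orthomap
  rather than defaulted to the tip class; downstream they then simply fall
  out of both TEI sums.

## Problem sizes used in the test suite

Randomized checks use ≤ 8 species, ≤ 50 groups, and ≤ 50 cells × 100 genes
per replicate (100 replicates for oracle-agreement and group-recovery
checks); the scaling check uses one 100,000 × 20,000 matrix at 1% density.
These sizes make every invariant checkable exhaustively against brute-force
oracles while the full suite stays fast.

## Known limitations

* No PLAZA-dialect parsing, no OrthoFinder/BLAST execution, no
  hierarchical-orthogroup handling, and no taxonomy download — inputs are
  files the caller provides.
* No statistical testing of TEI differences between groups; the package
  produces the per-cell and per-group quantities, inference is left to the
  caller.
* The continuity score depends on which species were included in the
  orthogroup run: sparse taxon sampling lowers scores without implying
  phyletic gaps.
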