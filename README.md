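# phylotei

Gene-age maps from orthologous groups, and expression-weighted evolutionary
indices for single-cell data.

## The problem

Phylostratigraphy asks how old each gene of a species is, and what that age
structure means for its transcriptome. Given orthologous groups across a set
of species (e.g. an OrthoFinder run, or a precomputed gene-family database in
eggNOG-style format), every gene of a chosen **query species** can be dated:
the age class of its orthogroup is the position, on the query's root→tip
taxonomic lineage, of the **lowest common ancestor (LCA)** shared with the
most distant member species. The resulting table — one row per query gene
with its orthogroup, age class (PSnum/PSname) and a continuity score — is an
**orthomap**.

With per-gene age classes in hand, the **transcriptome evolutionary index**
of a cell (or cell type) *c* is the expression-weighted arithmetic mean of
age classes:

```
TEI_c = Σ_i e_ic · ps_i / Σ_i e_ic
```

where `e_ic` is the expression of gene *i* in cell *c* and `ps_i` its
phylostratum (1 = oldest). Low TEI means an evolutionarily old transcriptome;
tracking TEI over embryonic stages is the standard way to look for the
developmental "hourglass". The same machinery accepts any binned per-gene
metric (Tajima's D, F statistics, adaptation scores) in place of ages.

All per-cell computations follow a sparse contract — cost proportional to
the number of nonzero counts, no dense cells × genes product — so they scale
to very large single-cell matrices.

The package is aimed at evolutionary biologists and single-cell analysts who
want to add an evolutionary layer to scRNA-seq objects; it interoperates
with AnnData through thin adapters.

## Worked example

Gene ages from a toy species tree and orthogroup table
(`examples/gene_ages.py`):

```
Query lineage (PSnum 1 = oldest, the taxonomy root):
  PS1  taxid 1  root
  PS2  taxid 2  clade2
  ...
  PS5  taxid 7  species0

seqID    Orthogroup  PSnum  PSname    PScontinuity
q0002_0  OG0002      1      root      0.7500
q0005_0  OG0005      2      clade2    0.6667
q0000_0  OG0000      5      species0  1.0000
```

`q0002_0` belongs to a group whose most distant member branches at the root
(oldest class, PS1); a continuity of 0.75 says three of the four lineage
nodes between that LCA and the species tip carry at least one member
species. Genes in query-only groups get the youngest class (the tip) with
continuity 1 by construction.

TEI per cell on a matrix built with old- vs young-biased cell groups
(`examples/tei_per_cell.py`):

```
mean TEI, old_biased   : 2.1938
mean TEI, young_biased : 4.6326
```

The old-biased group expresses low age classes more strongly, so its
expression-weighted mean age class is lower — exactly the signal TEI is
designed to pick up. `examples/partial_tei.py` decomposes these values into
additive per-age-class contributions (columns sum back to the TEI), and
`examples/binned_metrics.py` swaps age classes for quantile bins of a
continuous metric.

The same steps are available from a shell:

```sh
phylotei fixtures --out bundle --seed 13
phylotei qlin --taxid $(cat bundle/query_taxid.txt) --taxonomy bundle/taxonomy
phylotei of2orthomap --og bundle/orthogroups/Orthogroups.tsv \
    --speciesmap bundle/orthogroups/species_map.tsv \
    --taxonomy bundle/taxonomy --qtaxid $(cat bundle/query_taxid.txt) \
    --out orthomap.tsv
phylotei tei --expr bundle/counts --orthomap orthomap.tsv --out tei.tsv
```

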