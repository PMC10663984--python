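"""Assign gene age classes to a query species from an orthogroup table.

Builds a small random species tree and orthogroup table, extracts the
query's root-to-tip lineage (its phylostrata), and assigns every query gene
the age class of its orthogroup's oldest lowest common ancestor, plus a
continuity score measuring how gap-free the lineage support is.
"""

import io

from phylotei import extract_orthomap, get_lineage, load_lineage_tsv, read_member_table, write_orthomap
from phylotei.simulate import make_orthogroups, make_taxonomy

tree = make_taxonomy(n_species=6, depth=4, seed=4)
query = tree.species[0]
tax = load_lineage_tsv(io.StringIO(tree.lineage_tsv()))

lineage = get_lineage(tax, query)
print("Query lineage (PSnum 1 = oldest, the taxonomy root):")
for entry in lineage.entries:
    print(f"  PS{entry.psnum}  taxid {entry.taxid}  {entry.psname}")

ogs = make_orthogroups(tree, query, n_groups=8, seed=4)
table = read_member_table(io.StringIO(ogs.member_table()))
orthomap = extract_orthomap(table, tax, query)

print("\nOrthomap (one row per query gene; low PSnum = old gene):")
buffer = io.StringIO()
write_orthomap(orthomap, buffer)
print(buffer.getvalue())
print("PScontinuity = 1 means every lineage node between the group's LCA and")
print("the species tip is witnessed by at least one member species.")
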