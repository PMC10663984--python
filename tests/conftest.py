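import io
import os

import pytest

from phylotei import (
    extract_orthomap,
    get_lineage,
    load_taxonomy,
    read_orthofinder,
    read_species_map,
)
from phylotei.simulate import make_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One written synthetic study bundle shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    b = make_bundle(seed=11, n_species=7, depth=4, n_groups=25, n_cells=30)
    b.write(out)
    return b, out


@pytest.fixture(scope="session")
def bundle_parsed(bundle):
    """Taxonomy, lineage and orthomap parsed back from the bundle's files."""
    b, out = bundle
    tax = load_taxonomy(
        os.path.join(out, "taxonomy", "nodes.dmp"),
        os.path.join(out, "taxonomy", "names.dmp"),
    )
    table = read_orthofinder(
        os.path.join(out, "orthogroups", "Orthogroups.tsv"),
        read_species_map(os.path.join(out, "orthogroups", "species_map.tsv")),
    )
    om = extract_orthomap(table, tax, b.query)
    return tax, get_lineage(tax, b.query), om


def path_taxonomy_tsv(taxids_parents_names):
    """Helper: build a 3-column taxonomy TSV stream from tuples."""
    text = "taxid\tparent\tname\n" + "".join(
        f"{t}\t{p}\t{n}\n" for t, p, n in taxids_parents_names
    )
    return io.StringIO(text)
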