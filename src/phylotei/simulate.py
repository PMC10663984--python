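"""Deterministic generators for toy taxonomies, orthogroup tables, GTFs and
sparse count matrices, with ground truth computed by independent oracles.

Every generator takes an explicit seed and, given the same seed, writes
byte-identical files — no global random state is touched.  Ground-truth
quantities (gene-age classes, per-cell TEI) are derived here by deliberately
naive methods that share no code with the production modules:

* ages: explicit root-path intersection per member species (``oracle_lca``);
* TEI: a dense per-cell python loop over Eq.-style sums (``oracle_tei``).

The count generator emulates raw unique-molecule counts (Poisson draws with
per-group rate shifts over age classes); it makes no attempt to mimic real
single-cell dropout or overdispersion beyond those group-wise shifts, so
passing tests demonstrate algorithmic correctness, not biological realism.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.io
import scipy.sparse as sp

from .errors import PhyloteiError

__all__ = [
    "SimNode",
    "SimTaxonomy",
    "SimOrthogroups",
    "SimCounts",
    "make_taxonomy",
    "make_orthogroups",
    "make_counts",
    "make_bundle",
    "oracle_lca",
    "oracle_tei",
]


# ---------------------------------------------------------------------------
# taxonomy generation

@dataclass(frozen=True)
class SimNode:
    taxid: int
    parent: int
    name: str
    is_leaf: bool


@dataclass
class SimTaxonomy:
    nodes: list[SimNode]
    species: list[int]  # leaf taxids
    root: int = 1

    @property
    def parent_of(self) -> dict[int, int]:
        return {n.taxid: n.parent for n in self.nodes}

    def nodes_dmp(self) -> str:
        lines = []
        for n in self.nodes:
            rank = "species" if n.is_leaf else "no rank"
            lines.append(f"{n.taxid}\t|\t{n.parent}\t|\t{rank}\t|\n")
        return "".join(lines)

    def names_dmp(self) -> str:
        return "".join(
            f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n" for n in self.nodes
        )

    def lineage_tsv(self) -> str:
        lines = ["taxid\tparent\tname\n"]
        lines += [f"{n.taxid}\t{n.parent}\t{n.name}\n" for n in self.nodes]
        return "".join(lines)

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for fname, text in (
            ("nodes.dmp", self.nodes_dmp()),
            ("names.dmp", self.names_dmp()),
            ("taxonomy.tsv", self.lineage_tsv()),
        ):
            with open(os.path.join(out_dir, fname), "w", encoding="utf-8") as fh:
                fh.write(text)


def make_taxonomy(n_species: int, depth: int, seed: int = 0) -> SimTaxonomy:
    """Random rooted tree with ``n_species`` leaves and at most ``depth``
    levels below the root.

    Internal structure is sampled first (a random scaffold of up to
    ``2 * depth`` extra internal nodes), then each species leaf attaches to
    a random internal node.  Deterministic per seed.
    """
    if n_species < 2 or depth < 2:
        raise PhyloteiError(
            f"need n_species >= 2 and depth >= 2, got {n_species}, {depth}"
        )
    rng = np.random.default_rng(seed)
    nodes = [SimNode(1, 1, "root", False)]
    levels = {1: 0}
    internal = [1]
    next_taxid = 2
    n_internal = int(rng.integers(0, 2 * depth)) if depth > 2 else 0
    for _ in range(n_internal):
        candidates = [t for t in internal if levels[t] < depth - 1]
        parent = candidates[int(rng.integers(len(candidates)))]
        nodes.append(SimNode(next_taxid, parent, f"clade{next_taxid}", False))
        levels[next_taxid] = levels[parent] + 1
        internal.append(next_taxid)
        next_taxid += 1
    species = []
    for k in range(n_species):
        parent = internal[int(rng.integers(len(internal)))]
        nodes.append(SimNode(next_taxid, parent, f"species{k}", True))
        species.append(next_taxid)
        next_taxid += 1
    return SimTaxonomy(nodes, species)


# ---------------------------------------------------------------------------
# independent oracles

def root_path(parent_of: dict[int, int], taxid: int) -> list[int]:
    """Root-first path of taxids, by naive parent walking."""
    path = [taxid]
    while parent_of[path[-1]] != path[-1]:
        path.append(parent_of[path[-1]])
    return path[::-1]


def oracle_lca(parent_of: dict[int, int], query: int, other: int) -> int:
    """LCA position (1-based along the query's root path) via explicit
    path intersection — the brute-force reference for age assignment."""
    qpath = root_path(parent_of, query)
    opath = set(root_path(parent_of, other))
    deepest = 0
    for position, taxid in enumerate(qpath, start=1):
        if taxid in opath:
            deepest = position
    return deepest


def oracle_group_age(
    parent_of: dict[int, int], query: int, member_species: list[int]
) -> int:
    """Oldest (minimum) LCA position over a group's non-query members; the
    tip position when the group holds only the query species."""
    L = len(root_path(parent_of, query))
    others = [s for s in member_species if s != query]
    if not others:
        return L
    return min(oracle_lca(parent_of, query, s) for s in others)


def oracle_tei(counts: np.ndarray, ps: np.ndarray) -> np.ndarray:
    """Dense, loop-based TEI per cell: sum(e*ps)/sum(e), NaN for empty cells."""
    counts = np.asarray(counts, dtype=float)
    out = np.empty(counts.shape[0])
    for c in range(counts.shape[0]):
        total = counts[c].sum()
        out[c] = (counts[c] * ps).sum() / total if total > 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# orthogroup generation

@dataclass
class SimOrthogroups:
    query: int
    species_labels: dict[int, str]       # taxid -> OrthoFinder column label
    groups: dict[str, dict[int, list[str]]]  # og -> taxid -> seq IDs
    true_age: dict[str, int]             # og -> ground-truth psnum

    def orthofinder_tsv(self) -> str:
        taxids = sorted(self.species_labels)
        header = "Orthogroup\t" + "\t".join(self.species_labels[t] for t in taxids)
        lines = [header + "\n"]
        for og in sorted(self.groups):
            cells = [", ".join(self.groups[og].get(t, [])) for t in taxids]
            lines.append(og + "\t" + "\t".join(cells) + "\n")
        return "".join(lines)

    def member_table(self) -> str:
        lines = []
        for og in sorted(self.groups):
            members = [
                f"{taxid}.{seq}"
                for taxid in sorted(self.groups[og])
                for seq in self.groups[og][taxid]
            ]
            lines.append(og + "\t" + ",".join(members) + "\n")
        return "".join(lines)

    def species_map_tsv(self) -> str:
        return "".join(
            f"{self.species_labels[t]}\t{t}\n" for t in sorted(self.species_labels)
        )

    def query_genes(self) -> dict[str, int]:
        """Query-species gene -> ground-truth age class."""
        out = {}
        for og, by_taxid in self.groups.items():
            for seq in by_taxid.get(self.query, []):
                age = self.true_age[og]
                out[seq] = min(out.get(seq, age), age)
        return out

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for fname, text in (
            ("Orthogroups.tsv", self.orthofinder_tsv()),
            ("members.tsv", self.member_table()),
            ("species_map.tsv", self.species_map_tsv()),
        ):
            with open(os.path.join(out_dir, fname), "w", encoding="utf-8") as fh:
                fh.write(text)
        with open(os.path.join(out_dir, "true_ages.tsv"), "w", encoding="utf-8") as fh:
            fh.write("Orthogroup\tPSnum\n")
            for og in sorted(self.true_age):
                fh.write(f"{og}\t{self.true_age[og]}\n")


def make_orthogroups(
    tree: SimTaxonomy,
    query: int,
    n_groups: int,
    age_spectrum: dict[int, float] | None = None,
    seed: int = 0,
) -> SimOrthogroups:
    """Sample orthogroup compositions whose true LCA classes follow
    ``age_spectrum`` (psnum → weight), recording ground truth at build time.

    For a target class ``p`` below the tip, the group gets one species whose
    LCA with the query is exactly ``p`` plus random extra species with LCA
    ``>= p`` (extras can only be as old or younger, so the class is exact by
    construction).  The tip class yields query-only groups.  Weight on a
    class deeper than the query lineage, or on a class no species branches
    at, is a hard error.
    """
    if query not in tree.species:
        raise PhyloteiError(f"query {query} is not a species leaf of the tree")
    rng = np.random.default_rng(seed)
    parent_of = tree.parent_of
    L = len(root_path(parent_of, query))
    lca_of = {
        s: oracle_lca(parent_of, query, s) for s in tree.species if s != query
    }
    by_class: dict[int, list[int]] = {}
    for s, p in lca_of.items():
        by_class.setdefault(p, []).append(s)
    feasible = sorted(by_class) + [L]
    if age_spectrum is None:
        age_spectrum = {p: 1.0 for p in feasible}
    for p in age_spectrum:
        if p < 1 or p > L:
            raise PhyloteiError(f"age class {p} outside the query lineage [1, {L}]")
        if p != L and p not in by_class:
            raise PhyloteiError(f"no species branches at lineage position {p}")

    classes = sorted(age_spectrum)
    weights = np.array([age_spectrum[p] for p in classes], dtype=float)
    weights = weights / weights.sum()
    labels = {t: f"sp{t}" for t in tree.species}
    true_age: dict[str, int] = {}
    sim_groups: dict[str, dict[int, list[str]]] = {}
    for g in range(n_groups):
        og = f"OG{g:04d}"
        target = int(classes[rng.choice(len(classes), p=weights)])
        members: dict[int, list[str]] = {}
        n_query_genes = int(rng.integers(1, 4))
        members[query] = [f"q{g:04d}_{k}" for k in range(n_query_genes)]
        if target < L:
            anchor_pool = by_class[target]
            anchor = anchor_pool[int(rng.integers(len(anchor_pool)))]
            members[anchor] = [f"s{anchor}_{g:04d}"]
            extras = [s for s, p in lca_of.items() if p >= target and s != anchor]
            if extras:
                n_extra = int(rng.integers(0, len(extras) + 1))
                chosen = rng.choice(len(extras), size=n_extra, replace=False)
                for i in sorted(int(c) for c in chosen):
                    members[extras[i]] = [f"s{extras[i]}_{g:04d}"]
        sim_groups[og] = members
        true_age[og] = target
    return SimOrthogroups(query, labels, sim_groups, true_age)


# ---------------------------------------------------------------------------
# count-matrix generation

@dataclass
class SimCounts:
    matrix: sp.csr_matrix          # cells × genes
    cell_names: list[str]
    gene_names: list[str]
    gene_ps: dict[str, int]
    cell_groups: list[str]
    true_tei: np.ndarray           # oracle TEI per cell (NaN where empty)

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        scipy.io.mmwrite(
            os.path.join(out_dir, "matrix.mtx"), self.matrix.T.tocoo(), field="integer"
        )
        with open(os.path.join(out_dir, "barcodes.tsv"), "w", encoding="utf-8") as fh:
            fh.writelines(f"{c}\n" for c in self.cell_names)
        with open(os.path.join(out_dir, "features.tsv"), "w", encoding="utf-8") as fh:
            fh.writelines(f"{g}\n" for g in self.gene_names)
        with open(os.path.join(out_dir, "cell_groups.tsv"), "w", encoding="utf-8") as fh:
            fh.write("cell\tgroup\n")
            fh.writelines(
                f"{c}\t{g}\n" for c, g in zip(self.cell_names, self.cell_groups)
            )
        with open(os.path.join(out_dir, "true_tei.tsv"), "w", encoding="utf-8") as fh:
            fh.write("cell\tTEI\n")
            for c, v in zip(self.cell_names, self.true_tei):
                fh.write(f"{c}\t{'NA' if np.isnan(v) else format(v, '.12g')}\n")


def make_counts(
    n_cells: int,
    gene_ps: dict[str, int],
    group_labels: list[str] | None = None,
    seed: int = 0,
    base_rate: float = 2.0,
    bias: float = 0.8,
) -> SimCounts:
    """Sparse Poisson counts whose group means differ in age composition.

    Each group label carries a direction: labels containing ``old`` up-weight
    low age classes, labels containing ``young`` up-weight high ones, other
    labels are neutral.  Gene ``i`` in a cell of group ``g`` is drawn as
    Poisson(base_rate · exp(direction_g · bias · z_i)) with ``z_i`` the
    standardized age class, so old-biased groups have lower expected TEI by
    construction.  ``group_labels`` is one label per cell; the default
    alternates ``old_biased``/``young_biased``.  Ground-truth TEI comes from
    the dense oracle, not the production code.
    """
    if not gene_ps:
        raise PhyloteiError("gene list must not be empty")
    if n_cells < 1:
        raise PhyloteiError("n_cells must be >= 1")
    if group_labels is None:
        group_labels = ["old_biased" if c % 2 == 0 else "young_biased" for c in range(n_cells)]
    if len(group_labels) != n_cells:
        raise PhyloteiError("group_labels must supply one label per cell")
    rng = np.random.default_rng(seed)
    genes = list(gene_ps)
    ps = np.asarray([gene_ps[g] for g in genes], dtype=float)
    spread = ps.std() if ps.std() > 0 else 1.0
    z = (ps - ps.mean()) / spread

    def direction(label: str) -> float:
        label = label.lower()
        if "old" in label:
            return -1.0
        if "young" in label:
            return 1.0
        return 0.0

    rows = np.empty((n_cells, len(genes)), dtype=np.int64)
    for c in range(n_cells):
        lam = base_rate * np.exp(direction(group_labels[c]) * bias * z)
        rows[c] = rng.poisson(lam)
    matrix = sp.csr_matrix(rows)
    true = oracle_tei(rows, ps)
    cell_names = [f"cell{c:04d}" for c in range(n_cells)]
    return SimCounts(matrix, cell_names, genes, dict(gene_ps), list(group_labels), true)


# ---------------------------------------------------------------------------
# GTF generation and full bundles

def make_gtf(gene_ids: list[str], seed: int = 0) -> str:
    """Tiny GTF with one gene + transcript row per gene; transcript IDs are
    versioned (``<gene>.t1.1``) so version-stripping paths get exercised."""
    rng = np.random.default_rng(seed)
    lines = ["#!genome-build synthetic\n"]
    pos = 1
    for gid in gene_ids:
        span = int(rng.integers(200, 2000))
        attrs_gene = f'gene_id "{gid}"; gene_name "name_{gid}";'
        attrs_tx = f'gene_id "{gid}"; transcript_id "{gid}.t1.1"; gene_name "name_{gid}";'
        lines.append(f"chr1\tsynth\tgene\t{pos}\t{pos+span}\t.\t+\t.\t{attrs_gene}\n")
        lines.append(f"chr1\tsynth\ttranscript\t{pos}\t{pos+span}\t.\t+\t.\t{attrs_tx}\n")
        pos += span + 100
    return "".join(lines)


@dataclass
class FixtureBundle:
    """A complete synthetic study: taxonomy, orthogroups, GTF, counts and
    the ground truth each was generated with."""

    taxonomy: SimTaxonomy
    orthogroups: SimOrthogroups
    counts: SimCounts
    gtf: str
    query: int

    def write(self, out_dir: str | os.PathLike) -> None:
        out_dir = os.fspath(out_dir)
        self.taxonomy.write(os.path.join(out_dir, "taxonomy"))
        self.orthogroups.write(os.path.join(out_dir, "orthogroups"))
        self.counts.write(os.path.join(out_dir, "counts"))
        with open(os.path.join(out_dir, "annotation.gtf"), "w", encoding="utf-8") as fh:
            fh.write(self.gtf)
        with open(os.path.join(out_dir, "query_taxid.txt"), "w", encoding="utf-8") as fh:
            fh.write(f"{self.query}\n")


def make_bundle(
    seed: int = 0,
    n_species: int = 6,
    depth: int = 4,
    n_groups: int = 30,
    n_cells: int = 40,
) -> FixtureBundle:
    """Compose a taxonomy, orthogroups for a random query species, a GTF over
    the query genes, and a count matrix over those genes, all from one seed."""
    rng = np.random.default_rng(seed)
    tree = make_taxonomy(n_species, depth, seed=int(rng.integers(2**31)))
    query = tree.species[int(rng.integers(len(tree.species)))]
    ogs = make_orthogroups(tree, query, n_groups, seed=int(rng.integers(2**31)))
    gene_ps = ogs.query_genes()
    counts = make_counts(n_cells, gene_ps, seed=int(rng.integers(2**31)))
    gtf = make_gtf(sorted(gene_ps), seed=int(rng.integers(2**31)))
    return FixtureBundle(tree, ogs, counts, gtf, query)
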