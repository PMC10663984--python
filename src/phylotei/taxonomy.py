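"""Offline taxonomy handling: loading, lineage extraction, LCA-on-lineage queries.

A :class:`Taxonomy` is a rooted tree of taxa read either from NCBI-taxdump
style ``nodes.dmp``/``names.dmp`` files or from a simple 3-column TSV.  The
query species' root→tip path defines an ordered series of *phylostrata*:
position 1 is the taxonomy root (the oldest age class), the last position is
the query species itself (the youngest).  Gene-age assignment then reduces to
finding, for any other taxon, the deepest lineage position that is still an
ancestor of (or equal to) that taxon.

No network access is ever performed; callers supply the taxonomy files.
Unknown taxids are hard errors rather than being remapped.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Union

from .errors import ParseError, StructureError, TaxidNotFoundError

__all__ = [
    "TaxonNode",
    "Taxonomy",
    "LineageEntry",
    "Lineage",
    "load_taxonomy",
    "load_lineage_tsv",
    "get_lineage",
    "lca_on_lineage",
]

TextSource = Union[str, os.PathLike, IO[str]]


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identity, parent pointer, rank and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str

    @property
    def is_root(self) -> bool:
        return self.taxid == self.parent_taxid


class Taxonomy:
    """A validated rooted tree of :class:`TaxonNode` objects.

    The root is the unique node whose parent is itself (NCBI convention,
    usually taxid 1).  Construction validates uniqueness of taxids, presence
    of every parent, uniqueness of the root and absence of cycles.
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.taxid in self._nodes:
                raise StructureError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        if not self._nodes:
            raise StructureError("taxonomy contains no nodes")
        roots = [n.taxid for n in self._nodes.values() if n.is_root]
        if len(roots) != 1:
            raise StructureError(
                f"expected exactly one root (parent_taxid == taxid), found {len(roots)}"
            )
        self._root = roots[0]
        for node in self._nodes.values():
            if not node.is_root and node.parent_taxid not in self._nodes:
                raise StructureError(
                    f"node {node.taxid} references absent parent {node.parent_taxid}"
                )
        # cycle check: every node must reach the root in <= len(nodes) steps
        for taxid in self._nodes:
            current, steps = taxid, 0
            while current != self._root:
                current = self._nodes[current].parent_taxid
                steps += 1
                if steps > len(self._nodes):
                    raise StructureError(f"cycle detected walking parents from {taxid}")

    @property
    def root_taxid(self) -> int:
        return self._root

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self) -> Iterator[TaxonNode]:
        return iter(self._nodes.values())

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise TaxidNotFoundError(f"taxid {taxid} not in taxonomy") from None

    def root_path(self, taxid: int) -> list[int]:
        """Taxids on the root→``taxid`` path, inclusive, root first."""
        node = self.node(taxid)
        path = [node.taxid]
        while not node.is_root:
            node = self._nodes[node.parent_taxid]
            path.append(node.taxid)
        path.reverse()
        return path


@dataclass(frozen=True)
class LineageEntry:
    psnum: int
    taxid: int
    psname: str


@dataclass(frozen=True)
class Lineage:
    """Ordered root→tip path of the query species; positions are phylostrata.

    ``entries[0].psnum == 1`` at the root; the last entry is the query
    species with ``psnum == len(entries)``.  Smaller numbers are older.
    """

    entries: tuple[LineageEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def query_taxid(self) -> int:
        return self.entries[-1].taxid

    def psnum_of(self, taxid: int) -> int | None:
        for entry in self.entries:
            if entry.taxid == taxid:
                return entry.psnum
        return None

    def name_at(self, psnum: int) -> str:
        return self.entries[psnum - 1].psname


def _open_text(source: TextSource) -> IO[str]:
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8")
    return source


def _taxdump_records(source: TextSource, what: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (line number, fields) for each NCBI dump record.

    Fields are separated by ``\\t|\\t`` and the record is terminated by
    ``\\t|`` (the trailing separator may be absent in hand-written fixtures).
    """
    handle = _open_text(source)
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            if len(fields) < 2:
                raise ParseError(f"{what}: malformed record at line {lineno}: {raw!r}")
            yield lineno, fields
    finally:
        if isinstance(source, (str, os.PathLike)):
            handle.close()


def load_taxonomy(nodes_source: TextSource, names_source: TextSource) -> Taxonomy:
    """Load a taxonomy from NCBI-taxdump style ``nodes.dmp`` + ``names.dmp``.

    ``nodes.dmp`` supplies taxid, parent taxid and rank (first three fields);
    ``names.dmp`` supplies scientific names (rows whose name class is
    ``scientific name``).  Nodes without a scientific name are named
    ``taxid:<id>``.
    """
    parsed: dict[int, tuple[int, str]] = {}
    for lineno, fields in _taxdump_records(nodes_source, "nodes"):
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError:
            raise ParseError(f"nodes: non-integer taxid at line {lineno}") from None
        rank = fields[2].strip() if len(fields) > 2 else "no rank"
        if taxid in parsed:
            raise StructureError(f"duplicate taxid {taxid} in nodes file")
        parsed[taxid] = (parent, rank)

    names: dict[int, str] = {}
    for lineno, fields in _taxdump_records(names_source, "names"):
        try:
            taxid = int(fields[0])
        except ValueError:
            raise ParseError(f"names: non-integer taxid at line {lineno}") from None
        name_class = fields[3].strip() if len(fields) > 3 else "scientific name"
        if name_class == "scientific name":
            names[taxid] = fields[1].strip()

    return Taxonomy(
        TaxonNode(taxid, parent, rank, names.get(taxid, f"taxid:{taxid}"))
        for taxid, (parent, rank) in parsed.items()
    )


def load_lineage_tsv(source: TextSource) -> Taxonomy:
    """Load a taxonomy from the 3-column TSV dialect ``taxid\\tparent\\tname``.

    A header row with exactly those column names is required.  Same
    structural validation as :func:`load_taxonomy`.
    """
    handle = _open_text(source)
    try:
        header = handle.readline().rstrip("\n")
        if header.split("\t") != ["taxid", "parent", "name"]:
            raise ParseError(
                f"expected header 'taxid\\tparent\\tname', got {header!r}"
            )
        nodes = []
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"line {lineno}: expected 3 columns, got {len(fields)}")
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer taxid/parent") from None
            nodes.append(TaxonNode(taxid, parent, "no rank", fields[2].strip()))
    finally:
        if isinstance(source, (str, os.PathLike)):
            handle.close()
    return Taxonomy(nodes)


def load_any(path: TextSource) -> Taxonomy:
    """Load a taxonomy from either dialect.

    A directory is expected to contain ``nodes.dmp`` and ``names.dmp``; a
    file path or stream is read as the 3-column TSV dialect.
    """
    if isinstance(path, (str, os.PathLike)) and os.path.isdir(path):
        return load_taxonomy(
            os.path.join(path, "nodes.dmp"), os.path.join(path, "names.dmp")
        )
    return load_lineage_tsv(path)


def get_lineage(tax: Taxonomy, query_taxid: int) -> Lineage:
    """Root→tip lineage of ``query_taxid``; position 1 is the root.

    Every node present in the taxonomy along the path is included —
    granularity is controlled by what the caller puts in the taxonomy file.
    """
    path = tax.root_path(query_taxid)
    return Lineage(
        tuple(
            LineageEntry(psnum, taxid, tax.node(taxid).name)
            for psnum, taxid in enumerate(path, start=1)
        )
    )


def lca_on_lineage(lin: Lineage, tax: Taxonomy, other_taxid: int) -> int:
    """Phylostratum of the LCA between the lineage's query and ``other_taxid``.

    Returns the largest psnum whose taxid is an ancestor-or-self of
    ``other_taxid``; equals ``len(lin)`` when the other taxon is the query
    itself.  Always in ``[1, len(lin)]`` because both share the root.
    """
    other_ancestors = set(tax.root_path(other_taxid))
    deepest = 0
    for entry in lin.entries:
        if entry.taxid in other_ancestors:
            deepest = entry.psnum
    if deepest == 0:  # pragma: no cover - both paths include the root
        raise StructureError("lineage and taxon share no ancestor; foreign taxonomy?")
    return deepest


def lineage_to_tsv(lin: Lineage, handle: IO[str] | None = None) -> str:
    """Render a lineage as ``PSnum\\ttaxid\\tPSname`` TSV (with header)."""
    buf = io.StringIO()
    buf.write("PSnum\ttaxid\tPSname\n")
    for entry in lin.entries:
        buf.write(f"{entry.psnum}\t{entry.taxid}\t{entry.psname}\n")
    text = buf.getvalue()
    if handle is not None:
        handle.write(text)
    return text
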