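"""Orthologous-group tables and orthomap extraction.

An *orthomap* assigns every query-species gene an evolutionary age class
derived from the species composition of its orthogroup: the group's class is
the oldest (smallest-psnum) lowest common ancestor between the query species
and any member species.  A *continuity score* measures how completely the
lineage positions between that LCA and the query tip are witnessed by member
species; low values flag phyletic gaps (e.g. horizontal-transfer candidates).

Two input dialects are supported: OrthoFinder ``Orthogroups.tsv`` (one column
per species, comma-separated sequence IDs) and eggNOG-style member tables
(orthogroup ID plus comma-separated ``taxid.geneid`` tokens).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import pandas as pd

from .errors import ConfigError, ParseError, PhyloteiError, SchemaError
from .taxonomy import Lineage, Taxonomy, get_lineage, lca_on_lineage

__all__ = [
    "OrthogroupTable",
    "OrthomapRecord",
    "Orthomap",
    "read_orthofinder",
    "read_member_table",
    "read_species_map",
    "extract_orthomap",
    "continuity_score",
    "write_orthomap",
    "read_orthomap",
]

TextSource = Union[str, os.PathLike, IO[str]]

ORTHOMAP_COLUMNS = ["seqID", "Orthogroup", "PSnum", "PSname", "PScontinuity"]


@dataclass
class OrthogroupTable:
    """Orthogroup → species → sequence IDs, plus a species→taxid map."""

    groups: dict[str, dict[str, list[str]]]
    species_taxids: dict[str, int]

    def __post_init__(self) -> None:
        for og, by_species in self.groups.items():
            for label, seq_ids in by_species.items():
                if label not in self.species_taxids:
                    raise ConfigError(
                        f"species label {label!r} in group {og} has no taxid mapping"
                    )
                if any(s == "" for s in seq_ids):
                    raise ParseError(f"empty sequence ID in group {og}, species {label}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class OrthomapRecord:
    """One query gene with its age class and group continuity score."""

    seq_id: str
    orthogroup_id: str
    psnum: int
    psname: str
    pscontinuity: float


@dataclass
class Orthomap:
    """All orthomap records of one query species plus its lineage."""

    records: list[OrthomapRecord]
    query_taxid: int
    lineage: Lineage | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.seq_id, r.orthogroup_id, r.psnum, r.psname, r.pscontinuity)
                for r in self.records
            ],
            columns=ORTHOMAP_COLUMNS,
        )

    def ps_mapping(self) -> dict[str, int]:
        """gene → psnum mapping, the weight source for TEI computation."""
        return {r.seq_id: r.psnum for r in self.records}


def _open_lines(source: TextSource):
    if isinstance(source, (str, os.PathLike)):
        return open(source, "r", encoding="utf-8")
    return source


def read_species_map(source: TextSource) -> dict[str, int]:
    """Read a 2-column ``species_label\\ttaxid`` TSV (no header)."""
    mapping: dict[str, int] = {}
    handle = _open_lines(source)
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"species map line {lineno}: expected 2 columns")
            try:
                mapping[fields[0].strip()] = int(fields[1])
            except ValueError:
                raise ParseError(
                    f"species map line {lineno}: non-integer taxid {fields[1]!r}"
                ) from None
    finally:
        if isinstance(source, (str, os.PathLike)):
            handle.close()
    return mapping


def read_orthofinder(
    source: TextSource, species_taxids: dict[str, int]
) -> OrthogroupTable:
    """Parse an OrthoFinder ``Orthogroups.tsv``.

    First header column is the orthogroup ID; remaining headers are species
    labels which must all be present in ``species_taxids``.  Cells hold
    comma(-space) separated sequence IDs; empty cells yield empty lists and
    surrounding whitespace on IDs is stripped.
    """
    handle = _open_lines(source)
    try:
        header = handle.readline().rstrip("\n")
        if not header:
            raise ParseError("empty orthogroup table")
        columns = header.split("\t")
        species = columns[1:]
        missing = [s for s in species if s not in species_taxids]
        if missing:
            raise ConfigError(
                f"species label(s) missing from taxid map: {', '.join(missing)}"
            )
        groups: dict[str, dict[str, list[str]]] = {}
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) != len(columns):
                raise ParseError(
                    f"line {lineno}: expected {len(columns)} columns, got {len(cells)}"
                )
            og = cells[0].strip()
            if og in groups:
                raise ParseError(f"line {lineno}: duplicate orthogroup ID {og!r}")
            groups[og] = {
                label: [t.strip() for t in cell.split(",") if t.strip()]
                for label, cell in zip(species, cells[1:])
            }
    finally:
        if isinstance(source, (str, os.PathLike)):
            handle.close()
    return OrthogroupTable(groups, dict(species_taxids))


def read_member_table(source: TextSource) -> OrthogroupTable:
    """Parse an eggNOG-style member table.

    Each row carries an orthogroup ID and a comma-separated list of
    ``taxid.geneid`` tokens; the species→taxid map is derived from the taxid
    prefixes (species labels are the taxid strings) and sequence IDs keep
    everything after the *first* dot.
    """
    groups: dict[str, dict[str, list[str]]] = {}
    taxids: dict[str, int] = {}
    handle = _open_lines(source)
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected orthogroup ID and members")
            og = fields[0].strip()
            if og in groups:
                raise ParseError(f"line {lineno}: duplicate orthogroup ID {og!r}")
            by_species: dict[str, list[str]] = {}
            for token in fields[1].split(","):
                token = token.strip()
                if not token:
                    continue
                if "." not in token:
                    raise ParseError(
                        f"line {lineno}: member token {token!r} lacks a taxid prefix"
                    )
                taxid_str, seq_id = token.split(".", 1)
                try:
                    taxid = int(taxid_str)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-integer taxid in token {token!r}"
                    ) from None
                taxids[taxid_str] = taxid
                by_species.setdefault(taxid_str, []).append(seq_id)
            groups[og] = by_species
    finally:
        if isinstance(source, (str, os.PathLike)):
            handle.close()
    return OrthogroupTable(groups, taxids)


def continuity_score(
    member_taxids: Iterable[int], lin: Lineage, tax: Taxonomy, ps: int
) -> float:
    """Fraction of lineage positions between the LCA and the tip that are
    witnessed by at least one member species.

    Position ``p`` in ``[ps, L-1]`` counts as occupied when some member's
    LCA-psnum with the query equals ``p``; the LCA position itself is
    occupied by construction.  A query-only group (``ps == L``) scores 1.0
    vacuously.  The score is 1 for gap-free groups and drops when
    intermediate nodes lack any detectable ortholog.
    """
    L = len(lin)
    if not 1 <= ps <= L:
        raise PhyloteiError(f"psnum {ps} outside lineage range [1, {L}]")
    if ps == L:
        return 1.0
    occupied = {ps}
    for taxid in member_taxids:
        p = lca_on_lineage(lin, tax, taxid)
        if ps <= p <= L - 1:
            occupied.add(p)
    return len(occupied) / (L - ps)


def extract_orthomap(
    table: OrthogroupTable, tax: Taxonomy, query_taxid: int
) -> Orthomap:
    """Assign an age class (and continuity score) to every query gene.

    Only orthogroups whose query-species column is non-empty contribute.  A
    group's psnum is the minimum LCA-psnum over its member species — the
    deepest node toward the root, i.e. the oldest class; a query-only group
    gets the tip class ``L``.  All genes of one group share one
    (psnum, psname, pscontinuity) triple.

    A gene appearing in several groups (possible with eggNOG-style input)
    keeps the record with the smallest psnum (conservative, oldest age) and
    a warning is emitted.
    """
    query_labels = [s for s, t in table.species_taxids.items() if t == query_taxid]
    if not query_labels:
        raise ConfigError(f"query taxid {query_taxid} not among table species")
    query_label = query_labels[0]
    lin = get_lineage(tax, query_taxid)
    L = len(lin)

    best: dict[str, OrthomapRecord] = {}
    for og in sorted(table.groups):
        by_species = table.groups[og]
        query_ids = by_species.get(query_label, [])
        if not query_ids:
            continue
        member_taxids = {
            table.species_taxids[s]
            for s, ids in by_species.items()
            if ids and table.species_taxids[s] != query_taxid
        }
        if member_taxids:
            psnum = min(lca_on_lineage(lin, tax, t) for t in member_taxids)
        else:
            psnum = L
        cont = continuity_score(member_taxids, lin, tax, psnum)
        psname = lin.name_at(psnum)
        for seq_id in query_ids:
            record = OrthomapRecord(seq_id, og, psnum, psname, cont)
            if seq_id in best:
                warnings.warn(
                    f"gene {seq_id!r} appears in groups {best[seq_id].orthogroup_id!r} "
                    f"and {og!r}; keeping the older age class",
                    stacklevel=2,
                )
                if record.psnum < best[seq_id].psnum:
                    best[seq_id] = record
            else:
                best[seq_id] = record
    return Orthomap(list(best.values()), query_taxid, lin)


def write_orthomap(om: Orthomap, destination: TextSource) -> None:
    """Write the orthomap TSV.

    Exact header ``seqID\\tOrthogroup\\tPSnum\\tPSname\\tPScontinuity``;
    PScontinuity with 4 decimals; rows sorted by (PSnum, Orthogroup, seqID)
    so output is byte-stable.
    """
    rows = sorted(om.records, key=lambda r: (r.psnum, r.orthogroup_id, r.seq_id))
    own = isinstance(destination, (str, os.PathLike))
    handle = open(destination, "w", encoding="utf-8") if own else destination
    try:
        handle.write("\t".join(ORTHOMAP_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                f"{r.seq_id}\t{r.orthogroup_id}\t{r.psnum}\t{r.psname}"
                f"\t{r.pscontinuity:.4f}\n"
            )
    finally:
        if own:
            handle.close()


def read_orthomap(source: TextSource) -> list[OrthomapRecord]:
    """Read orthomap records from TSV.

    ``seqID`` and ``PSnum`` are mandatory; ``Orthogroup``/``PSname``/
    ``PScontinuity`` are filled with placeholders when absent, so
    pre-existing gene age maps with only (gene, age) columns import cleanly.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    for column in ("seqID", "PSnum"):
        if column not in df.columns:
            raise SchemaError(f"orthomap is missing mandatory column {column!r}")
    records = []
    for _, row in df.iterrows():
        try:
            psnum = int(row["PSnum"])
        except (TypeError, ValueError):
            raise ParseError(
                f"non-integer PSnum {row['PSnum']!r} for seqID {row['seqID']!r}"
            ) from None
        cont = row.get("PScontinuity")
        records.append(
            OrthomapRecord(
                seq_id=str(row["seqID"]),
                orthogroup_id=str(row.get("Orthogroup", "") or ""),
                psnum=psnum,
                psname=str(row.get("PSname", "") or ""),
                pscontinuity=float(cont) if cont is not None and cont == cont else float("nan"),
            )
        )
    return records
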