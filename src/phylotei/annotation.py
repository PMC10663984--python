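"""Transcript↔gene mapping from GTF and gene-name reconciliation.

Expression matrices and orthomaps frequently come from different annotation
sources, so their gene identifiers disagree — often only by an Ensembl-style
version suffix (``ENSDARG000.3`` vs ``ENSDARG000``) or because one side uses
transcript IDs.  This module extracts a transcript→gene table from a GTF and
resolves expression-matrix identifiers against orthomap sequence IDs with a
deterministic fallback chain; identifiers that cannot be resolved are
reported, never guessed.

Only GTF attributes are interpreted; coordinates, strand and features other
than ``transcript`` rows play no role here.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

from .errors import ParseError
from .orthogroups import OrthomapRecord

__all__ = ["T2GRecord", "gtf_to_t2g", "write_t2g", "map_genes", "strip_version"]

TextSource = Union[str, os.PathLike, IO[str]]

_VERSION_SUFFIX = re.compile(r"\.\d+$")
_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')


def strip_version(identifier: str) -> str:
    """Remove one trailing ``.<digits>`` run; other IDs pass unchanged."""
    return _VERSION_SUFFIX.sub("", identifier)


@dataclass(frozen=True)
class T2GRecord:
    transcript_id: str
    gene_id: str
    gene_name: str
    transcript_id_noversion: str
    gene_id_noversion: str


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return {key: value for key, value in _ATTR.findall(attr_field)}


def gtf_to_t2g(source: TextSource, include_name: bool = False) -> list[T2GRecord]:
    """Extract one record per distinct transcript from a GTF.

    Rows with feature type ``transcript`` are used; if a file has none (some
    annotations only ship exon/CDS rows), any row carrying both ``gene_id``
    and ``transcript_id`` attributes is used instead, deduplicated on
    transcript ID (first occurrence wins).  ``gene_name`` is kept only when
    ``include_name`` is set and the attribute is present.
    """
    own = isinstance(source, (str, os.PathLike))
    handle = open(source, "r", encoding="utf-8") if own else source
    transcript_rows: dict[str, tuple[str, str]] = {}
    fallback_rows: dict[str, tuple[str, str]] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(
                    f"GTF line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            feature = fields[2]
            attrs = _parse_attributes(fields[8])
            transcript_id = attrs.get("transcript_id")
            gene_id = attrs.get("gene_id")
            if transcript_id is None:
                continue
            if gene_id is None:
                raise ParseError(
                    f"GTF line {lineno}: transcript_id without gene_id"
                )
            name = attrs.get("gene_name", "") if include_name else ""
            if feature == "transcript":
                transcript_rows.setdefault(transcript_id, (gene_id, name))
            else:
                fallback_rows.setdefault(transcript_id, (gene_id, name))
    finally:
        if own:
            handle.close()
    rows = transcript_rows if transcript_rows else fallback_rows
    return [
        T2GRecord(
            transcript_id=tid,
            gene_id=gid,
            gene_name=name,
            transcript_id_noversion=strip_version(tid),
            gene_id_noversion=strip_version(gid),
        )
        for tid, (gid, name) in rows.items()
    ]


def write_t2g(records: Sequence[T2GRecord], destination: TextSource) -> None:
    """Write ``transcript_id\\tgene_id\\tgene_name`` TSV."""
    own = isinstance(destination, (str, os.PathLike))
    handle = open(destination, "w", encoding="utf-8") if own else destination
    try:
        handle.write("transcript_id\tgene_id\tgene_name\n")
        for r in records:
            handle.write(f"{r.transcript_id}\t{r.gene_id}\t{r.gene_name}\n")
    finally:
        if own:
            handle.close()


def _seqid_index(records: Iterable[OrthomapRecord]) -> tuple[dict[str, int], dict[str, int]]:
    """Exact and versionless seqID→psnum lookup tables.

    When two orthomap seqIDs collide on their versionless form, the older
    (smaller) psnum wins, with a warning — conservative age assignment.
    """
    exact: dict[str, int] = {}
    noversion: dict[str, int] = {}
    for r in records:
        exact.setdefault(r.seq_id, r.psnum)
        key = strip_version(r.seq_id)
        if key in noversion and noversion[key] != r.psnum:
            warnings.warn(
                f"versionless seqID {key!r} matches multiple age classes; "
                "keeping the older one",
                stacklevel=3,
            )
            noversion[key] = min(noversion[key], r.psnum)
        else:
            noversion.setdefault(key, r.psnum)
    return exact, noversion


def map_genes(
    names: Sequence[str],
    orthomap_records: Iterable[OrthomapRecord],
    t2g: Sequence[T2GRecord] | None = None,
) -> tuple[dict[str, int], list[str]]:
    """Resolve expression-matrix gene identifiers to age classes.

    Resolution order per identifier (first hit wins, deterministic):

    1. exact match against orthomap seqIDs;
    2. versionless match (both sides stripped of a trailing ``.<digits>``);
    3. transcript→gene translation through ``t2g``, then steps 1–2 on the
       gene ID.

    Returns the resolved mapping and the list of unresolved identifiers, in
    input order.  Many matrix names may resolve to one seqID; one name never
    resolves to two age classes.
    """
    exact, noversion = _seqid_index(orthomap_records)
    t2g_exact: dict[str, str] = {}
    t2g_noversion: dict[str, str] = {}
    for rec in t2g or ():
        t2g_exact.setdefault(rec.transcript_id, rec.gene_id)
        t2g_noversion.setdefault(rec.transcript_id_noversion, rec.gene_id)

    def resolve(name: str) -> int | None:
        if name in exact:
            return exact[name]
        stripped = strip_version(name)
        if stripped in noversion:
            return noversion[stripped]
        gene = t2g_exact.get(name) or t2g_noversion.get(stripped)
        if gene is not None:
            if gene in exact:
                return exact[gene]
            gene_stripped = strip_version(gene)
            if gene_stripped in noversion:
                return noversion[gene_stripped]
        return None

    mapping: dict[str, int] = {}
    unresolved: list[str] = []
    for name in names:
        ps = resolve(name)
        if ps is None:
            unresolved.append(name)
        else:
            mapping[name] = ps
    return mapping, unresolved
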