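"""Readers and writers for DrugProt-style corpus files.

All four file kinds are plain UTF-8 TSV without a header row:

* abstracts:   ``doc_id <TAB> title <TAB> abstract``
* entities:    ``doc_id <TAB> mention_id <TAB> etype <TAB> start <TAB> end <TAB> surface``
* relations:   ``doc_id <TAB> rtype <TAB> Arg1:Tx <TAB> Arg2:Ty``
* predictions: same shape as relations, deduplicated and sorted on write.

Offset dialect: character offsets are 0-based and half-open, computed over
``title + "\\t" + abstract`` (the concatenation used by the DrugProt
distribution). Offsets count raw code points; no Unicode normalization is
applied. A mention that straddles the title/abstract TAB separator is
rejected during validation rather than guessed at.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from dtre.relations import RELATION_TYPES, is_relation_type

log = logging.getLogger(__name__)

ENTITY_TYPES = ("CHEMICAL", "GENE-Y", "GENE-N")
GENE_TYPES = ("GENE-Y", "GENE-N")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files or inconsistent annotations."""


@dataclass
class Document:
    """A titled abstract with its derived full text.

    ``full_text`` is ``title + "\\t" + abstract``; entity offsets refer to
    it. ``sentence_spans`` starts empty and is filled by the sentence
    splitter in :mod:`dtre.instance_gen`.
    """

    doc_id: str
    title: str
    abstract: str
    sentence_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return self.title + "\t" + self.abstract


@dataclass(frozen=True)
class EntityMention:
    """A typed character span (chemical or gene) in one document."""

    mention_id: str
    doc_id: str
    etype: str
    start: int
    end: int
    surface: str
    norm_id: str | None = None

    @property
    def is_chemical(self) -> bool:
        return self.etype == "CHEMICAL"

    @property
    def is_gene(self) -> bool:
        return self.etype in GENE_TYPES


@dataclass(frozen=True, order=True)
class RelationAnnotation:
    """One gold or predicted relation: (doc, type, chemical arg, gene arg)."""

    doc_id: str
    rtype: str
    arg1: str
    arg2: str


@dataclass
class CorpusStats:
    n_documents: int
    n_chemical_mentions: int
    n_gene_mentions: int
    relation_counts: dict[str, int]


def _read_tsv_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            yield lineno, line.split("\t")


def read_abstracts(path: str | Path) -> list[Document]:
    """Read an abstracts TSV into Documents, preserving file order.

    Each line must carry at least (doc_id, title, abstract); any further
    TAB-separated fields are folded back into the abstract so that the
    derived full text keeps every character of the line after the second
    TAB.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 3:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
            )
        doc_id, title = fields[0], fields[1]
        abstract = "\t".join(fields[2:])
        if not doc_id:
            raise CorpusFormatError(f"{path}:{lineno}: empty doc_id")
        if doc_id in seen:
            raise CorpusFormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
        seen.add(doc_id)
        docs.append(Document(doc_id=doc_id, title=title, abstract=abstract))
    return docs


def read_entities(
    path: str | Path,
    documents: Sequence[Document] | None = None,
) -> list[EntityMention]:
    """Read an entity-span TSV; validate offsets when ``documents`` given.

    Validation checks that ``full_text[start:end] == surface`` and that the
    span does not straddle the title/abstract TAB separator.
    """
    by_doc = {d.doc_id: d for d in documents} if documents is not None else None
    mentions: list[EntityMention] = []
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 6:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 6 fields (doc_id, mention_id, etype, "
                f"start, end, surface), got {len(fields)}"
            )
        doc_id, mention_id, etype, start_s, end_s = fields[:5]
        surface = "\t".join(fields[5:])
        if etype not in ENTITY_TYPES:
            raise CorpusFormatError(
                f"{path}:{lineno}: unknown entity type {etype!r}; "
                f"expected one of {ENTITY_TYPES}"
            )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise CorpusFormatError(
                f"{path}:{lineno}: non-integer offsets {start_s!r}, {end_s!r}"
            ) from None
        if not (0 <= start < end):
            raise CorpusFormatError(
                f"{path}:{lineno}: invalid span [{start}, {end}) for {mention_id}"
            )
        m = EntityMention(
            mention_id=mention_id,
            doc_id=doc_id,
            etype=etype,
            start=start,
            end=end,
            surface=surface,
        )
        if by_doc is not None:
            doc = by_doc.get(doc_id)
            if doc is None:
                raise CorpusFormatError(
                    f"{path}:{lineno}: mention {mention_id} refers to unknown "
                    f"document {doc_id!r}"
                )
            validate_mention(m, doc)
        mentions.append(m)
    return mentions


def validate_mention(m: EntityMention, doc: Document) -> None:
    """Check a mention's span against its document's full text."""
    text = doc.full_text
    if m.end > len(text):
        raise CorpusFormatError(
            f"mention {m.mention_id} in {m.doc_id}: span [{m.start}, {m.end}) "
            f"exceeds text length {len(text)}"
        )
    actual = text[m.start : m.end]
    if actual != m.surface:
        raise CorpusFormatError(
            f"mention {m.mention_id} in {m.doc_id}: surface {m.surface!r} does "
            f"not match text at [{m.start}, {m.end}) ({actual!r})"
        )
    tab = len(doc.title)
    if m.start <= tab < m.end:
        raise CorpusFormatError(
            f"mention {m.mention_id} in {m.doc_id}: span [{m.start}, {m.end}) "
            f"straddles the title/abstract separator at {tab}"
        )


def _strip_arg(field_value: str, prefix: str, where: str) -> str:
    if not field_value.startswith(prefix):
        raise CorpusFormatError(f"{where}: expected {prefix!r} prefix in {field_value!r}")
    return field_value[len(prefix) :]


def read_relations(
    path: str | Path,
    entities: Sequence[EntityMention] | None = None,
) -> list[RelationAnnotation]:
    """Read a gold/prediction relation TSV.

    Duplicate rows are kept (gold may repeat); arg-type consistency
    (arg1 chemical, arg2 gene) is enforced when ``entities`` are given.
    """
    known: dict[tuple[str, str], EntityMention] = {}
    if entities is not None:
        known = {(m.doc_id, m.mention_id): m for m in entities}
    out: list[RelationAnnotation] = []
    for lineno, fields in _read_tsv_lines(path):
        if len(fields) < 4:
            raise CorpusFormatError(
                f"{path}:{lineno}: expected 4 fields (doc_id, rtype, Arg1:, Arg2:), "
                f"got {len(fields)}"
            )
        doc_id, rtype, a1, a2 = fields[:4]
        if not is_relation_type(rtype):
            raise CorpusFormatError(
                f"{path}:{lineno}: unknown relation type {rtype!r}; "
                f"expected one of {RELATION_TYPES}"
            )
        arg1 = _strip_arg(a1, "Arg1:", f"{path}:{lineno}")
        arg2 = _strip_arg(a2, "Arg2:", f"{path}:{lineno}")
        if entities is not None:
            m1 = known.get((doc_id, arg1))
            m2 = known.get((doc_id, arg2))
            if m1 is None or m2 is None:
                missing = arg1 if m1 is None else arg2
                raise CorpusFormatError(
                    f"{path}:{lineno}: relation refers to unknown mention "
                    f"{missing!r} in document {doc_id}"
                )
            if not m1.is_chemical:
                raise CorpusFormatError(
                    f"{path}:{lineno}: Arg1 {arg1} is {m1.etype}, expected CHEMICAL"
                )
            if not m2.is_gene:
                raise CorpusFormatError(
                    f"{path}:{lineno}: Arg2 {arg2} is {m2.etype}, expected GENE-Y/GENE-N"
                )
        out.append(RelationAnnotation(doc_id=doc_id, rtype=rtype, arg1=arg1, arg2=arg2))
    return out


def write_predictions(
    predictions: Iterable[RelationAnnotation], path: str | Path
) -> None:
    """Write predictions as a relation TSV: deduplicated, sorted rows."""
    rows = sorted(set(predictions))
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            fh.write(f"{r.doc_id}\t{r.rtype}\tArg1:{r.arg1}\tArg2:{r.arg2}\n")


def corpus_stats(
    docs: Sequence[Document],
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation],
) -> CorpusStats:
    """Exact corpus counts: documents, mentions by supertype, relations by type."""
    rel_counts: Counter[str] = Counter(r.rtype for r in relations)
    return CorpusStats(
        n_documents=len(docs),
        n_chemical_mentions=sum(1 for m in entities if m.is_chemical),
        n_gene_mentions=sum(1 for m in entities if m.is_gene),
        relation_counts={r: rel_counts.get(r, 0) for r in RELATION_TYPES},
    )
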