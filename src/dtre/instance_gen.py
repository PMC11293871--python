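"""Marker-tagged classification instances from annotated documents.

Every chemical-gene mention pair co-occurring inside a single sentence
becomes one multi-label instance. The candidate pair is localized for the
encoder with four sentinel tokens: ``[HEAD-S]``/``[HEAD-E]`` around the
chemical (head) and ``[TAIL-S]``/``[TAIL-E]`` around the gene (tail).
The label vector has a 1 for every gold relation type annotated on the
pair and is all-zero for negative pairs; there is no explicit NONE class.

Gold relations whose two arguments never share a sentence cannot be
represented by any instance. They are excluded from generation but can be
counted with :func:`find_unreachable`, since they bound attainable recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from dtre._sentences import sentence_spans
from dtre.corpus_io import Document, EntityMention, RelationAnnotation
from dtre.descriptions import DescriptionRecord, lookup
from dtre.relations import N_CLASSES, RELATION_TYPES, label_index

log = logging.getLogger(__name__)

HEAD_S, HEAD_E, TAIL_S, TAIL_E = "[HEAD-S]", "[HEAD-E]", "[TAIL-S]", "[TAIL-E]"
SEP = "[SEP]"
MARKERS = (HEAD_S, HEAD_E, TAIL_S, TAIL_E)


@dataclass
class RelationInstance:
    """One marker-tagged candidate pair with its multi-hot label."""

    instance_id: str
    doc_id: str
    head_id: str
    tail_id: str
    marked_text: str
    label: np.ndarray  # shape (13,), dtype int8, entries in {0, 1}
    chem_desc: str = ""
    gene_desc: str = ""
    chem_norm_id: str | None = None
    gene_norm_id: str | None = None
    feature_vector: np.ndarray | None = None

    def gold_types(self) -> list[str]:
        return [RELATION_TYPES[i] for i in np.flatnonzero(self.label)]


def split_sentences(doc: Document) -> list[tuple[int, int]]:
    """Sentence spans over ``doc.full_text``; the title is its own sentence.

    The title is everything before the TAB separator; the abstract is split
    with the shared punctuation/abbreviation rule. Stores the result on
    ``doc.sentence_spans`` and returns it.
    """
    spans: list[tuple[int, int]] = []
    title_len = len(doc.title)
    title = doc.title
    lead = len(title) - len(title.lstrip())
    trail = len(title) - len(title.rstrip())
    if lead < title_len - trail:
        spans.append((lead, title_len - trail))
    spans.extend(sentence_spans(doc.abstract, offset=title_len + 1))
    doc.sentence_spans = spans
    return spans


def strip_markers(marked_text: str) -> str:
    """Remove the four sentinel tokens, recovering the original sentence."""
    return (
        marked_text.replace(HEAD_S + " ", "")
        .replace(" " + HEAD_E, "")
        .replace(TAIL_S + " ", "")
        .replace(" " + TAIL_E, "")
    )


def _insert_markers(sentence: str, head: tuple[int, int], tail: tuple[int, int]) -> str:
    # insertions ordered rightmost-first so earlier offsets stay valid;
    # start markers carry a trailing space, end markers a leading space
    edits = sorted(
        [
            (head[0], HEAD_S + " "),
            (head[1], " " + HEAD_E),
            (tail[0], TAIL_S + " "),
            (tail[1], " " + TAIL_E),
        ],
        key=lambda e: e[0],
        reverse=True,
    )
    out = sentence
    for pos, token in edits:
        out = out[:pos] + token + out[pos:]
    return out


def _spans_overlap(a: EntityMention, b: EntityMention) -> bool:
    return a.start < b.end and b.start < a.end


def generate_instances(
    doc: Document,
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation],
) -> list[RelationInstance]:
    """All same-sentence chemical x gene pairs of one document as instances.

    Exactly one instance per co-occurring pair, ordered by (sentence start,
    head start, tail start). Pairs with overlapping or nested spans are
    skipped with a warning because their markup would be ambiguous.
    """
    spans = doc.sentence_spans or split_sentences(doc)
    doc_entities = [m for m in entities if m.doc_id == doc.doc_id]
    gold: dict[tuple[str, str], set[str]] = {}
    for r in relations:
        if r.doc_id == doc.doc_id:
            gold.setdefault((r.arg1, r.arg2), set()).add(r.rtype)

    instances: list[RelationInstance] = []
    for s_start, s_end in spans:
        inside = [m for m in doc_entities if s_start <= m.start and m.end <= s_end]
        chems = sorted((m for m in inside if m.is_chemical), key=lambda m: m.start)
        genes = sorted((m for m in inside if m.is_gene), key=lambda m: m.start)
        sentence = doc.full_text[s_start:s_end]
        for chem in chems:
            for gene in genes:
                if _spans_overlap(chem, gene):
                    log.warning(
                        "doc %s: overlapping spans %s/%s, pair skipped",
                        doc.doc_id,
                        chem.mention_id,
                        gene.mention_id,
                    )
                    continue
                marked = _insert_markers(
                    sentence,
                    (chem.start - s_start, chem.end - s_start),
                    (gene.start - s_start, gene.end - s_start),
                )
                label = np.zeros(N_CLASSES, dtype=np.int8)
                for rtype in gold.get((chem.mention_id, gene.mention_id), ()):
                    label[label_index(rtype)] = 1
                instances.append(
                    RelationInstance(
                        instance_id=f"{doc.doc_id}.{chem.mention_id}.{gene.mention_id}",
                        doc_id=doc.doc_id,
                        head_id=chem.mention_id,
                        tail_id=gene.mention_id,
                        marked_text=marked,
                        label=label,
                        chem_norm_id=chem.norm_id,
                        gene_norm_id=gene.norm_id,
                    )
                )
    return instances


def find_unreachable(
    doc: Document,
    entities: Sequence[EntityMention],
    relations: Sequence[RelationAnnotation],
) -> list[RelationAnnotation]:
    """Gold relations of ``doc`` whose arguments never share a sentence.

    These bound the recall attainable by any same-sentence extractor and
    should be reported alongside evaluation results.
    """
    spans = doc.sentence_spans or split_sentences(doc)
    by_id = {m.mention_id: m for m in entities if m.doc_id == doc.doc_id}
    out: list[RelationAnnotation] = []
    for r in relations:
        if r.doc_id != doc.doc_id:
            continue
        m1, m2 = by_id.get(r.arg1), by_id.get(r.arg2)
        if m1 is None or m2 is None:
            out.append(r)
            continue
        same = any(
            s <= m1.start and m1.end <= e and s <= m2.start and m2.end <= e
            for s, e in spans
        )
        if not same:
            out.append(r)
    return out


def augment_instance(
    inst: RelationInstance,
    chem_table: Mapping[str, DescriptionRecord],
    gene_table: Mapping[str, DescriptionRecord],
) -> RelationInstance:
    """Attach chemical and gene description text looked up by normalized ID.

    Missing descriptions (including GENE-N mentions without an ID) yield
    empty strings; the model-facing text then degrades to the bare
    marker-tagged sentence.
    """
    return replace(
        inst,
        chem_desc=lookup(inst.chem_norm_id, chem_table),
        gene_desc=lookup(inst.gene_norm_id, gene_table),
    )


def build_model_text(
    inst: RelationInstance,
    use_chem_desc: bool = True,
    use_gene_desc: bool = True,
    max_tokens: int = 512,
) -> str:
    """Encoder input: sentence [SEP] chemical description [SEP] gene description.

    A fixed whitespace-token budget applies; the marker-tagged sentence is
    preserved first, then the chemical description, and the gene
    description is truncated last. Separators are emitted only when the
    corresponding description side is enabled.
    """
    parts = [inst.marked_text]
    if use_chem_desc:
        parts += [SEP, inst.chem_desc]
    if use_gene_desc:
        parts += [SEP, inst.gene_desc]
    tokens: list[str] = []
    for part in parts:
        tokens.extend(part.split())
        if len(tokens) >= max_tokens:
            tokens = tokens[:max_tokens]
            break
    return " ".join(tokens)


def write_instances(instances: Iterable[RelationInstance], path: str | Path) -> None:
    """Serialize instances to a TSV for inspection and caching."""
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            label = ",".join(str(int(v)) for v in inst.label)
            fh.write(
                "\t".join(
                    [
                        inst.instance_id,
                        inst.doc_id,
                        inst.head_id,
                        inst.tail_id,
                        inst.marked_text,
                        label,
                        inst.chem_desc,
                        inst.gene_desc,
                        inst.chem_norm_id or "",
                        inst.gene_norm_id or "",
                    ]
                )
                + "\n"
            )


def read_instances(path: str | Path) -> list[RelationInstance]:
    out: list[RelationInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(f"{path}:{lineno}: expected 10 fields, got {len(fields)}")
            label = np.array([int(v) for v in fields[4 + 1].split(",")], dtype=np.int8)
            if label.shape != (N_CLASSES,):
                raise ValueError(f"{path}:{lineno}: label is not {N_CLASSES}-dimensional")
            out.append(
                RelationInstance(
                    instance_id=fields[0],
                    doc_id=fields[1],
                    head_id=fields[2],
                    tail_id=fields[3],
                    marked_text=fields[4],
                    label=label,
                    chem_desc=fields[6],
                    gene_desc=fields[7],
                    chem_norm_id=fields[8] or None,
                    gene_norm_id=fields[9] or None,
                )
            )
    return out
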