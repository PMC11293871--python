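"""Seeded synthetic DrugProt-style corpora with controllable structure.

The generator emulates the shape of an annotated chemical-gene corpus:
multi-sentence abstracts whose sentences each carry one chemical and one
gene span (plus filler), relation labels drawn from the 13-type schema
with a configurable (by default heavily INHIBITOR-skewed) class
distribution, description tables keyed by MeSH / NCBI Gene IDs, and FASTA
sequences for every gene.

Two knobs control where the class signal lives:

* ``trigger_strength`` - probability that a relation sentence contains its
  class's unique trigger lexeme. At 1.0 the corpus is linearly separable
  from sentence text alone (one otherwise-unused token per class), which
  turns end-to-end learnability into a constructive guarantee rather than
  an empirical hope.
* ``description_informativeness`` - probability that, when the sentence
  signal was withheld, the gene's description embeds the class cue
  instead. At (trigger_strength=0, informativeness=1) the corpus is
  solvable only by models that read gene descriptions - the setting used
  to demonstrate the advantage of description-augmented configurations.

Every gene entity is fresh (never shared across documents) and carries the
class of its relation pair, so sentence-only models cannot shortcut a
description-only corpus by memorizing gene names across the train/test
split. A complete ledger records every generated pair, its class and
where its signal lives; ledger counts are the exact oracle for corpus
statistics and instance enumeration tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dtre.corpus_io import Document, EntityMention, RelationAnnotation
from dtre.relations import RELATION_TYPES

# Proportional to a DrugProt-like training distribution: INHIBITOR most
# frequent, AGONIST-INHIBITOR / SUBSTRATE_PRODUCT-OF / AGONIST-ACTIVATOR
# vanishingly rare.
_DEFAULT_WEIGHTS = {
    "INHIBITOR": 5388,
    "DIRECT-REGULATOR": 2247,
    "SUBSTRATE": 2003,
    "ACTIVATOR": 1429,
    "INDIRECT-UPREGULATOR": 1379,
    "INDIRECT-DOWNREGULATOR": 1330,
    "ANTAGONIST": 972,
    "PRODUCT-OF": 921,
    "PART-OF": 886,
    "AGONIST": 659,
    "AGONIST-ACTIVATOR": 29,
    "SUBSTRATE_PRODUCT-OF": 24,
    "AGONIST-INHIBITOR": 13,
}
_TOTAL = sum(_DEFAULT_WEIGHTS.values())
DEFAULT_CLASS_DISTRIBUTION = {r: _DEFAULT_WEIGHTS[r] / _TOTAL for r in RELATION_TYPES}

# one unique, otherwise-unused lexeme per relation class
TRIGGER_TOKENS = {
    r: "trg" + r.lower().replace("-", "").replace("_", "") for r in RELATION_TYPES
}


@dataclass
class SyntheticCorpusConfig:
    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (3, 6)
    class_distribution: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DISTRIBUTION)
    )
    negative_pair_rate: float = 0.3
    trigger_strength: float = 1.0
    description_informativeness: float = 0.0
    gene_n_rate: float = 0.05
    vocab_size: int = 60
    n_chemicals: int = 30
    seq_length_range: tuple[int, int] = (100, 300)
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs <= 0:
            raise ValueError("n_docs must be positive")
        lo, hi = self.sentences_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("sentences_per_doc must be a nonempty positive range")
        total = sum(self.class_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_distribution sums to {total}, expected 1")
        for name, value in [
            ("negative_pair_rate", self.negative_pair_rate),
            ("trigger_strength", self.trigger_strength),
            ("description_informativeness", self.description_informativeness),
            ("gene_n_rate", self.gene_n_rate),
        ]:
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for rtype in self.class_distribution:
            if rtype not in RELATION_TYPES:
                raise ValueError(f"unknown relation type in distribution: {rtype!r}")
        if self.vocab_size < 5:
            raise ValueError("vocab_size must be >= 5")


@dataclass
class SyntheticCorpus:
    docs: list[Document]
    entities: list[EntityMention]
    relations: list[RelationAnnotation]
    ledger: dict
    config: SyntheticCorpusConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write abstracts/entities/relations TSVs plus ledger.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abstracts": outdir / "abstracts.tsv",
            "entities": outdir / "entities.tsv",
            "relations": outdir / "relations.tsv",
            "ledger": outdir / "ledger.json",
        }
        with open(paths["abstracts"], "w", encoding="utf-8") as fh:
            for d in self.docs:
                fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")
        with open(paths["entities"], "w", encoding="utf-8") as fh:
            for m in self.entities:
                fh.write(
                    f"{m.doc_id}\t{m.mention_id}\t{m.etype}\t{m.start}\t{m.end}"
                    f"\t{m.surface}\n"
                )
        with open(paths["relations"], "w", encoding="utf-8") as fh:
            for r in self.relations:
                fh.write(f"{r.doc_id}\t{r.rtype}\tArg1:{r.arg1}\tArg2:{r.arg2}\n")
        with open(paths["ledger"], "w", encoding="utf-8") as fh:
            json.dump(self.ledger, fh, indent=1, sort_keys=True)
        return paths


def _sample_class(rng: np.random.Generator, dist: dict[str, float]) -> str:
    names = [r for r in RELATION_TYPES if dist.get(r, 0.0) > 0]
    probs = np.array([dist[r] for r in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def generate_corpus(config: SyntheticCorpusConfig) -> SyntheticCorpus:
    """Generate a corpus; byte-identical outputs for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = [f"w{i:03d}" for i in range(config.vocab_size)]
    chem_names = [f"cpd{i:02d}" for i in range(config.n_chemicals)]

    docs: list[Document] = []
    entities: list[EntityMention] = []
    relations: list[RelationAnnotation] = []
    pairs: list[dict] = []
    gene_counter = 0

    for di in range(config.n_docs):
        doc_id = str(10000000 + di)
        title = f"Synthetic abstract {doc_id}."
        sentences: list[str] = []
        # (sentence_idx, token_idx_in_sentence, surface, etype, norm_id)
        marks: list[tuple[int, int, str, str, str | None]] = []
        lo, hi = config.sentences_per_doc
        n_sent = int(rng.integers(lo, hi + 1))
        for si in range(n_sent):
            is_negative = rng.random() < config.negative_pair_rate
            chem_idx = int(rng.integers(len(chem_names)))
            chem_surface = chem_names[chem_idx]
            chem_norm = f"MESH:D{chem_idx:06d}"
            gene_counter += 1
            gene_surface = f"gene{gene_counter:05d}"
            is_gene_n = rng.random() < config.gene_n_rate
            gene_norm = None if is_gene_n else str(100000 + gene_counter)
            gene_etype = "GENE-N" if is_gene_n else "GENE-Y"

            rtype: str | None = None
            signal = "none"
            if not is_negative:
                rtype = _sample_class(rng, config.class_distribution)
                signal = (
                    "sentence" if rng.random() < config.trigger_strength else "description"
                )

            tokens: list[str] = [vocab[int(rng.integers(len(vocab)))].capitalize()]
            mid_fill = [
                vocab[int(rng.integers(len(vocab)))]
                for _ in range(int(rng.integers(1, 4)))
            ]
            chem_first = bool(rng.integers(2))
            first, second = (
                (chem_surface, gene_surface) if chem_first else (gene_surface, chem_surface)
            )
            tokens.append(first)
            tokens.extend(mid_fill)
            if signal == "sentence" and rtype is not None:
                tokens.append(TRIGGER_TOKENS[rtype])
                tokens.append(vocab[int(rng.integers(len(vocab)))])
            tokens.append(second)
            tokens.append(vocab[int(rng.integers(len(vocab)))])
            sentence = " ".join(tokens) + "."
            for surface, etype, norm in (
                (chem_surface, "CHEMICAL", chem_norm),
                (gene_surface, gene_etype, gene_norm),
            ):
                marks.append((si, tokens.index(surface), surface, etype, norm))
            sentences.append(sentence)
            pairs.append(
                {
                    "doc_id": doc_id,
                    "sentence_index": si,
                    "chem_norm": chem_norm,
                    "gene_norm": gene_norm,
                    "gene_surface": gene_surface,
                    "rtype": rtype,
                    "signal": signal,
                }
            )

        abstract = " ".join(sentences)
        doc = Document(doc_id=doc_id, title=title, abstract=abstract)
        docs.append(doc)

        # character offsets over full_text = title + TAB + abstract
        sent_starts: list[int] = []
        pos = len(title) + 1
        for s in sentences:
            sent_starts.append(pos)
            pos += len(s) + 1
        t_counter = 0
        mention_ids: dict[tuple[int, str], str] = {}
        for si, tok_idx, surface, etype, norm in marks:
            sentence = sentences[si]
            toks = sentence[:-1].split(" ")
            start = sent_starts[si] + sum(len(t) + 1 for t in toks[:tok_idx])
            end = start + len(surface)
            t_counter += 1
            mid = f"T{t_counter}"
            mention_ids[(si, surface)] = mid
            entities.append(
                EntityMention(
                    mention_id=mid,
                    doc_id=doc_id,
                    etype=etype,
                    start=start,
                    end=end,
                    surface=surface,
                    norm_id=norm,
                )
            )

        # attach mention ids to ledger pairs for this document
        chem_by_sent = {
            si: (sur, mention_ids[(si, sur)])
            for si, _, sur, et, _ in marks
            if et == "CHEMICAL"
        }
        gene_by_sent = {
            si: (sur, mention_ids[(si, sur)])
            for si, _, sur, et, _ in marks
            if et != "CHEMICAL"
        }
        for p in pairs:
            if p["doc_id"] != doc_id:
                continue
            si = p["sentence_index"]
            p["chem_mention"] = chem_by_sent[si][1]
            p["gene_mention"] = gene_by_sent[si][1]
            if p["rtype"] is not None:
                relations.append(
                    RelationAnnotation(
                        doc_id=doc_id,
                        rtype=p["rtype"],
                        arg1=p["chem_mention"],
                        arg2=p["gene_mention"],
                    )
                )

    class_counts: dict[str, int] = {r: 0 for r in RELATION_TYPES}
    for p in pairs:
        if p["rtype"] is not None:
            class_counts[p["rtype"]] += 1
    ledger = {
        "pairs": pairs,
        "class_counts": class_counts,
        "n_docs": len(docs),
        "n_pairs": len(pairs),
        "config": dataclasses.asdict(config),
        "trigger_tokens": dict(TRIGGER_TOKENS),
    }
    return SyntheticCorpus(
        docs=docs, entities=entities, relations=relations, ledger=ledger, config=config
    )


def generate_description_tables(
    corpus: SyntheticCorpus,
) -> tuple[dict[str, str], dict[str, str]]:
    """Chemical and gene description texts keyed by normalized ID.

    Gene descriptions embed the class cue lexeme (the trigger token) with
    probability ``description_informativeness`` for pairs whose sentence
    signal was withheld; the ledger pair entries are annotated with
    ``cue_in_description``. Chemical descriptions are neutral two-sentence
    definitions, exercising the first-sentence rule.
    """
    config = corpus.config
    rng = np.random.default_rng([config.seed, 1])
    chem_table: dict[str, str] = {}
    gene_table: dict[str, str] = {}
    for p in corpus.ledger["pairs"]:
        chem_key = p["chem_norm"]
        if chem_key not in chem_table:
            chem_table[chem_key] = (
                f"A synthetic benchmarking compound ({chem_key}). "
                "It has no physiological role."
            )
        gene_key = p["gene_norm"]
        if gene_key is None:
            p["cue_in_description"] = False
            continue
        text = f"{p['gene_surface']} encodes a synthetic protein."
        cue = (
            p["signal"] == "description"
            and rng.random() < config.description_informativeness
        )
        if cue:
            token = TRIGGER_TOKENS[p["rtype"]]
            text += f" It is associated with {token} activity."
        p["cue_in_description"] = bool(cue)
        gene_table[gene_key] = text
    return chem_table, gene_table


def write_description_table(table: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, text in table.items():
            fh.write(f"{key}\t{text}\n")


def generate_fasta(corpus: SyntheticCorpus, path: str | Path | None = None) -> dict[str, str]:
    """One random amino-acid sequence per normalizable gene ID, seeded."""
    config = corpus.config
    rng = np.random.default_rng([config.seed, 2])
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    lo, hi = config.seq_length_range
    seqs: dict[str, str] = {}
    for p in corpus.ledger["pairs"]:
        key = p["gene_norm"]
        if key is None or key in seqs:
            continue
        length = int(rng.integers(lo, hi + 1))
        seqs[key] = "".join(alphabet[rng.integers(0, 20, size=length)])
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, seq in seqs.items():
                fh.write(f">{key}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    return seqs
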