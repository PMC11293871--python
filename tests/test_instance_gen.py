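import numpy as np
import pytest

from dtre.corpus_io import Document, EntityMention, RelationAnnotation
from dtre.descriptions import DescriptionRecord
from dtre.instance_gen import (
    augment_instance,
    build_model_text,
    find_unreachable,
    generate_instances,
    read_instances,
    split_sentences,
    strip_markers,
    write_instances,
)
from dtre.relations import label_index
from dtre.synthetic_data import SyntheticCorpusConfig, generate_corpus


class TestSplitSentences:
    def test_title_is_its_own_sentence(self):
        doc = Document("1", "T.", "A first. A second.")
        spans = split_sentences(doc)
        assert len(spans) == 3
        assert doc.full_text[slice(*spans[0])] == "T."
        assert doc.full_text[slice(*spans[1])] == "A first."
        assert doc.full_text[slice(*spans[2])] == "A second."

    def test_no_terminal_punctuation_single_span(self):
        doc = Document("1", "Title", "no punctuation here")
        spans = split_sentences(doc)
        assert len(spans) == 2

    def test_abbreviation_does_not_split(self):
        doc = Document("1", "T.", "See Fig. 2 for details. Next sentence.")
        spans = split_sentences(doc)
        texts = [doc.full_text[slice(*s)] for s in spans]
        assert texts == ["T.", "See Fig. 2 for details.", "Next sentence."]


class TestGenerateInstances:
    def test_two_chemicals_one_gene_two_instances(self):
        doc = Document("1", "T.", "Aspirin and ibuprofen inhibit COX2 here.")
        ents = [
            EntityMention("T1", "1", "CHEMICAL", 3, 10, "Aspirin"),
            EntityMention("T2", "1", "CHEMICAL", 15, 24, "ibuprofen"),
            EntityMention("T3", "1", "GENE-Y", 33, 37, "COX2", "101"),
        ]
        insts = generate_instances(doc, ents, [])
        assert [(i.head_id, i.tail_id) for i in insts] == [("T1", "T3"), ("T2", "T3")]

    def test_cross_sentence_pair_excluded_and_reported(self):
        doc = Document("1", "T.", "Aspirin was given. COX2 fell.")
        ents = [
            EntityMention("T1", "1", "CHEMICAL", 3, 10, "Aspirin"),
            EntityMention("T2", "1", "GENE-Y", 22, 26, "COX2", "101"),
        ]
        rels = [RelationAnnotation("1", "INHIBITOR", "T1", "T2")]
        assert generate_instances(doc, ents, rels) == []
        assert find_unreachable(doc, ents, rels) == rels

    def test_label_multi_hot_from_gold(self):
        doc = Document("1", "T.", "Aspirin inhibits COX2 now.")
        ents = [
            EntityMention("T1", "1", "CHEMICAL", 3, 10, "Aspirin"),
            EntityMention("T2", "1", "GENE-Y", 20, 24, "COX2", "101"),
        ]
        rels = [
            RelationAnnotation("1", "INHIBITOR", "T1", "T2"),
            RelationAnnotation("1", "DIRECT-REGULATOR", "T1", "T2"),
        ]
        (inst,) = generate_instances(doc, ents, rels)
        assert inst.label.sum() == 2
        assert inst.label[label_index("INHIBITOR")] == 1
        assert inst.label[label_index("DIRECT-REGULATOR")] == 1

    def test_overlapping_spans_skipped(self, caplog):
        doc = Document("1", "T.", "Aspirin-COX2 conjugate acts here.")
        ents = [
            EntityMention("T1", "1", "CHEMICAL", 3, 15, "Aspirin-COX2"),
            EntityMention("T2", "1", "GENE-Y", 11, 15, "COX2", "101"),
        ]
        assert generate_instances(doc, ents, []) == []

    def test_matches_brute_force_pair_enumeration(self):
        """Instance sets equal exhaustive same-sentence chemical x gene pairs."""
        corpus = generate_corpus(SyntheticCorpusConfig(n_docs=100, seed=5))
        for doc in corpus.docs:
            spans = split_sentences(doc)
            ents = [m for m in corpus.entities if m.doc_id == doc.doc_id]
            expected = set()
            for s, e in spans:
                inside = [m for m in ents if s <= m.start and m.end <= e]
                for c in inside:
                    for g in inside:
                        if c.is_chemical and g.is_gene:
                            expected.add((c.mention_id, g.mention_id))
            got = {
                (i.head_id, i.tail_id)
                for i in generate_instances(doc, ents, corpus.relations)
            }
            assert got == expected

    def test_marker_removal_recovers_sentence_exactly(self, small_corpus):
        for doc in small_corpus.docs:
            spans = split_sentences(doc)
            sentences = {doc.full_text[slice(*s)] for s in spans}
            for inst in generate_instances(doc, small_corpus.entities, small_corpus.relations):
                for marker in ("[HEAD-S]", "[HEAD-E]", "[TAIL-S]", "[TAIL-E]"):
                    assert inst.marked_text.count(marker) == 1
                assert strip_markers(inst.marked_text) in sentences

    def test_every_reachable_gold_is_labelled_once(self, small_corpus):
        hits = {}
        for doc in small_corpus.docs:
            for inst in generate_instances(doc, small_corpus.entities, small_corpus.relations):
                for rtype in inst.gold_types():
                    key = (inst.doc_id, rtype, inst.head_id, inst.tail_id)
                    hits[key] = hits.get(key, 0) + 1
        gold = {(r.doc_id, r.rtype, r.arg1, r.arg2) for r in small_corpus.relations}
        assert set(hits) == gold  # generator produces same-sentence gold only
        assert all(v == 1 for v in hits.values())


class TestAugmentation:
    def make_tables(self):
        chem = {"MESH:D010126": DescriptionRecord("MESH:D010126", "CTD_CHEMICAL", "An oxidant gas.")}
        gene = {"3569": DescriptionRecord("3569", "ENTREZ_GENE", "Cytokine with many roles.")}
        return chem, gene

    def test_descriptions_appended_after_separators(self, tiny_doc):
        doc, ents, rels = tiny_doc
        chem, gene = self.make_tables()
        insts = generate_instances(doc, ents, rels)
        inst = augment_instance(insts[0], chem, gene)
        assert inst.chem_desc == "An oxidant gas."
        assert inst.gene_desc == "Cytokine with many roles."
        text = build_model_text(inst)
        assert text.endswith("[SEP] An oxidant gas. [SEP] Cytokine with many roles.")

    def test_gene_n_without_norm_id_gets_empty_desc(self, tiny_doc):
        doc, ents, rels = tiny_doc
        chem, gene = self.make_tables()
        tnf = [i for i in generate_instances(doc, ents, rels) if i.tail_id == "T3"]
        inst = augment_instance(tnf[0], chem, gene)
        assert inst.gene_desc == ""

    def test_empty_tables_keep_sentence_only(self, tiny_doc):
        doc, ents, rels = tiny_doc
        inst = augment_instance(generate_instances(doc, ents, rels)[0], {}, {})
        assert build_model_text(inst) == inst.marked_text + " [SEP] [SEP]"

    def test_truncation_keeps_sentence_then_chem_then_gene(self, tiny_doc):
        doc, ents, rels = tiny_doc
        inst = generate_instances(doc, ents, rels)[0]
        inst.chem_desc = "c " * 5
        inst.gene_desc = "g " * 50
        n_sentence = len(inst.marked_text.split())
        text = build_model_text(inst, max_tokens=n_sentence + 7)
        tokens = text.split()
        assert len(tokens) == n_sentence + 7
        assert tokens[:n_sentence] == inst.marked_text.split()
        assert "g" not in tokens  # gene description truncated away first


class TestInstanceTsvRoundTrip:
    def test_round_trip(self, tmp_path, small_corpus):
        doc = small_corpus.docs[0]
        insts = generate_instances(doc, small_corpus.entities, small_corpus.relations)
        path = tmp_path / "inst.tsv"
        write_instances(insts, path)
        back = read_instances(path)
        assert len(back) == len(insts)
        for a, b in zip(insts, back):
            assert a.instance_id == b.instance_id
            assert a.marked_text == b.marked_text
            assert np.array_equal(a.label, b.label)
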