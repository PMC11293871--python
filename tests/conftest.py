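import numpy as np
import pytest

from dtre.corpus_io import Document, EntityMention, RelationAnnotation
from dtre.synthetic_data import SyntheticCorpusConfig, generate_corpus


@pytest.fixture
def tiny_doc():
    """One title + two abstract sentences with a chemical and two genes."""
    doc = Document(
        doc_id="1001",
        title="Ozone study.",
        abstract="Ozone increased IL-6 and TNF levels.",
    )
    entities = [
        EntityMention("T1", "1001", "CHEMICAL", 13, 18, "Ozone", "MESH:D010126"),
        EntityMention("T2", "1001", "GENE-Y", 29, 33, "IL-6", "3569"),
        EntityMention("T3", "1001", "GENE-N", 38, 41, "TNF", None),
    ]
    relations = [RelationAnnotation("1001", "INDIRECT-UPREGULATOR", "T1", "T2")]
    return doc, entities, relations


@pytest.fixture
def small_corpus():
    """A 30-document synthetic corpus with full trigger signal."""
    return generate_corpus(SyntheticCorpusConfig(n_docs=30, seed=11))


@pytest.fixture
def corpus_files(tmp_path, small_corpus):
    paths = small_corpus.write(tmp_path)
    return paths, small_corpus
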