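"""From an annotated abstract to marker-tagged, description-augmented instances.

Builds one document by hand, enumerates same-sentence chemical-gene pairs,
and shows the encoder-facing text with [HEAD]/[TAIL] markers and [SEP]-joined
descriptions.
"""

from dtre import Document, EntityMention, RelationAnnotation
from dtre.descriptions import DescriptionRecord
from dtre.instance_gen import augment_instance, build_model_text, generate_instances

doc = Document(
    doc_id="1001",
    title="Ozone study.",
    abstract="Ozone increased IL-6 and TNF levels.",
)
entities = [
    EntityMention("T1", "1001", "CHEMICAL", 13, 18, "Ozone", "MESH:D010126"),
    EntityMention("T2", "1001", "GENE-Y", 29, 33, "IL-6", "3569"),
    EntityMention("T3", "1001", "GENE-N", 38, 41, "TNF", None),  # not normalizable
]
gold = [RelationAnnotation("1001", "INDIRECT-UPREGULATOR", "T1", "T2")]

chem_table = {
    "MESH:D010126": DescriptionRecord(
        "MESH:D010126", "CTD_CHEMICAL", "A highly reactive oxidant gas."
    )
}
gene_table = {
    "3569": DescriptionRecord("3569", "ENTREZ_GENE", "Cytokine involved in inflammation.")
}

for inst in generate_instances(doc, entities, gold):
    inst = augment_instance(inst, chem_table, gene_table)
    print(f"pair {inst.head_id}-{inst.tail_id}  gold={inst.gold_types() or ['(negative)']}")
    print("  " + build_model_text(inst))
# One instance per same-sentence chemical x gene pair: the Ozone/IL-6 pair
# carries the gold label, the Ozone/TNF pair is a negative (all-zero label)
# and its gene description is empty because GENE-N mentions have no ID.
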