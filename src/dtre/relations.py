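"""The 13-type chemical-gene relation schema.

The relation label space is fixed: every classifier head, label vector and
evaluation report in this package is indexed by the tuple below, in this
order. There is no explicit NONE class; an instance with no relation
carries the all-zero label vector.
"""

RELATION_TYPES: tuple[str, ...] = (
    "INDIRECT-DOWNREGULATOR",
    "INDIRECT-UPREGULATOR",
    "DIRECT-REGULATOR",
    "ACTIVATOR",
    "INHIBITOR",
    "AGONIST",
    "ANTAGONIST",
    "AGONIST-ACTIVATOR",
    "AGONIST-INHIBITOR",
    "PRODUCT-OF",
    "SUBSTRATE",
    "SUBSTRATE_PRODUCT-OF",
    "PART-OF",
)

N_CLASSES: int = len(RELATION_TYPES)

_INDEX: dict[str, int] = {r: i for i, r in enumerate(RELATION_TYPES)}


def label_index(rtype: str) -> int:
    """Column index of ``rtype`` in label vectors and probability matrices.

    Raises ``ValueError`` for a string outside the 13-type schema.
    """
    try:
        return _INDEX[rtype]
    except KeyError:
        raise ValueError(
            f"unknown relation type {rtype!r}; expected one of {RELATION_TYPES}"
        ) from None


def is_relation_type(rtype: str) -> bool:
    return rtype in _INDEX
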