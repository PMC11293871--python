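"""Chemical and gene description dictionaries.

Chemical descriptions follow the CTD convention: the first sentence of a
compound's definition field, keyed by MeSH ID. Gene descriptions are
Entrez-style free-text summaries keyed by NCBI Gene ID, stored verbatim
(truncation, when needed, happens at instance-building time). Lookups
never fail: a missing or unnormalizable key (e.g. a GENE-N mention with
no database ID) maps to the empty string so augmentation degrades
gracefully to the sentence-only case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from dtre._sentences import sentence_spans

log = logging.getLogger(__name__)

SOURCES = ("CTD_CHEMICAL", "ENTREZ_GENE", "UNIPROT_PROTEIN")


@dataclass(frozen=True)
class DescriptionRecord:
    key: str
    source: str
    text: str


def load_description_table(
    path: str | Path, source: str = "ENTREZ_GENE"
) -> dict[str, DescriptionRecord]:
    """Load a 2-column (key, text) TSV into a description table.

    Later duplicates overwrite earlier ones with a logged warning. A line
    with no TAB is treated as a key with an empty description.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown description source {source!r}; expected {SOURCES}")
    table: dict[str, DescriptionRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            key, _, text = line.partition("\t")
            if not key:
                raise ValueError(f"{path}:{lineno}: empty key")
            if key in table:
                log.warning(
                    "%s:%d: duplicate key %r, overwriting earlier description",
                    path,
                    lineno,
                    key,
                )
            table[key] = DescriptionRecord(key=key, source=source, text=text)
    return table


def first_sentence(text: str) -> str:
    """First sentence of a definition, per the shared boundary rule.

    Returns the input unchanged (stripped) when no boundary is found.
    Idempotent: applying it twice equals applying it once.
    """
    spans = sentence_spans(text)
    if not spans:
        return text.strip()
    start, end = spans[0]
    return text[start:end]


def lookup(key: str | None, table: Mapping[str, DescriptionRecord]) -> str:
    """Description text for ``key``; empty string for missing/None keys."""
    if key is None:
        return ""
    rec = table.get(key)
    return rec.text if rec is not None else ""
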