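"""Deterministic, dependency-free sentence boundary detection.

A boundary is a run of sentence-terminal punctuation (``. ? !``) followed
by whitespace and an uppercase letter, unless the token ending in the
period is a known abbreviation or a single-letter initial ("J. Smith").
The rule is deliberately simple so that splits are reproducible and easy
to audit; it is shared by the description first-sentence rule and the
abstract sentence splitter.
"""

from __future__ import annotations

import re

# lower-cased trailing tokens that do not terminate a sentence
ABBREVIATIONS = frozenset(
    {
        "e.g.",
        "i.e.",
        "etc.",
        "cf.",
        "vs.",
        "ca.",
        "approx.",
        "dr.",
        "prof.",
        "fig.",
        "figs.",
        "eq.",
        "ref.",
        "refs.",
        "al.",  # "et al."
        "no.",
        "st.",
        "mr.",
        "mrs.",
        "ms.",
    }
)

_BOUNDARY = re.compile(r"[.?!]+(?=\s+[A-Z])")
_TRAILING_TOKEN = re.compile(r"\S+$")
_INITIAL = re.compile(r"(?:^|\s)[A-Z]\.$")


def _is_boundary(text: str, punct_end: int) -> bool:
    token_match = _TRAILING_TOKEN.search(text, 0, punct_end)
    if token_match is None:
        return True
    token = token_match.group(0)
    if token.lower() in ABBREVIATIONS:
        return False
    if _INITIAL.search(text[max(0, punct_end - 3) : punct_end]):
        return False
    return True


def sentence_spans(text: str, offset: int = 0) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans, trimmed of surrounding whitespace.

    Returns ``(start, end)`` pairs relative to the original string shifted
    by ``offset``. Spans cover all non-whitespace characters; text without
    any detected boundary yields a single span.
    """
    cuts = [0]
    for m in _BOUNDARY.finditer(text):
        if _is_boundary(text, m.end()):
            cuts.append(m.end())
    cuts.append(len(text))
    spans: list[tuple[int, int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        chunk = text[a:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if a + lead < b - trail:
            spans.append((offset + a + lead, offset + b - trail))
    return spans
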