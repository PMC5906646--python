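"""Sentence segmentation tuned for scientific prose with inline citations.

Text is split on the terminal period (also ``?``/``!``) with a set of
protection heuristics so that the dot of common scholarly short-hands
("et al.", "ca.", "e.g.") or of abbreviated species names ("H. pylori")
never ends a sentence.  Inline citation markers (see
:mod:`citance.markers`) are preserved in the output, and bibliographic
markers placed *after* a sentence's terminal period — a common JATS
typesetting pattern — are kept with the sentence they belong to, together
with any brackets enclosing them, up to the first alphanumeric character of
the next sentence.

Segmentation is lossless: joining the returned sentences with single spaces
reproduces the input text modulo inter-sentence whitespace.
"""

from __future__ import annotations

import re

from .markers import MARK_END, MARK_START

__all__ = ["PROTECTED_ABBREVIATIONS", "segment_sentences"]

# Vendored, versioned protection list.  Matching is case-insensitive and
# anchored at a word boundary, so "Et al." and "et al." are both protected.
PROTECTED_ABBREVIATIONS: tuple[str, ...] = (
    "et al.",
    "ca.",
    "e.g.",
    "i.e.",
    "cf.",
    "etc.",
    "vs.",
    "viz.",
    "approx.",
    "no.",
    "fig.",
    "figs.",
    "eq.",
    "eqs.",
    "ref.",
    "refs.",
    "dr.",
    "prof.",
    "st.",
    "inc.",
)

_TERMINALS = ".?!"
# Characters that may trail a terminal period and still belong to the
# finished sentence when they enclose a post-period citation marker.
_ATTACHABLE = set(" \t\n\r[](),;") | {MARK_START, MARK_END}

_MARKER_BLOCK = re.compile(
    re.escape(MARK_START) + r"[^" + MARK_END + r"]*" + MARK_END
)


def _abbreviation_end_positions(text: str) -> set[int]:
    """Indices of periods that terminate a protected abbreviation."""
    protected: set[int] = set()
    lower = text.lower()
    for abbr in PROTECTED_ABBREVIATIONS:
        start = 0
        while True:
            i = lower.find(abbr, start)
            if i < 0:
                break
            # require a word boundary before the abbreviation
            if i == 0 or not lower[i - 1].isalnum():
                # protect every '.' inside the abbreviation (e.g. "e.g.")
                for j, ch in enumerate(abbr):
                    if ch == ".":
                        protected.add(i + j)
            start = i + 1
    return protected


def _is_initial(text: str, i: int) -> bool:
    """True if the period at *i* is the dot of an abbreviated species-style
    name: a single capital letter starting a word, followed by a word that
    begins lowercase ("H. pylori").  "showed X. We" is *not* protected —
    the next word starts with a capital, so the period is terminal."""
    if i == 0 or not text[i - 1].isupper():
        return False
    if i >= 2 and text[i - 2].isalnum():
        return False  # "...X." where X ends a longer word
    j = i + 1
    n = len(text)
    while j < n and text[j].isspace():
        j += 1
    return j < n and text[j].islower()


def _attachment_end(text: str, i: int) -> int:
    """Given a terminal at index *i*, return the exclusive end index of the
    sentence after attaching any post-period citation markers.

    Scans forward through whitespace, brackets, commas and marker blocks;
    if at least one marker occurs in that run, the sentence extends through
    the last marker (plus immediately following closing brackets).
    """
    n = len(text)
    j = i + 1
    last_attach = i + 1  # exclusive end if we do attach
    saw_marker = False
    while j < n:
        ch = text[j]
        if ch == MARK_START:
            m = _MARKER_BLOCK.match(text, j)
            if m is None:
                break
            j = m.end()
            saw_marker = True
            last_attach = j
            continue
        if ch in _ATTACHABLE:
            j += 1
            if saw_marker and ch in ")]":
                last_attach = j
            continue
        break
    return last_attach if saw_marker else i + 1


def segment_sentences(text: str) -> list[str]:
    """Split a paragraph into sentences, preserving citation markers.

    Returns an ordered list of sentence strings; empty or whitespace-only
    input yields an empty list.
    """
    if not text or not text.strip():
        return []
    protected = _abbreviation_end_positions(text)
    sentences: list[str] = []
    n = len(text)
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch == MARK_START:
            m = _MARKER_BLOCK.match(text, i)
            if m is not None:
                i = m.end()
                continue
        if ch in _TERMINALS:
            if ch == ".":
                if i in protected or _is_initial(text, i):
                    i += 1
                    continue
                nxt = text[i + 1] if i + 1 < n else ""
                # a period not followed by whitespace/marker/closing bracket
                # is internal ("3.5", "a.b.c")
                if nxt and not (nxt.isspace() or nxt in ")]" or nxt == MARK_START):
                    i += 1
                    continue
            end = _attachment_end(text, i)
            sentence = text[start:end].strip()
            if sentence:
                sentences.append(sentence)
            start = end
            i = end
            continue
        i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences
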