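"""Inline citation-marker encoding for parsed paragraph text.

When a JATS body is flattened to plain text, every ``<xref>`` element is
replaced by a typed inline marker so downstream sentence segmentation and
CS extraction can see where citations sit without re-parsing XML.  Markers
are delimited with Unicode private-use sentinels, which cannot collide with
article text:

    <bibr:B1>        a bibliographic citation pointing at rid B1
    <nonbibr:F1>     a non-bibliographic xref (figure, table, ...)

A single marker may carry several space-separated rids (JATS allows
``rid="B1 B2"``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "MARK_START",
    "MARK_END",
    "Marker",
    "bibr_marker",
    "nonbibr_marker",
    "iter_markers",
    "strip_markers",
    "contains_marker",
]

MARK_START = "\ue000"
MARK_END = "\ue001"

_MARKER_RE = re.compile(
    re.escape(MARK_START) + r"(bibr|nonbibr):([^" + MARK_END + r"]*)" + MARK_END
)


@dataclass(frozen=True)
class Marker:
    """One inline xref occurrence: its kind and the rids it points at."""

    kind: str  # "bibr" | "nonbibr"
    rids: tuple[str, ...]

    @property
    def bibliographic(self) -> bool:
        return self.kind == "bibr"


def _encode(kind: str, rids: str | tuple[str, ...]) -> str:
    if isinstance(rids, str):
        rids = (rids,)
    return f"{MARK_START}{kind}:{' '.join(rids)}{MARK_END}"


def bibr_marker(rids: str | tuple[str, ...]) -> str:
    return _encode("bibr", rids)


def nonbibr_marker(rids: str | tuple[str, ...]) -> str:
    return _encode("nonbibr", rids)


def iter_markers(text: str) -> Iterator[Marker]:
    for m in _MARKER_RE.finditer(text):
        yield Marker(kind=m.group(1), rids=tuple(m.group(2).split()))


def contains_marker(text: str) -> bool:
    return _MARKER_RE.search(text) is not None


def strip_markers(text: str) -> str:
    """Remove all inline markers and tidy the whitespace they leave behind.

    Bracket pairs that enclosed only markers (``[]``, ``()``) are dropped,
    runs of whitespace are collapsed, and stray spaces before sentence
    punctuation are removed, so "X is known <bibr:B1>." comes out
    as "X is known."
    """
    out = _MARKER_RE.sub("", text)
    # bracket pairs left holding only list separators once markers are gone
    out = re.sub(r"\[[\s,;]*\]|\([\s,;]*\)", "", out)
    out = re.sub(r"\s+", " ", out)
    out = re.sub(r"\s+([.,;:?!])", r"\1", out)
    return out.strip()
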