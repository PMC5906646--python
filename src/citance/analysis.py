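"""Text normalization shared by the search index and the fingerprint metric.

The analysis chain mirrors what a stock English retrieval analyzer does to
text before indexing, applied in a fixed order:

    tokenize -> case-fold -> strip punctuation -> drop stop words -> stem

Tokenization splits on any character that is not a letter or a digit, so
punctuation (including hyphens: "α-helix" becomes two tokens) is removed in
the same pass while non-ASCII letters such as Greek symbols survive as
tokens.  The stop-word list is a vendored snapshot of the classic 33-word
English stop set used by mainstream Lucene-style analyzers, pinned here so
analysis is bit-stable across environments.  Stemming is the vendored Porter
stemmer (:mod:`citance.porter`).

The same chain backs both :func:`analyze` (retrieval) and the fingerprint
pipeline, so the fingerprint genuinely emulates how the search engine "sees"
a text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field

from .porter import stem

__all__ = ["STOP_WORDS", "AnalyzedText", "analyze", "tokenize"]

# Vendored snapshot: the classic English stop set of Lucene's StandardAnalyzer.
STOP_WORDS: frozenset[str] = frozenset(
    """
    a an and are as at be but by for if in into is it no not of on or such
    that the their then there these they this to was will with
    """.split()
)

# A token is a maximal run of letters and digits (unicode-aware); everything
# else — punctuation, symbols, underscores — is a separator.
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Split text into raw word tokens, discarding punctuation."""
    return _TOKEN_RE.findall(unicodedata.normalize("NFC", text))


@dataclass(frozen=True)
class AnalyzedText:
    """Ordered, normalized token stream of a text."""

    tokens: tuple[str, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)


def analyze(text: str) -> AnalyzedText:
    """Run the full analysis chain on *text*.

    Returns the ordered list of lower-cased, punctuation-free,
    stop-word-free, stemmed tokens.  Deterministic; empty input yields an
    empty token stream.
    """
    out: list[str] = []
    for raw in tokenize(text):
        word = raw.casefold()
        if word in STOP_WORDS:
            continue
        out.append(stem(word))
    return AnalyzedText(tokens=tuple(out))
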