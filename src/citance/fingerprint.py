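"""Set-based text fingerprints and the CS-vs-source difference statistic.

A *fingerprint* is the deduplicated set of normalized words of a text —
tokenized, case-folded, punctuation-stripped (special symbols such as Greek
letters are kept as tokens), stop-word-free and stemmed, in that order.  It
is a proxy for how a keyword retrieval system "sees" the text, and it uses
exactly the same analysis chain as the search index
(:mod:`citance.analysis`).

The *difference* between a Cited Statement's fingerprint and a reference
fingerprint (the title/abstract or full text of the work it cites) is the
number of CS fingerprint words absent from the reference, reported both as
a count and as a percentage of the CS fingerprint size.  A high difference
means the citing sentence carries wording a keyword search of the cited
document itself could never match.  Per cited document, the analysis keeps
the maximally different CS against each reference — the quantity whose
corpus distribution measures how much information lives only in citing
text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .analysis import analyze

__all__ = [
    "Fingerprint",
    "DifferenceResult",
    "PRComparisonRecord",
    "DifferenceDistribution",
    "make_fingerprint",
    "difference",
    "max_difference_per_pr",
    "compare_corpus",
    "difference_distribution",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fingerprint:
    """Deduplicated set of normalized words of a text."""

    words: frozenset[str]

    def __len__(self) -> int:
        return len(self.words)

    def __bool__(self) -> bool:
        return bool(self.words)


@dataclass(frozen=True)
class DifferenceResult:
    """Words of a CS fingerprint missing from a reference fingerprint."""

    absolute: int
    percent: float


@dataclass(frozen=True)
class PRComparisonRecord:
    """Per-document maxima of the CS-vs-reference difference."""

    pr_id: str
    max_diff_vs_title_abstract: float
    max_diff_vs_fulltext: float
    n_cs: int


def make_fingerprint(text: str) -> Fingerprint:
    """Build the normalized word set of *text* (empty text → empty set)."""
    return Fingerprint(words=frozenset(analyze(text).tokens))


def difference(cs_fp: Fingerprint, ref_fp: Fingerprint) -> DifferenceResult:
    """Count CS fingerprint words absent from the reference fingerprint.

    ``percent`` is 100 * absolute / |cs_fp|.  Raises :class:`ValueError` on
    an empty statement fingerprint, for which the percentage is undefined.
    """
    if not cs_fp:
        raise ValueError("empty statement fingerprint")
    missing = cs_fp.words - ref_fp.words
    absolute = len(missing)
    return DifferenceResult(
        absolute=absolute, percent=100.0 * absolute / len(cs_fp)
    )


def max_difference_per_pr(
    pr_id: str,
    title_abstract_text: str,
    fulltext_text: str,
    cs_texts: Sequence[str],
) -> PRComparisonRecord | None:
    """Maximal CS difference against a document's title/abstract and full text.

    Statements whose fingerprint is empty are skipped with a warning; if no
    usable statement remains, the document is excluded (returns ``None``,
    logged).
    """
    ta_fp = make_fingerprint(title_abstract_text)
    ft_fp = make_fingerprint(fulltext_text)
    max_ta: float | None = None
    max_ft: float | None = None
    n_used = 0
    for text in cs_texts:
        cs_fp = make_fingerprint(text)
        if not cs_fp:
            logger.warning(
                "document %r: skipping statement with empty fingerprint: %r",
                pr_id,
                text,
            )
            continue
        n_used += 1
        d_ta = difference(cs_fp, ta_fp).percent
        d_ft = difference(cs_fp, ft_fp).percent
        max_ta = d_ta if max_ta is None else max(max_ta, d_ta)
        max_ft = d_ft if max_ft is None else max(max_ft, d_ft)
    if n_used == 0:
        logger.warning("document %r has no usable statement; excluded", pr_id)
        return None
    return PRComparisonRecord(
        pr_id=pr_id,
        max_diff_vs_title_abstract=max_ta,
        max_diff_vs_fulltext=max_ft,
        n_cs=n_used,
    )


@dataclass(frozen=True)
class DifferenceDistribution:
    """Histogram of per-document maximum differences for one reference type."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    threshold_fractions: Mapping[float, float]


def _histogram(
    values: np.ndarray, bin_width: float, thresholds: Iterable[float]
) -> DifferenceDistribution:
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, edges = np.histogram(values, bins=edges)
    fractions = {
        float(t): float(np.mean(values >= t)) for t in thresholds
    }
    return DifferenceDistribution(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        threshold_fractions=fractions,
    )


def difference_distribution(
    records: Sequence[PRComparisonRecord],
    bin_width: float = 10.0,
    thresholds_title_abstract: Iterable[float] = (50.0,),
    thresholds_fulltext: Iterable[float] = (25.0,),
) -> dict[str, DifferenceDistribution]:
    """Histogram the per-document maxima for both reference types.

    Returns ``{"title_abstract": ..., "fulltext": ...}``; each histogram's
    counts sum to ``len(records)`` and carry the fraction of documents at or
    above the given thresholds (by default the headline cuts: 50% against
    title/abstract, 25% against full text).
    """
    if not records:
        raise ValueError("no comparison records")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ta = np.array([r.max_diff_vs_title_abstract for r in records], dtype=float)
    ft = np.array([r.max_diff_vs_fulltext for r in records], dtype=float)
    return {
        "title_abstract": _histogram(ta, bin_width, thresholds_title_abstract),
        "fulltext": _histogram(ft, bin_width, thresholds_fulltext),
    }


def compare_corpus(
    cs_list: Sequence,
    pr_texts: Mapping[str, Mapping[str, str]],
) -> list[PRComparisonRecord]:
    """Run the per-document maximum-difference analysis over a CS corpus.

    ``pr_texts`` maps a cited-work identifier (PMID, else DOI, else raw
    reference key) to its ``title_abstract`` and ``fulltext`` strings.
    Statements are grouped by the identifiers they cite; documents without
    reference texts or without usable statements are skipped.  Records come
    back sorted by document id.
    """
    grouped: dict[str, list[str]] = {}
    for cs in cs_list:
        for work in cs.cited:
            key = work.identity[1]
            if key in pr_texts:
                grouped.setdefault(key, []).append(cs.text)
    records: list[PRComparisonRecord] = []
    for pr_id in sorted(grouped):
        texts = pr_texts[pr_id]
        rec = max_difference_per_pr(
            pr_id,
            texts.get("title_abstract", ""),
            texts.get("fulltext", ""),
            grouped[pr_id],
        )
        if rec is not None:
            records.append(rec)
    return records
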