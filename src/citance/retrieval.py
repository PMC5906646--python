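"""Keyword search over Cited Statements with two-tier ranking.

The index stores only the text of each Cited Statement — article and
journal titles are carried as result metadata but are never searchable, so
a query can only match what a citing sentence actually says.

Scoring is Okapi BM25 (k1 = 1.2, b = 0.75) with the smoothed
inverse-document-frequency used by Lucene-family engines:

    idf(t)      = ln(1 + (N - df_t + 0.5) / (df_t + 0.5))
    score(q, d) = sum over query-token occurrences t of
                  idf(t) * tf_td * (k1 + 1) / (tf_td + k1 * (1 - b + b * |d|/avgdl))

where tf_td is t's frequency in the analyzed CS, |d| the analyzed token
count and avgdl its corpus mean.  Document length and all term statistics
are computed on the analyzed (case-folded, stop-word-free, stemmed) tokens.

Results are ordered by the raw score rounded to one decimal place
(descending), ties broken by the number of *shared citations* — for each
retrieved statement, how many other retrieved statements cite at least one
common work — and finally by CS id ascending for determinism.  The
shared-citation pass runs over the full candidate pool (capped at
``pool_size``) before top-k truncation, so statements about heavily
co-cited work float to the top of equal-relevance bands.
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

from .analysis import AnalyzedText, analyze
from .records import CitedStatement

__all__ = [
    "BM25_K1",
    "BM25_B",
    "CSIndex",
    "SearchResult",
    "build_index",
    "score",
    "shared_citation_counts",
    "search",
    "round_score",
]

logger = logging.getLogger(__name__)

BM25_K1 = 1.2
BM25_B = 0.75

#: cap on the candidate pool over which shared citations are counted
DEFAULT_POOL_SIZE = 1000


@dataclass
class CSIndex:
    """Inverted index over Cited-Statement text.

    ``postings`` maps each analyzed token to ``{cs_id: term frequency}``;
    ``store`` keeps the full CS records for result presentation.  CS ids are
    the 0-based positions of the statements in the list the index was built
    from.
    """

    postings: dict[str, dict[int, int]] = field(default_factory=dict)
    doc_lengths: dict[int, int] = field(default_factory=dict)
    store: dict[int, CitedStatement] = field(default_factory=dict)

    @property
    def doc_count(self) -> int:
        return len(self.store)

    @property
    def mean_doc_length(self) -> float:
        if not self.doc_lengths:
            return 0.0
        return sum(self.doc_lengths.values()) / len(self.doc_lengths)

    def save(self, path: str | Path) -> None:
        """Persist the index as JSON (statements plus analyzed postings)."""
        payload = {
            "format": "citance-index-v1",
            "statements": [self.store[i].to_dict() for i in sorted(self.store)],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False)

    @classmethod
    def load(cls, path: str | Path) -> "CSIndex":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format") != "citance-index-v1":
            raise ValueError(f"{path}: not a citance index file")
        cs_list = [CitedStatement.from_dict(d) for d in payload["statements"]]
        return build_index(cs_list)


@dataclass(frozen=True)
class SearchResult:
    cs_id: int
    cs: CitedStatement
    raw_score: float
    rounded_score: float
    shared_citations: int = 0


def build_index(cs_list: Sequence[CitedStatement]) -> CSIndex:
    """Index a non-empty list of Cited Statements.

    Only ``cs.text`` is analyzed and indexed; titles stay metadata.
    """
    if not cs_list:
        raise ValueError("empty corpus")
    index = CSIndex()
    for cs_id, cs in enumerate(cs_list):
        tokens = analyze(cs.text).tokens
        index.store[cs_id] = cs
        index.doc_lengths[cs_id] = len(tokens)
        for token, tf in Counter(tokens).items():
            index.postings.setdefault(token, {})[cs_id] = tf
    return index


def _idf(index: CSIndex, token: str) -> float:
    df = len(index.postings.get(token, ()))
    n = index.doc_count
    return math.log(1.0 + (n - df + 0.5) / (df + 0.5))


def score(index: CSIndex, query: AnalyzedText, cs_id: int) -> float:
    """BM25 relevance of one indexed statement for an analyzed query.

    0.0 when no query token occurs in the statement.  Repeated query tokens
    contribute once per occurrence, as in a standard bag-of-words query.
    """
    if cs_id not in index.store:
        raise KeyError(f"unknown CS id {cs_id}")
    dl = index.doc_lengths[cs_id]
    avgdl = index.mean_doc_length
    total = 0.0
    for token in query:
        tf = index.postings.get(token, {}).get(cs_id, 0)
        if tf == 0:
            continue
        norm = BM25_K1 * (1.0 - BM25_B + BM25_B * dl / avgdl)
        total += _idf(index, token) * tf * (BM25_K1 + 1.0) / (tf + norm)
    return total


def round_score(raw: float) -> float:
    """Round a raw relevance score to one decimal, half away from zero."""
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def shared_citation_counts(results: Iterable[SearchResult]) -> list[SearchResult]:
    """Fill ``shared_citations`` for a retrieved set.

    For each result, counts the *other* results in the set whose cited-work
    set intersects its own (work identity: PMID, else DOI, else raw key).
    """
    results = list(results)
    id_sets = [frozenset(w.identity for w in r.cs.cited) for r in results]
    out: list[SearchResult] = []
    for i, r in enumerate(results):
        count = sum(
            1
            for j, other in enumerate(id_sets)
            if j != i and not id_sets[i].isdisjoint(other)
        )
        out.append(
            SearchResult(
                cs_id=r.cs_id,
                cs=r.cs,
                raw_score=r.raw_score,
                rounded_score=r.rounded_score,
                shared_citations=count,
            )
        )
    return out


def search(
    index: CSIndex,
    keywords: str,
    top_k: int = 10,
    pool_size: int = DEFAULT_POOL_SIZE,
) -> list[SearchResult]:
    """Rank Cited Statements for a keyword query.

    Candidates are all statements with positive BM25 score, capped at
    ``pool_size`` (by raw score, id ascending); shared citations are counted
    over that pool before truncation; the final order is rounded score
    descending, shared citations descending, CS id ascending.
    """
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    query = analyze(keywords)
    if not query.tokens:
        logger.info("query %r is empty after analysis; returning no results", keywords)
        return []

    candidate_ids: set[int] = set()
    for token in set(query.tokens):
        candidate_ids.update(index.postings.get(token, ()))

    scored = []
    for cs_id in candidate_ids:
        raw = score(index, query, cs_id)
        if raw > 0.0:
            scored.append(
                SearchResult(
                    cs_id=cs_id,
                    cs=index.store[cs_id],
                    raw_score=raw,
                    rounded_score=round_score(raw),
                )
            )
    scored.sort(key=lambda r: (-r.raw_score, r.cs_id))
    pool = shared_citation_counts(scored[:pool_size])
    pool.sort(key=lambda r: (-r.rounded_score, -r.shared_citations, r.cs_id))
    return pool[:top_k]
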