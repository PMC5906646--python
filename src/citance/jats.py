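"""JATS (NLM/PMC) article parsing and Cited-Statement extraction.

The Open Access subset of PubMed Central distributes full-text articles in
the JATS XML schema.  Inside a JATS body, citations appear as ``<xref>``
elements whose ``rid`` points into the back-matter ``<ref-list>``; the same
element type is also used for non-bibliographic cross-references (figures,
tables, supplementary files).  This module flattens the body to plain text
with typed inline markers, resolves the reference list into
PMID/DOI-bearing :class:`~citance.records.CitedWork` entries, and emits one
:class:`~citance.records.CitedStatement` per sentence that carries at least
one bibliographic citation.

An ``<xref>`` is treated as bibliographic when ``ref-type="bibr"``, or when
it has no ``ref-type`` but its ``rid`` resolves into the reference list.
Figure/table/other typed xrefs never produce a Cited Statement.
"""

from __future__ import annotations

import logging
import unicodedata

from lxml import etree

from .markers import (
    bibr_marker,
    contains_marker,
    iter_markers,
    nonbibr_marker,
    strip_markers,
)
from .records import ArticleRecord, CitedStatement, CitedWork
from .segmentation import segment_sentences

__all__ = ["parse_jats", "extract_cited_statements", "NON_BIBLIOGRAPHIC_REF_TYPES"]

logger = logging.getLogger(__name__)

# JATS ref-type values that never point at the reference list.
NON_BIBLIOGRAPHIC_REF_TYPES = frozenset(
    {
        "fig",
        "table",
        "table-fn",
        "supplementary-material",
        "sec",
        "app",
        "disp-formula",
        "statement",
        "boxed-text",
        "fn",
        "other",
    }
)


def _text_of(element) -> str:
    return "".join(element.itertext()).strip() if element is not None else ""


def _first(tree, *xpaths):
    for xp in xpaths:
        hits = tree.xpath(xp)
        if hits:
            return hits[0]
    return None


def _parse_references(tree) -> dict[str, CitedWork]:
    references: dict[str, CitedWork] = {}
    for ref in tree.xpath("//back//ref-list/ref | //ref-list/ref"):
        rid = ref.get("id")
        if not rid or rid in references:
            continue
        pmid = doi = None
        for pub_id in ref.xpath(".//pub-id"):
            kind = (pub_id.get("pub-id-type") or "").lower()
            value = (pub_id.text or "").strip()
            if not value:
                continue
            if kind == "pmid" and pmid is None:
                pmid = value
            elif kind == "doi" and doi is None:
                doi = value
        references[rid] = CitedWork(raw_key=rid, pmid=pmid, doi=doi)
    return references


def _flatten(node, references: dict[str, CitedWork], parts: list[str]) -> None:
    """Depth-first flatten of a body element, replacing xrefs by markers."""
    if node.text:
        parts.append(node.text)
    for child in node:
        tag = child.tag if isinstance(child.tag, str) else ""
        if tag == "xref":
            ref_type = (child.get("ref-type") or "").lower()
            rids = tuple((child.get("rid") or "").split())
            if ref_type == "bibr":
                bibliographic = True
            elif ref_type in NON_BIBLIOGRAPHIC_REF_TYPES:
                bibliographic = False
            else:
                # untyped xref: bibliographic iff every rid resolves into
                # the reference list
                bibliographic = bool(rids) and all(r in references for r in rids)
            if rids:
                parts.append(
                    bibr_marker(rids) if bibliographic else nonbibr_marker(rids)
                )
        else:
            _flatten(child, references, parts)
        if child.tail:
            parts.append(child.tail)


def parse_jats(xml_document: str | bytes) -> ArticleRecord:
    """Parse a single JATS article document into an :class:`ArticleRecord`.

    Raises :class:`ValueError` on malformed XML (naming the offending
    line/column) and on documents without a ``<body>``.  A missing
    reference list yields an empty reference map plus a logged warning.
    """
    if isinstance(xml_document, str):
        xml_document = xml_document.encode("utf-8")
    try:
        tree = etree.fromstring(xml_document)
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed JATS XML at line {exc.lineno}, column {exc.position[1]}: "
            f"{exc.msg}"
        ) from exc

    article_id = ""
    for kind in ("pmcid", "pmc", "pmid", "doi"):
        el = _first(tree, f'//article-meta/article-id[@pub-id-type="{kind}"]')
        if el is not None and (el.text or "").strip():
            article_id = el.text.strip()
            break

    article_title = _text_of(_first(tree, "//article-meta//article-title"))
    journal_title = _text_of(
        _first(tree, "//journal-meta//journal-title", "//journal-title")
    )

    body = _first(tree, "//body")
    if body is None:
        raise ValueError("no body")

    references = _parse_references(tree)
    if not references and _first(tree, "//ref-list") is None:
        logger.warning(
            "article %r has no reference list; citations will be unresolved",
            article_id or article_title,
        )

    paragraphs: list[str] = []
    for p in body.xpath(".//p"):
        parts: list[str] = []
        _flatten(p, references, parts)
        text = unicodedata.normalize("NFC", "".join(parts)).strip()
        if text:
            paragraphs.append(text)

    record = ArticleRecord(
        article_id=article_id,
        article_title=article_title,
        journal_title=journal_title,
        paragraphs=paragraphs,
        references=references,
    )
    for paragraph in paragraphs:
        for marker in iter_markers(paragraph):
            if marker.bibliographic:
                for rid in marker.rids:
                    if rid not in references:
                        logger.warning(
                            "article %r: bibliographic xref rid %r does not "
                            "resolve in the reference list",
                            article_id,
                            rid,
                        )
    return record


def _resolve(rid: str, references: dict[str, CitedWork]) -> CitedWork:
    return references.get(rid, CitedWork(raw_key=rid))


def extract_cited_statements(article: ArticleRecord) -> list[CitedStatement]:
    """Extract one Cited Statement per sentence with a bibliographic citation.

    Sentences carrying only non-bibliographic markers (figures, tables)
    yield nothing.  Cited works are deduplicated by PMID, then DOI, then raw
    reference key; markers are stripped from the stored sentence text.
    Unresolved rids still produce a :class:`CitedWork` carrying only the raw
    key (with a logged warning at parse time).
    """
    statements: list[CitedStatement] = []
    for paragraph in article.paragraphs:
        if not contains_marker(paragraph):
            # fast path: a paragraph with no xref can hold no CS
            continue
        for sentence in segment_sentences(paragraph):
            cited: list[CitedWork] = []
            seen: set[tuple[str, str]] = set()
            for marker in iter_markers(sentence):
                if not marker.bibliographic:
                    continue
                for rid in marker.rids:
                    work = _resolve(rid, article.references)
                    if work.identity not in seen:
                        seen.add(work.identity)
                        cited.append(work)
            if not cited:
                continue
            text = strip_markers(sentence)
            if not text:
                continue
            statements.append(
                CitedStatement(
                    text=text,
                    cited=tuple(cited),
                    source_article_id=article.article_id,
                    source_article_title=article.article_title,
                    source_journal_title=article.journal_title,
                )
            )
    return statements
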