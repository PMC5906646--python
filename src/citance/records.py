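"""Core record types: parsed articles, cited works, and Cited Statements.

A Cited Statement (CS) is a sentence from a peer-reviewed article that
carries at least one bibliographic citation.  Each CS record bundles the
citing sentence, the identifiers of the works it cites (PMID or DOI when
resolvable, the raw reference key otherwise), and metadata on the article it
came from (article and journal titles).  CS records are serialized as
newline-delimited JSON, one object per line, which is the bulk interchange
format between pipeline stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

__all__ = [
    "CitedWork",
    "ArticleRecord",
    "CitedStatement",
    "write_cs_json",
    "read_cs_json",
]


@dataclass(frozen=True)
class CitedWork:
    """One entry of an article's reference list.

    At minimum the raw JATS reference key (``rid``) is known; PMID and DOI
    are carried when the reference list resolves them.
    """

    raw_key: str
    pmid: str | None = None
    doi: str | None = None

    @property
    def identity(self) -> tuple[str, str]:
        """Dedup/equality key: PMID if present, else DOI, else the raw rid."""
        if self.pmid:
            return ("pmid", self.pmid)
        if self.doi:
            return ("doi", self.doi)
        return ("raw", self.raw_key)


@dataclass
class ArticleRecord:
    """A parsed JATS article: identifiers, titles, body, reference map.

    ``paragraphs`` holds body text blocks with inline citation markers
    preserved (see :mod:`citance.jats` for the marker encoding);
    ``references`` maps each JATS reference ``rid`` to its
    :class:`CitedWork`.
    """

    article_id: str
    article_title: str = ""
    journal_title: str = ""
    paragraphs: list[str] = field(default_factory=list)
    references: dict[str, CitedWork] = field(default_factory=dict)


@dataclass(frozen=True)
class CitedStatement:
    text: str
    cited: tuple[CitedWork, ...]
    source_article_id: str
    source_article_title: str = ""
    source_journal_title: str = ""

    def __post_init__(self) -> None:
        if not self.cited:
            raise ValueError("a Cited Statement must cite at least one work")

    def to_dict(self) -> dict:
        return {
            "text": self.text,
            "cited": [
                {"pmid": w.pmid, "doi": w.doi, "raw_key": w.raw_key}
                for w in self.cited
            ],
            "source_article_id": self.source_article_id,
            "source_article_title": self.source_article_title,
            "source_journal_title": self.source_journal_title,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CitedStatement":
        return cls(
            text=d["text"],
            cited=tuple(
                CitedWork(
                    raw_key=w.get("raw_key", ""),
                    pmid=w.get("pmid"),
                    doi=w.get("doi"),
                )
                for w in d["cited"]
            ),
            source_article_id=d["source_article_id"],
            source_article_title=d.get("source_article_title", ""),
            source_journal_title=d.get("source_journal_title", ""),
        )


def _open_dest(destination: Union[str, Path, IO[str]], mode: str):
    if hasattr(destination, "write") or hasattr(destination, "read"):
        return destination, False
    return open(destination, mode, encoding="utf-8"), True


def write_cs_json(
    cs_list: Iterable[CitedStatement], destination: Union[str, Path, IO[str]]
) -> int:
    """Write CS records as newline-delimited JSON (UTF-8, stable key order).

    Returns the number of records written.  ``destination`` may be a path or
    an open text handle.
    """
    handle, owned = _open_dest(destination, "w")
    count = 0
    try:
        for cs in cs_list:
            handle.write(json.dumps(cs.to_dict(), ensure_ascii=False))
            handle.write("\n")
            count += 1
    finally:
        if owned:
            handle.close()
    return count


def read_cs_json(source: Union[str, Path, IO[str]]) -> Iterator[CitedStatement]:
    """Stream CS records back from newline-delimited JSON."""
    handle, owned = _open_dest(source, "r")
    try:
        for line in handle:
            line = line.strip()
            if line:
                yield CitedStatement.from_dict(json.loads(line))
    finally:
        if owned:
            handle.close()
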