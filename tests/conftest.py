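import pytest

from citance import (
    CitedStatement,
    CitedWork,
    CorpusSpec,
    build_index,
    extract_cited_statements,
    generate_corpus,
    parse_jats,
)

MINIMAL_JATS = """<article>
 <front>
  <journal-meta><journal-title-group><journal-title>J</journal-title></journal-title-group></journal-meta>
  <article-meta>
   <article-id pub-id-type="pmcid">PMC42</article-id>
   <title-group><article-title>T</article-title></title-group>
  </article-meta>
 </front>
 <body><sec><p>One paragraph of text <xref ref-type="bibr" rid="B1">[1]</xref>.</p></sec></body>
 <back><ref-list>
  <ref id="B1"><element-citation><pub-id pub-id-type="pmid">123</pub-id></element-citation></ref>
 </ref-list></back>
</article>"""


def make_cs(text, pmids=("1",), article_id="PMCX", title="", journal=""):
    return CitedStatement(
        text=text,
        cited=tuple(CitedWork(raw_key=f"B{i}", pmid=p) for i, p in enumerate(pmids)),
        source_article_id=article_id,
        source_article_title=title,
        source_journal_title=journal,
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 30-article generated corpus with its ground truth."""
    spec = CorpusSpec(n_articles=30, sentences_per_article=10, seed=11)
    articles, gt = generate_corpus(spec)
    return spec, articles, gt


@pytest.fixture(scope="session")
def small_cs_list(small_corpus):
    _, articles, _ = small_corpus
    return [
        cs
        for xml in articles
        for cs in extract_cited_statements(parse_jats(xml))
    ]


@pytest.fixture(scope="session")
def small_index(small_cs_list):
    return build_index(small_cs_list)
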