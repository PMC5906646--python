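# citance

Cited-Statement extraction, search and information-content analysis for
biomedical full-text literature.

A **Cited Statement** (CS, also called a *citance*) is a sentence in a
peer-reviewed article that cites other works. Because scientific narrative
is built by citing findings, numbers and techniques from prior
publications, the set of all citing sentences forms a compact,
evidence-annotated view of the literature: each CS is a short comment on
the cited work (*Primary Research*, PR), written by scientists who were
generally not its authors. This package is for text-mining researchers and
literature-search tool builders who want to:

* **extract** CS records from JATS XML (the PubMed Central full-text
  format): the citing sentence, the PMID/DOI of every work it cites, and
  the source article/journal titles;
* **search** a corpus restricted to CS text only, ranked by BM25 relevance
  rounded to one decimal with ties broken by shared citations among the
  results, so statements about heavily co-cited work surface first;
* **quantify** how much of a citing sentence's vocabulary is absent from
  the cited document's own text — the fingerprint-difference statistic that
  measures whether citing text carries information a title/abstract or
  full-text search of the PR itself could never match.

A built-in synthetic JATS corpus generator with exact ground truth makes
every stage testable offline.

## The method

**Extraction.** Body paragraphs are segmented on terminal periods with
protection heuristics for scholarly short-hands ("et al.", "ca.", "e.g.")
and abbreviated species names ("H. pylori"); bibliographic `<xref>`
elements — including those typeset after the sentence's terminal period —
are attached to their sentence, resolved through the back-matter reference
list, and deduplicated by PMID → DOI → raw key. Figure/table xrefs never
produce a CS.

**Ranking.** For an analyzed query q and statement d,

    score(q, d) = Σ_t  idf(t) · tf_td (k1+1) / (tf_td + k1 (1 − b + b·|d|/avgdl))
    idf(t)      = ln(1 + (N − df_t + 0.5)/(df_t + 0.5)),   k1 = 1.2, b = 0.75

Results are ordered by score rounded to one decimal (descending), then by
the number of other retrieved statements sharing ≥ 1 cited work
(descending), then by statement id.

**Fingerprint difference.** A fingerprint is the deduplicated set of
case-folded, punctuation-stripped, stop-word-free, Porter-stemmed words of
a text (Greek symbols retained). For statement fingerprint S and reference
fingerprint R,

    difference = |S \ R|,    percent = 100 · |S \ R| / |S|

and per cited document the analysis reports the *maximum* percent over its
citing statements, against the title/abstract and against the full text.

## Worked example

```bash
citance simulate --out-dir corpus --n-articles 50 --seed 7 --planted-levels '{"PR_A": 50}'
# wrote 50 articles, 266 ground-truth statements to corpus
citance extract corpus --out cs.jsonl
# extracted 266 cited statements from 50 files
citance index cs.jsonl --out cs.index.json
# indexed 266 statements -> cs.index.json
citance search cs.index.json "receptor kinase" --top-k 3
```

```
[  5.8] A synthetic study of electrophoresis and receptor
        Receptor bacteria predation channel xylem amplification kinase diffusion.
        cites: 500009, 500006, 500008
[  3.7] A synthetic study of cognition and vascular
        Capsid cortex cardiac receptor.
        cites: 700000
[  3.4] A synthetic study of vitamin and insulin
        Segregation kinase differentiation stimulus liver.
        cites: 500002, 500008, 500007
```

Each hit shows the rounded relevance score, the title of the article the
statement appears in, the statement itself, and the identifiers of the
works it cites — the triple a CS-based search returns instead of a
title/abstract list. The top hit matches both query stems; the next two
tie groups are ordered by shared citations with the other results.

```bash
citance diff cs.jsonl corpus/pr_texts.json --out diff.tsv
# compared 13 documents -> diff.tsv
head -4 diff.tsv
# pr_id  max_diff_vs_title_abstract  max_diff_vs_fulltext  n_cs
# 500000 100.0000                    100.0000              51
# 500001 100.0000                    100.0000              33
# 500002 100.0000                    100.0000              61
```

Random synthetic statements share no vocabulary with their cited documents,
so their maxima sit at 100%; the planted document `PR_A` (pmid 700000)
comes out at exactly its constructed 50%. The same functions are available
as a library (`parse_jats`, `extract_cited_statements`, `build_index`,
`search`, `make_fingerprint`, `difference`, `compare_corpus`, …) and via
`citance serve` as a JSON-over-HTTP search endpoint.

Statements are interchanged between stages as newline-delimited JSON, one
object per line:

```json
{"text": "...", "cited": [{"pmid": "...", "doi": null, "raw_key": "B1"}],
 "source_article_id": "PMC...", "source_article_title": "...",
 "source_journal_title": "..."}
```

## Layout

| Path | Contents |
| --- | --- |
| `src/citance/jats.py` | JATS parsing, CS extraction |
| `src/citance/segmentation.py` | sentence splitting with abbreviation heuristics |
| `src/citance/analysis.py`, `porter.py` | shared normalization chain, vendored stemmer |
| `src/citance/retrieval.py` | inverted index, BM25, two-tier ranking |
| `src/citance/fingerprint.py` | fingerprints, difference statistic, per-PR maxima |
| `src/citance/synthetic.py` | ground-truth JATS corpus generator |
| `src/citance/cli.py` | `citance simulate / extract / index / search / diff / serve` |
| `docs/methods.md` | model, heuristics, parameter choices, limitations |
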