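# Methods

## What the package computes

A **Cited Statement** (CS, "citance") is a sentence in a peer-reviewed
article that carries at least one bibliographic citation. The package
implements three connected procedures on JATS-formatted full text:

1. **Extraction** — parse JATS XML, segment body paragraphs into sentences,
   and emit one CS record per sentence containing a bibliographic `<xref>`,
   with the cited works resolved to PMID/DOI through the back-matter
   reference list.
2. **Retrieval** — keyword search over a corpus restricted to CS text, with
   BM25 relevance rounded to one decimal and ties broken by shared
   citations among the retrieved set.
3. **Information-content comparison** — per cited document, the maximum
   fingerprint difference between the statements citing it and the
   document's own title/abstract and full text.

## Extraction

### Sentence segmentation

Text is split at terminal `.`, `?`, `!` with protection heuristics:

* **Short-hand list** (vendored, versioned, case-insensitive, word-boundary
  anchored): `et al.`, `ca.`, `e.g.`, `i.e.`, `cf.`, `etc.`, `vs.`, `viz.`,
  `approx.`, `no.`, `fig./figs.`, `eq./eqs.`, `ref./refs.`, `dr.`, `prof.`,
  `st.`, `inc.`. Every dot inside a protected form is non-terminal. The
  cost of the heuristic is deliberate: a sentence genuinely ending in "no."
  will not split. In scientific prose the protected reading is far more
  frequent.
* **Abbreviated name rule**: a period after a single capital letter that
  starts a word is non-terminal when the next word begins lowercase —
  "H. pylori", "S. cerevisiae". The lowercase-next-word condition keeps
  "… showed X. We confirm …" splitting correctly. Initials followed by a
  capitalized surname ("J. Smith") therefore split; such constructions are
  rare inside PMC body text, where narrative citations read "Smith et al.".
* **Numeric guard**: a period not followed by whitespace (or a citation
  marker / closing bracket) is internal — decimals ("pH 7.4") never split.

Inline `<xref>` elements are carried through segmentation as typed markers
delimited by Unicode private-use sentinels (U+E000/U+E001), which cannot
occur in article text. A bibliographic marker (plus brackets and list
separators enclosing it) that follows a sentence's terminal period attaches
backward, up to the first alphanumeric character of the next sentence.
Segmentation is lossless: joining the output reproduces the input modulo
inter-sentence whitespace.

### Bibliographic vs non-bibliographic xrefs

`ref-type="bibr"` is bibliographic; the known non-bibliographic types
(`fig`, `table`, `supplementary-material`, …) never produce a CS; an
untyped `<xref>` is bibliographic iff every `rid` it carries resolves into
`<ref-list>`. Cited works are deduplicated within a sentence by identity
PMID → DOI → raw `rid`. Marker text (the inline "[1]") and bracket pairs
left empty by marker removal are stripped from stored CS text, the
searchable unit being the statement, not reference numerals.

## Text normalization

One analysis chain backs both the index and the fingerprints, in fixed
order: tokenize (split on any non-letter/digit, so punctuation and hyphens
vanish while Greek letters and digits survive as token characters) →
case-fold → drop stop words → stem.

* **Stop words**: the classic 33-word English stop set of Lucene's
  StandardAnalyzer, vendored in `citance.analysis` so results are bit-stable.
* **Stemmer**: the Porter algorithm, implemented in `citance.porter` and
  validated against 75 canonical example pairs from the algorithm's
  published description. Only lower-case ASCII-alphabetic tokens of length
  ≥ 3 are transformed.

Suffix-stripping stemmers are not idempotent ("secretase" → "secretas" →
"secreta"), so re-fingerprinting a fingerprint's own words can rewrite
stems. The package never restems stored tokens; the property tests assert
stability on stem-fixed-point vocabulary only.

## Retrieval

Okapi BM25 with k1 = 1.2, b = 0.75 and the +1-smoothed IDF
`ln(1 + (N − df + 0.5)/(df + 0.5))`; document length is the analyzed token
count and repeated query tokens contribute per occurrence. These constants
are the contemporary defaults of Lucene-family engines; the formula is
fully documented so an independent closed-form evaluation can serve as
test oracle.

Ranking is two-tier: raw scores are rounded to one decimal
(half-away-from-zero, applied via `decimal` on the shortest repr, so
binary-float artifacts do not flip ties), results ordered by rounded score
descending, then **shared citations** descending, then CS id ascending.
Shared citations for a result = the number of *other* results in the
candidate pool whose cited-work set intersects its own. The pool is all
positive-score statements capped at `pool_size` (default 1000, by raw
score then id) and is formed *before* top-k truncation, so the tie-break
sees the same neighbourhood regardless of k. Alternative readings of
"shared citations" (summing per-work co-citation counts, or global citation
counts of the cited work) would also favour heavily co-cited work; the
pairwise-intersection count was chosen as the simplest order-determining
quantity and is what the tests specify. Only CS text is searchable;
article/journal titles are result metadata.

The index keeps postings in memory and persists as JSON of the CS records;
loading rebuilds postings, which for corpora in the intended range (≤ a few
hundred thousand short statements) is cheaper than maintaining an
incremental on-disk structure.

## Fingerprint difference

`difference(cs, ref) = |cs_fp \ ref_fp|`, as a count and as a percentage of
`|cs_fp|` — the denominator is the statement fingerprint because the
question asked is how much of the statement is absent from the reference.
An empty statement fingerprint is an error (skipped with a warning at
pipeline level). Per cited document the analysis reports the maximum
percentage over its citing statements against two references:
title+abstract concatenated, and full text (which includes title/abstract
but excludes the reference list — including bibliographies would trivially
match cited-author surnames). `difference_distribution` histograms the
per-document maxima (default bin width 10 points) and reports the fraction
of documents at or above thresholds, by default 50% vs title/abstract and
25% vs full text.

## Synthetic corpus generator

The generator emulates exactly the structural hazards the extractor must
survive: inline, bracketed-group and post-period bibliographic xrefs,
figure xrefs, protected abbreviations and species short-hands, and a
resolvable reference list. Defaults are the study conditions used
throughout the tests: 200 articles × 10 sentences, citing fraction 0.5,
abbreviation rate 0.3, post-period citation rate 0.2, non-bibliographic
xref rate 0.2 (a modest realistic rate; the first three are the pinned test
conditions, the last is the generator's own choice). Articles cite a
default pool of `max(10, n_articles/4)` external PMIDs (or a caller-pinned
citation graph), which produces overlapping cited-work sets and hence
non-trivial shared-citation tie-breaks.

Sentence vocabulary is a fixed word list filtered at import so every word
survives stop-word removal and maps to a pairwise-distinct stem. Planted
difference levels are therefore engineered in stem space with exact
arithmetic: for a level L% the generator picks the smallest fingerprint
size k ≤ 40 with L·k/100 integral, writes one statement of k reserved
words, a title/abstract sharing exactly k − L·k/100 of them plus filler
from a disjoint reserved block, and a full text adding only more filler; a
second statement made of the shared words (difference 0) exercises the
maximum without moving it. Unattainable levels raise an error naming the
constraint. All randomness derives from `seed` via per-article streams, so
a fixed seed is byte-identical and articles are independent of corpus size.

What the generator does **not** emulate: real citation-count distributions,
multilingual or OCR-damaged text, JATS vendor quirks beyond the tags
parsed, and statements whose wording overlaps the cited document in the
statistically-graded way real citances do. Passing tests therefore show
the machinery is exact on well-formed JATS under these hazards, not that
corpus-scale difference distributions on real PMC data are reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script run on corpora of 10–200 articles
(≈ 50–1000 statements), 20-query oracle sweeps, and 1000 random set pairs —
sizes at which the brute-force oracles (O(n²) shared-citation scan, full
rescoring, naive set subtraction) are exact and fast. BM25 oracle agreement
is asserted to 1e-9 (pure double arithmetic in the same order); planted
difference recovery is asserted exactly (integer set arithmetic);
percentage comparisons elsewhere use exact equality where construction
guarantees it. Degenerate inputs: empty query → empty result (logged);
empty corpus → error; malformed XML → error naming line/column; missing
`<body>` → error; missing `<ref-list>` → warning, extraction proceeds with
raw-key cited works.

## Known limitations

* The abbreviation list is a fixed snapshot; unseen short-hands ("ibid.")
  will split. Results are defined relative to the vendored list and stemmer.
* Sentences in figure captions, tables and footnotes are not extracted
  (only `<body>` `<p>` content), matching the statement-in-prose focus.
* The percent denominator convention (statement fingerprint size) and the
  shared-citation definition are package choices among several defensible
  readings; both are documented above and pinned by tests.
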