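"""Index construction, BM25 scoring oracle, tie-breaking and search contract."""

import math
import random
from collections import Counter

import pytest

from citance import analyze, build_index, score, search, shared_citation_counts
from citance.retrieval import (
    BM25_B,
    BM25_K1,
    SearchResult,
    round_score,
)
from conftest import make_cs


def bm25_reference(cs_texts, query_text, doc_index):
    """Direct evaluation of the documented scoring formula, independent of
    the index implementation."""
    docs = [analyze(t).tokens for t in cs_texts]
    n = len(docs)
    avgdl = sum(len(d) for d in docs) / n
    doc = docs[doc_index]
    tf = Counter(doc)
    total = 0.0
    for token in analyze(query_text).tokens:
        if tf[token] == 0:
            continue
        df = sum(1 for d in docs if token in d)
        idf = math.log(1.0 + (n - df + 0.5) / (df + 0.5))
        norm = BM25_K1 * (1.0 - BM25_B + BM25_B * len(doc) / avgdl)
        total += idf * tf[token] * (BM25_K1 + 1.0) / (tf[token] + norm)
    return total


class TestBuildIndex:
    def test_single_statement_postings(self):
        idx = build_index([make_cs("protein binds DNA")])
        assert set(idx.postings) == {"protein", "bind", "dna"}
        assert idx.doc_count == 1
        assert idx.doc_lengths[0] == 3

    def test_identical_texts_share_postings(self):
        idx = build_index([make_cs("same words"), make_cs("same words")])
        for token in idx.postings:
            assert set(idx.postings[token]) == {0, 1}

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError, match="empty corpus"):
            build_index([])

    def test_corpus_stats_match_recount(self, small_index, small_cs_list):
        """Stored document lengths and counts equal a from-scratch recount."""
        assert small_index.doc_count == len(small_cs_list)
        for cs_id, cs in enumerate(small_cs_list):
            assert small_index.doc_lengths[cs_id] == len(analyze(cs.text))
        for token, postings in small_index.postings.items():
            for cs_id, tf in postings.items():
                recount = Counter(analyze(small_cs_list[cs_id].text).tokens)
                assert recount[token] == tf


class TestScore:
    def test_no_matching_token_scores_zero(self):
        idx = build_index([make_cs("protein binds DNA")])
        assert score(idx, analyze("ribosome"), 0) == 0.0

    def test_unknown_cs_id_is_an_error(self):
        idx = build_index([make_cs("protein binds DNA")])
        with pytest.raises(KeyError):
            score(idx, analyze("protein"), 5)

    def test_single_document_closed_form(self):
        texts = ["protein binds protein strongly"]
        idx = build_index([make_cs(t) for t in texts])
        got = score(idx, analyze("protein binding"), 0)
        want = bm25_reference(texts, "protein binding", 0)
        assert got == pytest.approx(want, abs=1e-9)
        assert want > 0

    def test_duplicate_documents_score_identically(self):
        idx = build_index([make_cs("kinase cascade"), make_cs("kinase cascade")])
        q = analyze("kinase")
        assert score(idx, q, 0) == score(idx, q, 1)

    def test_monotone_in_term_frequency(self):
        # same document length, increasing frequency of the matched term
        idx = build_index(
            [
                make_cs("kinase alpha beta gamma"),
                make_cs("kinase kinase beta gamma"),
                make_cs("kinase kinase kinase gamma"),
            ]
        )
        q = analyze("kinase")
        s = [score(idx, q, i) for i in range(3)]
        assert s[0] < s[1] < s[2]

    def test_engine_equals_oracle_on_generated_corpus(self, small_cs_list):
        texts = [cs.text for cs in small_cs_list[:50]]
        idx = build_index([make_cs(t) for t in texts])
        rng = random.Random(202)
        vocab = sorted({w for t in texts for w in t.replace(".", "").split()})
        for _ in range(20):
            query = " ".join(rng.sample(vocab, 3))
            for cs_id in range(len(texts)):
                assert score(idx, analyze(query), cs_id) == pytest.approx(
                    bm25_reference(texts, query, cs_id), abs=1e-9
                )


class TestSharedCitations:
    def _results(self, cited_groups):
        out = []
        for i, pmids in enumerate(cited_groups):
            cs = make_cs(f"text {i}", pmids=pmids)
            out.append(
                SearchResult(cs_id=i, cs=cs, raw_score=1.0, rounded_score=1.0)
            )
        return out

    def test_all_citing_same_work(self):
        results = shared_citation_counts(self._results([("9",), ("9",), ("9",)]))
        assert [r.shared_citations for r in results] == [2, 2, 2]

    def test_pairwise_disjoint_sets(self):
        results = shared_citation_counts(self._results([("1",), ("2",), ("3",)]))
        assert [r.shared_citations for r in results] == [0, 0, 0]

    def test_mixed_set_matches_brute_force(self):
        groups = [("1", "2"), ("2", "3"), ("4",), ("1", "4"), ("5",)]
        results = shared_citation_counts(self._results(groups))
        sets = [set(g) for g in groups]
        brute = [
            sum(1 for j in range(len(sets)) if j != i and sets[i] & sets[j])
            for i in range(len(sets))
        ]
        assert [r.shared_citations for r in results] == brute


class TestSearch:
    def test_single_match_ranks_first(self):
        idx = build_index(
            [make_cs("unrelated words here"), make_cs("telomere shortening")]
        )
        results = search(idx, "telomere")
        assert [r.cs_id for r in results] == [1]

    def test_equal_rounded_scores_break_by_shared_citations(self):
        # identical texts -> identical scores; citation overlap differs
        idx = build_index(
            [
                make_cs("telomere length", pmids=("solo",)),
                make_cs("telomere length", pmids=("hub",)),
                make_cs("telomere maintenance", pmids=("hub",)),
            ]
        )
        results = search(idx, "telomere length", top_k=3)
        assert results[0].cs_id == 1  # shares "hub" with cs 2
        assert results[0].shared_citations == 1
        assert results[1].cs_id == 0

    def test_empty_query_after_analysis_returns_nothing(self, small_index):
        assert search(small_index, "the of and") == []
        assert search(small_index, "") == []

    def test_query_matching_only_titles_returns_nothing(self):
        idx = build_index(
            [make_cs("membrane transport", title="zebrafish cartography atlas")]
        )
        assert search(idx, "zebrafish cartography atlas") == []

    def test_ordering_matches_brute_force(self, small_index, small_cs_list):
        rng = random.Random(77)
        vocab = sorted(
            {w for cs in small_cs_list for w in cs.text.replace(".", "").split()}
        )
        for _ in range(20):
            query = " ".join(rng.sample(vocab, 2))
            got = search(small_index, query, top_k=len(small_cs_list))
            # brute force: score every doc, round, count shared citations
            q = analyze(query)
            cands = [
                (i, score(small_index, q, i))
                for i in range(len(small_cs_list))
                if score(small_index, q, i) > 0
            ]
            pool = shared_citation_counts(
                SearchResult(
                    cs_id=i,
                    cs=small_cs_list[i],
                    raw_score=s,
                    rounded_score=round_score(s),
                )
                for i, s in cands
            )
            want = sorted(
                pool,
                key=lambda r: (-r.rounded_score, -r.shared_citations, r.cs_id),
            )
            assert [(r.cs_id, r.rounded_score, r.shared_citations) for r in got] == [
                (r.cs_id, r.rounded_score, r.shared_citations) for r in want
            ]

    def test_top_k_is_a_prefix_of_the_full_ranking(self, small_index):
        full = search(small_index, "protein receptor", top_k=1000)
        head = search(small_index, "protein receptor", top_k=3)
        assert [r.cs_id for r in head] == [r.cs_id for r in full[:3]]

    def test_repeated_queries_are_deterministic(self, small_index):
        a = search(small_index, "kinase pathway", top_k=20)
        b = search(small_index, "kinase pathway", top_k=20)
        assert [(r.cs_id, r.raw_score) for r in a] == [
            (r.cs_id, r.raw_score) for r in b
        ]


class TestRounding:
    @pytest.mark.parametrize(
        "raw,expected",
        [(0.25, 0.3), (0.24, 0.2), (1.05, 1.1), (2.349, 2.3), (0.0, 0.0)],
    )
    def test_half_away_from_zero_to_one_decimal(self, raw, expected):
        assert round_score(raw) == expected


def test_index_persistence_round_trip(tmp_path, small_cs_list):
    from citance.retrieval import CSIndex

    idx = build_index(small_cs_list)
    path = tmp_path / "idx.json"
    idx.save(path)
    loaded = CSIndex.load(path)
    assert loaded.postings == idx.postings
    assert loaded.doc_lengths == idx.doc_lengths
    assert loaded.store == idx.store
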