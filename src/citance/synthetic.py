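"""Synthetic JATS corpus generator with exact Cited-Statement ground truth.

Generates well-formed JATS article XML whose citing sentences, citation
targets and text content are known by construction, so extraction,
retrieval ranking and fingerprint analyses can be validated without any
external download.  The generator emulates the features of real PMC
articles that the extraction heuristics must survive:

* body paragraphs of multi-word sentences,
* inline ``<xref ref-type="bibr">`` citations, singly and in bracketed
  groups, at configurable rates,
* citations typeset *after* the sentence's terminal period,
* non-bibliographic ``<xref>`` elements (figure references) that must never
  produce a Cited Statement,
* abbreviation-bearing text ("et al.", "ca.", abbreviated species names)
  that must not trigger sentence splits,
* a back-matter reference list resolving each rid to a PMID.

Sentence vocabulary is drawn from a fixed word list filtered so that every
word survives stop-word removal and maps to a distinct stem; planted
fingerprint-difference levels are therefore engineered exactly, in stem
space.  All randomness derives from the spec's seed; a fixed seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from lxml import etree

from .analysis import STOP_WORDS
from .porter import stem

__all__ = ["CorpusSpec", "GroundTruth", "generate_article", "generate_corpus"]

# Candidate vocabulary; filtered below so every kept word is stop-word-free
# and stems are pairwise distinct — fingerprint arithmetic is then exact.
_RAW_VOCABULARY = """
protein binding receptor kinase pathway signal membrane nucleus genome
transcription expression sequence mutation variant allele phenotype enzyme
substrate inhibitor activation phosphorylation cascade cytoplasm organelle
mitochondria ribosome translation polymerase replication chromatin histone
methylation antibody antigen epitope lymphocyte macrophage cytokine
inflammation infection bacteria virus capsid plasmid vector cloning primer
amplification electrophoresis chromatography spectrometry microscopy
fluorescence crystallography resolution structure domain helix strand loop
folding stability affinity kinetics equilibrium gradient diffusion osmosis
channel transporter pump synapse neuron axon dendrite cortex hippocampus
behavior cognition memory stimulus response dosage toxicity clearance
metabolism liver kidney cardiac vascular endothelium platelet coagulation
tumor metastasis apoptosis proliferation differentiation stemness niche
microbiome symbiosis ecology population diversity selection drift lineage
phylogeny speciation adaptation fitness genotype epistasis recombination
segregation meiosis mitosis spindle centromere telomere senescence
oxidation reduction catalysis cofactor vitamin hormone insulin glucose
lipid cholesterol micelle bilayer porin flagellum chemotaxis biofilm
quorum sporulation germination drought salinity photosynthesis chlorophyll
stomata xylem phloem pollination herbivory predation parasitism mutualism
""".split()


def _build_vocabulary(raw: Sequence[str]) -> tuple[str, ...]:
    seen_stems: set[str] = set()
    vocab: list[str] = []
    for word in raw:
        s = stem(word)
        if word in STOP_WORDS or s in STOP_WORDS or s in seen_stems:
            continue
        seen_stems.add(s)
        vocab.append(word)
    return tuple(vocab)


VOCABULARY: tuple[str, ...] = _build_vocabulary(_RAW_VOCABULARY)

# Abbreviation-bearing sentence openers; the protected dots must never end
# a sentence.
_ABBREV_OPENERS = (
    "Smith et al. reported that",
    "In H. pylori,",
    "Estimates of ca.",
    "E. coli assays suggest",
    "Earlier work (e.g. classic assays) indicated",
)

_JOURNALS = (
    "Journal of Synthetic Biology",
    "Annals of Generated Research",
    "Synthetic Reviews in Medicine",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a generated corpus.

    Rates are proportions in [0, 1]; ``shared_citation_graph`` optionally
    pins which PMIDs each article may cite (keyed by article index);
    ``planted_difference_levels`` maps a document label to the exact maximum
    fingerprint difference (percent) its Cited Statements must exhibit.
    """

    n_articles: int = 200
    sentences_per_article: int = 10
    citing_fraction: float = 0.5
    abbreviation_rate: float = 0.3
    post_period_citation_rate: float = 0.2
    non_bibliographic_rate: float = 0.2
    shared_citation_graph: Mapping[int, Sequence[str]] | None = None
    planted_difference_levels: Mapping[str, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 1:
            raise ValueError("n_articles must be >= 1")
        if self.sentences_per_article < 1:
            raise ValueError("sentences_per_article must be >= 1")
        for name in (
            "citing_fraction",
            "abbreviation_rate",
            "post_period_citation_rate",
            "non_bibliographic_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.planted_difference_levels:
            for label, level in self.planted_difference_levels.items():
                if not 0.0 <= level <= 100.0:
                    raise ValueError(
                        f"planted level for {label!r} must be in [0, 100]"
                    )
                _fingerprint_size_for_level(level)  # raises if unattainable


@dataclass(frozen=True)
class GTStatement:
    """Ground truth for one citing sentence: its marker-free text and the
    PMIDs it cites, in order of first occurrence."""

    text: str
    cited_pmids: tuple[str, ...]


@dataclass
class GroundTruth:
    """What the generator actually wrote: every citing sentence per article,
    planted difference levels, and the reference texts of cited documents."""

    statements_per_article: dict[str, list[GTStatement]] = field(
        default_factory=dict
    )
    #: label -> {"pmid": ..., "level": ...} for planted documents
    planted: dict[str, dict] = field(default_factory=dict)
    #: pmid -> {"title_abstract": ..., "fulltext": ...}
    pr_texts: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def cs_count(self) -> int:
        return sum(len(v) for v in self.statements_per_article.values())

    def to_json(self) -> str:
        payload = {
            "cs_count": self.cs_count,
            "articles": [
                {
                    "article_id": aid,
                    "statements": [
                        {"text": s.text, "cited_pmids": list(s.cited_pmids)}
                        for s in stmts
                    ],
                }
                for aid, stmts in self.statements_per_article.items()
            ],
            "planted": self.planted,
            "pr_texts": self.pr_texts,
        }
        return json.dumps(payload, ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        gt = cls()
        for art in payload["articles"]:
            gt.statements_per_article[art["article_id"]] = [
                GTStatement(
                    text=s["text"], cited_pmids=tuple(s["cited_pmids"])
                )
                for s in art["statements"]
            ]
        gt.planted = payload.get("planted", {})
        gt.pr_texts = payload.get("pr_texts", {})
        return gt


def _fingerprint_size_for_level(level: float) -> int:
    """Smallest statement fingerprint size at which *level* percent of the
    words can be missing from the reference with zero remainder."""
    for k in range(4, 41):
        missing = level * k / 100.0
        if abs(missing - round(missing)) < 1e-9:
            return k
    raise ValueError(
        f"planted difference level {level}% is not attainable with a "
        f"statement fingerprint of at most 40 words"
    )


def _article_pmcid(index: int) -> str:
    return f"PMC{1000000 + index}"


# ---------------------------------------------------------------------------
# sentence assembly


@dataclass
class _Sentence:
    """One generated sentence: XML parts (text or xref tuples) plus the
    marker-free text and (rid, pmid) citation pairs recorded as ground
    truth."""

    parts: list  # str | ("xref", ref_type, rid, display)
    plain: str
    cites: tuple[tuple[str, str], ...] = ()

    @property
    def cited_pmids(self) -> tuple[str, ...]:
        return tuple(p for _, p in self.cites)


def _compose_citing(
    core: str, rid_pmids: Sequence[tuple[str, str]], rng: random.Random,
    post_period: bool,
) -> _Sentence:
    """Attach bibliographic xrefs to a sentence core (no trailing period)."""
    xrefs = [
        ("xref", "bibr", rid, f"[{i + 1}]") for i, (rid, _) in enumerate(rid_pmids)
    ]
    cites = tuple(rid_pmids)
    if post_period:
        parts: list = [core + "."]
        parts.extend(xrefs)
        return _Sentence(parts=parts, plain=core + ".", cites=cites)
    style = rng.choice(("inline", "bracketed"))
    parts = [core + " "]
    if style == "bracketed":
        parts.append("[")
        for i, x in enumerate(xrefs):
            if i:
                parts.append(", ")
            parts.append(x)
        parts.append("].")
    else:
        for i, x in enumerate(xrefs):
            if i:
                parts.append(" ")
            parts.append(x)
        parts.append(".")
    return _Sentence(parts=parts, plain=core + ".", cites=cites)


def _random_sentence(
    spec: CorpusSpec,
    rng: random.Random,
    targets: Sequence[tuple[str, str]],
    fig_counter: list[int],
) -> _Sentence:
    n_words = rng.randint(5, 9)
    words = rng.sample(VOCABULARY, n_words)
    core = " ".join(words)
    if rng.random() < spec.abbreviation_rate:
        core = rng.choice(_ABBREV_OPENERS) + " " + core
    else:
        core = core[0].upper() + core[1:]

    cites = bool(targets) and rng.random() < spec.citing_fraction
    fig = rng.random() < spec.non_bibliographic_rate
    if fig:
        fig_counter[0] += 1
        fig_part = ("xref", "fig", f"F{fig_counter[0]}", f"Fig. {fig_counter[0]}")

    if not cites:
        parts = [core + " (", fig_part, ")."] if fig else [core + "."]
        return _Sentence(parts=parts, plain=core + ".")

    n_cites = rng.randint(1, min(3, len(targets)))
    rid_pmids = rng.sample(list(targets), n_cites)
    post = rng.random() < spec.post_period_citation_rate
    if fig:
        # "(Fig. N)" sits inside the xref, so marker stripping removes the
        # whole parenthetical and the plain text stays the bare core
        sent = _compose_citing(core, rid_pmids, rng, post_period=False)
        sent.parts[0] = core + " ("
        sent.parts.insert(1, fig_part)
        sent.parts.insert(2, ") ")
        return sent
    return _compose_citing(core, rid_pmids, rng, post_period=post)


def _build_paragraph(sentences: Sequence[_Sentence]) -> etree._Element:
    p = etree.Element("p")
    cursor = None  # last child element, or None while still in p.text
    for si, sent in enumerate(sentences):
        parts = list(sent.parts)
        if si:
            parts.insert(0, " ")
        for part in parts:
            if isinstance(part, str):
                if cursor is None:
                    p.text = (p.text or "") + part
                else:
                    cursor.tail = (cursor.tail or "") + part
            else:
                _, ref_type, rid, display = part
                x = etree.SubElement(p, "xref", rid=rid)
                x.set("ref-type", ref_type)
                x.text = display
                cursor = x
    return p


def _build_article_xml(
    index: int,
    journal: str,
    title: str,
    paragraphs: Sequence[etree._Element],
    references: Sequence[tuple[str, str]],
) -> str:
    article = etree.Element("article")
    front = etree.SubElement(article, "front")
    jm = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(jm, "journal-title-group")
    etree.SubElement(jtg, "journal-title").text = journal
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id")
    aid.set("pub-id-type", "pmcid")
    aid.text = _article_pmcid(index)
    tg = etree.SubElement(am, "title-group")
    etree.SubElement(tg, "article-title").text = title
    body = etree.SubElement(article, "body")
    sec = etree.SubElement(body, "sec")
    for p in paragraphs:
        sec.append(p)
    back = etree.SubElement(article, "back")
    ref_list = etree.SubElement(back, "ref-list")
    for rid, pmid in references:
        ref = etree.SubElement(ref_list, "ref", id=rid)
        cit = etree.SubElement(ref, "element-citation")
        pub = etree.SubElement(cit, "pub-id")
        pub.set("pub-id-type", "pmid")
        pub.text = pmid
    return etree.tostring(
        article, encoding="unicode", pretty_print=False
    )


def generate_article(
    spec: CorpusSpec,
    article_index: int,
    extra_sentences: Sequence[_Sentence] = (),
) -> tuple[str, list[GTStatement]]:
    """Generate one JATS article and its ground-truth citing sentences.

    Deterministic in ``(spec.seed, article_index)``; ``extra_sentences``
    lets :func:`generate_corpus` append planted statements.
    """
    spec.validate()
    rng = random.Random(f"{spec.seed}:article:{article_index}")

    if spec.shared_citation_graph is not None:
        target_pmids = list(spec.shared_citation_graph.get(article_index, ()))
    else:
        pool = _default_pmid_pool(spec)
        target_pmids = rng.sample(pool, min(5, len(pool)))
    targets = [(f"B{i + 1}", pmid) for i, pmid in enumerate(target_pmids)]

    fig_counter = [0]
    sentences = [
        _random_sentence(spec, rng, targets, fig_counter)
        for _ in range(spec.sentences_per_article)
    ]
    sentences.extend(extra_sentences)

    # reference list: every rid actually cited, with its pmid
    rid_to_pmid: dict[str, str] = {}
    for sent in sentences:
        for rid, pmid in sent.cites:
            rid_to_pmid[rid] = pmid
    references = sorted(rid_to_pmid.items(), key=lambda rp: (len(rp[0]), rp[0]))

    # paragraphs of 3-5 sentences
    paragraphs = []
    i = 0
    while i < len(sentences):
        size = rng.randint(3, 5)
        paragraphs.append(_build_paragraph(sentences[i : i + size]))
        i += size

    title_words = rng.sample(VOCABULARY, 4)
    title = "A synthetic study of " + " and ".join(title_words[:2])
    journal = rng.choice(_JOURNALS)
    xml = _build_article_xml(article_index, journal, title, paragraphs, references)

    gt = [
        GTStatement(text=s.plain, cited_pmids=s.cited_pmids)
        for s in sentences
        if s.cited_pmids
    ]
    return xml, gt


def _default_pmid_pool(spec: CorpusSpec) -> list[str]:
    size = max(10, spec.n_articles // 4)
    return [str(500000 + i) for i in range(size)]


def _plant_statements(
    spec: CorpusSpec, rng: random.Random
) -> tuple[dict[int, list[_Sentence]], dict[str, dict], dict[str, dict[str, str]]]:
    """Build planted-difference statements, reference texts and bookkeeping.

    For each planted document the primary statement shares exactly the right
    number of stems with the document's title/abstract; the full text adds
    reserved filler words absent from every statement, so the planted level
    holds against both references.
    """
    per_article: dict[int, list[_Sentence]] = {}
    planted: dict[str, dict] = {}
    pr_texts: dict[str, dict[str, str]] = {}
    if not spec.planted_difference_levels:
        return per_article, planted, pr_texts

    labels = sorted(spec.planted_difference_levels)
    # reserve vocabulary: planted statements draw from one end, filler from
    # the other, so stems never collide across roles
    filler_words = list(VOCABULARY[-30:])
    usable = list(VOCABULARY[:-30])
    rng.shuffle(usable)
    cursor = 0
    for li, label in enumerate(labels):
        level = float(spec.planted_difference_levels[label])
        k = _fingerprint_size_for_level(level)
        missing = round(level * k / 100.0)
        shared = k - missing
        if cursor + k > len(usable):
            raise ValueError(
                "not enough reserved vocabulary for the requested planted "
                "levels; reduce the number of planted documents"
            )
        words = usable[cursor : cursor + k]
        cursor += k
        pmid = str(700000 + li)
        rid = f"P{li + 1}"
        shared_words = words[:shared]
        core = " ".join(words)
        core = core[0].upper() + core[1:]
        primary = _compose_citing(core, [(rid, pmid)], rng, post_period=False)
        stmts = [primary]
        if shared >= 1:
            sub_core = " ".join(shared_words)
            sub_core = sub_core[0].upper() + sub_core[1:]
            stmts.append(
                _compose_citing(sub_core, [(rid, pmid)], rng, post_period=False)
            )
        article_index = li % spec.n_articles
        per_article.setdefault(article_index, []).extend(stmts)

        ta_fill = rng.sample(filler_words, 3)
        title_abstract = " ".join(shared_words + ta_fill) if shared else " ".join(
            ta_fill
        )
        ft_fill = rng.sample(filler_words, 5)
        fulltext = title_abstract + " " + " ".join(ft_fill)
        planted[label] = {"pmid": pmid, "level": level}
        pr_texts[pmid] = {
            "title_abstract": title_abstract,
            "fulltext": fulltext,
        }
    return per_article, planted, pr_texts


def generate_corpus(spec: CorpusSpec) -> tuple[list[str], GroundTruth]:
    """Generate a whole corpus: article XML strings plus ground truth.

    Reference texts for every citable document (the default PMID pool and
    any planted documents) are recorded in ``GroundTruth.pr_texts`` so the
    fingerprint-difference pipeline can run end-to-end on generated data.
    """
    spec.validate()
    rng = random.Random(f"{spec.seed}:corpus")
    planted_per_article, planted, planted_texts = _plant_statements(spec, rng)

    gt = GroundTruth(planted=planted)
    gt.pr_texts.update(planted_texts)
    if spec.shared_citation_graph is None:
        for pmid in _default_pmid_pool(spec):
            ta = " ".join(rng.sample(VOCABULARY, 12))
            gt.pr_texts[pmid] = {
                "title_abstract": ta,
                "fulltext": ta + " " + " ".join(rng.sample(VOCABULARY, 20)),
            }

    articles: list[str] = []
    for i in range(spec.n_articles):
        xml, stmts = generate_article(
            spec, i, extra_sentences=planted_per_article.get(i, ())
        )
        articles.append(xml)
        gt.statements_per_article[_article_pmcid(i)] = stmts
    return articles, gt
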