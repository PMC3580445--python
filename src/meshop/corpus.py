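"""Annotated article corpora, entity-article links, and validation label sets.

An :class:`AnnotatedCorpus` holds, per article, the ancestor-closed set of
MeSH terms assigned to it, together with the "universal background": the
total number of annotated articles ``N`` and, per term, the number of
articles ``n_i`` whose closed set contains the term.  These background
counts are the null model for the over-representation test.

Entity-article links (gene2pubmed-style) attach article sets to entities;
validation sets label (gene, disease) pairs as positive or negative, either
from a past/future corpus split (novel co-occurrence) or from curated
relationship tuples.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, TextIO

from .vocabulary import MeshVocabulary

__all__ = [
    "AnnotatedCorpus",
    "EntityLinkSet",
    "ValidationSet",
    "PairPolicy",
    "CorpusError",
    "parse_annotations",
    "parse_entity_links",
    "disease_article_set",
    "cooccurrence_count",
    "extract_novel_cooccurrences",
    "load_curated_tuples",
]

logger = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed corpus input or inconsistent label construction."""


class PairPolicy(str, Enum):
    """How pairs already co-occurring in the past corpus enter the universe.

    ``exclude`` drops them entirely (default: no label leakage);
    ``as_negative`` keeps them as negatives; ``as_positive`` labels them
    positive (evaluating recovery of pre-existing relationships).
    """

    EXCLUDE = "exclude"
    AS_NEGATIVE = "as_negative"
    AS_POSITIVE = "as_positive"


@dataclass
class AnnotatedCorpus:
    """Articles with ancestor-closed term sets plus background term counts."""

    articles: dict[str, frozenset[str]] = field(default_factory=dict)
    term_counts: Counter = field(default_factory=Counter)

    @property
    def N(self) -> int:
        """Number of annotated articles in the background."""
        return len(self.articles)

    def term_articles(self, term_id: str) -> set[str]:
        """All articles whose closed term set contains the term."""
        return {aid for aid, terms in self.articles.items() if term_id in terms}


@dataclass
class EntityLinkSet:
    """Deduplicated entity -> article-id-set links with a source label."""

    links: dict[str, frozenset[str]] = field(default_factory=dict)
    source_tag: str = "generic"

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.links

    def articles(self, entity_id: str) -> frozenset[str]:
        return self.links.get(entity_id, frozenset())


@dataclass
class ValidationSet:
    """Labeled (gene, disease) pair universe.

    ``positives`` is a subset of ``universe``; pairs in the universe but
    not in positives are the negatives.
    """

    positives: frozenset[tuple[str, str]]
    universe: frozenset[tuple[str, str]]
    mode: str

    def __post_init__(self) -> None:
        if not self.positives <= self.universe:
            raise CorpusError("positives must be a subset of the universe")

    @property
    def negatives(self) -> frozenset[tuple[str, str]]:
        return self.universe - self.positives

    def label(self, pair: tuple[str, str]) -> bool:
        return pair in self.positives


def _data_rows(stream: TextIO | Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def parse_annotations(
    stream: TextIO | Iterable[str], vocab: MeshVocabulary
) -> AnnotatedCorpus:
    """Read an annotation TSV (article_id, term_id) into an AnnotatedCorpus.

    Per-article term sets are ancestor-closed before counting, so a term
    assigned to an article also increments the count of every ancestor.
    Rows whose term id is not in the vocabulary are skipped and counted in
    a log message; this keeps partial vocabularies usable.
    """
    raw: dict[str, set[str]] = {}
    skipped = 0
    for lineno, fields in _data_rows(stream):
        if len(fields) != 2:
            raise CorpusError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        article_id, term_id = (f.strip() for f in fields)
        if not article_id or not term_id:
            raise CorpusError(f"line {lineno}: empty article id or term id")
        if term_id not in vocab:
            skipped += 1
            continue
        raw.setdefault(article_id, set()).add(term_id)
    if skipped:
        logger.info("parse_annotations: skipped %d rows with unknown terms", skipped)

    corpus = AnnotatedCorpus()
    for article_id, terms in raw.items():
        closed = frozenset(vocab.closure(terms))
        corpus.articles[article_id] = closed
        corpus.term_counts.update(closed)
    return corpus


def parse_entity_links(
    stream: TextIO | Iterable[str],
    dialect: str = "generic",
    taxon_filter: str | None = None,
    source_tag: str | None = None,
) -> EntityLinkSet:
    """Read entity-article links in the gene2pubmed or generic TSV dialect.

    The ``gene2pubmed`` dialect has columns (tax_id, GeneID, PubMed_ID) with
    a ``#``-prefixed header, bit-compatible with the NCBI file layout;
    ``taxon_filter`` keeps only rows of that taxon.  The ``generic`` dialect
    is 2 columns (entity_id, article_id).
    """
    if dialect not in ("gene2pubmed", "generic"):
        raise CorpusError(f"unknown link dialect {dialect!r}")
    links: dict[str, set[str]] = {}
    for lineno, fields in _data_rows(stream):
        if dialect == "gene2pubmed":
            if len(fields) != 3:
                raise CorpusError(
                    f"line {lineno}: gene2pubmed dialect expects 3 fields, "
                    f"got {len(fields)}"
                )
            tax_id, entity_id, article_id = (f.strip() for f in fields)
            if taxon_filter is not None and tax_id != taxon_filter:
                continue
        else:
            if len(fields) != 2:
                raise CorpusError(
                    f"line {lineno}: generic dialect expects 2 fields, "
                    f"got {len(fields)}"
                )
            entity_id, article_id = (f.strip() for f in fields)
        if not entity_id or not article_id:
            raise CorpusError(f"line {lineno}: empty entity id or article id")
        links.setdefault(entity_id, set()).add(article_id)
    if not links:
        logger.warning("parse_entity_links: no links after filtering")
    return EntityLinkSet(
        links={e: frozenset(a) for e, a in links.items()},
        source_tag=source_tag or dialect,
    )


def disease_article_set(corpus: AnnotatedCorpus, disease_term_id: str) -> set[str]:
    """Articles whose closed term set contains the disease term.

    Thanks to closure, an article annotated with a child term matches its
    parent disease term as well.
    """
    if corpus.term_counts.get(disease_term_id, 0) == 0:
        logger.warning("disease term %r absent from corpus", disease_term_id)
        return set()
    return corpus.term_articles(disease_term_id)


def cooccurrence_count(
    links: EntityLinkSet,
    corpus: AnnotatedCorpus,
    entity_id: str,
    disease_term_id: str,
) -> int:
    """Number of the entity's articles carrying the disease term (post-closure)."""
    if entity_id not in links:
        logger.warning("entity %r has no article links", entity_id)
        return 0
    return sum(
        1
        for aid in links.articles(entity_id)
        if disease_term_id in corpus.articles.get(aid, frozenset())
    )


def extract_novel_cooccurrences(
    old: tuple[AnnotatedCorpus, EntityLinkSet],
    new: tuple[AnnotatedCorpus, EntityLinkSet],
    genes: Iterable[str],
    diseases: Iterable[str],
    policy: PairPolicy = PairPolicy.EXCLUDE,
) -> ValidationSet:
    """Label gene-disease pairs by time-split co-occurrence.

    Positives are pairs that never co-occur in the ``old`` snapshot but
    share at least one article in the ``new`` snapshot.  Pairs already
    co-occurring in ``old`` enter the universe according to ``policy``.
    """
    genes = sorted(set(genes))
    diseases = sorted(set(diseases))
    if not genes or not diseases:
        raise CorpusError("gene and disease sets must be non-empty")
    old_corpus, old_links = old
    new_corpus, new_links = new

    positives: set[tuple[str, str]] = set()
    universe: set[tuple[str, str]] = set()
    for g in genes:
        old_arts = old_links.articles(g)
        new_arts = new_links.articles(g)
        for d in diseases:
            pair = (g, d)
            pre_existing = any(
                d in old_corpus.articles.get(a, frozenset()) for a in old_arts
            )
            if pre_existing:
                if policy is PairPolicy.EXCLUDE:
                    continue
                universe.add(pair)
                if policy is PairPolicy.AS_POSITIVE:
                    positives.add(pair)
                continue
            universe.add(pair)
            if any(d in new_corpus.articles.get(a, frozenset()) for a in new_arts):
                positives.add(pair)
    return ValidationSet(
        positives=frozenset(positives),
        universe=frozenset(universe),
        mode="novel_cooccurrence" if policy is not PairPolicy.AS_POSITIVE else "pre_existing",
    )


def load_curated_tuples(
    stream: TextIO | Iterable[str],
    genes: Iterable[str] | None = None,
    diseases: Iterable[str] | None = None,
) -> ValidationSet:
    """Read curated (gene_id, disease_term_id) relationship rows.

    Positives are the (deduplicated) rows; the universe is the cross
    product of the declared gene and disease sets (by default, those
    appearing in the file).
    """
    rows: set[tuple[str, str]] = set()
    for lineno, fields in _data_rows(stream):
        if len(fields) != 2:
            raise CorpusError(
                f"line {lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        g, d = (f.strip() for f in fields)
        if not g or not d:
            raise CorpusError(f"line {lineno}: empty gene id or disease term id")
        rows.add((g, d))
    if not rows:
        logger.warning("load_curated_tuples: empty relationship file")
    gene_set = set(genes) if genes is not None else {g for g, _ in rows}
    disease_set = set(diseases) if diseases is not None else {d for _, d in rows}
    universe = frozenset((g, d) for g in gene_set for d in disease_set)
    return ValidationSet(positives=frozenset(rows) & universe, universe=universe, mode="curated")
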