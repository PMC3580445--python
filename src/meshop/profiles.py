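"""MeSH over-representation profiles (MeSHOPs).

A MeSHOP summarizes the literature of an entity (a gene or a disease) as a
vector of per-term association measures computed from the entity's article
set against the universal background of the whole annotated corpus:

* ``count`` — number of entity articles whose closed term set contains the
  term (the term's support within the entity literature);
* ``fraction`` — count normalized by the total number of term-article
  incidences over the profile support, so fractions sum to 1;
* ``tfidf`` — count x ln(N / n_i), a term-frequency-inverse-document-
  frequency weight against the background;
* ``pvalue`` — one-sided (upper-tail) Fisher's exact test probability of
  seeing at least this many term-carrying articles among the entity's
  articles, under the hypergeometric null with the background margins.

P-values are floored at ``epsilon_p`` (default 1e-300) so that logarithms
taken downstream stay finite even when the test underflows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, TextIO

import numpy as np
from scipy.stats import hypergeom

from .corpus import AnnotatedCorpus, EntityLinkSet, disease_article_set

__all__ = [
    "EPSILON_P",
    "TermMeasures",
    "MeSHOP",
    "ContingencyTable",
    "ProfileError",
    "fisher_overrepresentation_p",
    "build_contingency",
    "build_meshop",
    "build_disease_meshop",
    "direct_association_p",
    "write_profiles",
    "read_profiles",
]

EPSILON_P = 1e-300


class ProfileError(ValueError):
    """Undefined profile (empty article set) or invalid contingency table."""


class TermMeasures(NamedTuple):
    count: int
    fraction: float
    tfidf: float
    pvalue: float


@dataclass
class MeSHOP:
    """Per-entity vector of (term, measures) tuples."""

    entity_id: str
    entity_articles_n: int
    measures: dict[str, TermMeasures]

    @property
    def support(self) -> set[str]:
        return set(self.measures)

    def pvalue(self, term_id: str, default: float = 1.0) -> float:
        m = self.measures.get(term_id)
        return m.pvalue if m is not None else default

    def __len__(self) -> int:
        return len(self.measures)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one term against one entity's article set.

    a: entity articles with the term; b: entity articles without it;
    c: background (non-entity) articles with the term; d: the rest.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ProfileError(f"negative contingency cell in {self}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_overrepresentation_p(table: ContingencyTable) -> float:
    """One-sided upper-tail Fisher's exact test, P(X >= a).

    X follows the hypergeometric law with population N = a+b+c+d, a+c
    term-carrying articles, and a+b draws (the entity's articles).  With a
    degenerate term margin (a + c = 0) the tail probability is 1.
    """
    if table.a + table.c == 0:
        return 1.0
    p = float(hypergeom.sf(table.a - 1, table.N, table.a + table.c, table.a + table.b))
    return min(max(p, 0.0), 1.0)


def build_contingency(
    entity_articles: Iterable[str], corpus: AnnotatedCorpus, term_id: str
) -> ContingencyTable:
    """Assemble the 2x2 table for a term against an entity's article set."""
    arts = set(entity_articles)
    missing = arts - corpus.articles.keys()
    if missing:
        raise ProfileError(
            f"entity articles absent from corpus: {sorted(missing)[:5]}"
        )
    a = sum(1 for aid in arts if term_id in corpus.articles[aid])
    b = len(arts) - a
    n_i = corpus.term_counts.get(term_id, 0)
    c = n_i - a
    d = (corpus.N - len(arts)) - c
    return ContingencyTable(a, b, c, d)


def build_meshop(
    entity_id: str,
    entity_articles: Iterable[str],
    corpus: AnnotatedCorpus,
    epsilon_p: float = EPSILON_P,
) -> MeSHOP:
    """Build the profile of an entity from its article set.

    The support is every term occurring in at least one entity article
    (article term sets are already ancestor-closed in the corpus).
    """
    arts = set(entity_articles)
    if not arts:
        raise ProfileError(f"entity {entity_id!r} has no articles; profile undefined")
    missing = arts - corpus.articles.keys()
    if missing:
        raise ProfileError(
            f"entity articles absent from corpus: {sorted(missing)[:5]}"
        )

    counts: dict[str, int] = {}
    for aid in arts:
        for term in corpus.articles[aid]:
            counts[term] = counts.get(term, 0) + 1
    total = sum(counts.values())
    n_entity = len(arts)
    N = corpus.N

    terms = sorted(counts)
    a = np.array([counts[t] for t in terms], dtype=np.int64)
    n_i = np.array([corpus.term_counts[t] for t in terms], dtype=np.int64)
    # P(X >= a) under hypergeometric(N, n_i, n_entity), vectorized over terms
    pvals = hypergeom.sf(a - 1, N, n_i, n_entity)
    pvals = np.clip(pvals, epsilon_p, 1.0)
    tfidf = a * np.log(N / n_i)

    measures = {
        t: TermMeasures(int(a[i]), a[i] / total, float(tfidf[i]), float(pvals[i]))
        for i, t in enumerate(terms)
    }
    return MeSHOP(entity_id=entity_id, entity_articles_n=n_entity, measures=measures)


def build_disease_meshop(
    disease_term_id: str,
    corpus: AnnotatedCorpus,
    epsilon_p: float = EPSILON_P,
    exclude_self: bool = False,
) -> MeSHOP:
    """Profile a disease from the articles carrying its MeSH term.

    The defining term itself remains in the profile unless ``exclude_self``
    is set, in which case it is removed after fraction normalization.
    """
    arts = disease_article_set(corpus, disease_term_id)
    if not arts:
        raise ProfileError(f"disease term {disease_term_id!r} has no articles")
    prof = build_meshop(disease_term_id, arts, corpus, epsilon_p=epsilon_p)
    if exclude_self:
        prof.measures.pop(disease_term_id, None)
    return prof


def direct_association_p(
    links: EntityLinkSet,
    corpus: AnnotatedCorpus,
    entity_id: str,
    disease_term_id: str,
    correction_n: int | None = None,
) -> tuple[float, float | None]:
    """Fisher test for direct entity-disease co-occurrence in the corpus.

    Returns ``(raw_p, corrected_p)`` where the corrected value is the
    Bonferroni-style ``min(1, raw_p * correction_n)`` when a correction
    factor is supplied, else ``None``.
    """
    arts = links.articles(entity_id)
    if not arts:
        raise ProfileError(f"entity {entity_id!r} has no articles")
    raw = fisher_overrepresentation_p(
        build_contingency(arts, corpus, disease_term_id)
    )
    corrected = min(1.0, raw * correction_n) if correction_n is not None else None
    return raw, corrected


def write_profiles(profiles: Iterable[MeSHOP], stream: TextIO) -> None:
    """Write profiles as TSV (entity_id, term_id, count, fraction, tfidf, pvalue).

    Terms are emitted in ascending id order for diffability.
    """
    stream.write("#entity_id\tterm_id\tcount\tfraction\ttfidf\tpvalue\n")
    for prof in profiles:
        for term in sorted(prof.measures):
            m = prof.measures[term]
            stream.write(
                f"{prof.entity_id}\t{term}\t{m.count}\t{m.fraction:.12g}"
                f"\t{m.tfidf:.12g}\t{m.pvalue:.12g}\n"
            )


def read_profiles(stream: Iterable[str]) -> list[MeSHOP]:
    """Read profiles written by :func:`write_profiles`.

    The TSV does not carry the entity's article count, so
    ``entity_articles_n`` is reconstructed as the largest per-term count
    (a lower bound); downstream similarity scoring does not use it.
    """
    by_entity: dict[str, dict[str, TermMeasures]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ProfileError(f"line {lineno}: expected 6 fields, got {len(fields)}")
        entity, term, count, fraction, tfidf, pvalue = fields
        by_entity.setdefault(entity, {})[term] = TermMeasures(
            int(count), float(fraction), float(tfidf), float(pvalue)
        )
    return [
        MeSHOP(entity_id=e,
               entity_articles_n=max(m.count for m in measures.values()),
               measures=measures)
        for e, measures in by_entity.items()
    ]
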