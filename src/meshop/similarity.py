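"""Profile-similarity scoring for gene-disease MeSHOP pairs.

Sixteen scorers are registered, spanning four families:

* cosine similarity of tf-idf, P-value, or term-fraction vectors;
* sums of log-combined P-values and of log P-value differences;
* squared-L2 distances (no square root; monotone-equivalent for ranking)
  of log-P, P, fraction, or raw-count vectors, over the support union M =
  G u D or over the overlap G n D only;
* set-cardinality and bibliometric scorers (|G u D|, |G n D|, |G|, |D|,
  gene database id).

Sums run over the union of the two supports with absence conventions:
count, fraction and tf-idf are 0 and the P-value is 1 for a term missing
from a profile, which makes every formula well defined (an absent term
contributes nothing to combined-P or log-ratio sums).

Each scorer declares an *orientation* — whether larger raw values mean
more similar.  :func:`score_all_pairs` applies the orientation (distances
are negated) so a larger stored score always means "predicted more
similar", which is what the downstream ROC machinery assumes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .profiles import MeSHOP

__all__ = [
    "PairView",
    "MetricSpec",
    "METRICS",
    "SimilarityError",
    "vectorize_pair",
    "cosine_score",
    "l2_score",
    "sum_log_combined_p",
    "sum_diff_log_p",
    "count_scores",
    "shared_term_score",
    "shared_term_report",
    "score_all_pairs",
    "score_matrices",
    "write_scores",
]

logger = logging.getLogger(__name__)


class SimilarityError(ValueError):
    """Invalid metric request or undefined score."""


@dataclass
class PairView:
    """Aligned per-term component vectors for one (gene, disease) pair.

    Terms are ordered ascending by id; ``overlap`` marks terms present in
    both supports.
    """

    terms: list[str]
    g_count: np.ndarray
    d_count: np.ndarray
    g_fraction: np.ndarray
    d_fraction: np.ndarray
    g_tfidf: np.ndarray
    d_tfidf: np.ndarray
    g_p: np.ndarray
    d_p: np.ndarray
    overlap: np.ndarray  # boolean mask
    n_gene_terms: int
    n_disease_terms: int


def vectorize_pair(gene: MeSHOP, disease: MeSHOP) -> PairView:
    """Align two profiles on the union of their supports."""
    if not gene.measures or not disease.measures:
        raise SimilarityError("cannot vectorize an empty profile")
    terms = sorted(gene.support | disease.support)
    n = len(terms)
    arrays = {
        k: np.zeros(n) for k in ("g_count", "d_count", "g_fraction", "d_fraction",
                                 "g_tfidf", "d_tfidf")
    }
    g_p = np.ones(n)
    d_p = np.ones(n)
    overlap = np.zeros(n, dtype=bool)
    for i, t in enumerate(terms):
        gm = gene.measures.get(t)
        dm = disease.measures.get(t)
        if gm is not None:
            arrays["g_count"][i] = gm.count
            arrays["g_fraction"][i] = gm.fraction
            arrays["g_tfidf"][i] = gm.tfidf
            g_p[i] = gm.pvalue
        if dm is not None:
            arrays["d_count"][i] = dm.count
            arrays["d_fraction"][i] = dm.fraction
            arrays["d_tfidf"][i] = dm.tfidf
            d_p[i] = dm.pvalue
        overlap[i] = gm is not None and dm is not None
    return PairView(
        terms=terms,
        g_p=g_p,
        d_p=d_p,
        overlap=overlap,
        n_gene_terms=len(gene.measures),
        n_disease_terms=len(disease.measures),
        **arrays,
    )


def _weights(pair: PairView, weighting: str) -> tuple[np.ndarray, np.ndarray]:
    if weighting == "tfidf":
        return pair.g_tfidf, pair.d_tfidf
    if weighting == "pvalue":
        return pair.g_p, pair.d_p
    if weighting == "fraction":
        return pair.g_fraction, pair.d_fraction
    if weighting == "frequency":
        return pair.g_count, pair.d_count
    raise SimilarityError(f"unknown weighting {weighting!r}")


def cosine_score(pair: PairView, weighting: str) -> float:
    """Cosine similarity of the chosen weight vectors over the union M."""
    wg, wd = _weights(pair, weighting)
    ng = float(np.linalg.norm(wg))
    nd = float(np.linalg.norm(wd))
    if ng == 0.0 or nd == 0.0:
        logger.warning("cosine undefined: zero-norm %s vector", weighting)
        return float("nan")
    return float(wg @ wd / (ng * nd))


def l2_score(pair: PairView, transform: str, domain: str = "union") -> float:
    """Sum of squared componentwise differences (no square root).

    ``transform`` selects the component (frequency, fraction, pvalue, or
    log_pvalue); ``domain`` restricts the sum to the overlap G n D or runs
    over the whole union.  An empty overlap yields 0 (nothing to compare).
    """
    if transform == "log_pvalue":
        g = np.log(pair.g_p)
        d = np.log(pair.d_p)
    else:
        g, d = _weights(pair, transform)
    if domain == "overlap":
        if not pair.overlap.any():
            logger.warning("l2_score: empty overlap, distance 0")
            return 0.0
        g = g[pair.overlap]
        d = d[pair.overlap]
    elif domain != "union":
        raise SimilarityError(f"unknown domain {domain!r}")
    diff = g - d
    return float(diff @ diff)


def sum_log_combined_p(pair: PairView) -> float:
    """Sum over M of ln(gp + dp - gp*dp).

    The combined value is the probability that at least one of two
    independent tests at levels gp, dp fires; a term absent from either
    profile has p = 1 there, forcing the combined value to 1 and a zero
    contribution.
    """
    combined = pair.g_p + pair.d_p - pair.g_p * pair.d_p
    return float(np.log(combined).sum())


def sum_diff_log_p(pair: PairView) -> float:
    """Sum over M of (ln gp - ln dp); antisymmetric under profile swap."""
    return float((np.log(pair.g_p) - np.log(pair.d_p)).sum())


def count_scores(pair: PairView) -> tuple[int, int, int, int]:
    """(|G n D|, |G u D|, |G|, |D|) for the pair's supports."""
    overlap = int(pair.overlap.sum())
    coverage = len(pair.terms)
    return overlap, coverage, pair.n_gene_terms, pair.n_disease_terms


def shared_term_score(g_p: float, d_p: float) -> float:
    """Absolute P-value difference |gp - dp| for one shared term.

    Smaller means the two profiles assign the term more similar
    significance; used to order shared-term reports.
    """
    if not (0.0 <= g_p <= 1.0 and 0.0 <= d_p <= 1.0):
        raise SimilarityError(f"p-values out of [0, 1]: {g_p}, {d_p}")
    return abs(g_p - d_p)


def shared_term_report(gene: MeSHOP, disease: MeSHOP) -> pd.DataFrame:
    """Terms shared by both profiles, ordered by P-value similarity.

    Columns: term_id, g_p, d_p, score (= |g_p - d_p|), ascending by score.
    """
    shared = sorted(gene.support & disease.support)
    rows = [
        (t, gene.measures[t].pvalue, disease.measures[t].pvalue,
         shared_term_score(gene.measures[t].pvalue, disease.measures[t].pvalue))
        for t in shared
    ]
    df = pd.DataFrame(rows, columns=["term_id", "g_p", "d_p", "score"])
    return df.sort_values(["score", "term_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Metric registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSpec:
    """One registered scorer: raw computation plus its orientation."""

    name: str
    family: str  # cosine | l2 | sum_log | count
    weighting: str  # frequency | fraction | tfidf | pvalue | log_pvalue | id
    domain: str  # union | overlap
    orientation: str  # higher_is_similar | lower_is_similar
    description: str
    compute: Callable[[PairView], float] | None = None

    def oriented(self, raw: float) -> float:
        """Map a raw score so that larger always means more similar."""
        if math.isnan(raw):
            return raw
        return raw if self.orientation == "higher_is_similar" else -raw


def _registry() -> dict[str, MetricSpec]:
    specs = [
        MetricSpec("cosine_tfidf", "cosine", "tfidf", "union", "higher_is_similar",
                   "Cosine similarity of tf-idf vectors",
                   lambda p: cosine_score(p, "tfidf")),
        MetricSpec("cosine_pvalue", "cosine", "pvalue", "union", "higher_is_similar",
                   "Cosine similarity of P-value vectors",
                   lambda p: cosine_score(p, "pvalue")),
        MetricSpec("cosine_fraction", "cosine", "fraction", "union", "higher_is_similar",
                   "Cosine similarity of term-fraction vectors",
                   lambda p: cosine_score(p, "fraction")),
        MetricSpec("sum_log_combined_p", "sum_log", "pvalue", "union", "lower_is_similar",
                   "Sum of the log of combined P-values",
                   sum_log_combined_p),
        MetricSpec("sum_diff_log_p", "sum_log", "log_pvalue", "union", "lower_is_similar",
                   "Sum of the differences of log P-values",
                   sum_diff_log_p),
        MetricSpec("l2_log_p_overlap", "l2", "log_pvalue", "overlap", "lower_is_similar",
                   "Squared L2 of log-P over overlapping terms only",
                   lambda p: l2_score(p, "log_pvalue", "overlap")),
        MetricSpec("l2_fraction_overlap", "l2", "fraction", "overlap", "lower_is_similar",
                   "Squared L2 of term fractions over overlapping terms only",
                   lambda p: l2_score(p, "fraction", "overlap")),
        MetricSpec("l2_log_p", "l2", "log_pvalue", "union", "lower_is_similar",
                   "Squared L2 of log-P over the support union",
                   lambda p: l2_score(p, "log_pvalue", "union")),
        MetricSpec("l2_pvalue", "l2", "pvalue", "union", "lower_is_similar",
                   "Squared L2 of P-values over the support union",
                   lambda p: l2_score(p, "pvalue", "union")),
        MetricSpec("l2_fraction", "l2", "fraction", "union", "lower_is_similar",
                   "Squared L2 of term fractions over the support union",
                   lambda p: l2_score(p, "fraction", "union")),
        MetricSpec("l2_frequency", "l2", "frequency", "union", "lower_is_similar",
                   "Squared L2 of raw term counts over the support union",
                   lambda p: l2_score(p, "frequency", "union")),
        MetricSpec("term_coverage", "count", "frequency", "union", "higher_is_similar",
                   "Term coverage |G u D|",
                   lambda p: float(count_scores(p)[1])),
        MetricSpec("term_overlap", "count", "frequency", "overlap", "higher_is_similar",
                   "Term overlap |G n D|",
                   lambda p: float(count_scores(p)[0])),
        MetricSpec("n_gene_terms", "count", "frequency", "union", "higher_is_similar",
                   "Number of gene profile terms |G| (bibliometric)",
                   lambda p: float(p.n_gene_terms)),
        MetricSpec("n_disease_terms", "count", "frequency", "union", "higher_is_similar",
                   "Number of disease profile terms |D| (bibliometric)",
                   lambda p: float(p.n_disease_terms)),
        # Gene database id: entity-constant baseline; lower (older) ids are
        # predicted more disease-associated.  Computed from the gene id, not
        # from the pair view.
        MetricSpec("gene_id", "count", "id", "union", "lower_is_similar",
                   "Gene database id order (bibliometric baseline)", None),
    ]
    return {s.name: s for s in specs}


METRICS: dict[str, MetricSpec] = _registry()


def _gene_id_value(entity_id: str, ordering: Sequence[str]) -> float:
    """Numeric id when parseable, else the lexicographic rank in ``ordering``."""
    try:
        return float(int(entity_id))
    except ValueError:
        return float(ordering.index(entity_id))


def score_all_pairs(
    genes: Iterable[MeSHOP],
    diseases: Iterable[MeSHOP],
    metric: MetricSpec | str,
    orientation_override: str | None = None,
) -> pd.DataFrame:
    """Oriented score matrix (genes x diseases) under one metric.

    Rows are gene ids, columns disease ids; larger stored values always
    mean "predicted more similar".  Profiles with empty supports are
    dropped (their rows/columns are absent, as with entities lacking
    profiles in the source data).
    """
    if isinstance(metric, str):
        try:
            metric = METRICS[metric]
        except KeyError:
            raise SimilarityError(f"unknown metric {metric!r}") from None
    if orientation_override is not None:
        metric = MetricSpec(
            metric.name, metric.family, metric.weighting, metric.domain,
            orientation_override, metric.description, metric.compute,
        )
    gene_list = [g for g in genes if g.measures]
    disease_list = [d for d in diseases if d.measures]
    if not gene_list or not disease_list:
        raise SimilarityError("need at least one non-empty profile per side")
    gene_ids = [g.entity_id for g in gene_list]
    disease_ids = [d.entity_id for d in disease_list]

    values = np.empty((len(gene_list), len(disease_list)))
    if metric.name == "gene_id":
        ordering = sorted(gene_ids)
        col = np.array([
            metric.oriented(_gene_id_value(g, ordering)) for g in gene_ids
        ])
        values[:] = col[:, None]
    else:
        assert metric.compute is not None
        for i, g in enumerate(gene_list):
            for j, d in enumerate(disease_list):
                values[i, j] = metric.oriented(metric.compute(vectorize_pair(g, d)))
    df = pd.DataFrame(values, index=gene_ids, columns=disease_ids)
    df.attrs["metric"] = metric.name
    df.attrs["orientation"] = metric.orientation
    return df


def score_matrices(
    genes: Iterable[MeSHOP],
    diseases: Iterable[MeSHOP],
    metrics: Iterable[MetricSpec | str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Oriented score matrices for several metrics, sharing pair views.

    Builds each (gene, disease) pair view once, which is much cheaper than
    calling :func:`score_all_pairs` per metric when profiles are large.
    """
    specs = [
        METRICS[m] if isinstance(m, str) else m
        for m in (metrics if metrics is not None else METRICS)
    ]
    gene_list = [g for g in genes if g.measures]
    disease_list = [d for d in diseases if d.measures]
    if not gene_list or not disease_list:
        raise SimilarityError("need at least one non-empty profile per side")
    gene_ids = [g.entity_id for g in gene_list]
    disease_ids = [d.entity_id for d in disease_list]

    pair_specs = [s for s in specs if s.compute is not None]
    out = {
        s.name: np.empty((len(gene_list), len(disease_list))) for s in pair_specs
    }
    for i, g in enumerate(gene_list):
        for j, d in enumerate(disease_list):
            view = vectorize_pair(g, d)
            for s in pair_specs:
                out[s.name][i, j] = s.oriented(s.compute(view))

    result: dict[str, pd.DataFrame] = {}
    for s in specs:
        if s.compute is None:  # gene_id baseline metric
            result[s.name] = score_all_pairs(gene_list, disease_list, s)
            continue
        df = pd.DataFrame(out[s.name], index=gene_ids, columns=disease_ids)
        df.attrs["metric"] = s.name
        df.attrs["orientation"] = s.orientation
        result[s.name] = df
    return result


def write_scores(matrix: pd.DataFrame, stream: TextIO) -> None:
    """Write a score matrix as long-form TSV (gene, disease, metric, score)."""
    metric = matrix.attrs.get("metric", "unknown")
    stream.write("#gene_id\tdisease_term_id\tmetric\toriented_score\n")
    for g in matrix.index:
        for d in matrix.columns:
            stream.write(f"{g}\t{d}\t{metric}\t{matrix.at[g, d]:.12g}\n")
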