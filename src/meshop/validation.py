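"""Evaluation of pair scorers against labeled gene-disease validation sets.

The central quantity is the tie-aware ROC AUC, computed as the
Mann-Whitney statistic

    AUC = P(score_pos > score_neg) + 1/2 P(score_pos = score_neg)

over all positive x negative pairs in the validation universe.  Ties
produce diagonal segments in the ROC curve; the trapezoidal area under
the emitted curve equals the Mann-Whitney value exactly.

An AUC converts analytically to the expected rank of a single positive
among n candidates: rank = 1 + (1 - AUC)(n - 1).  The ranked-list test
checks this by simulation: repeatedly rank 1 sampled positive among n - 1
sampled negatives (mid-rank ties) and average the positive's rank.

Bibliometric baselines are entity-constant scorers (publication counts,
profile sizes, database-id order): they rank genes identically for every
disease and quantify how far literature volume alone predicts future
gene-disease co-occurrence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .corpus import ValidationSet

__all__ = [
    "RocResult",
    "FeatureBaseline",
    "ValidationError",
    "pair_scores",
    "roc",
    "auc",
    "mean_rank_from_auc",
    "ranked_list_test",
    "average_precision",
    "map_over_diseases",
    "baseline_scores",
    "evaluate",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Degenerate validation input (no positives or no negatives)."""


@dataclass
class RocResult:
    """AUC plus the full (fpr, tpr) curve and class sizes."""

    auc: float
    curve: np.ndarray  # shape (k, 2): (false positive rate, sensitivity)
    n_pos: int
    n_neg: int


@dataclass
class FeatureBaseline:
    """Entity-constant feature scorer with a declared orientation.

    ``orientation`` is ``higher`` when larger feature values predict
    association (e.g. publication counts) and ``lower`` when smaller
    values do (e.g. database ids, oldest-publication year).
    ``axis`` says whether values attach to genes or diseases.
    """

    feature_name: str
    values: Mapping[str, float]
    orientation: str = "higher"
    axis: str = "gene"

    def oriented_value(self, entity_id: str) -> float | None:
        v = self.values.get(entity_id)
        if v is None:
            return None
        return float(v) if self.orientation == "higher" else -float(v)


def pair_scores(
    matrix: pd.DataFrame, validation: ValidationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Split universe pair scores into (positive, negative) arrays.

    Pairs whose gene or disease has no score (no profile) are dropped and
    counted in a log message, mirroring "NA" entries in real runs.
    """
    pos, neg, dropped = [], [], 0
    for g, d in validation.universe:
        if g in matrix.index and d in matrix.columns:
            s = matrix.at[g, d]
            if not np.isnan(s):
                (pos if (g, d) in validation.positives else neg).append(float(s))
                continue
        dropped += 1
    if dropped:
        logger.info("pair_scores: dropped %d universe pairs without scores", dropped)
    return np.asarray(pos), np.asarray(neg)


def roc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> RocResult:
    """Tie-aware ROC over raw positive/negative score arrays.

    AUC is computed from mid-ranks (exactly the Mann-Whitney statistic);
    the curve walks thresholds from high to low, and a score level shared
    by positives and negatives contributes a diagonal segment.
    """
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need at least one positive and one negative")

    allscores = np.concatenate([pos_scores, neg_scores])
    ranks = rankdata(allscores)  # mid-ranks, ascending
    r_pos = ranks[:n_pos].sum()
    auc_value = (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Curve: group by unique score descending; each level adds one vertex.
    order = np.argsort(-allscores, kind="stable")
    labels = np.concatenate([np.ones(n_pos, dtype=bool), np.zeros(n_neg, dtype=bool)])
    sorted_scores = allscores[order]
    sorted_labels = labels[order]
    # boundaries of tie groups
    boundaries = np.flatnonzero(np.diff(sorted_scores)) + 1
    group_ends = np.append(boundaries, len(sorted_scores))
    tp = np.cumsum(sorted_labels)[group_ends - 1]
    fp = group_ends - tp
    curve = np.vstack([
        np.concatenate([[0.0], fp / n_neg]),
        np.concatenate([[0.0], tp / n_pos]),
    ]).T
    return RocResult(auc=float(auc_value), curve=curve, n_pos=n_pos, n_neg=n_neg)


def auc(matrix: pd.DataFrame, validation: ValidationSet) -> RocResult:
    """Tie-aware ROC/AUC of a score matrix against a validation set."""
    pos, neg = pair_scores(matrix, validation)
    return roc(pos, neg)


def mean_rank_from_auc(auc_value: float, n: int) -> float:
    """Expected rank of the positive in an n-candidate list: 1 + (1-AUC)(n-1)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValidationError(f"AUC out of [0, 1]: {auc_value}")
    if n < 1:
        raise ValidationError(f"list size must be >= 1, got {n}")
    return 1.0 + (1.0 - auc_value) * (n - 1)


def ranked_list_test(
    scorer: Callable[[str], float],
    positives: Sequence[str],
    negatives: Sequence[str],
    n: int = 200,
    trials: int = 2000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean rank of one sampled positive among n - 1 sampled negatives.

    Per trial: draw 1 positive and n - 1 negatives without replacement,
    rank all n candidates by oriented score (descending, mid-rank ties),
    and record the positive's rank.  Returns the mean over trials.
    """
    positives = list(positives)
    negatives = list(negatives)
    if not positives:
        raise ValidationError("need at least one positive")
    if len(negatives) < n - 1:
        raise ValidationError(
            f"need at least n-1={n - 1} negatives, have {len(negatives)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg_scores = np.array([scorer(e) for e in negatives])
    pos_scores = np.array([scorer(e) for e in positives])

    ranks = np.empty(trials)
    for t in range(trials):
        p = pos_scores[rng.integers(len(positives))]
        sample = neg_scores[rng.choice(len(negatives), size=n - 1, replace=False)]
        scores = np.concatenate([[p], sample])
        # descending mid-rank: rank 1 = highest score
        ranks[t] = rankdata(-scores)[0]
    return float(ranks.mean())


def average_precision(labels: Sequence[bool]) -> float:
    """AP of a ranked label sequence: mean precision at each positive."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("ranking contains no positives")
    hits = np.cumsum(labels)
    ranks = np.arange(1, len(labels) + 1)
    return float((hits[labels] / ranks[labels]).mean())


def map_over_diseases(matrix: pd.DataFrame, validation: ValidationSet) -> float:
    """Mean average precision, one query per disease.

    For each disease with at least one positive in the universe, rank the
    universe genes by score (descending, ties broken by gene id for
    determinism) and take the AP; the MAP is the unweighted mean over
    diseases.  Diseases without positives are skipped and logged.
    """
    by_disease: dict[str, list[tuple[str, bool]]] = {}
    for g, d in validation.universe:
        if g in matrix.index and d in matrix.columns and not np.isnan(matrix.at[g, d]):
            by_disease.setdefault(d, []).append((g, (g, d) in validation.positives))
    aps = []
    skipped = 0
    for d in sorted(by_disease):
        entries = by_disease[d]
        if not any(lab for _, lab in entries):
            skipped += 1
            continue
        entries.sort(key=lambda e: (-matrix.at[e[0], d], e[0]))
        aps.append(average_precision([lab for _, lab in entries]))
    if skipped:
        logger.info("map_over_diseases: skipped %d diseases without positives", skipped)
    if not aps:
        raise ValidationError("no disease has positives with scores")
    return float(np.mean(aps))


def baseline_scores(
    baseline: FeatureBaseline, universe: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Expand an entity-constant feature into an oriented pair-score matrix.

    The score of (gene, disease) is the oriented feature value of the gene
    (or of the disease, for disease-axis features), constant across the
    partner dimension.  Entities without a feature value are dropped.
    """
    universe = list(universe)
    genes = sorted({g for g, _ in universe})
    diseases = sorted({d for _, d in universe})
    if not baseline.values:
        raise ValidationError(f"baseline {baseline.feature_name!r} has no values")
    entities = genes if baseline.axis == "gene" else diseases
    oriented = {e: baseline.oriented_value(e) for e in entities}
    missing = [e for e, v in oriented.items() if v is None]
    if missing:
        logger.info(
            "baseline %s: %d entities without feature values dropped",
            baseline.feature_name, len(missing),
        )
    values = np.full((len(genes), len(diseases)), np.nan)
    for i, g in enumerate(genes):
        for j, d in enumerate(diseases):
            v = oriented[g] if baseline.axis == "gene" else oriented[d]
            if v is not None:
                values[i, j] = v
    df = pd.DataFrame(values, index=genes, columns=diseases)
    df.attrs["metric"] = baseline.feature_name
    return df


@dataclass
class MetricReport:
    """Tabular evaluation results plus the provenance needed to recompute them."""

    table: pd.DataFrame
    seed: int | None = None
    trials: int | None = None
    rank_list_n: int | None = None
    notes: dict = field(default_factory=dict)


def evaluate(
    matrices: Mapping[str, pd.DataFrame],
    validations: Mapping[str, ValidationSet],
    rank_list_n: int = 200,
    with_map: bool = True,
) -> MetricReport:
    """AUC per (scorer, validation set) plus summary columns.

    Output columns: one AUC per validation set, ``mean_auc``, ``rank`` of
    the scorer by mean AUC (1 = best), ``mean_test_rank`` from the pooled
    mean AUC via the analytic conversion at ``rank_list_n`` candidates,
    and MAP per validation set when requested.
    """
    if not matrices or not validations:
        raise ValidationError("need at least one scorer and one validation set")
    rows = {}
    for name, matrix in matrices.items():
        row: dict[str, float] = {}
        for vname, vset in validations.items():
            row[f"auc_{vname}"] = auc(matrix, vset).auc
            if with_map:
                row[f"map_{vname}"] = map_over_diseases(matrix, vset)
        aucs = [v for k, v in row.items() if k.startswith("auc_")]
        row["mean_auc"] = float(np.mean(aucs))
        row["mean_test_rank"] = mean_rank_from_auc(row["mean_auc"], rank_list_n)
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table["rank"] = (
        table["mean_auc"].rank(ascending=False, method="min").astype(int)
    )
    table = table.sort_values(["rank", "mean_auc"], kind="stable")
    table.index.name = "metric"
    return MetricReport(table=table, rank_list_n=rank_list_n)
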