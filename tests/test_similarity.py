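import math

import numpy as np
import pytest

import meshop as M
from meshop.profiles import MeSHOP, TermMeasures
from meshop.similarity import (
    METRICS,
    SimilarityError,
    cosine_score,
    count_scores,
    l2_score,
    shared_term_score,
    sum_diff_log_p,
    sum_log_combined_p,
    vectorize_pair,
)


def profile(entity_id, spec):
    """Build a MeSHOP from {term: (count, fraction, tfidf, pvalue)}."""
    return MeSHOP(
        entity_id=entity_id,
        entity_articles_n=max((v[0] for v in spec.values()), default=1),
        measures={t: TermMeasures(*v) for t, v in spec.items()},
    )


def random_profile(rng, entity_id, terms):
    support = rng.choice(terms, size=rng.integers(2, len(terms)), replace=False)
    counts = rng.integers(1, 20, size=len(support))
    fr = counts / counts.sum()
    return profile(entity_id, {
        t: (int(c), float(f), float(c * rng.random()), float(rng.uniform(1e-30, 1)))
        for t, c, f in zip(support, counts, fr)
    })


class TestVectorize:
    def test_union_and_overlap(self):
        g = profile("g", {"t1": (1, 0.5, 1.0, 0.1), "t2": (1, 0.5, 1.0, 0.2)})
        d = profile("d", {"t2": (2, 0.6, 2.0, 0.3), "t3": (1, 0.4, 1.0, 0.4)})
        v = vectorize_pair(g, d)
        assert v.terms == ["t1", "t2", "t3"]
        assert list(v.overlap) == [False, True, False]

    def test_absence_conventions(self):
        g = profile("g", {"t1": (1, 1.0, 2.0, 0.1)})
        d = profile("d", {"t2": (1, 1.0, 2.0, 0.2)})
        v = vectorize_pair(g, d)
        i = v.terms.index("t1")
        assert v.d_p[i] == 1.0 and v.d_count[i] == 0.0 and v.d_tfidf[i] == 0.0

    def test_identical_supports(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.5)})
        v = vectorize_pair(g, g)
        assert len(v.terms) == 1 and v.overlap.all()

    def test_empty_profile_rejected(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.5)})
        with pytest.raises(SimilarityError):
            vectorize_pair(g, MeSHOP("e", 1, {}))


class TestCosine:
    def test_self_similarity_is_one(self):
        g = profile("g", {"t1": (3, 0.75, 2.0, 0.1), "t2": (1, 0.25, 0.5, 0.2)})
        assert cosine_score(vectorize_pair(g, g), "tfidf") == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.1)})
        d = profile("d", {"t2": (1, 1.0, 1.0, 0.1)})
        assert cosine_score(vectorize_pair(g, d), "fraction") == 0.0

    def test_hand_computed_frequency_cosine(self):
        g = profile("g", {"t1": (1, 1 / 3, 0.0, 0.5), "t2": (2, 2 / 3, 0.0, 0.5)})
        d = profile("d", {"t1": (2, 2 / 3, 0.0, 0.5), "t2": (1, 1 / 3, 0.0, 0.5)})
        assert cosine_score(vectorize_pair(g, d), "frequency") == pytest.approx(0.8)

    def test_zero_norm_returns_nan(self):
        g = profile("g", {"t1": (1, 1.0, 0.0, 0.5)})
        assert math.isnan(cosine_score(vectorize_pair(g, g), "tfidf"))


class TestL2:
    def test_identity_of_indiscernibles(self):
        g = profile("g", {"t1": (2, 1.0, 1.0, 0.05)})
        for transform in ("frequency", "fraction", "pvalue", "log_pvalue"):
            assert l2_score(vectorize_pair(g, g), transform) == 0.0

    def test_union_frequency_distance(self):
        g = profile("g", {"t1": (3, 1.0, 1.0, 0.5)})
        d = profile("d", {"t2": (4, 1.0, 1.0, 0.5)})
        assert l2_score(vectorize_pair(g, d), "frequency") == 25.0

    def test_log_p_against_absent_term(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 1e-2)})
        d = profile("d", {"t2": (1, 1.0, 1.0, 0.5)})
        v = vectorize_pair(g, d)
        expected = math.log(1e-2) ** 2 + math.log(0.5) ** 2
        assert l2_score(v, "log_pvalue", "union") == pytest.approx(expected)
        assert math.log(1e-2) ** 2 == pytest.approx(21.2076, abs=1e-4)

    def test_empty_overlap_gives_zero(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.1)})
        d = profile("d", {"t2": (1, 1.0, 1.0, 0.1)})
        assert l2_score(vectorize_pair(g, d), "log_pvalue", "overlap") == 0.0


class TestLogPSums:
    def test_all_ones_give_zero(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 1.0)})
        d = profile("d", {"t2": (1, 1.0, 1.0, 1.0)})
        assert sum_log_combined_p(vectorize_pair(g, d)) == 0.0

    def test_single_shared_term_combined(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.1)})
        d = profile("d", {"t1": (1, 1.0, 1.0, 0.1)})
        assert sum_log_combined_p(vectorize_pair(g, d)) == pytest.approx(
            math.log(0.19), abs=1e-12
        )
        assert math.log(0.19) == pytest.approx(-1.6607, abs=1e-4)

    def test_term_with_p_one_is_absorbed(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 1.0)})
        d = profile("d", {"t1": (1, 1.0, 1.0, 0.37)})
        assert sum_log_combined_p(vectorize_pair(g, d)) == 0.0

    def test_diff_log_p_value_and_antisymmetry(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.01)})
        d = profile("d", {"t1": (1, 1.0, 1.0, 0.1)})
        forward = sum_diff_log_p(vectorize_pair(g, d))
        assert forward == pytest.approx(math.log(0.1), abs=1e-12)
        assert sum_diff_log_p(vectorize_pair(d, g)) == pytest.approx(-forward)

    def test_identical_profiles_cancel(self):
        g = profile("g", {"t1": (1, 1.0, 1.0, 0.01), "t2": (1, 1.0, 1.0, 0.3)})
        assert sum_diff_log_p(vectorize_pair(g, g)) == 0.0


class TestCounts:
    @pytest.mark.parametrize(
        "gt, dt, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, (2, 4, 3, 3)),
            ({"a"}, {"b"}, (0, 2, 1, 1)),
            ({"a", "b"}, {"a", "b"}, (2, 2, 2, 2)),
        ],
    )
    def test_set_cardinalities(self, gt, dt, expected):
        g = profile("g", {t: (1, 1 / len(gt), 1.0, 0.5) for t in gt})
        d = profile("d", {t: (1, 1 / len(dt), 1.0, 0.5) for t in dt})
        assert count_scores(vectorize_pair(g, d)) == expected


class TestSharedTermScore:
    @pytest.mark.parametrize(
        "g_p, d_p, printed",
        [
            (8.53e-24, 2.98e-23, "2.13e-23"),
            (6.82e-24, 0.0, "6.82e-24"),
            (9.77e-15, 2.11e-21, "9.77e-15"),
        ],
    )
    def test_published_shared_term_examples(self, g_p, d_p, printed):
        assert f"{shared_term_score(g_p, d_p):.2e}" == printed

    def test_identity(self):
        assert shared_term_score(0.25, 0.25) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(SimilarityError):
            shared_term_score(1.5, 0.5)

    def test_report_is_sorted_ascending(self, world_profiles):
        genes, diseases = world_profiles
        report = M.shared_term_report(genes[0], diseases[0])
        assert (report["score"].diff().dropna() >= 0).all()
        assert set(report.columns) == {"term_id", "g_p", "d_p", "score"}


class TestRegistry:
    def test_exactly_sixteen_scorers(self):
        assert len(METRICS) == 16

    def test_families_and_orientations_declared(self):
        for spec in METRICS.values():
            assert spec.family in {"cosine", "l2", "sum_log", "count"}
            assert spec.orientation in {"higher_is_similar", "lower_is_similar"}

    def test_distances_oriented_lower_is_similar(self):
        for name in ("l2_log_p_overlap", "l2_pvalue", "sum_log_combined_p"):
            assert METRICS[name].orientation == "lower_is_similar"
        for name in ("cosine_tfidf", "term_overlap", "n_gene_terms"):
            assert METRICS[name].orientation == "higher_is_similar"


class TestScoreAllPairs:
    @pytest.fixture
    def pairs(self):
        rng = np.random.default_rng(5)
        terms = [f"t{i}" for i in range(12)]
        genes = [random_profile(rng, str(i + 1), terms) for i in range(3)]
        diseases = [random_profile(rng, f"d{i}", terms) for i in range(2)]
        return genes, diseases

    def test_matrix_shape_and_labels(self, pairs):
        genes, diseases = pairs
        mat = M.score_all_pairs(genes, diseases, "cosine_fraction")
        assert mat.shape == (3, 2)
        assert list(mat.index) == ["1", "2", "3"]

    def test_orientation_negates_distances(self, pairs):
        genes, diseases = pairs
        mat = M.score_all_pairs(genes, diseases, "l2_frequency")
        raw = l2_score(vectorize_pair(genes[0], diseases[0]), "frequency")
        assert mat.iloc[0, 0] == pytest.approx(-raw)
        assert (mat.values <= 0).all()

    def test_gene_id_metric_prefers_low_ids(self, pairs):
        genes, diseases = pairs
        mat = M.score_all_pairs(genes, diseases, "gene_id")
        assert (mat.loc["1"] > mat.loc["2"]).all()
        assert mat.loc["1"].nunique() == 1  # constant across diseases

    def test_empty_profile_row_absent(self, pairs):
        genes, diseases = pairs
        genes = genes + [MeSHOP("99", 1, {})]
        mat = M.score_all_pairs(genes, diseases, "cosine_fraction")
        assert "99" not in mat.index

    def test_symmetric_metrics_commute(self, pairs):
        genes, diseases = pairs
        symmetric = ["cosine_tfidf", "cosine_pvalue", "cosine_fraction",
                     "sum_log_combined_p", "l2_log_p_overlap", "l2_fraction",
                     "l2_frequency", "l2_pvalue", "term_coverage", "term_overlap"]
        for name in symmetric:
            spec = METRICS[name]
            for g in genes:
                for d in diseases:
                    assert spec.compute(vectorize_pair(g, d)) == pytest.approx(
                        spec.compute(vectorize_pair(d, g)), rel=1e-12
                    )

    def test_score_matrices_agrees_with_single_metric_path(self, pairs):
        genes, diseases = pairs
        multi = M.score_matrices(genes, diseases, ["cosine_tfidf", "gene_id"])
        single = M.score_all_pairs(genes, diseases, "cosine_tfidf")
        assert np.allclose(multi["cosine_tfidf"].values, single.values)

    def test_unknown_metric_rejected(self, pairs):
        genes, diseases = pairs
        with pytest.raises(SimilarityError):
            M.score_all_pairs(genes, diseases, "not_a_metric")
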