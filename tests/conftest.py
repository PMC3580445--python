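import pytest

import meshop as M


@pytest.fixture
def chain_vocab():
    """Vocabulary with a 3-level disease chain plus two other categories."""
    rows = [
        "T1\tneoplasms\tC04",
        "T2\tneoplasms by histology\tC04.557",
        "T3\tlymphoma\tC04.557.337",
        "T4\torganic chemicals\tD02",
        "T5\tbehavior\tF01",
    ]
    return M.parse_vocabulary(rows)


@pytest.fixture
def flat_vocab():
    """Four unrelated top-level terms, one of them a disease."""
    rows = [
        "t1\talpha\tD01",
        "t2\tbeta\tD02",
        "t3\tgamma\tD03",
        "dis\tsome disease\tC01",
    ]
    return M.parse_vocabulary(rows)


@pytest.fixture(scope="session")
def default_world():
    """The pinned synthetic study world (seed 17)."""
    return M.generate_world(M.SyntheticConfig())


@pytest.fixture(scope="session")
def world_profiles(default_world):
    w = default_world
    genes = [
        M.build_meshop(g, w.past_links.articles(g), w.past_corpus)
        for g in w.gene_ids
    ]
    diseases = [
        M.build_disease_meshop(d, w.past_corpus) for d in w.disease_term_ids
    ]
    return genes, diseases


@pytest.fixture(scope="session")
def world_validation(default_world):
    w = default_world
    return M.extract_novel_cooccurrences(
        (w.past_corpus, w.past_links),
        (w.future_corpus, w.future_links),
        w.gene_ids,
        w.disease_term_ids,
    )
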