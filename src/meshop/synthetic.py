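"""Synthetic literature worlds for end-to-end testing of profile comparison.

The generator emulates, at desk scale, the statistical structure that the
profiling and validation machinery assumes about a bibliographic corpus:

* a term vocabulary arranged as a random forest of tree numbers, with a
  flat disease category (``C``) and several general categories;
* a heavy-tailed (Zipf) marginal over general terms — each article carries
  a term independently with a term-specific probability, so frequent terms
  are uninformative and rare ones carry signal;
* genes and diseases as entities with article sets of heterogeneous size
  (literature-volume bias is built in on purpose);
* topical structure: every entity has a small set of "topic" terms whose
  per-article probability is multiplied by ``enrichment_factor``;
* three classes of future gene-disease co-occurrence, none of which
  co-occur in the past corpus (suppressed by construction): *planted*
  pairs (the exported curated ground truth) and *emergent* pairs both
  share their disease's full topic with comparable literature depth —
  genuine relationships, of which only the planted subset is "curated";
  *noise* pairs share only ``noise_topic_share`` topic terms and their
  genes are sampled proportionally to literature volume raised to
  ``literature_bias``, emulating the empirical tendency of well-studied
  genes to acquire new disease links for reasons only weakly topical.

Everything is reproducible from ``(config, seed)``; exported files use the
same TSV dialects the corpus module parses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .corpus import AnnotatedCorpus, EntityLinkSet, parse_annotations, parse_entity_links
from .vocabulary import MeshVocabulary, parse_vocabulary

__all__ = ["SyntheticConfig", "SyntheticWorld", "generate_world", "export_world"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; defaults are the pinned study conditions."""

    seed: int = 17
    n_terms: int = 300
    tree_branching: int = 3
    n_background_articles: int = 2000
    zipf_exponent: float = 1.1
    n_genes: int = 50
    n_diseases: int = 20
    articles_per_entity: tuple[int, int] = (5, 30)
    n_planted_pairs: int = 10
    n_emergent_pairs: int = 15
    topic_size: int = 8
    enrichment_factor: float = 5.0
    future_fraction: float = 0.25
    mean_terms_per_article: float = 12.0
    n_future_noise_pairs: int = 15
    noise_topic_share: int = 2
    literature_bias: float = 2.0
    preexisting_link_prob: float = 0.02
    gene_id_jitter: float = 12.0

    def __post_init__(self) -> None:
        if self.n_terms <= self.n_diseases:
            raise ValueError("n_terms must exceed n_diseases")
        if self.topic_size > self.n_terms - self.n_diseases:
            raise ValueError("topic_size larger than the general vocabulary")
        if self.n_planted_pairs > min(self.n_genes, self.n_diseases):
            raise ValueError("more planted pairs than distinct genes/diseases")
        if self.n_planted_pairs + self.n_emergent_pairs > self.n_genes:
            raise ValueError("planted + emergent pairs exceed the gene count")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not 0 < self.future_fraction < 1:
            raise ValueError("future_fraction must lie in (0, 1)")
        if self.noise_topic_share > self.topic_size:
            raise ValueError("noise_topic_share cannot exceed topic_size")
        for name in ("n_background_articles", "n_genes", "n_diseases", "tree_branching"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def null(cls, seed: int = 17, **overrides) -> "SyntheticConfig":
        """A world with no planted signal and no literature bias.

        Used for calibration: with enrichment 1 and unbiased future
        co-occurrences every scorer should be at chance.  The larger
        noise-pair count narrows the AUC sampling spread around 0.5.
        """
        base = dict(
            seed=seed,
            enrichment_factor=1.0,
            n_planted_pairs=0,
            n_emergent_pairs=0,
            noise_topic_share=0,
            literature_bias=0.0,
            n_future_noise_pairs=200,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticWorld:
    """A generated corpus pair (past/future) with ground-truth labels."""

    config: SyntheticConfig
    vocabulary: MeshVocabulary
    past_corpus: AnnotatedCorpus
    past_links: EntityLinkSet
    future_corpus: AnnotatedCorpus
    future_links: EntityLinkSet
    gene_ids: list[str]
    disease_term_ids: list[str]
    planted_pairs: frozenset[tuple[str, str]]
    emergent_pairs: frozenset[tuple[str, str]]
    noise_pairs: frozenset[tuple[str, str]]
    # raw tables, kept for lossless export
    vocab_rows: list[tuple[str, str, str]] = field(default_factory=list)
    past_annotation_rows: list[tuple[str, str]] = field(default_factory=list)
    future_annotation_rows: list[tuple[str, str]] = field(default_factory=list)
    past_link_rows: list[tuple[str, str, str]] = field(default_factory=list)
    future_link_rows: list[tuple[str, str, str]] = field(default_factory=list)


def _make_vocabulary_rows(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[list[tuple[str, str, str]], list[str], list[str]]:
    """Random forest of tree numbers: flat C roots plus general categories."""
    rows: list[tuple[str, str, str]] = []
    disease_ids: list[str] = []
    for i in range(config.n_diseases):
        tid = f"D{i + 1:05d}"
        rows.append((tid, f"disease {i + 1}", f"C{i + 1:02d}"))
        disease_ids.append(tid)

    general_ids: list[str] = []
    categories = ["D", "E", "F", "G"]
    # per category: list of (tree_number, n_children)
    nodes: dict[str, list[list]] = {c: [] for c in categories}
    roots: dict[str, int] = {c: 0 for c in categories}
    n_general = config.n_terms - config.n_diseases
    for i in range(n_general):
        tid = f"D{config.n_diseases + i + 1:05d}"
        cat = categories[int(rng.integers(len(categories)))]
        open_nodes = [n for n in nodes[cat] if n[1] < config.tree_branching]
        if open_nodes and rng.random() > 0.3:
            parent = open_nodes[int(rng.integers(len(open_nodes)))]
            parent[1] += 1
            tn = f"{parent[0]}.{parent[1]:02d}"
        else:
            roots[cat] += 1
            tn = f"{cat}{roots[cat]:02d}"
        nodes[cat].append([tn, 0])
        rows.append((tid, f"term {config.n_diseases + i + 1}", tn))
        general_ids.append(tid)
    return rows, disease_ids, general_ids


def _article_block(
    rng: np.random.Generator,
    n_articles: int,
    pi: np.ndarray,
    general_ids: list[str],
    zipf_w: np.ndarray,
) -> list[list[str]]:
    """Per-article general-term draws; every article gets at least one term."""
    hits = rng.random((n_articles, len(pi))) < pi
    out: list[list[str]] = []
    p_fallback = zipf_w / zipf_w.sum()
    for row in hits:
        idx = np.flatnonzero(row)
        if idx.size == 0:
            idx = rng.choice(len(pi), size=1, p=p_fallback)
        out.append([general_ids[i] for i in idx])
    return out


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Build a reproducible synthetic world from the configuration."""
    rng = np.random.default_rng(config.seed)

    vocab_rows, disease_ids, general_ids = _make_vocabulary_rows(config, rng)
    vocab = parse_vocabulary(
        "\t".join(r) for r in vocab_rows
    )

    n_general = len(general_ids)
    zipf_w = (np.arange(1, n_general + 1)) ** (-config.zipf_exponent)
    pi = np.minimum(0.5, config.mean_terms_per_article * zipf_w / zipf_w.sum())

    # Topic terms come from the mid-frequency band: frequent enough that a
    # small article set samples them, rare enough to be informative.
    band = np.flatnonzero((pi >= 0.04) & (pi <= 0.25))
    if band.size < config.topic_size:
        band = np.arange(n_general)

    disease_topics = {
        d: rng.choice(band, size=config.topic_size, replace=False)
        for d in disease_ids
    }

    # Literature volumes for both entity classes, then gene database ids
    # assigned in jittered volume order: lower ids tend to belong to
    # better-studied genes.
    lo, hi = config.articles_per_entity
    disease_volume = {
        d: int(rng.integers(lo, hi + 1)) for d in disease_ids
    }
    volumes = rng.integers(lo, hi + 1, size=config.n_genes)
    order = np.argsort(-(volumes + rng.normal(0, config.gene_id_jitter, config.n_genes)),
                       kind="stable")
    gene_ids = [""] * config.n_genes
    for rank, idx in enumerate(order):
        gene_ids[idx] = str(rank + 1)
    gene_volume = {gene_ids[k]: int(volumes[k]) for k in range(config.n_genes)}

    gene_topics = {
        g: rng.choice(band, size=config.topic_size, replace=False)
        for g in gene_ids
    }

    # True relationships: the gene inherits the disease topic wholesale,
    # modelling a shared research program, and the two literatures get
    # comparable depth so shared-topic significance levels can match.  A
    # curated subset ("planted", the exported ground truth) and an
    # uncurated remainder ("emergent") are built identically; both are
    # sampled with a mild volume bias, since well-studied genes are
    # over-represented even among genuine relationships.
    all_genes = list(gene_volume)
    vol_w = np.array([gene_volume[g] for g in all_genes], dtype=float)
    n_true = config.n_planted_pairs + config.n_emergent_pairs
    if n_true:
        idx = rng.choice(len(all_genes), size=n_true, replace=False,
                         p=vol_w / vol_w.sum())
        true_genes = [all_genes[i] for i in idx]
    else:
        true_genes = []
    planted_genes = true_genes[: config.n_planted_pairs]
    emergent_genes = true_genes[config.n_planted_pairs:]
    planted_diseases = [
        disease_ids[i]
        for i in rng.choice(config.n_diseases, size=config.n_planted_pairs,
                            replace=False)
    ]
    other_diseases = [d for d in disease_ids if d not in planted_diseases]
    if not other_diseases:
        other_diseases = disease_ids
    emergent_diseases = [
        other_diseases[int(rng.integers(len(other_diseases)))]
        for _ in emergent_genes
    ]
    planted = frozenset(zip(planted_genes, planted_diseases))
    emergent = frozenset(zip(emergent_genes, emergent_diseases))
    for g, d in sorted(planted | emergent):
        gene_topics[g] = disease_topics[d].copy()
    partner_vols: dict[str, list[int]] = {}
    for g, d in planted | emergent:
        partner_vols.setdefault(d, []).append(gene_volume[g])
    for d in sorted(partner_vols):
        disease_volume[d] = int(np.clip(
            round(float(np.mean(partner_vols[d]))) + rng.integers(-3, 4), lo, hi))

    # Volume-driven co-mentions: genes sampled with replacement by
    # literature volume raised to the bias exponent (so heavily studied
    # genes acquire several future partners), diseases uniformly; each
    # such pair shares only a few topic terms with its disease.
    free_genes = [g for g in all_genes if g not in set(true_genes)]
    weights = np.array([gene_volume[g] for g in free_genes], dtype=float)
    weights = weights ** config.literature_bias
    weights /= weights.sum()
    noise: set[tuple[str, str]] = set()
    guard = 0
    while len(noise) < config.n_future_noise_pairs and guard < 10000:
        guard += 1
        g = free_genes[int(rng.choice(len(free_genes), p=weights))]
        d = disease_ids[int(rng.integers(config.n_diseases))]
        if (g, d) not in noise:
            noise.add((g, d))
    noise_pairs = frozenset(noise)
    for g, d in sorted(noise_pairs):
        if config.noise_topic_share == 0:
            continue
        shared = rng.choice(disease_topics[d], size=config.noise_topic_share,
                            replace=False)
        slots = rng.choice(config.topic_size, size=config.noise_topic_share,
                           replace=False)
        topic = gene_topics[g].copy()
        topic[slots] = shared
        gene_topics[g] = topic

    blocked: dict[str, set[str]] = {g: set() for g in gene_ids}
    for g, d in planted | emergent | noise_pairs:
        blocked[g].add(d)

    # ------------------------------------------------------------------
    # Past articles
    # ------------------------------------------------------------------
    annotations: list[tuple[str, str]] = []
    link_rows: list[tuple[str, str, str]] = []
    counter = 0

    def next_article(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:06d}"

    def boosted(topic: np.ndarray) -> np.ndarray:
        p = pi.copy()
        p[topic] = np.minimum(0.9, config.enrichment_factor * p[topic])
        return p

    for terms in _article_block(rng, config.n_background_articles, pi,
                                general_ids, zipf_w):
        aid = next_article("A")
        annotations.extend((aid, t) for t in terms)

    for d in disease_ids:
        for terms in _article_block(rng, disease_volume[d], boosted(disease_topics[d]),
                                    general_ids, zipf_w):
            aid = next_article("A")
            annotations.append((aid, d))
            annotations.extend((aid, t) for t in terms)

    for g in gene_ids:
        m = gene_volume[g]
        for terms in _article_block(rng, m, boosted(gene_topics[g]),
                                    general_ids, zipf_w):
            aid = next_article("A")
            link_rows.append(("9606", g, aid))
            annotations.extend((aid, t) for t in terms)
            if rng.random() < config.preexisting_link_prob:
                allowed = [d for d in disease_ids if d not in blocked[g]]
                if allowed:
                    annotations.append((aid, allowed[int(rng.integers(len(allowed)))]))

    # ------------------------------------------------------------------
    # Future articles (disjoint id block)
    # ------------------------------------------------------------------
    f_annotations: list[tuple[str, str]] = []
    f_link_rows: list[tuple[str, str, str]] = []

    n_future_bg = int(config.n_background_articles * config.future_fraction)
    for terms in _article_block(rng, n_future_bg, pi, general_ids, zipf_w):
        aid = next_article("F")
        f_annotations.extend((aid, t) for t in terms)

    def realize(g: str, d: str, k: int) -> None:
        for terms in _article_block(rng, k, boosted(gene_topics[g]),
                                    general_ids, zipf_w):
            aid = next_article("F")
            f_link_rows.append(("9606", g, aid))
            f_annotations.append((aid, d))
            f_annotations.extend((aid, t) for t in terms)

    for g, d in sorted(planted | emergent):
        realize(g, d, int(rng.integers(1, 4)))
    for g, d in sorted(noise_pairs):
        realize(g, d, 1)

    past_corpus = parse_annotations(("\t".join(r) for r in annotations), vocab)
    future_corpus = parse_annotations(("\t".join(r) for r in f_annotations), vocab)
    past_links = parse_entity_links(("\t".join(r) for r in link_rows),
                                    dialect="gene2pubmed", taxon_filter="9606",
                                    source_tag="synthetic-gene2pubmed")
    future_links = parse_entity_links(("\t".join(r) for r in f_link_rows),
                                      dialect="gene2pubmed", taxon_filter="9606",
                                      source_tag="synthetic-gene2pubmed")

    return SyntheticWorld(
        config=config,
        vocabulary=vocab,
        past_corpus=past_corpus,
        past_links=past_links,
        future_corpus=future_corpus,
        future_links=future_links,
        gene_ids=sorted(gene_ids, key=int),
        disease_term_ids=list(disease_ids),
        planted_pairs=planted,
        emergent_pairs=emergent,
        noise_pairs=noise_pairs,
        vocab_rows=vocab_rows,
        past_annotation_rows=annotations,
        future_annotation_rows=f_annotations,
        past_link_rows=link_rows,
        future_link_rows=f_link_rows,
    )


def export_world(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world as TSV files in the corpus-module dialects.

    Emits the vocabulary, past/future annotation tables, past/future
    gene2pubmed-dialect link files, the ground-truth planted-pair table,
    and a YAML manifest recording the configuration.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(name: str, header: str, rows) -> None:
        path = directory / name
        with path.open("w") as fh:
            fh.write(header)
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[name] = path

    write("vocabulary.tsv", "#term_id\tname\ttree_number\n", world.vocab_rows)
    write("annotations_past.tsv", "#article_id\tterm_id\n",
          world.past_annotation_rows)
    write("annotations_future.tsv", "#article_id\tterm_id\n",
          world.future_annotation_rows)
    write("gene2pubmed_past.tsv", "#tax_id\tGeneID\tPubMed_ID\n",
          world.past_link_rows)
    write("gene2pubmed_future.tsv", "#tax_id\tGeneID\tPubMed_ID\n",
          world.future_link_rows)
    write("planted_pairs.tsv", "#gene_id\tdisease_term_id\n",
          sorted(world.planted_pairs))

    manifest = directory / "manifest.yaml"
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(world.config).items()
    }
    with manifest.open("w") as fh:
        yaml.safe_dump({"config": cfg}, fh, sort_keys=True)
    paths["manifest.yaml"] = manifest
    return paths
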