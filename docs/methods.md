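# Methods

## Profile construction

A MeSHOP is built from an entity's article set against a *universal
background*: the full annotated corpus, shared by genes and diseases so
that their profiles are comparable.  `N` counts only articles that carry
at least one resolvable annotation; articles without MeSH terms do not
enter the background.

Annotation sets are ancestor-closed before anything is counted: a term
implies every ancestor along each of its tree numbers, so an article
annotated with a leaf contributes to the background count `n_t` of the
whole chain.  Closure guarantees the hierarchy-monotonicity invariant
`n_parent ≥ n_child`, which the corpus parser's tests assert.  Tree-number
prefixes absent from the supplied vocabulary are skipped silently — partial
and subset vocabularies are legal inputs, and the profile machinery takes
whatever vocabulary file it is given.

Per-term measures:

- `count` — articles of the entity carrying the term (set semantics: an
  article contributes at most once per term).
- `fraction` — count divided by the total number of term–article
  incidences over the profile support; fractions sum to 1.
- `tfidf` — `count × ln(N / n_t)`.  The inverse-document-frequency factor
  is the natural log of the background odds; any monotone idf variant
  would preserve rankings only approximately, so this choice is pinned.
- `pvalue` — the one-sided upper tail `P(X ≥ count)` of the
  hypergeometric law with the table's margins (Fisher's exact test).  Only
  over-representation is of interest, so no two-sided variant is offered.
  The tail is computed with `scipy.stats.hypergeom.sf`; the test suite
  checks it against exact integer enumeration over every 2×2 table with
  `N ≤ 60` at an absolute tolerance of 1e-12 (observed agreement is at
  machine precision, ~4e-16).

P-values are floored at `epsilon_p = 1e-300` (configurable).  Profile
P-values in heavily annotated corpora underflow double precision; the
floor keeps the logarithms used by several similarity scores finite
without affecting any ranking.

Disease profiles are ordinary profiles over the article set carrying the
disease's term (post-closure).  The defining term itself stays in the
profile by default; `exclude_self` removes it after fraction
normalization, for uses where self-matching would be circular.

## Similarity panel

All sums run over the union `M = G ∪ D` of the two supports with absence
conventions: count/fraction/tfidf = 0 and p = 1 for a term missing from a
profile.  Under these conventions each formula is well defined — an absent
term contributes nothing to the combined-P sum (`gp + dp − gp·dp = 1`) and
the log-ratio sums behave as written.  The L2 family is implemented as
the sum of squared differences without a square root, which is
monotone-equivalent for every ranking use.  Natural logarithms are used
throughout; a different base rescales scores monotonically and cannot
change AUC or rank outputs.

Orientation is an explicit part of each scorer's registration: distances
and both log-P sums default to lower-is-similar, cosine and cardinality
scores to higher-is-similar, and `score_all_pairs` stores oriented values
(distances negated) so that downstream evaluation can always treat larger
as more similar.  Orientations are overridable per call: for
`sum_diff_log_p` in particular the natural direction is genuinely
ambiguous (the score is antisymmetric in the pair), so the default is a
documented convention rather than a derived fact.

The per-term shared score used in the shared-term report is the absolute
P-value difference `|gp − dp|`; reports are sorted ascending so the most
similarly significant terms come first.

The gene-database-id scorer is registered with the other fifteen for
completeness but is a pure bibliometric baseline: id order proxies the
length of a gene's study history, not any pair property.

## Evaluation

AUC is the Mann–Whitney statistic `P(s_pos > s_neg) + ½·P(tie)` computed
from mid-ranks; the emitted ROC curve walks score levels from high to low,
so tied levels produce diagonal segments and the trapezoidal area under
the curve equals the Mann–Whitney value exactly (asserted to 1e-12).
Pairs whose gene or disease lacks a profile are dropped pairwise and
counted, never imputed.

The analytic conversion `rank = 1 + (1 − AUC)(n − 1)` gives the expected
rank of a single positive among `n` candidates.  Note the random-scorer
value is `(n + 1)/2`, not `n/2`: the formula is authoritative.  The
ranked-list simulation draws 1 positive and `n − 1` negatives without
replacement per trial and ranks with mid-rank ties, so an all-tied scorer
returns exactly `(n + 1)/2` and an oracle scorer exactly 1.

MAP is defined per disease (the disease is the query, genes are ranked),
the standard information-retrieval reading; the averaging axis is a
package convention.  Pooled-pair AUC over the whole labeled universe is
the default; per-disease evaluation is available through the same
primitives.

Validation labels come from three constructions: time-split novel
co-occurrence (positive = pair with zero shared articles in the past
snapshot and ≥ 1 in the future snapshot), curated relationship tuples,
and a pre-existing mode.  Pairs already co-occurring in the past enter
the universe under an explicit policy — `exclude` (default, avoids label
leakage), `as_negative`, or `as_positive` (the pre-existing evaluation) —
because all three framings are legitimate questions.

## Synthetic worlds

`SyntheticConfig` defaults define the pinned study conditions: 300 terms,
2000 background articles, 50 genes, 20 diseases, 10 planted pairs,
enrichment factor 5, seed 17.  Articles carry each general term
independently with a Zipf-decaying probability (exponent 1.1, scaled to a
mean of 12 terms per article, matching the order of real per-article MeSH
assignment counts).  Entity literatures span 5–30 articles, so
literature-volume heterogeneity — the central bibliometric bias — is built
in.  Gene integer ids are assigned in jittered volume order (jitter SD 12),
emulating sequential database accession: lower ids tend to be
better-studied genes, noisily.

Each entity has a topic of 8 terms drawn from the mid-frequency band
(per-article probability 0.04–0.25) whose probabilities are multiplied by
the enrichment factor in that entity's articles.  The band matters: rarer
terms are not sampled reliably enough for a small article set to carry
signal, more frequent ones are uninformative.

Future co-occurrences (realized as a disjoint article-id block rather
than timestamps — the validation machinery only needs a past/future
split) come in three classes:

- **planted** (10): curated ground truth.  The gene inherits its
  disease's full topic, and the two literatures get comparable depth
  (coupled volumes), modelling a shared research program whose
  significance levels can match on both sides.
- **emergent** (15): constructed identically but not exported as curated
  truth — genuine relationships the curated set does not know about, as
  with any real curated database.
- **noise** (15): volume-driven co-mentions.  Genes are sampled with
  replacement proportionally to volume² (so heavily studied genes acquire
  several future partners); the pair shares only 2 topic terms.

Both genuine classes are sampled with a mild volume bias (∝ volume),
since well-studied genes are over-represented even among curated
relationships.  Past co-occurrence is suppressed by construction for all
three classes, and a small rate (2%) of random disease-term annotations
on gene articles provides pre-existing pairs for the policy machinery.

`SyntheticConfig.null()` removes every signal source — enrichment 1, no
planted/emergent pairs, unbiased future co-mentions with no topical
share — and enlarges the future co-mention count to 200 so the AUC
sampling spread around 0.5 is narrow; it is the calibration world in
which every scorer should sit at chance.

What the generator does **not** emulate: MEDLINE scale (profiles here
have tens of articles, not tens of thousands, so P-values bottom out
around 1e-40 rather than underflowing), correlated term usage beyond the
planted topics, multi-gene articles, annotation drift over time, and
actual MeSH content.  Passing tests on these worlds demonstrate that the
statistical machinery behaves as specified and that planted topical
signal is recoverable above volume bias at desk scale — not that any
particular real-data AUC would be reproduced.

## Numerical and design notes

- Tie handling is mid-rank / half-credit everywhere (ROC, ranked lists),
  which makes the all-ties → 0.5 contract exact and reproducible.
- Score matrices are deterministic given inputs; the only randomness in
  evaluation is the ranked-list sampling, driven by a single seed
  recorded in the report.
- Degenerate inputs: a term margin of zero gives p = 1; an empty overlap
  gives an L2-overlap distance of 0 (nothing to compare — logged); a
  zero-norm weight vector makes cosine undefined (NaN with a warning, and
  such pairs are dropped from evaluation).
- Profile TSVs do not carry the entity article count; reading them back
  reconstructs a lower bound that similarity scoring never uses.
- Test problem sizes (N ≤ 60 for the exhaustive Fisher sweep, ≤ 50 pairs
  for the AUC oracle instances, the pinned world sizes above) were chosen
  as the smallest scales at which the checked properties are
  non-trivially exercised.

## Known limitations

- The direct-association multiple-testing correction factor is
  caller-supplied; the package does not guess the number of implicit
  comparisons.
- The `sum_diff_log_p` orientation and the headline-score scaling are
  conventions; the antisymmetric score in particular has no intrinsic
  "similar" direction.
- Per-disease class-specific backgrounds are not implemented; the
  universal background is shared by both entity classes.
- Null-world calibration is a stochastic property: at the pinned seed all
  sixteen scorers sit within [0.45, 0.55], but individual scorers at
  other seeds can graze the band edges (sampling SD ≈ 0.02 at 200
  positives).
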