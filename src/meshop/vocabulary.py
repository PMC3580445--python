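"""Medical Subject Headings (MeSH) vocabulary as a forest of tree numbers.

MeSH terms occupy one or more positions in a hierarchy of dot-delimited
"tree numbers" (e.g. ``C04.557``).  An article annotated with a term is,
for profiling purposes, considered annotated with every ancestor of that
term along each of its tree numbers, so the vocabulary's job here is to
answer ancestor queries and to classify terms by category (diseases live
under the ``C`` subtree by convention).

The input format is a 3-column TSV (``term_id``, ``name``, ``tree_number``)
with one row per tree number; a term with several positions appears on
several rows.  Lines starting with ``#`` are comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

__all__ = [
    "MeshTerm",
    "MeshVocabulary",
    "VocabularyError",
    "parse_vocabulary",
]


class VocabularyError(ValueError):
    """Malformed vocabulary input or unresolvable term lookup."""


@dataclass(frozen=True)
class MeshTerm:
    """A single vocabulary term with its hierarchy positions."""

    term_id: str
    name: str
    tree_numbers: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tree_numbers:
            raise VocabularyError(f"term {self.term_id!r} has no tree numbers")


def _prefixes(tree_number: str) -> Iterator[str]:
    """Yield every proper dot-prefix of a tree number, shortest first."""
    parts = tree_number.split(".")
    for i in range(1, len(parts)):
        yield ".".join(parts[:i])


@dataclass
class MeshVocabulary:
    """A collection of terms indexed by id and by tree number.

    The tree-number index is injective: a position in the forest belongs
    to exactly one term.
    """

    terms: dict[str, MeshTerm] = field(default_factory=dict)
    index: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> MeshTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise VocabularyError(f"unknown term id {term_id!r}") from None

    def add(self, term: MeshTerm) -> None:
        if term.term_id in self.terms:
            raise VocabularyError(f"duplicate term id {term.term_id!r}")
        for tn in term.tree_numbers:
            owner = self.index.get(tn)
            if owner is not None:
                raise VocabularyError(
                    f"tree number {tn!r} claimed by both {owner!r} and {term.term_id!r}"
                )
        self.terms[term.term_id] = term
        for tn in term.tree_numbers:
            self.index[tn] = term.term_id

    def ancestors(self, term_id: str) -> set[str]:
        """Term ids at every proper dot-prefix of the term's tree numbers.

        The term itself is never included.  Prefixes not present in the
        vocabulary (legal in partial/subset vocabularies) are skipped.
        """
        term = self[term_id]
        out: set[str] = set()
        for tn in term.tree_numbers:
            for prefix in _prefixes(tn):
                owner = self.index.get(prefix)
                if owner is not None:
                    out.add(owner)
        out.discard(term_id)
        return out

    def closure(self, term_ids: Iterable[str]) -> set[str]:
        """The input set unioned with the ancestors of every member.

        Idempotent and monotone in the input set.
        """
        out: set[str] = set()
        for tid in term_ids:
            out.add(self[tid].term_id)
            out.update(self.ancestors(tid))
        return out

    def is_disease_term(self, term_id: str, category_prefix: str = "C") -> bool:
        """True iff any tree number of the term lies under the disease category."""
        term = self[term_id]
        return any(
            tn == category_prefix or tn.startswith(category_prefix)
            for tn in term.tree_numbers
        )

    def disease_terms(self, category_prefix: str = "C") -> set[str]:
        """All term ids in the disease category."""
        return {
            tid for tid in self.terms if self.is_disease_term(tid, category_prefix)
        }


def _iter_rows(stream: TextIO | Iterable[str]) -> Iterator[tuple[int, list[str]]]:
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


def parse_vocabulary(stream: TextIO | Iterable[str]) -> MeshVocabulary:
    """Read a vocabulary TSV (term_id, name, tree_number) into a MeshVocabulary.

    A term appearing on multiple rows (one per tree number) is merged by
    id; a tree number claimed by two different term ids is a hard error.
    """
    ids: dict[str, str] = {}  # term_id -> name
    trees: dict[str, set[str]] = {}
    owners: dict[str, str] = {}  # tree_number -> term_id
    for lineno, fields in _iter_rows(stream):
        if len(fields) != 3:
            raise VocabularyError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        term_id, name, tree_number = (f.strip() for f in fields)
        if not term_id or not tree_number:
            raise VocabularyError(f"line {lineno}: empty term id or tree number")
        owner = owners.get(tree_number)
        if owner is not None and owner != term_id:
            raise VocabularyError(
                f"line {lineno}: tree number {tree_number!r} claimed by both "
                f"{owner!r} and {term_id!r}"
            )
        owners[tree_number] = term_id
        ids.setdefault(term_id, name)
        trees.setdefault(term_id, set()).add(tree_number)

    vocab = MeshVocabulary()
    for term_id, name in ids.items():
        vocab.add(MeshTerm(term_id, name, frozenset(trees[term_id])))
    return vocab
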