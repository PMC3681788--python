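"""Core data types shared across the toolkit.

A candidate drug-drug interaction (DDI) instance is one sentence with two
focused drug mentions blinded to ``drug1``/``drug2`` (any other drug mention
becomes ``drug0``); the classification task is to decide whether the sentence
asserts an interaction between the focused pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: Surface forms treated as generic (non-specific) drug mentions.
GENERIC_DRUG_SURFACES = frozenset({"drug", "drugs", "Drug", "Drugs"})

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


@dataclass
class Token:
    """One token of a sentence; ``index`` is 0-based and contiguous."""

    index: int
    surface: str
    lemma: Optional[str] = None
    pos: Optional[str] = None
    semtypes: frozenset = frozenset()

    @property
    def lemma_or_surface(self) -> str:
        return self.lemma if self.lemma else self.surface.lower()


@dataclass
class EntityMention:
    """A drug mention covering an inclusive 0-based token span."""

    id: str
    token_span: tuple  # (start, end) inclusive
    surface: str

    @property
    def is_generic(self) -> bool:
        return self.surface in GENERIC_DRUG_SURFACES

    @property
    def start(self) -> int:
        return self.token_span[0]

    @property
    def end(self) -> int:
        return self.token_span[1]


@dataclass
class SentenceRecord:
    """One annotated sentence: tokens, entities, parses and gold pair labels.

    ``dep_edges`` holds ``(head_index, dependent_index, relation)`` triples over
    token indices (the root has no incoming edge).  ``const_tree`` is a
    :class:`ddikernels.tree_kernel.TreeNode` or ``None`` when no constituency
    parse is attached.
    """

    doc_id: str
    sent_id: str
    tokens: list
    entities: list
    dep_edges: list = field(default_factory=list)
    const_tree: object = None
    gold_pairs: list = field(default_factory=list)

    @property
    def text(self) -> str:
        return " ".join(t.surface for t in self.tokens)

    def pair_label(self, e1_id: str, e2_id: str) -> str:
        for a, b, label in self.gold_pairs:
            if {a, b} == {e1_id, e2_id}:
                return label
        return UNKNOWN


@dataclass
class CandidateInstance:
    """A blinded candidate pair ready for feature/kernel computation.

    ``tokens`` are blinded surfaces; ``d1``/``d2`` index the ``drug1``/``drug2``
    tokens and ``end`` the last token.  ``dep_edges`` are remapped onto the
    blinded indices.  ``e1_leaf``/``e2_leaf`` index the entity leaves in the
    *original* (unblinded) constituency tree of the sentence.
    """

    pair_id: str
    tokens: list
    d1: int
    d2: int
    end: int
    label: str
    e1: EntityMention
    e2: EntityMention
    lemmas: list = None
    pos: list = None
    semtypes: list = None
    dep_edges: list = field(default_factory=list)
    const_tree: object = None
    e1_leaf: Optional[int] = None
    e2_leaf: Optional[int] = None
    sentence_ref: Optional[SentenceRecord] = None

    def __post_init__(self):
        if not (0 <= self.d1 < self.d2 <= self.end):
            raise ValueError(
                f"{self.pair_id}: require 0 <= d1 < d2 <= END, "
                f"got d1={self.d1} d2={self.d2} END={self.end}"
            )
        if self.tokens[self.d1] != "drug1" or self.tokens[self.d2] != "drug2":
            raise ValueError(f"{self.pair_id}: blinding broken at d1/d2")
        if self.lemmas is None:
            self.lemmas = [t.lower() for t in self.tokens]
        if self.pos is None:
            self.pos = [None] * len(self.tokens)
        if self.semtypes is None:
            self.semtypes = [frozenset()] * len(self.tokens)
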