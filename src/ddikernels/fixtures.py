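"""Synthetic annotated corpora for end-to-end testing without any download.

Sentences are built from a small set of templates with hand-written, exact
dependency parses and constituency bracketings, so gold parses are correct
by construction.  Interacting sentences plant an interaction cue verb in the
inner area between the focused drugs; non-interacting sentences use neutral
wording or a negated pattern; a ``noise_rate`` fraction of sentences carry
labels inconsistent with their wording.  The pair-level class imbalance
defaults to roughly 10% positives, emulating the strong negative skew of
real pharmacology corpora (about one positive for every nine negative
candidate pairs).  A toy DrugBank-style snapshot gives interacting drugs
overlapping field text so the cosine-similarity feature carries signal at
the 0.4 threshold.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass
from pathlib import Path

from .corpus_io import generate_instances, write_conll, write_trees, write_unified_xml
from .feature_kernel import DrugBankSnapshot
from .tree_kernel import parse_penn
from .types import (
    NEGATIVE,
    POSITIVE,
    CandidateInstance,
    EntityMention,
    SentenceRecord,
    Token,
)

DRUG_NAME_POOL = (
    "Alprazodine", "Betaprolol", "Carbamexil", "Dexofenac", "Ethambucin",
    "Fluoxamil", "Gabapentil", "Haloperine", "Ibuprofanil", "Ketoconazil",
    "Lamotrigal", "Metforminol", "Naproxetine", "Omeprazil", "Phenytoral",
    "Quinaprilat", "Ranitidol", "Sertralex", "Tolbutamol", "Valproxen",
    "Warfarilin", "Xylometazil", "Zidovudal", "Amiodaril", "Bupropiona",
    "Cimetidal", "Diazepanol", "Erythromax", "Felodipral", "Glipizal",
)

SEMTYPE_CHOICES = (
    frozenset({"phsu"}), frozenset({"clnd"}), frozenset({"phsu", "bacs"}),
    frozenset({"antb"}), frozenset({"aapp", "phsu"}), frozenset({"chvs"}),
)


@dataclass
class SyntheticConfig:
    """Conditions of the synthetic corpus.

    ``positive_rate`` is the target fraction of positive candidate *pairs*
    (default 0.10, matching a roughly 1:9 positive:negative imbalance);
    ``noise_rate`` is the fraction of sentences whose labels contradict
    their wording; ``seed`` is mandatory.
    """

    n_sentences: int = 60
    entities_per_sentence: tuple = (2, 3)
    positive_rate: float = 0.10
    noise_rate: float = 0.05
    generic_rate: float = 0.08
    cue_keywords: tuple = ("increase", "decrease", "inhibit", "potentiate",
                           "enhance", "reduce")
    sentences_per_document: int = 5
    seed: int = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.positive_rate, self.noise_rate, self.generic_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.entities_per_sentence
        if lo < 2 or hi > 3 or lo > hi:
            raise ValueError("entities_per_sentence must be within [2, 3]")


@dataclass
class _Template:
    tokens: list
    pos: list
    deps: list                  # (head, dependent, relation)
    penn: str
    entity_slots: dict          # "E1"/"E2"/"E3" -> token index
    pair_labels: list           # (slot_a, slot_b, label)
    cue_slot: int = None
    n_entities: int = 2


CUE2 = _Template(
    tokens=["E1", "markedly", "CUE", "the", "effect", "of", "E2", "in",
            "patients", "."],
    pos=["NN", "RB", "VBZ", "DT", "NN", "IN", "NN", "IN", "NNS", "."],
    deps=[(2, 0, "nsubj"), (2, 1, "advmod"), (2, 4, "dobj"), (4, 3, "det"),
          (4, 5, "prep"), (5, 6, "pobj"), (2, 7, "prep"), (7, 8, "pobj"),
          (2, 9, "punct")],
    penn="(S (NP (NN E1)) (VP (ADVP (RB markedly)) (VBZ CUE) "
         "(NP (NP (DT the) (NN effect)) (PP (IN of) (NP (NN E2)))) "
         "(PP (IN in) (NP (NNS patients)))) (. .))",
    entity_slots={"E1": 0, "E2": 6},
    pair_labels=[("E1", "E2", POSITIVE)],
    cue_slot=2, n_entities=2)

CUE3 = _Template(
    tokens=["Coadministration", "of", "E1", "with", "E3", "significantly",
            "CUE", "serum", "concentrations", "of", "E2", "."],
    pos=["NN", "IN", "NN", "IN", "NN", "RB", "VBZ", "JJ", "NNS", "IN", "NN",
         "."],
    deps=[(6, 0, "nsubj"), (0, 1, "prep"), (1, 2, "pobj"), (0, 3, "prep"),
          (3, 4, "pobj"), (6, 5, "advmod"), (6, 8, "dobj"), (8, 7, "nn"),
          (8, 9, "prep"), (9, 10, "pobj"), (6, 11, "punct")],
    penn="(S (NP (NP (NN Coadministration)) (PP (IN of) (NP (NN E1))) "
         "(PP (IN with) (NP (NN E3)))) (VP (ADVP (RB significantly)) "
         "(VBZ CUE) (NP (NP (JJ serum) (NNS concentrations)) "
         "(PP (IN of) (NP (NN E2))))) (. .))",
    entity_slots={"E1": 2, "E3": 4, "E2": 10},
    pair_labels=[("E1", "E2", POSITIVE), ("E3", "E2", POSITIVE),
                 ("E1", "E3", NEGATIVE)],
    cue_slot=6, n_entities=3)

NEUTRAL2 = _Template(
    tokens=["E1", "and", "E2", "were", "administered", "to", "healthy",
            "volunteers", "."],
    pos=["NN", "CC", "NN", "VBD", "VBN", "TO", "JJ", "NNS", "."],
    deps=[(0, 1, "cc"), (0, 2, "conj"), (4, 0, "nsubjpass"),
          (4, 3, "auxpass"), (4, 5, "prep"), (5, 7, "pobj"), (7, 6, "amod"),
          (4, 8, "punct")],
    penn="(S (NP (NN E1) (CC and) (NN E2)) (VP (VBD were) "
         "(VP (VBN administered) (PP (TO to) (NP (JJ healthy) "
         "(NNS volunteers))))) (. .))",
    entity_slots={"E1": 0, "E2": 2},
    pair_labels=[("E1", "E2", NEGATIVE)],
    n_entities=2)

NEGWORD2 = _Template(
    tokens=["E1", "was", "not", "studied", "together", "with", "E2", "."],
    pos=["NN", "VBD", "RB", "VBN", "RB", "IN", "NN", "."],
    deps=[(3, 0, "nsubjpass"), (3, 1, "auxpass"), (3, 2, "neg"),
          (3, 4, "advmod"), (4, 5, "prep"), (5, 6, "pobj"), (3, 7, "punct")],
    penn="(S (NP (NN E1)) (VP (VBD was) (RB not) (VP (VBN studied) "
         "(ADVP (RB together)) (PP (IN with) (NP (NN E2))))) (. .))",
    entity_slots={"E1": 0, "E2": 6},
    pair_labels=[("E1", "E2", NEGATIVE)],
    n_entities=2)

NEUTRAL3 = _Template(
    tokens=["E1", "was", "given", "together", "with", "E2", "and", "E3",
            "in", "the", "study", "."],
    pos=["NN", "VBD", "VBN", "RB", "IN", "NN", "CC", "NN", "IN", "DT", "NN",
         "."],
    deps=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "advmod"),
          (3, 4, "prep"), (4, 5, "pobj"), (5, 6, "cc"), (5, 7, "conj"),
          (2, 8, "prep"), (8, 10, "pobj"), (10, 9, "det"), (2, 11, "punct")],
    penn="(S (NP (NN E1)) (VP (VBD was) (VP (VBN given) "
         "(ADVP (RB together)) (PP (IN with) (NP (NN E2) (CC and) "
         "(NN E3))) (PP (IN in) (NP (DT the) (NN study))))) (. .))",
    entity_slots={"E1": 0, "E2": 5, "E3": 7},
    pair_labels=[("E1", "E2", NEGATIVE), ("E1", "E3", NEGATIVE),
                 ("E2", "E3", NEGATIVE)],
    n_entities=3)


def _interacting_sentence_rate(config: SyntheticConfig) -> float:
    """Per-sentence probability of the interacting pattern that yields the
    target pair-level positive rate."""
    lo, hi = config.entities_per_sentence
    counts = range(lo, hi + 1)
    pk = 1.0 / len(counts)
    pos_per_int = sum(pk * (1 if k == 2 else 2) for k in counts)
    pairs_per_sent = sum(pk * math.comb(k, 2) for k in counts)
    return min(1.0, config.positive_rate * pairs_per_sent / pos_per_int)


def _build_sentence(template: _Template, names: dict, cue_base: str,
                    doc_id: str, sent_id: str, semtype_of: dict,
                    force_labels: dict = None) -> SentenceRecord:
    slot_surface = {slot: names[slot] for slot in template.entity_slots}
    tokens = []
    for i, tok in enumerate(template.tokens):
        if tok == "CUE":
            surface, lemma = cue_base + "s", cue_base
        elif tok in template.entity_slots and template.entity_slots[tok] == i:
            surface = slot_surface[tok]
            lemma = surface.lower()
        else:
            surface, lemma = tok, tok.lower()
        st = frozenset()
        if tok in template.entity_slots and template.entity_slots[tok] == i:
            st = semtype_of.get(surface, frozenset())
        tokens.append(Token(i, surface, lemma=lemma, pos=template.pos[i],
                            semtypes=st))
    entities = []
    slot_entity_id = {}
    for k, (slot, idx) in enumerate(sorted(template.entity_slots.items(),
                                           key=lambda kv: kv[1])):
        eid = f"{sent_id}.e{k}"
        slot_entity_id[slot] = eid
        entities.append(EntityMention(eid, (idx, idx), slot_surface[slot]))
    gold = []
    for sa, sb, label in template.pair_labels:
        if force_labels and (sa, sb) in force_labels:
            label = force_labels[(sa, sb)]
        gold.append((slot_entity_id[sa], slot_entity_id[sb], label))
    penn = template.penn
    for slot, idx in template.entity_slots.items():
        penn = penn.replace(f"(NN {slot})", f"(NN {slot_surface[slot]})")
    penn = penn.replace("(VBZ CUE)", f"(VBZ {cue_base}s)")
    return SentenceRecord(doc_id, sent_id, tokens, entities,
                          dep_edges=list(template.deps),
                          const_tree=parse_penn(penn), gold_pairs=gold)


def _alpha(i: int) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def _build_snapshot(records) -> dict:
    """Toy DrugBank snapshot: interacting drugs share field vocabulary."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    names = set()
    for rec in records:
        surf = {e.id: e.surface for e in rec.entities}
        for e in rec.entities:
            if not e.is_generic:
                names.add(e.surface)
        for e1, e2, label in rec.gold_pairs:
            a, b = surf[e1], surf[e2]
            if label == POSITIVE and a != b and not (
                    a in ("drugs", "drug") or b in ("drugs", "drug")):
                union(a, b)
    groups = {}
    for name in sorted(names):
        groups.setdefault(find(name), []).append(name)
    core_words = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")
    snapshot = {}
    for gi, (_, members) in enumerate(sorted(groups.items())):
        shared = len(members) > 1
        for name in members:
            fields = {}
            for tag, fname in (("ind", "indication"), ("pha", "pharmacology"),
                               ("des", "description")):
                words = [name.lower() + "one", name.lower() + "two"]
                if shared:
                    words += [f"{tag}{_alpha(gi)}{w}" for w in core_words]
                else:
                    words += [f"{tag}{name.lower()}{w}" for w in core_words]
                fields[fname] = " ".join(words)
            snapshot[name] = fields
    return snapshot


def generate_records(config: SyntheticConfig):
    """In-memory corpus: (SentenceRecord list, DrugBank snapshot dict)."""
    rng = random.Random(config.seed)
    q = _interacting_sentence_rate(config)
    lo, hi = config.entities_per_sentence
    semtype_of = {name: rng.choice(SEMTYPE_CHOICES) for name in DRUG_NAME_POOL}
    records = []
    for si in range(config.n_sentences):
        doc_id = f"d{si // config.sentences_per_document}"
        sent_id = f"{doc_id}.s{si % config.sentences_per_document}"
        k = rng.randint(lo, hi)
        interacting = rng.random() < q
        noisy = rng.random() < config.noise_rate
        if interacting:
            template = (CUE2 if k == 2 else CUE3)
            if noisy:  # positive labels without the cue wording
                neutral = NEUTRAL2 if k == 2 else NEUTRAL3
                force = {(sa, sb): lab for (sa, sb, lab) in template.pair_labels
                         if (sa, sb) in {(a, b) for a, b, _ in neutral.pair_labels}}
                template, force_labels = neutral, force
            else:
                force_labels = None
        else:
            if noisy:  # cue wording, all labels negative
                template = CUE2 if k == 2 else CUE3
                force_labels = {(sa, sb): NEGATIVE
                                for sa, sb, _ in template.pair_labels}
            else:
                template = (rng.choice([NEUTRAL2, NEGWORD2]) if k == 2
                            else NEUTRAL3)
                force_labels = None
        pool = rng.sample(DRUG_NAME_POOL, template.n_entities)
        names = {slot: pool[i]
                 for i, slot in enumerate(sorted(template.entity_slots))}
        if rng.random() < config.generic_rate:
            names["E2"] = "drugs"
        cue = rng.choice(config.cue_keywords)
        records.append(_build_sentence(template, names, cue, doc_id, sent_id,
                                       semtype_of, force_labels))
    snapshot = _build_snapshot(records)
    return records, snapshot


def generate_corpus(config: SyntheticConfig, out_dir):
    """Write the full synthetic file set; deterministic for a fixed seed.

    Emits ``corpus.xml`` (unified dialect with token semantic types),
    ``corpus.conll``, ``corpus.trees`` and ``drugbank.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, snapshot = generate_records(config)
    write_unified_xml(records, out / "corpus.xml")
    write_conll(records, out / "corpus.conll")
    write_trees(records, out / "corpus.trees")
    (out / "drugbank.json").write_text(
        json.dumps(snapshot, indent=2, sort_keys=True), encoding="utf-8")
    return records


def generate_instances_and_snapshot(config: SyntheticConfig):
    """(instances, DrugBankSnapshot) ready for feature/kernel computation."""
    records, snapshot = generate_records(config)
    instances = []
    for rec in records:
        instances.extend(generate_instances(rec))
    return instances, DrugBankSnapshot(snapshot)


GOLDEN_SENTENCE = ("Plasma concentrations of drug1 are decreased when "
                   "administered with drug2 containing drug0 or drug0.")


def golden_instance() -> CandidateInstance:
    """The worked-example instance used across the test suite.

    The blinded token sequence is fixed; the unblinded entity surfaces are
    synthetic stand-ins (specific, non-generic drug names).  Entity semantic
    types are carb,phsu for entity1 and gngm for entity2.
    """
    tokens = GOLDEN_SENTENCE.split()
    d1, d2 = tokens.index("drug1"), tokens.index("drug2")
    semtypes = [frozenset()] * len(tokens)
    semtypes[d1] = frozenset({"carb", "phsu"})
    semtypes[d2] = frozenset({"gngm"})
    return CandidateInstance(
        pair_id="golden.p0", tokens=list(tokens), d1=d1, d2=d2,
        end=len(tokens) - 1, label=POSITIVE,
        e1=EntityMention("golden.e1", (d1, d1), "Cerivastin"),
        e2=EntityMention("golden.e2", (d2, d2), "Antagrel"),
        semtypes=semtypes)
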