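"""Feature-based kernel: sparse lexical + domain-knowledge feature vectors.

A blinded instance ``Left_Area drug1 Inner_Area drug2 Right_Area`` yields:

* **Abon** — bag-of-n-grams (n = 1..3) per general area;
* **San** — n-grams from the four 4-token windows around each drug
  (D1_left, D1_right, D2_left, D2_right);
* **Cpn** — conjunctions of n-grams from the two areas adjacent to each drug
  with the discretized inter-drug distance.  Note the adjacency reading: the
  areas flanking drug1 are the left and inner areas, those flanking drug2 are
  the inner and right areas, which is what the worked-example feature strings
  (e.g. ``Plasma^are^5``) require;
* five extra features: a negative-word presence flag, the generic-mention
  (NameIsDrug) +/-1 pair, inner-area interaction keywords, the entities'
  semantic-type codes, and three binary DrugBank field-similarity flags
  (cosine of bag-of-word vectors thresholded at 0.4).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

log = logging.getLogger(__name__)

#: Distance bins partitioning the non-negative integers (label, lo, hi).
DISTANCE_BINS = (
    ("0", 0, 0), ("1", 1, 1), ("2", 2, 2), ("3", 3, 3), ("4", 4, 4),
    ("5", 5, 5), ("6~7", 6, 7), ("8~10", 8, 10), ("11~15", 11, 15),
    ("16~20", 16, 20), ("21~30", 21, 30), ("31~40", 31, 40),
    ("40~", 41, None),
)

SEMTYPE_WHITELIST = frozenset({"clnd", "phsu", "antb", "bacs", "chvs", "aapp"})

# stripped longest-first so "decreased" -> "decreas" matches "decrease" -> "decreas"
_SUFFIXES = ("ing", "ion", "ed", "es", "s", "d", "e")


@dataclass
class FeatureConfig:
    """Switches and thresholds of the feature-based kernel."""

    ngram_max: int = 3
    window: int = 4
    cosine_threshold: float = 0.4
    abon: bool = True
    san: bool = True
    cpn: bool = True
    negative_word: bool = True
    name_is_drug: bool = True
    keyword: bool = True
    semantic_type: bool = True
    drugbank: bool = True


def _load_lines(name):
    text = resources.files("ddikernels.data").joinpath(name).read_text("utf-8")
    seen, out = set(), []
    for line in text.splitlines():
        entry = line.strip().lower()
        if entry and entry not in seen:
            seen.add(entry)
            out.append(entry)
    return out


@dataclass
class Lexicons:
    """Negative-word and interaction-keyword lists (lower-cased, deduplicated)."""

    negative_words: list = field(default_factory=lambda: _load_lines("negative_words.txt"))
    keywords: list = field(default_factory=lambda: _load_lines("keywords.txt"))

    @classmethod
    def from_files(cls, negative_path=None, keyword_path=None):
        lex = cls()
        for attr, path in (("negative_words", negative_path),
                           ("keywords", keyword_path)):
            if path is not None:
                entries, seen = [], set()
                for line in Path(path).read_text("utf-8").splitlines():
                    e = line.strip().lower()
                    if e and e not in seen:
                        seen.add(e)
                        entries.append(e)
                setattr(lex, attr, entries)
        return lex


class DrugBankSnapshot:
    """Local drug -> {indication, pharmacology, description} -> word-bag lookup.

    Lookup is case-insensitive; unknown drugs map to empty bags.  Loaded from
    a JSON file mapping drug name -> field name -> free text.
    """

    FIELDS = ("indication", "pharmacology", "description")

    def __init__(self, mapping=None):
        self._bags = {}
        for name, fields in (mapping or {}).items():
            self._bags[name.lower()] = {
                f: frozenset(re.findall(r"[a-z]+", str(fields.get(f, "")).lower()))
                for f in self.FIELDS
            }

    @classmethod
    def from_json(cls, path):
        return cls(json.loads(Path(path).read_text("utf-8")))

    def bag(self, drug_name, field_name):
        return self._bags.get(drug_name.lower(), {}).get(field_name, frozenset())


@dataclass
class AreaSpans:
    """Inclusive token-index ranges; a range with start > end is empty."""

    left: tuple
    inner: tuple
    right: tuple
    d1_left: tuple
    d1_right: tuple
    d2_left: tuple
    d2_right: tuple

    @staticmethod
    def tokens(instance, span):
        a, b = span
        return instance.tokens[a:b + 1] if a <= b else []


def split_areas(instance, config: FeatureConfig = None) -> AreaSpans:
    """General areas split by drug1/drug2 plus the four surrounding windows."""
    w = (config or FeatureConfig()).window
    d1, d2, end = instance.d1, instance.d2, instance.end
    return AreaSpans(
        left=(0, d1 - 1),
        inner=(d1 + 1, d2 - 1),
        right=(d2 + 1, end),
        d1_left=(max(0, d1 - w), d1 - 1),
        d1_right=(d1 + 1, min(end, d1 + w)),
        d2_left=(max(0, d2 - w), d2 - 1),
        d2_right=(d2 + 1, min(end, d2 + w)),
    )


def discretize_distance(inner_count: int) -> str:
    """Map an inner token count to its distance bin label."""
    if inner_count < 0:
        raise ValueError(f"inner_count must be >= 0, got {inner_count}")
    for label, lo, hi in DISTANCE_BINS:
        if inner_count >= lo and (hi is None or inner_count <= hi):
            return label
    raise AssertionError("distance bins do not cover %d" % inner_count)


def _ngrams(tokens, nmax):
    for n in range(1, nmax + 1):
        for i in range(len(tokens) - n + 1):
            yield " ".join(tokens[i:i + n])


def abon_features(instance, config: FeatureConfig = None) -> dict:
    """Bag-of-n-grams per general area, e.g. ``left_area=Plasma concentrations``."""
    config = config or FeatureConfig()
    areas = split_areas(instance, config)
    feats = {}
    for name, span in (("left_area", areas.left), ("inner_area", areas.inner),
                       ("right_area", areas.right)):
        for gram in _ngrams(AreaSpans.tokens(instance, span), config.ngram_max):
            feats[f"{name}={gram}"] = 1.0
    return feats


def san_features(instance, config: FeatureConfig = None) -> dict:
    """n-grams from the four 4-token windows, e.g. ``D1_right=are decreased``."""
    config = config or FeatureConfig()
    areas = split_areas(instance, config)
    feats = {}
    for name, span in (("D1_left", areas.d1_left), ("D1_right", areas.d1_right),
                       ("D2_left", areas.d2_left), ("D2_right", areas.d2_right)):
        for gram in _ngrams(AreaSpans.tokens(instance, span), config.ngram_max):
            feats[f"{name}={gram}"] = 1.0
    return feats


def cpn_features(instance, config: FeatureConfig = None) -> dict:
    """Conjunct-position n-grams over the areas adjacent to each drug.

    For each direction combination, same-length n-grams from the drug1-side
    area and the drug2-side area are conjoined with the discretized distance,
    e.g. ``D1_left^D2_left^distance=Plasma^are^5``.
    """
    config = config or FeatureConfig()
    areas = split_areas(instance, config)
    inner_tokens = AreaSpans.tokens(instance, areas.inner)
    dist = discretize_distance(len(inner_tokens))
    sides1 = (("D1_left", AreaSpans.tokens(instance, areas.left)),
              ("D1_right", inner_tokens))
    sides2 = (("D2_left", inner_tokens),
              ("D2_right", AreaSpans.tokens(instance, areas.right)))
    feats = {}
    for n in range(1, config.ngram_max + 1):
        for name1, toks1 in sides1:
            grams1 = [" ".join(toks1[i:i + n])
                      for i in range(len(toks1) - n + 1)]
            for name2, toks2 in sides2:
                grams2 = [" ".join(toks2[i:i + n])
                          for i in range(len(toks2) - n + 1)]
                for g1 in grams1:
                    for g2 in grams2:
                        feats[f"{name1}^{name2}^distance={g1}^{g2}^{dist}"] = 1.0
    return feats


def negative_word_feature(instance, lexicons: Lexicons = None) -> float:
    """1 if any negative word/phrase occurs anywhere in the instance, else 0.

    Entries match whole lower-cased tokens; multi-word entries must match
    consecutive tokens.
    """
    lexicons = lexicons or Lexicons()
    low = [t.lower() for t in instance.tokens]
    for entry in lexicons.negative_words:
        parts = entry.split()
        n = len(parts)
        for i in range(len(low) - n + 1):
            if low[i:i + n] == parts:
                return 1.0
    return 0.0


def name_is_drug_feature(instance) -> tuple:
    """(+1/-1, +1/-1): +1 marks a generic 'drug'/'drugs' mention, -1 a name."""
    return (1.0 if instance.e1.is_generic else -1.0,
            1.0 if instance.e2.is_generic else -1.0)


def _stem(word):
    word = word.lower()
    for suf in _SUFFIXES:
        if word.endswith(suf) and len(word) - len(suf) >= 3:
            return word[:-len(suf)]
    return word


def keyword_feature(instance, lexicons: Lexicons = None) -> dict:
    """Binary feature per keyword whose variant matches an inner-area token.

    Matching is lower-cased surface (or lemma) plus a light suffix-stripping
    variant match, so "decreased" matches the lexicon entry "decrease".
    Keywords are searched only between the two drugs.
    """
    lexicons = lexicons or Lexicons()
    if not lexicons.keywords:
        log.warning("empty keyword lexicon")
        return {}
    a, b = instance.d1 + 1, instance.d2 - 1
    forms = set()
    for i in range(a, b + 1):
        forms.add(instance.tokens[i].lower())
        forms.add(_stem(instance.tokens[i]))
        if instance.lemmas and instance.lemmas[i]:
            forms.add(instance.lemmas[i].lower())
            forms.add(_stem(instance.lemmas[i]))
    feats = {}
    for entry in lexicons.keywords:
        if entry in forms or _stem(entry) in forms:
            feats[f"keyword={entry}"] = 1.0
    return feats


def semantic_type_feature(instance) -> dict:
    """Categorical features for the sorted, comma-joined type codes of each entity."""
    feats = {}
    for name, idx in (("semtype1", instance.d1), ("semtype2", instance.d2)):
        codes = instance.semtypes[idx]
        if codes:
            feats[f"{name}={','.join(sorted(codes))}"] = 1.0
    return feats


def cosine_bag_similarity(bag1, bag2) -> float:
    """Cosine of binary word vectors: |intersection| / sqrt(|b1| |b2|)."""
    if not bag1 or not bag2:
        return 0.0
    return len(bag1 & bag2) / math.sqrt(len(bag1) * len(bag2))


def drugbank_feature(e1_surface, e2_surface, field_name,
                     snapshot: DrugBankSnapshot, threshold: float = 0.4) -> float:
    """1 if the cosine similarity of the two drugs' field word-bags >= threshold."""
    sim = cosine_bag_similarity(snapshot.bag(e1_surface, field_name),
                                snapshot.bag(e2_surface, field_name))
    return 1.0 if sim >= threshold else 0.0


def assemble_vector(instance, config: FeatureConfig = None,
                    lexicons: Lexicons = None,
                    snapshot: DrugBankSnapshot = None) -> dict:
    """Union of all enabled feature families with namespaced, deterministic names."""
    config = config or FeatureConfig()
    lexicons = lexicons or Lexicons()
    feats = {}
    if config.abon:
        feats.update(abon_features(instance, config))
    if config.san:
        feats.update(san_features(instance, config))
    if config.cpn:
        feats.update(cpn_features(instance, config))
    if config.negative_word:
        feats["negative_word"] = negative_word_feature(instance, lexicons)
    if config.name_is_drug:
        v1, v2 = name_is_drug_feature(instance)
        feats["nameisdrug_entity1"] = v1
        feats["nameisdrug_entity2"] = v2
    if config.keyword:
        feats.update(keyword_feature(instance, lexicons))
    if config.semantic_type:
        feats.update(semantic_type_feature(instance))
    if config.drugbank and snapshot is not None:
        for fname in DrugBankSnapshot.FIELDS:
            feats[f"drugbank_{fname}"] = drugbank_feature(
                instance.e1.surface, instance.e2.surface, fname, snapshot,
                config.cosine_threshold)
    return feats


def dump_libsvm(vectors, labels, path):
    """Sparse libSVM-style text export (+1/-1 labels, 1-based feature ids)."""
    vocab = {}
    for vec in vectors:
        for name in vec:
            vocab.setdefault(name, len(vocab) + 1)
    with open(path, "w", encoding="utf-8") as fh:
        for vec, label in zip(vectors, labels):
            y = "+1" if label == "positive" else "-1"
            cols = sorted((vocab[n], v) for n, v in vec.items())
            fh.write(y + " " + " ".join(f"{i}:{v:g}" for i, v in cols) + "\n")
    return vocab
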