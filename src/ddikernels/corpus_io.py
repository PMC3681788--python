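"""Read/write annotated DDI corpora and build blinded candidate instances.

Corpus dialect (the normative fixture schema, loosely following the unified
XML of the DDI-extraction shared tasks)::

    <corpus id="...">
      <document id="d0">
        <sentence id="d0.s0" text="Plasma concentrations of Foo ...">
          <entity id="d0.s0.e0" charOffset="25-27" text="Foo"/>
          <pair id="d0.s0.p0" e1="d0.s0.e0" e2="d0.s0.e1" interaction="true"/>
          <semtypes tokens="3:carb,phsu 9:gngm"/>   <!-- optional -->
        </sentence>
      </document>
    </corpus>

Sentences are whitespace-tokenized from ``text``; entity ``charOffset`` is an
inclusive character range mapped onto the tokens it overlaps.  Dependency
parses are supplied separately as CoNLL-X files (one block per sentence, in
corpus order), constituency parses as Penn-bracketed trees, one per line (an
empty line marks a missing parse).
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path

from lxml import etree

from .tree_kernel import parse_penn
from .types import (
    UNKNOWN,
    CandidateInstance,
    EntityMention,
    SentenceRecord,
    Token,
)

log = logging.getLogger(__name__)


class CorpusError(ValueError):
    """Malformed or inconsistent corpus input."""


def _token_char_ranges(text):
    """Inclusive character range of each whitespace token of ``text``."""
    ranges, pos = [], 0
    for tok in text.split():
        start = text.index(tok, pos)
        ranges.append((start, start + len(tok) - 1))
        pos = start + len(tok)
    return ranges


def _parse_semtypes(attr):
    """Parse ``"3:carb,phsu 9:gngm"`` into {token index: frozenset of codes}."""
    out = {}
    for chunk in attr.split():
        idx, _, codes = chunk.partition(":")
        out[int(idx)] = frozenset(c for c in codes.split(",") if c)
    return out


def read_unified_xml(path) -> list:
    """Read a corpus file into :class:`SentenceRecord` objects."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc

    records = []
    for doc in tree.getroot().iter("document"):
        doc_id = doc.get("id", "")
        for sent in doc.iter("sentence"):
            sent_id = sent.get("id", "")
            text = sent.get("text", "")
            ranges = _token_char_ranges(text)
            semtypes = {}
            st_el = sent.find("semtypes")
            if st_el is not None and st_el.get("tokens"):
                semtypes = _parse_semtypes(st_el.get("tokens"))
            tokens = [
                Token(i, text[a:b + 1], semtypes=semtypes.get(i, frozenset()))
                for i, (a, b) in enumerate(ranges)
            ]
            entities = []
            for ent in sent.findall("entity"):
                off = ent.get("charOffset", "")
                try:
                    a, b = (int(x) for x in off.split("-"))
                except ValueError as exc:
                    raise CorpusError(
                        f"sentence {sent_id}: bad charOffset {off!r}") from exc
                covered = [i for i, (ta, tb) in enumerate(ranges)
                           if not (tb < a or ta > b)]
                if not covered or b > ranges[-1][1]:
                    raise CorpusError(
                        f"sentence {sent_id}: entity {ent.get('id')} offset "
                        f"{off} outside sentence")
                entities.append(EntityMention(
                    ent.get("id"), (covered[0], covered[-1]),
                    ent.get("text", text[a:b + 1])))
            ent_ids = {e.id for e in entities}
            gold_pairs = []
            for pair in sent.findall("pair"):
                e1, e2 = pair.get("e1"), pair.get("e2")
                if e1 not in ent_ids or e2 not in ent_ids:
                    raise CorpusError(
                        f"sentence {sent_id}: pair {pair.get('id')} references "
                        f"undeclared entity")
                label = ("positive" if pair.get("interaction") == "true"
                         else "negative")
                gold_pairs.append((e1, e2, label))
            records.append(SentenceRecord(
                doc_id, sent_id, tokens, entities, gold_pairs=gold_pairs))
    return records


def write_unified_xml(records, path):
    """Write records in the corpus dialect (inverse of :func:`read_unified_xml`)."""
    root = etree.Element("corpus", id="ddikernels")
    by_doc = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec)
    for doc_id, recs in by_doc.items():
        doc_el = etree.SubElement(root, "document", id=doc_id)
        for rec in recs:
            text = rec.text
            ranges = _token_char_ranges(text)
            sent_el = etree.SubElement(doc_el, "sentence", id=rec.sent_id,
                                       text=text)
            for ent in rec.entities:
                a = ranges[ent.start][0]
                b = ranges[ent.end][1]
                etree.SubElement(sent_el, "entity", id=ent.id,
                                 charOffset=f"{a}-{b}", text=ent.surface)
            for i, (e1, e2, label) in enumerate(rec.gold_pairs):
                etree.SubElement(
                    sent_el, "pair", id=f"{rec.sent_id}.p{i}", e1=e1, e2=e2,
                    interaction="true" if label == "positive" else "false")
            st = " ".join(
                f"{t.index}:{','.join(sorted(t.semtypes))}"
                for t in rec.tokens if t.semtypes)
            if st:
                etree.SubElement(sent_el, "semtypes", tokens=st)
    Path(path).write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True,
                       encoding="UTF-8"))


def read_conll(path):
    """Read a CoNLL-X file into per-sentence lists of row dicts."""
    sentences, rows = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.rstrip()
        if not line:
            if rows:
                sentences.append(rows)
                rows = []
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise CorpusError(f"CoNLL row with {len(cols)} columns: {line!r}")
        rows.append({
            "id": int(cols[0]), "form": cols[1],
            "lemma": None if cols[2] == "_" else cols[2],
            "pos": None if cols[4] == "_" else cols[4],
            "head": int(cols[6]), "deprel": cols[7],
        })
    if rows:
        sentences.append(rows)
    return sentences


def write_conll(records, path):
    blocks = []
    for rec in records:
        heads = {}
        for h, d, rel in rec.dep_edges:
            heads[d] = (h + 1, rel)
        lines = []
        for t in rec.tokens:
            head, rel = heads.get(t.index, (0, "root"))
            lines.append("\t".join([
                str(t.index + 1), t.surface, t.lemma or "_", "_",
                t.pos or "_", "_", str(head), rel, "_", "_",
            ]))
        blocks.append("\n".join(lines))
    Path(path).write_text("\n\n".join(blocks) + "\n", encoding="utf-8")


def write_trees(records, path):
    lines = []
    for rec in records:
        lines.append(rec.const_tree.to_penn() if rec.const_tree is not None
                     else "")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def attach_parses(records, conll_path=None, trees_path=None):
    """Attach dependency (CoNLL-X) and constituency (Penn) parses in corpus order.

    Token counts must agree sentence by sentence; a blank tree line flags the
    record as tree-absent (``const_tree is None``) without failing.
    """
    if conll_path is not None:
        blocks = read_conll(conll_path)
        if len(blocks) != len(records):
            raise CorpusError(
                f"CoNLL file has {len(blocks)} sentences, corpus has "
                f"{len(records)}")
        for rec, rows in zip(records, blocks):
            if len(rows) != len(rec.tokens):
                raise CorpusError(
                    f"sentence {rec.sent_id}: {len(rows)} CoNLL rows vs "
                    f"{len(rec.tokens)} corpus tokens")
            edges = []
            for row, tok in zip(rows, rec.tokens):
                if row["form"] != tok.surface:
                    raise CorpusError(
                        f"sentence {rec.sent_id}: token mismatch "
                        f"{row['form']!r} vs {tok.surface!r}")
                tok.lemma = row["lemma"]
                tok.pos = row["pos"]
                if row["head"] > 0:
                    edges.append((row["head"] - 1, row["id"] - 1,
                                  row["deprel"]))
            for h, d, _ in edges:
                if not (0 <= h < len(rec.tokens)):
                    raise CorpusError(
                        f"sentence {rec.sent_id}: head index {h} out of range")
            rec.dep_edges = edges
    if trees_path is not None:
        lines = Path(trees_path).read_text(encoding="utf-8").splitlines()
        if len(lines) != len(records):
            raise CorpusError(
                f"tree file has {len(lines)} lines, corpus has {len(records)}")
        for rec, line in zip(records, lines):
            if not line.strip():
                rec.const_tree = None
                continue
            tree = parse_penn(line)
            leaves = [l.label for l in tree.leaves()]
            if leaves != [t.surface for t in rec.tokens]:
                raise CorpusError(
                    f"sentence {rec.sent_id}: tree leaves do not match tokens")
            rec.const_tree = tree
    return records


def _overlapping(entities):
    """Ids of entities whose spans overlap another entity's span."""
    bad = set()
    for a, b in itertools.combinations(entities, 2):
        if not (a.end < b.start or b.end < a.start):
            bad.add(a.id)
            bad.add(b.id)
    return bad


def generate_instances(record: SentenceRecord) -> list:
    """Blind every unordered entity pair of a sentence into a candidate instance.

    The textually earlier entity becomes ``drug1``; every mention span
    collapses to a single blinded token (other candidate drugs -> ``drug0``).
    Dependency edges and token annotations are remapped onto the blinded
    indices.  Pairs involving overlapping entity mentions are skipped with a
    warning.
    """
    ents = sorted(record.entities, key=lambda e: (e.start, e.end))
    bad = _overlapping(ents)
    instances = []
    for a, b in itertools.combinations(ents, 2):
        if a.id in bad or b.id in bad:
            log.warning("sentence %s: skipping pair (%s, %s) with "
                        "overlapping entity spans", record.sent_id, a.id, b.id)
            continue
        good_ents = [e for e in ents if e.id not in bad]
        spans = {e.id: e.token_span for e in good_ents}
        blind = {a.id: "drug1", b.id: "drug2"}
        # map original token index -> (new index, blinded surface or None)
        tokens, lemmas, pos, semtypes = [], [], [], []
        mapping = {}
        i = 0
        while i < len(record.tokens):
            owner = next((e for e in good_ents
                          if spans[e.id][0] == i), None)
            if owner is not None:
                start, end = spans[owner.id]
                surface = blind.get(owner.id, "drug0")
                # non-candidate drugs keep tokenizer residue (e.g. "CandD."
                # -> "drug0.") when the mention is a proper prefix of its
                # single token; drug1/drug2 stay bare by contract
                tok_surface = record.tokens[start].surface
                if (owner.id not in blind and start == end
                        and tok_surface != owner.surface
                        and tok_surface.startswith(owner.surface)):
                    surface += tok_surface[len(owner.surface):]
                new_idx = len(tokens)
                for j in range(start, end + 1):
                    mapping[j] = new_idx
                tokens.append(surface)
                lemmas.append(surface)
                pos.append(record.tokens[start].pos or "NN")
                st = frozenset().union(
                    *(record.tokens[j].semtypes for j in range(start, end + 1)))
                semtypes.append(st)
                i = end + 1
            else:
                t = record.tokens[i]
                mapping[i] = len(tokens)
                tokens.append(t.surface)
                lemmas.append(t.lemma_or_surface)
                pos.append(t.pos)
                semtypes.append(t.semtypes)
                i += 1
        new_edges, seen = [], set()
        for h, d, rel in record.dep_edges:
            nh, nd = mapping[h], mapping[d]
            if nh == nd or (nh, nd, rel) in seen:
                continue
            seen.add((nh, nd, rel))
            new_edges.append((nh, nd, rel))
        d1 = mapping[a.start]
        d2 = mapping[b.start]
        instances.append(CandidateInstance(
            pair_id=f"{record.sent_id}.{a.id}-{b.id}",
            tokens=tokens, d1=d1, d2=d2, end=len(tokens) - 1,
            label=record.pair_label(a.id, b.id),
            e1=a, e2=b, lemmas=lemmas, pos=pos, semtypes=semtypes,
            dep_edges=new_edges, const_tree=record.const_tree,
            e1_leaf=a.start, e2_leaf=b.start, sentence_ref=record))
    return instances


def load_corpus(xml_path, conll_path=None, trees_path=None):
    """Read a corpus plus parses and return all candidate instances."""
    records = read_unified_xml(xml_path)
    attach_parses(records, conll_path, trees_path)
    instances = []
    for rec in records:
        if len(rec.entities) >= 2:
            instances.extend(generate_instances(rec))
    return records, instances


def dump_instances_jsonl(instances, path):
    """JSON-lines export of instances (tokens, indices, label)."""
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(json.dumps({
                "pair_id": inst.pair_id, "tokens": inst.tokens,
                "d1": inst.d1, "d2": inst.d2, "label": inst.label,
            }) + "\n")
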