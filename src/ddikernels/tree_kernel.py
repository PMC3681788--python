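"""Convolution (Collins-Duffy) tree kernel over constituency structures.

Two tree views of a candidate pair are scored:

* the shortest-path-enclosed tree (SPT): the smallest constituency subtree
  covering both entity leaves, expanded one level at a time while it has
  fewer than ``min_spt_leaves`` leaves;
* a flat "dependency path tree": the drug1->drug2 dependency path re-encoded
  as ``(DEPENDENCY (REL (head dependent)) ...)`` so the tree kernel can match
  path subsequences, extended with two extra edges when the path is shorter
  than ``min_path_len``.

The kernel counts common subtree fragments: a fragment is rooted at any node
and, at every included node, keeps either none or all of that node's
children.  Each fragment is discounted by ``lambda_decay`` per production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

log = logging.getLogger(__name__)


class TreeNode:
    """A constituency-tree node.

    Leaves have no children and their ``label`` is the word surface.
    A preterminal has exactly one leaf child (a POS tag over a word).
    """

    __slots__ = ("label", "children", "parent")

    def __init__(self, label, children=None):
        self.label = label
        self.children = list(children) if children else []
        self.parent = None
        for c in self.children:
            c.parent = self

    @property
    def is_leaf(self):
        return not self.children

    @property
    def is_preterminal(self):
        return len(self.children) == 1 and self.children[0].is_leaf

    @property
    def production(self):
        """(label, child labels) — for preterminals this includes the word."""
        return (self.label, tuple(c.label for c in self.children))

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def subtree_nodes(self):
        """All internal (non-leaf) nodes, preorder."""
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if not n.is_leaf:
                out.append(n)
                stack.extend(reversed(n.children))
        return out

    def copy(self):
        return TreeNode(self.label, [c.copy() for c in self.children])

    def to_penn(self):
        if self.is_leaf:
            return self.label
        inner = " ".join(c.to_penn() for c in self.children)
        return f"({self.label} {inner})"

    def __repr__(self):
        return f"TreeNode({self.to_penn()!r})"


def parse_penn(text: str) -> TreeNode:
    """Parse one Penn-bracketed tree string, e.g. ``(NP (DT the) (NN drug))``."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    if not tokens:
        raise ValueError("empty tree string")
    pos = 0

    def parse_node():
        nonlocal pos
        if tokens[pos] != "(":
            # bare leaf
            leaf = TreeNode(tokens[pos])
            pos += 1
            return leaf
        pos += 1  # "("
        if pos >= len(tokens) or tokens[pos] in "()":
            raise ValueError(f"malformed tree near position {pos}: {text!r}")
        node = TreeNode(tokens[pos])
        pos += 1
        children = []
        while pos < len(tokens) and tokens[pos] != ")":
            children.append(parse_node())
        if pos >= len(tokens):
            raise ValueError(f"unbalanced brackets in {text!r}")
        pos += 1  # ")"
        for c in children:
            c.parent = node
        node.children = children
        return node

    root = parse_node()
    if pos != len(tokens):
        raise ValueError(f"trailing material after tree in {text!r}")
    return root


@dataclass
class TreeKernelConfig:
    """Tunables of the tree kernel.

    ``lambda_decay`` is the per-production decay of the fragment count
    (1.0 = raw common-fragment count); ``min_spt_leaves`` and
    ``min_path_len`` trigger the SPT / dependency-path extensions.
    """

    lambda_decay: float = 0.4
    min_spt_leaves: int = 4
    min_path_len: int = 3
    single_step_expansion: bool = False

    def __post_init__(self):
        if not 0 < self.lambda_decay <= 1:
            raise ValueError("lambda_decay must be in (0, 1]")
        if self.min_spt_leaves < 1 or self.min_path_len < 1:
            raise ValueError("thresholds must be positive")


def cd_kernel(t1: TreeNode, t2: TreeNode, lam: float = 0.4) -> float:
    """Collins-Duffy convolution kernel: discounted count of common fragments.

    K(T1,T2) = sum over node pairs of C(n1,n2), where C is 0 for differing
    productions, ``lam`` for matching preterminals, and otherwise
    ``lam * prod_i (1 + C(ch(n1,i), ch(n2,i)))``.
    """
    n1s = t1.subtree_nodes()
    n2s = t2.subtree_nodes()
    # group by production so only matching pairs are visited
    by_prod = {}
    for n in n2s:
        by_prod.setdefault(n.production, []).append(n)

    memo = {}

    def C(a, b):
        key = (id(a), id(b))
        if key in memo:
            return memo[key]
        if a.production != b.production:
            val = 0.0
        elif a.is_preterminal:
            val = lam
        else:
            val = lam
            for ca, cb in zip(a.children, b.children):
                if ca.is_leaf:  # identical labels guaranteed by production match
                    continue
                val *= 1.0 + C(ca, cb)
        memo[key] = val
        return val

    total = 0.0
    for a in n1s:
        for b in by_prod.get(a.production, ()):
            total += C(a, b)
    return total


def normalized_cd_kernel(t1, t2, lam: float = 0.4) -> float:
    """Cosine-normalized kernel: K(a,b)/sqrt(K(a,a) K(b,b)); 0 if either self-kernel is 0."""
    k11 = cd_kernel(t1, t1, lam)
    k22 = cd_kernel(t2, t2, lam)
    if k11 <= 0 or k22 <= 0:
        return 0.0
    return cd_kernel(t1, t2, lam) / (k11 * k22) ** 0.5


def _leaf_span(node, leaf_index):
    """Map id(node) -> (first leaf pos, last leaf pos) for every internal node."""
    spans = {}

    def walk(n):
        if n.is_leaf:
            i = leaf_index[id(n)]
            return (i, i)
        lo, hi = None, None
        for c in n.children:
            clo, chi = walk(c)
            lo = clo if lo is None else min(lo, clo)
            hi = chi if hi is None else max(hi, chi)
        spans[id(n)] = (lo, hi)
        return (lo, hi)

    walk(node)
    return spans


def _prune_to_span(node, lo, hi, spans):
    """Copy of ``node`` keeping only children whose leaf span intersects [lo, hi]."""
    if node.is_leaf:
        return TreeNode(node.label)
    kept = []
    for c in node.children:
        if c.is_leaf:
            kept.append(TreeNode(c.label))
            continue
        clo, chi = spans[id(c)]
        if chi < lo or clo > hi:
            continue
        kept.append(_prune_to_span(c, lo, hi, spans))
    return TreeNode(node.label, kept)


def extract_spt(tree: TreeNode, e1_leaf: int, e2_leaf: int,
                config: TreeKernelConfig = None) -> TreeNode:
    """Shortest-path-enclosed tree around two entity leaves (by leaf position).

    The lowest common ancestor of the leaves is found, its subtree is pruned
    to the inter-entity leaf span, and while the result has fewer than
    ``min_spt_leaves`` leaves and a parent exists, the (unpruned) subtree one
    level up replaces it.
    """
    config = config or TreeKernelConfig()
    leaves = tree.leaves()
    if not (0 <= e1_leaf < len(leaves)) or not (0 <= e2_leaf < len(leaves)):
        raise LookupError(
            f"entity leaf index out of range: {e1_leaf}, {e2_leaf} "
            f"(tree has {len(leaves)} leaves)"
        )
    lo, hi = min(e1_leaf, e2_leaf), max(e1_leaf, e2_leaf)
    leaf_index = {id(l): i for i, l in enumerate(leaves)}
    spans = _leaf_span(tree, leaf_index)

    # deepest node covering both leaves
    node = leaves[lo].parent
    while node is not None:
        nlo, nhi = spans[id(node)]
        if nlo <= lo and nhi >= hi:
            break
        node = node.parent
    if node is None:
        node = tree

    spt = _prune_to_span(node, lo, hi, spans)
    while len(spt.leaves()) < config.min_spt_leaves and node.parent is not None:
        node = node.parent
        spt = node.copy()
        if config.single_step_expansion:
            break
    return spt


def dep_path_tree(dep_edges, d1: int, d2: int, tokens,
                  config: TreeKernelConfig = None) -> TreeNode:
    """Flat tree encoding of the drug1->drug2 dependency path.

    Each path edge becomes a child of the DEPENDENCY root, labeled with its
    (upper-cased) relation and dominating ``(head dependent)`` word forms,
    e.g. ``(DEPENDENCY (NSUBJ (interacts drug1)) (PREP (interacts with))
    (POBJ (with drug2)))``.  Paths shorter than ``min_path_len`` edges are
    extended with two extra edges taken from the left of drug1 when at least
    two are available there, otherwise from the right of drug2.  A pair that
    is disconnected in the dependency graph yields an empty-path marker tree.
    """
    config = config or TreeKernelConfig()
    g = nx.Graph()
    g.add_nodes_from(range(len(tokens)))
    edge_rel = {}
    for h, d, rel in dep_edges:
        g.add_edge(h, d)
        edge_rel[frozenset((h, d))] = (h, d, rel)

    if not nx.has_path(g, d1, d2):
        log.warning("drug pair %d-%d disconnected in dependency graph", d1, d2)
        return TreeNode("DEPENDENCY", [TreeNode("NOPATH", [TreeNode("empty")])])

    path = nx.shortest_path(g, d1, d2)
    path_edges = []
    on_path = set()
    for a, b in zip(path, path[1:]):
        h, d, rel = edge_rel[frozenset((a, b))]
        path_edges.append((h, d, rel))
        on_path.add(frozenset((a, b)))

    def edge_node(h, d, rel):
        return TreeNode(rel.upper(), [TreeNode(tokens[h], [TreeNode(tokens[d])])])

    children = [edge_node(h, d, rel) for h, d, rel in path_edges]

    if len(path_edges) < config.min_path_len:
        left = [(h, d, rel) for h, d, rel in dep_edges
                if frozenset((h, d)) not in on_path and max(h, d) <= d1]
        right = [(h, d, rel) for h, d, rel in dep_edges
                 if frozenset((h, d)) not in on_path and min(h, d) >= d2]
        extra = []
        if len(left) >= 2:
            # the two edges nearest drug1
            left.sort(key=lambda e: -max(e[0], e[1]))
            extra = left[:2]
        elif len(right) >= 2:
            right.sort(key=lambda e: min(e[0], e[1]))
            extra = right[:2]
        for h, d, rel in sorted(extra, key=lambda e: min(e[0], e[1])):
            children.append(edge_node(h, d, rel))

    return TreeNode("DEPENDENCY", children)


def instance_trees(instance, config: TreeKernelConfig = None):
    """(SPT, dependency-path tree) for one candidate instance; either may be None."""
    config = config or TreeKernelConfig()
    spt = None
    if instance.const_tree is not None and instance.e1_leaf is not None:
        spt = extract_spt(instance.const_tree, instance.e1_leaf,
                          instance.e2_leaf, config)
    dpt = None
    if instance.dep_edges:
        dpt = dep_path_tree(instance.dep_edges, instance.d1, instance.d2,
                            instance.tokens, config)
    return spt, dpt


def tree_kernel_score(inst1, inst2, config: TreeKernelConfig = None) -> float:
    """Similarity of two instances: sum of the normalized kernels of the two
    tree views (SPT pair + dependency-path pair); a missing view contributes 0."""
    config = config or TreeKernelConfig()
    spt1, dpt1 = instance_trees(inst1, config)
    spt2, dpt2 = instance_trees(inst2, config)
    score = 0.0
    if spt1 is not None and spt2 is not None:
        score += normalized_cd_kernel(spt1, spt2, config.lambda_decay)
    if dpt1 is not None and dpt2 is not None:
        score += normalized_cd_kernel(dpt1, dpt2, config.lambda_decay)
    return score
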