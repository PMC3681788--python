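"""All-paths graph kernel over a dependency + linear-order graph pair.

Each candidate instance becomes one labeled, weighted graph with two
disconnected components:

* a **parse component** with a word vertex per token (labels: lemma, POS) and
  a link vertex per dependency edge (label: relation), wired
  head -> link -> dependent.  Vertices and link vertices on the undirected
  shortest dependency path between the two drugs carry additional
  ``*_IP`` labels, and the path's edges get weight ``sp_weight`` (0.9) while
  every other edge gets ``other_weight`` (0.3);
* a **linear component** with one vertex per token whose labels are
  position-tagged lemma and POS — (B)efore / (M)iddle / (A)fter relative to
  the pair — chained left to right with weight ``other_weight``.

Summing the weights of all walks between every vertex pair (the Neumann
series G = sum_{k>=1} A^k) gives a relation-strength matrix; the kernel of
two instances is the sum over common label pairs of the products of their
relation strengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)


@dataclass
class GraphConfig:
    """Edge weights and series truncation for the all-paths kernel."""

    sp_weight: float = 0.9
    other_weight: float = 0.3
    max_series_terms: int = 200

    def __post_init__(self):
        for w in (self.sp_weight, self.other_weight):
            if not 0 < w < 1:
                raise ValueError("edge weights must lie in (0, 1)")


@dataclass
class LabeledGraph:
    """Vertices with label sets plus a non-negative weighted adjacency matrix."""

    labels: list  # per-vertex frozenset of label strings
    adjacency: np.ndarray
    names: list = None  # optional per-vertex debug names

    def __post_init__(self):
        n = len(self.labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match vertex count")
        if (self.adjacency < 0).any():
            raise ValueError("adjacency must be non-negative")

    @property
    def n(self):
        return len(self.labels)

    def to_node_link(self):
        """JSON-serializable node-link dump for debugging."""
        nodes = [{"id": i, "labels": sorted(l), "name": (self.names or [None] * self.n)[i]}
                 for i, l in enumerate(self.labels)]
        rows, cols = np.nonzero(self.adjacency)
        edges = [{"source": int(i), "target": int(j),
                  "weight": float(self.adjacency[i, j])}
                 for i, j in zip(rows, cols)]
        return {"nodes": nodes, "edges": edges}


def build_graph_representation(instance, config: GraphConfig = None) -> LabeledGraph:
    """Build the combined (block-diagonal) parse + linear-order graph."""
    config = config or GraphConfig()
    tokens = instance.tokens
    lemmas = instance.lemmas
    pos = instance.pos
    n_tok = len(tokens)

    skeleton = nx.Graph()
    skeleton.add_nodes_from(range(n_tok))
    for h, d, _ in instance.dep_edges:
        skeleton.add_edge(h, d)
    path_tokens: set = set()
    path_edges: set = set()
    if instance.dep_edges and nx.has_path(skeleton, instance.d1, instance.d2):
        path = nx.shortest_path(skeleton, instance.d1, instance.d2)
        path_tokens = set(path)
        path_edges = {frozenset(e) for e in zip(path, path[1:])}
    elif instance.dep_edges:
        log.warning("instance %s: drugs disconnected in dependency graph; "
                    "no shortest-path specialization", instance.pair_id)

    labels, names = [], []

    def add_vertex(base_labels, name, on_path=False):
        ls = set(base_labels)
        if on_path:
            ls |= {f"{l}_IP" for l in base_labels}
        labels.append(frozenset(ls))
        names.append(name)
        return len(labels) - 1

    # parse component: word vertices
    word_vertex = {}
    for i in range(n_tok):
        base = {lemmas[i]}
        if pos[i]:
            base.add(pos[i])
        word_vertex[i] = add_vertex(base, f"w{i}:{tokens[i]}",
                                    on_path=i in path_tokens)
    # link vertices, one per dependency edge
    edges = []  # (src vertex, dst vertex, weight)
    for h, d, rel in instance.dep_edges:
        on_path = frozenset((h, d)) in path_edges
        lv = add_vertex({rel}, f"link:{rel}", on_path=on_path)
        w = config.sp_weight if on_path else config.other_weight
        edges.append((word_vertex[h], lv, w))
        edges.append((lv, word_vertex[d], w))

    # linear component
    for i in range(n_tok):
        if i == instance.d1:
            base = {"drug1"}
        elif i == instance.d2:
            base = {"drug2"}
        else:
            tag = "B" if i < instance.d1 else ("M" if i < instance.d2 else "A")
            base = {f"{lemmas[i]}_{tag}"}
            if pos[i]:
                base.add(f"{pos[i]}_{tag}")
        v = add_vertex(base, f"lin{i}:{tokens[i]}")
        if i > 0:
            edges.append((v - 1, v, config.other_weight))

    adj = np.zeros((len(labels), len(labels)))
    for s, t, w in edges:
        adj[s, t] = w
    return LabeledGraph(labels=labels, adjacency=adj, names=names)


def neumann_graph_matrix(A: np.ndarray, max_terms: int = None) -> np.ndarray:
    """All-walk weight matrix G = sum_{k>=1} A^k = (I - A)^{-1} - I.

    Requires spectral radius of A strictly below 1; otherwise the series
    diverges and a ValueError advises reducing the edge weights.
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n == 0:
        return A.copy()
    rho = max(abs(np.linalg.eigvals(A)))
    if rho >= 1 - 1e-12:
        raise ValueError(
            f"Neumann series diverges: spectral radius {rho:.4f} >= 1; "
            "reduce the edge weights")
    return np.linalg.solve(np.eye(n) - A, A)


def truncated_series_matrix(A: np.ndarray, terms: int = 200) -> np.ndarray:
    """Direct evaluation of sum_{k=1..terms} A^k (verification path)."""
    A = np.asarray(A, dtype=float)
    G = np.zeros_like(A)
    P = np.eye(A.shape[0])
    for _ in range(terms):
        P = P @ A
        G += P
    return G


def _label_projection(graph: LabeledGraph, G: np.ndarray, vocab: dict) -> np.ndarray:
    """R[a, b] = sum of G[i, j] over vertices i with label a and j with label b."""
    L = np.zeros((len(vocab), graph.n))
    for j, ls in enumerate(graph.labels):
        for l in ls:
            if l in vocab:
                L[vocab[l], j] = 1.0
    return L @ G @ L.T


def graph_kernel_value(g1: LabeledGraph, g2: LabeledGraph,
                       G1: np.ndarray = None, G2: np.ndarray = None) -> float:
    """Sum over common label pairs of the products of relation weights."""
    if G1 is None:
        G1 = neumann_graph_matrix(g1.adjacency)
    if G2 is None:
        G2 = neumann_graph_matrix(g2.adjacency)
    shared = sorted(frozenset().union(*g1.labels, frozenset())
                    & frozenset().union(*g2.labels, frozenset()))
    if not shared:
        return 0.0
    vocab = {l: i for i, l in enumerate(shared)}
    R1 = _label_projection(g1, G1, vocab)
    R2 = _label_projection(g2, G2, vocab)
    return float((R1 * R2).sum())


def graph_gram_matrix(instances, config: GraphConfig = None) -> np.ndarray:
    """Symmetric Gram matrix of the all-paths kernel over instances."""
    config = config or GraphConfig()
    graphs, Gs = [], []
    for inst in instances:
        try:
            g = build_graph_representation(inst, config)
            graphs.append(g)
            Gs.append(neumann_graph_matrix(g.adjacency))
        except Exception as exc:
            raise RuntimeError(
                f"graph construction failed for instance "
                f"{getattr(inst, 'pair_id', '?')}: {exc}") from exc
    n = len(instances)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            K[i, j] = K[j, i] = graph_kernel_value(
                graphs[i], graphs[j], Gs[i], Gs[j])
    return K


def graph_cross_kernel(instances_a, instances_b, config: GraphConfig = None) -> np.ndarray:
    """Kernel values between two instance collections (rows: a, cols: b)."""
    config = config or GraphConfig()
    ga = [build_graph_representation(i, config) for i in instances_a]
    gb = [build_graph_representation(i, config) for i in instances_b]
    Ga = [neumann_graph_matrix(g.adjacency) for g in ga]
    Gb = [neumann_graph_matrix(g.adjacency) for g in gb]
    K = np.zeros((len(ga), len(gb)))
    for i in range(len(ga)):
        for j in range(len(gb)):
            K[i, j] = graph_kernel_value(ga[i], gb[j], Ga[i], Gb[j])
    return K
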