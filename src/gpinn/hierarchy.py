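"""Knowledge-hierarchy graphs and their compilation into layered connectivity masks.

A knowledge branch (an ontology such as GO, or a pathway database such as
Reactome) is modelled as a directed acyclic graph whose leaves are genes and
whose internal nodes are terms; every edge points from a child towards a
parent (gene -> annotating term, term -> broader term).  To turn the DAG into
a feed-forward network the graph is *stratified* into a fixed number of
layers and every surviving edge is re-wired so that it only connects adjacent
layers; the result is a stack of binary connectivity masks that define which
weights of the neural network are trainable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

log = logging.getLogger(__name__)

GENE = "gene"
TERM = "term"

#: separator used to build deterministic identifiers for pass-through units
PASSTHROUGH_SEP = "::pt::"


class HierarchyError(ValueError):
    """Raised for malformed knowledge-base inputs (cycles, bad files, ...)."""


@dataclass(frozen=True)
class KnowledgeNode:
    id: str
    label: str = ""
    kind: str = TERM          # "gene" or "term"
    branch: str = "ontology"  # "ontology" or "pathway"


@dataclass
class HierarchyGraph:
    """Validated DAG of genes and terms; edges are (child_id, parent_id)."""

    nodes: dict[str, KnowledgeNode]
    edges: set[tuple[str, str]]
    branch: str = "ontology"

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.nodes or parent not in self.nodes:
                raise HierarchyError(f"edge ({child}, {parent}) references unknown node")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def gene_ids(self) -> list[str]:
        return sorted(n for n, node in self.nodes.items() if node.kind == GENE)

    @property
    def term_ids(self) -> list[str]:
        return sorted(n for n, node in self.nodes.items() if node.kind == TERM)

    @property
    def roots(self) -> list[str]:
        """Term nodes with no parent."""
        with_parent = {c for c, _ in self.edges}
        return sorted(t for t in self.term_ids if t not in with_parent)

    def summary(self) -> dict:
        return {
            "branch": self.branch,
            "n_genes": len(self.gene_ids),
            "n_terms": len(self.term_ids),
            "n_edges": len(self.edges),
            "roots": self.roots,
        }


@dataclass
class LayerStratification:
    """Assignment of term nodes to network layers (1 = closest to genes).

    ``layer_nodes`` additionally contains the pass-through units inserted by
    the edge re-wiring rule, i.e. exactly the node sets the compiled network
    will have; ``rewired_edges`` hold only adjacent-layer connections
    (layer 0 = gene layer).
    """

    n_layers: int
    layers: list[list[str]]                      # term nodes only, index 0 = L1
    assignment: dict[str, int]                   # term id -> 1-based layer
    merged: dict[str, str]                       # collapsed node -> representative
    layer_nodes: list[list[str]]                 # incl. pass-through units
    rewired_edges: list[tuple[str, str, int]]    # (src, dst, dst_layer); src in dst_layer-1
    dropped_edges: list[tuple[str, str]] = field(default_factory=list)
    excluded_terms: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "layer_sizes": [len(l) for l in self.layer_nodes],
            "n_rewired_edges": len(self.rewired_edges),
            "n_dropped_edges": len(self.dropped_edges),
            "n_merged": len(self.merged),
            "n_excluded_terms": len(self.excluded_terms),
        }


@dataclass
class ConnectivityMask:
    """Binary adjacency between two consecutive network layers."""

    source_ids: list[str]
    target_ids: list[str]
    mask: np.ndarray  # shape (len(source_ids), len(target_ids)), {0,1}

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.mask.shape != (len(self.source_ids), len(self.target_ids)):
            raise ValueError("mask shape does not match id lists")

    @property
    def n_connections(self) -> int:
        return int(self.mask.sum())

    def to_triplets(self) -> list[tuple[str, str, int]]:
        rows, cols = np.nonzero(self.mask)
        return [(self.source_ids[i], self.target_ids[j], 1) for i, j in zip(rows, cols)]

    def write_triplets(self, path) -> None:
        with open(path, "w") as fh:
            for s, t, v in self.to_triplets():
                fh.write(f"{s}\t{t}\t{v}\n")


# ---------------------------------------------------------------------------
# file parsing
# ---------------------------------------------------------------------------

def load_gene_sets(path) -> dict[str, set[str]]:
    """Parse a GMT file: ``term_id<TAB>description<TAB>gene1<TAB>gene2...``.

    Gene symbols are de-duplicated within a term.  A line with fewer than
    three fields, an empty member list, or a repeated term id is an error.
    """
    gene_sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise HierarchyError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            term = fields[0]
            if term in gene_sets:
                raise HierarchyError(f"{path}: line {lineno}: duplicate term id {term!r}")
            members = {g for g in fields[2:] if g}
            if not members:
                raise HierarchyError(f"{path}: line {lineno}: term {term!r} has no members")
            gene_sets[term] = members
    return gene_sets


def load_relations(path) -> set[tuple[str, str]]:
    """Parse a child/parent TSV into a de-duplicated edge set; self-loops rejected."""
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise HierarchyError(f"{path}: line {lineno}: expected two columns (child, parent)")
            child, parent = fields[0], fields[1]
            if child == parent:
                raise HierarchyError(f"{path}: line {lineno}: self-loop on {child!r}")
            edges.add((child, parent))
    return edges


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(
    gene_sets: dict[str, set[str]],
    relations: set[tuple[str, str]] | None = None,
    branch: str = "ontology",
) -> HierarchyGraph:
    """Assemble the branch DAG from term memberships and term-term relations.

    Gene nodes are created for every annotated symbol, with one edge
    gene -> annotating term per membership (no up-propagation to ancestors:
    the layered network itself performs that propagation).  Acyclicity is
    verified; a cycle raises with one offending cycle listed.
    """
    relations = set(relations or ())
    term_ids = set(gene_sets) | {t for e in relations for t in e}
    genes = sorted({g for members in gene_sets.values() for g in members})
    if term_ids & set(genes):
        clash = sorted(term_ids & set(genes))[:5]
        raise HierarchyError(f"identifiers used as both gene and term: {clash}")

    nodes = {t: KnowledgeNode(t, kind=TERM, branch=branch) for t in sorted(term_ids)}
    nodes.update({g: KnowledgeNode(g, kind=GENE, branch=branch) for g in genes})

    edges: set[tuple[str, str]] = set(relations)
    for term, members in gene_sets.items():
        for g in members:
            edges.add((g, term))

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise HierarchyError(f"hierarchy contains a cycle: {cycle}")

    # terms with neither direct genes nor any gene-bearing descendant
    gene_reachable = set(genes) | {
        d for gene in genes for d in nx.descendants(g, gene)
    }
    unsupported = sorted(t for t in term_ids if t not in gene_reachable)
    if unsupported:
        warnings.warn(
            f"{len(unsupported)} term(s) have no annotated gene below them "
            f"(e.g. {unsupported[:3]}); retained in the graph but they will be "
            "excluded from the compiled network",
            stacklevel=2,
        )

    graph = HierarchyGraph(nodes=nodes, edges=edges, branch=branch)
    roots = graph.roots
    if not roots:
        raise HierarchyError("hierarchy has no root term")
    return graph


def degree(graph: HierarchyGraph) -> dict[str, int]:
    """Total degree (in + out) of every node in the hierarchy graph."""
    d = dict.fromkeys(graph.nodes, 0)
    for child, parent in graph.edges:
        d[child] += 1
        d[parent] += 1
    return d


# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------

def _passthrough_id(src: str, dst: str, layer: int) -> str:
    return f"{src}{PASSTHROUGH_SEP}{dst}@L{layer}"


def is_passthrough(node_id: str) -> bool:
    return PASSTHROUGH_SEP in node_id


def stratify(graph: HierarchyGraph, n_layers: int = 5) -> LayerStratification:
    """Assign term nodes to ``n_layers`` network layers and re-wire edges.

    The layer index of a term is its shortest-path distance from the gene
    layer (min over member genes' paths), clamped at ``n_layers``.  Chains of
    clamped nodes in the final layer are collapsed into their nearest retained
    ancestor.  Edges that end up spanning non-adjacent layers are realised as
    identity pass-through units in the intervening layers, so every compiled
    connection joins adjacent strata.  Terms with no annotated gene below them
    (hence no defined distance) are excluded with a warning.
    """
    if n_layers < 1:
        raise HierarchyError(f"n_layers must be >= 1, got {n_layers}")

    g = graph.to_networkx()
    genes = graph.gene_ids

    # multi-source BFS distance from the gene layer
    depth: dict[str, int] = {}
    frontier = list(genes)
    for gene in genes:
        depth[gene] = 0
    level = 0
    while frontier:
        level += 1
        nxt = []
        for u in frontier:
            for v in g.successors(u):
                if v not in depth:
                    depth[v] = level
                    nxt.append(v)
        frontier = nxt

    excluded = sorted(t for t in graph.term_ids if t not in depth)
    if excluded:
        warnings.warn(
            f"{len(excluded)} term(s) unreachable from the gene layer excluded "
            f"from stratification (e.g. {excluded[:3]})",
            stacklevel=2,
        )

    assignment = {
        t: min(depth[t], n_layers) for t in graph.term_ids if t in depth
    }

    # collapse clamped chains in the final layer into their topmost ancestor
    final = [t for t, l in assignment.items() if l == n_layers]
    final_set = set(final)
    merged: dict[str, str] = {}

    def _rep(u: str, _seen: tuple = ()) -> str:
        if u in merged:
            return merged[u]
        parents = sorted(p for p in g.successors(u) if p in final_set)
        if not parents:
            merged[u] = u
        else:
            merged[u] = _rep(parents[0])
        return merged[u]

    for t in sorted(final):
        _rep(t)
    # identity entries are kept only for collapsed nodes' bookkeeping
    merged = {k: v for k, v in merged.items() if k != v}

    def node_of(t: str) -> str:
        return merged.get(t, t)

    retained = {t: l for t, l in assignment.items() if t not in merged}
    layers = [sorted(t for t, l in retained.items() if l == k + 1) for k in range(n_layers)]

    # re-wire every original edge onto the retained, layered node set
    layer_of = dict(retained)
    layer_of.update({gene: 0 for gene in genes})
    raw_edges: set[tuple[str, str]] = set()
    dropped: list[tuple[str, str]] = []
    for child, parent in sorted(graph.edges):
        if child not in depth or parent not in depth:
            continue
        u, v = node_of(child), node_of(parent)
        if u == v:  # edge absorbed by a collapse
            continue
        lu, lv = layer_of[u], layer_of[v]
        if lv <= lu:
            dropped.append((child, parent))
            continue
        raw_edges.add((u, v))
    if dropped:
        warnings.warn(
            f"{len(dropped)} edge(s) pointing sideways/backwards after "
            "stratification were dropped",
            stacklevel=2,
        )

    # decompose skip edges through identity pass-through units
    layer_nodes = [list(l) for l in layers]
    rewired: list[tuple[str, str, int]] = []
    for u, v in sorted(raw_edges):
        lu, lv = layer_of[u], layer_of[v]
        prev = u
        for k in range(lu + 1, lv):
            pt = _passthrough_id(u, v, k)
            layer_nodes[k - 1].append(pt)
            rewired.append((prev, pt, k))
            prev = pt
        rewired.append((prev, v, lv))
    layer_nodes = [sorted(l) for l in layer_nodes]

    return LayerStratification(
        n_layers=n_layers,
        layers=layers,
        assignment=retained,
        merged=merged,
        layer_nodes=layer_nodes,
        rewired_edges=sorted(rewired),
        dropped_edges=dropped,
        excluded_terms=excluded,
    )


def masks(
    strat: LayerStratification,
    graph: HierarchyGraph,
    gene_roster: list[str] | None = None,
) -> list[ConnectivityMask]:
    """Materialise the gene->L1 mask plus one mask per adjacent layer pair.

    ``gene_roster`` optionally fixes the gene ordering of the input layer;
    roster genes absent from this branch are given an identity pass-through
    chain up to the final layer so no input feature is silently dropped.
    Node ordering is lexicographic throughout, so masks are reproducible.
    """
    genes = graph.gene_ids
    if gene_roster is None:
        gene_roster = genes
    else:
        gene_roster = list(gene_roster)
        if len(set(gene_roster)) != len(gene_roster):
            raise HierarchyError("gene roster contains duplicates")

    layer_nodes = [list(l) for l in strat.layer_nodes]
    rewired = list(strat.rewired_edges)

    missing = [g for g in gene_roster if g not in graph.nodes]
    if missing:
        log.info(
            "%d roster gene(s) absent from branch %r get a pass-through chain",
            len(missing), graph.branch,
        )
        for g in missing:
            prev = g
            for k in range(1, strat.n_layers + 1):
                pt = _passthrough_id(g, "sink", k)
                layer_nodes[k - 1].append(pt)
                rewired.append((prev, pt, k))
                prev = pt
    layer_nodes = [sorted(l) for l in layer_nodes]

    out: list[ConnectivityMask] = []
    sources = list(gene_roster)
    for k in range(1, strat.n_layers + 1):
        targets = layer_nodes[k - 1]
        src_index = {s: i for i, s in enumerate(sources)}
        tgt_index = {t: j for j, t in enumerate(targets)}
        m = np.zeros((len(sources), len(targets)), dtype=np.int8)
        for u, v, lv in rewired:
            if lv == k:
                if u not in src_index:
                    # gene annotated in the graph but not on the roster
                    continue
                m[src_index[u], tgt_index[v]] = 1
        out.append(ConnectivityMask(sources, targets, m))
        sources = targets
    return out


def stratified_degree(masks_list: list[ConnectivityMask]) -> dict[str, int]:
    """Total degree of every node of the compiled (re-wired) network.

    Pass-through units acquire their natural degree here, which the original
    hierarchy's degree table cannot provide.
    """
    d: dict[str, int] = {}
    for cm in masks_list:
        row = cm.mask.sum(axis=1)
        col = cm.mask.sum(axis=0)
        for i, s in enumerate(cm.source_ids):
            d[s] = d.get(s, 0) + int(row[i])
        for j, t in enumerate(cm.target_ids):
            d[t] = d.get(t, 0) + int(col[j])
    return d


def write_summary(graph: HierarchyGraph, strat: LayerStratification, path) -> None:
    with open(path, "w") as fh:
        json.dump({"graph": graph.summary(), "stratification": strat.summary()}, fh, indent=2)
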