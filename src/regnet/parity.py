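"""Signed influence inference: net activators and inhibitors of a target.

To decide the overall effect of an upstream entity on a gene product, we
build a signed graph over all entities (genes unified with their primary
polypeptide/RNA product; complexes, modified forms and compounds as their
own nodes) containing every unambiguous positive or negative influence:

* expression regulations contribute an edge from the regulator entity to
  each regulated gene, signed by mode (dual contributes both signs; a
  regulation of unknown mode carries no information and is omitted);
* enzyme-activity regulations contribute an edge from the modulator to the
  enzyme;
* an irreversible reaction makes its reactants and enzyme activators of
  each reaction product, and makes the enzyme and the other reactants
  inhibitors of each reactant (they promote its consumption); reversible
  reactions are ignored;
* complex formation makes each component an activator of the complex, and
  an unmodified form an activator of its modified form;
* compounds participating in more than ``hub_threshold`` reactions are
  dropped entirely — ubiquitous metabolites are unlikely to carry
  regulatory signal and only clutter the graph.

Signs multiply along a path (an inhibitor of an inhibitor is an indirect
activator).  An entity reachable by both a net-positive and a net-negative
path has an unknown overall effect, and influences further upstream of it
are ignored.  Classification uses simple paths of bounded length whose
intermediate nodes are themselves determined, iterated to a fixpoint:
entities found ambiguous are excluded as intermediates and the signs are
recomputed until nothing changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (
    ENZYME_ACTIVITY,
    REGULATION_CLASSES,
    RegulatoryModel,
    regulated_genes,
)

__all__ = [
    "ParityOptions",
    "ParityGraph",
    "ParityClassification",
    "SignedPath",
    "build_parity_graph",
    "classify_influences",
    "influence_paths",
    "entity_node",
]

_SIGNS = {"+": {1}, "-": {-1}, "dual": {1, -1}}


@dataclass
class ParityOptions:
    """depth: maximum path length considered; hub_threshold: compounds in
    more than this many reactions are excluded; physiological_only drops
    regulations explicitly flagged not physiologically relevant."""

    depth: int = 6
    hub_threshold: int = 10
    physiological_only: bool = False
    include_classes: Optional[frozenset] = None  # None = all regulation classes

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.hub_threshold <= 0:
            raise ValueError("hub_threshold must be positive")


class ParityGraph:
    """Signed entity graph; parallel signs on one ordered pair merge to +-."""

    def __init__(self):
        self.graph = nx.DiGraph()
        self.excluded_hubs: set[str] = set()

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def add_edge(self, src: str, tgt: str, signs: Iterable[int], provenance: str) -> None:
        signs = set(signs)
        if self.graph.has_edge(src, tgt):
            d = self.graph.edges[src, tgt]
            d["signs"] = d["signs"] | signs
            d["provenance"] = d["provenance"] | {provenance}
        else:
            self.graph.add_edge(src, tgt, signs=frozenset(signs), provenance=frozenset({provenance}))

    def nodes(self):
        return set(self.graph.nodes)

    def edges(self):
        return set(self.graph.edges)

    def edge_signs(self, src: str, tgt: str) -> frozenset:
        return frozenset(self.graph.edges[src, tgt]["signs"])


def entity_node(entity_id: str, model: RegulatoryModel) -> str:
    """Map an entity to its parity-graph node.

    A gene and its primary polypeptide/RNA product share one node (the
    gene id); complexes, modified forms and compounds are their own nodes.
    """
    if entity_id in model.genes:
        return entity_id
    prod = model.products.get(entity_id)
    if prod is not None and prod.kind in ("polypeptide", "rna") and prod.gene_ids:
        return sorted(prod.gene_ids)[0]
    return entity_id


def _hub_compounds(model: RegulatoryModel, threshold: int) -> set[str]:
    return {
        cid
        for cid, rxns in model.compound_to_reactions.items()
        if len(rxns) > threshold
    }


def build_parity_graph(model: RegulatoryModel, opts: Optional[ParityOptions] = None) -> ParityGraph:
    """Assemble the signed entity graph of all regulatory influences."""
    opts = opts or ParityOptions()
    include = opts.include_classes if opts.include_classes is not None else REGULATION_CLASSES
    hubs = _hub_compounds(model, opts.hub_threshold)
    pg = ParityGraph()
    pg.excluded_hubs = hubs
    for g in model.genes:
        pg.add_node(g)

    def node(eid: str) -> Optional[str]:
        n = entity_node(eid, model)
        return None if n in hubs else n

    for reg_id in sorted(model.regulations):
        reg = model.regulations[reg_id]
        if reg.reg_class not in include or reg.reg_class not in REGULATION_CLASSES:
            continue
        if opts.physiological_only and reg.physiologically_relevant is False:
            continue
        signs = _SIGNS.get(reg.mode)
        if signs is None:  # unknown mode carries no sign information
            continue
        src = node(reg.regulator_id)
        if src is None:
            continue
        if reg.reg_class == ENZYME_ACTIVITY:
            eid = reg.regulated_entity_id
            if eid in model.products:
                enzymes = [eid]
            else:
                rxn = model.reactions.get(eid)
                enzymes = list(rxn.enzyme_ids) if rxn else []
            for enz in enzymes:
                tgt = node(enz)
                if tgt is not None:
                    pg.add_edge(src, tgt, signs, reg.id)
        else:
            for g in regulated_genes(reg, model):
                pg.add_edge(src, g, signs, reg.id)

    for rxn_id in sorted(model.reactions):
        rxn = model.reactions[rxn_id]
        if rxn.reversible:
            continue  # direction ambiguous: no net influence derivable
        reactants = [node(c) for c in rxn.reactant_ids]
        reactants = [c for c in reactants if c is not None]
        products = [node(c) for c in rxn.product_ids]
        products = [c for c in products if c is not None]
        enzymes = [node(e) for e in rxn.enzyme_ids]
        enzymes = [e for e in enzymes if e is not None]
        for p in products:
            for c in reactants:
                if c != p:
                    pg.add_edge(c, p, {1}, rxn.id)
            for e in enzymes:
                if e != p:
                    pg.add_edge(e, p, {1}, rxn.id)
        for c in reactants:
            for e in enzymes:
                if e != c:
                    pg.add_edge(e, c, {-1}, rxn.id)
            for other in reactants:
                if other != c:
                    pg.add_edge(other, c, {-1}, rxn.id)

    for pid in sorted(model.products):
        prod = model.products[pid]
        tgt = node(pid)
        if tgt is None:
            continue
        if prod.kind == "complex":
            for comp in prod.component_ids:
                src = node(comp)
                if src is not None and src != tgt:
                    pg.add_edge(src, tgt, {1}, f"component-of:{pid}")
        elif prod.kind == "modified-form" and prod.unmodified_form_id:
            src = node(prod.unmodified_form_id)
            if src is not None and src != tgt:
                pg.add_edge(src, tgt, {1}, f"modified-from:{pid}")
    return pg


@dataclass
class ParityClassification:
    target: str
    activators: set[str] = field(default_factory=set)
    inhibitors: set[str] = field(default_factory=set)
    unknown: set[str] = field(default_factory=set)
    sign_sets: dict[str, frozenset] = field(default_factory=dict)
    depth_used: int = 0
    fixpoint_rounds: int = 0


def _collect_signs(
    graph: nx.DiGraph, target: str, depth: int, excluded: set[str]
) -> dict[str, set[int]]:
    """Sign products over simple paths to ``target``, via backward DFS.

    Paths may not revisit nodes and may not pass *through* an excluded
    node (excluded nodes can still start a path and so receive signs).
    """
    signs: dict[str, set[int]] = {}

    def dfs(node: str, suffix: frozenset, depth_left: int, on_path: frozenset) -> None:
        for u in graph.predecessors(node):
            if u == target or u in on_path:
                continue
            products = {e * s for e in graph.edges[u, node]["signs"] for s in suffix}
            signs.setdefault(u, set()).update(products)
            if depth_left > 1 and u not in excluded:
                dfs(u, frozenset(products), depth_left - 1, on_path | {u})

    dfs(target, frozenset({1}), depth, frozenset({target}))
    return signs


def classify_influences(
    pgraph: ParityGraph, target: str, depth: int = 6
) -> ParityClassification:
    """Classify every upstream entity as net activator, inhibitor or unknown.

    Iterated fixpoint: compute sign sets over simple paths of length <=
    ``depth``; entities reached with both signs become "unknown" and are
    excluded as path intermediates ("further regulatory effects are
    ignored"); recompute until stable.  The unknown set grows
    monotonically, so at most |V| rounds are needed.
    """
    if target not in pgraph.graph:
        raise ValueError(f"target {target!r} not in parity graph")
    unknown: set[str] = set()
    rounds = 0
    n_nodes = pgraph.graph.number_of_nodes()
    while True:
        rounds += 1
        if rounds > n_nodes + 1:
            raise RuntimeError("parity fixpoint failed to stabilize")  # pragma: no cover
        signs = _collect_signs(pgraph.graph, target, depth, unknown)
        new_unknown = {u for u, s in signs.items() if s >= {1, -1}}
        if new_unknown <= unknown:
            break
        unknown |= new_unknown
    # Nodes flagged ambiguous stay unknown as long as they retain any
    # admissible path; nodes whose every path was pruned away are not
    # classified at all ("further regulatory effects ... are ignored").
    cls = ParityClassification(target=target, depth_used=depth, fixpoint_rounds=rounds)
    for u, s in signs.items():
        if u in unknown:
            cls.unknown.add(u)
            cls.sign_sets[u] = frozenset({1, -1})
        elif s == {1}:
            cls.activators.add(u)
            cls.sign_sets[u] = frozenset({1})
        elif s == {-1}:
            cls.inhibitors.add(u)
            cls.sign_sets[u] = frozenset({-1})
    return cls


def min_path_lengths(pgraph: ParityGraph, classification: ParityClassification) -> dict[str, int]:
    """Shortest admissible path length to the target per classified entity.

    Breadth-first search backwards from the target, expanding only through
    determined entities (unknown entities may terminate a path but not be
    crossed), capped at the classification depth.
    """
    target = classification.target
    determined = classification.activators | classification.inhibitors
    dist: dict[str, int] = {target: 0}
    frontier = [target]
    while frontier:
        nxt = []
        for v in frontier:
            if v != target and v not in determined:
                continue  # unknown nodes are never crossed
            d = dist[v]
            if d >= classification.depth_used:
                continue
            for u in pgraph.graph.predecessors(v):
                if u not in dist:
                    dist[u] = d + 1
                    nxt.append(u)
        frontier = nxt
    return {u: d for u, d in dist.items() if u in classification.sign_sets}


@dataclass
class SignedPath:
    nodes: tuple[str, ...]
    edge_signs: tuple[frozenset, ...]

    @property
    def product_signs(self) -> frozenset:
        out = {1}
        for es in self.edge_signs:
            out = {e * s for e in es for s in out}
        return frozenset(out)

    def sign_string(self) -> str:
        p = self.product_signs
        if p == {1}:
            return "+"
        if p == {-1}:
            return "-"
        return "+/-"


def influence_paths(
    pgraph: ParityGraph,
    regulator: str,
    target: str,
    depth: int = 6,
    classification: Optional[ParityClassification] = None,
) -> list[SignedPath]:
    """All admissible simple paths regulator -> target of length <= depth.

    Intermediate nodes must be determined (net activators or inhibitors in
    the classification); paths through unknown entities are excluded.
    Sorted by length, then lexicographically.
    """
    if regulator not in pgraph.graph or target not in pgraph.graph:
        return []
    if classification is None:
        classification = classify_influences(pgraph, target, depth)
    determined = classification.activators | classification.inhibitors
    paths: list[SignedPath] = []

    def dfs(node: str, path: list[str]) -> None:
        if len(path) - 1 > depth:
            return
        if node == target:
            signs = tuple(
                pgraph.edge_signs(path[i], path[i + 1]) for i in range(len(path) - 1)
            )
            paths.append(SignedPath(tuple(path), signs))
            return
        if len(path) - 1 == depth:
            return
        for nxt in pgraph.graph.successors(node):
            if nxt in path:
                continue
            if nxt != target and nxt not in determined:
                continue
            dfs(nxt, path + [nxt])

    dfs(regulator, [regulator])
    paths.sort(key=lambda p: (len(p.nodes), p.nodes))
    return paths
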