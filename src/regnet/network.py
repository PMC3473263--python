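"""Gene-level signed regulatory network: construction, clustering, layouts.

The network is a directed gene-to-gene graph: an edge from gene A to gene B
means A regulates B through some included regulation class.  Every
regulation contributes edges from each gene encoding its regulator to each
gene it regulates (promoter regulation expands to the whole transcription
unit, attenuation only to downstream genes).  Enzyme-activity regulation is
never part of this graph.  Sigma-factor recognition of a promoter, when
included, contributes activation edges from the sigma factor's gene to the
promoter's TU genes.

When several regulations give the same ordered gene pair conflicting signs
the merged edge label is "dual"; "unknown" is absorbed by any informative
label (merge lattice: unknown < activation/inhibition < dual).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .model import (
    ENZYME_ACTIVITY,
    TRANSCRIPTIONAL_CLASSES,
    TRANSLATIONAL_CLASSES,
    RegulatoryModel,
    product_genes,
    regulated_genes,
    regulator_genes,
)

__all__ = [
    "EDGE_MODES",
    "GeneNetwork",
    "LayoutResult",
    "build_gene_network",
    "merge_labels",
    "cluster_genes_by_regulators",
    "elliptical_layout",
    "layered_layout",
    "subnetwork",
    "sigma_factor_genes",
]

EDGE_MODES = ("activation", "inhibition", "dual", "unknown")

MODE_TO_LABEL = {"+": "activation", "-": "inhibition", "dual": "dual", "unknown": "unknown"}


def merge_labels(a: str, b: str) -> str:
    """Merge two edge labels: unknown < activation/inhibition < dual."""
    if a == b:
        return a
    if a == "unknown":
        return b
    if b == "unknown":
        return a
    return "dual"


class GeneNetwork:
    """Directed gene graph with per-edge mode label and provenance set."""

    def __init__(self, includes: Iterable[str] = ()):  # noqa: D107
        self.graph = nx.DiGraph()
        self.includes = frozenset(includes)

    # -- construction ----------------------------------------------------
    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def add_edge(self, src: str, tgt: str, mode: str, provenance: Iterable[str]) -> None:
        if mode not in EDGE_MODES:
            raise ValueError(f"unknown edge mode {mode!r}")
        prov = set(provenance)
        if not prov:
            raise ValueError("edge provenance must be nonempty")
        if self.graph.has_edge(src, tgt):
            data = self.graph.edges[src, tgt]
            data["mode"] = merge_labels(data["mode"], mode)
            data["provenance"] = data["provenance"] | prov
        else:
            self.graph.add_edge(src, tgt, mode=mode, provenance=frozenset(prov))

    # -- queries ---------------------------------------------------------
    def nodes(self):
        return set(self.graph.nodes)

    def edges(self):
        return set(self.graph.edges)

    def edge_data(self, src: str, tgt: str) -> tuple[str, frozenset]:
        d = self.graph.edges[src, tgt]
        return d["mode"], frozenset(d["provenance"])

    def regulators_of_gene(self, gene: str) -> set[str]:
        return set(self.graph.predecessors(gene))

    def targets_of_gene(self, gene: str) -> set[str]:
        return set(self.graph.successors(gene))

    def out_degree(self, gene: str) -> int:
        return self.graph.out_degree(gene)

    def regulator_nodes(self) -> set[str]:
        """Genes with at least one outgoing regulatory edge."""
        return {g for g in self.graph.nodes if self.graph.out_degree(g) > 0}

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        if self.nodes() != other.nodes() or self.edges() != other.edges():
            return False
        return all(self.edge_data(u, v) == other.edge_data(u, v) for u, v in self.edges())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def sigma_factor_genes(model: RegulatoryModel) -> set[str]:
    """Genes encoding any product referenced as a promoter's sigma factor."""
    out: set[str] = set()
    for prom in model.promoters.values():
        if prom.sigma_factor_id:
            out.update(product_genes(prom.sigma_factor_id, model))
    return out


DEFAULT_INCLUDE = frozenset({"transcriptional", "translational", "sigma"})


def build_gene_network(model: RegulatoryModel, include: Iterable[str] = DEFAULT_INCLUDE) -> GeneNetwork:
    """Build the gene-level regulatory network for the included classes.

    ``include`` is a subset of {"transcriptional", "translational",
    "sigma"}.  Enzyme-activity regulation never contributes edges.  All
    model genes appear as nodes, so purely unregulated genes participate in
    clustering and layouts.
    """
    include = frozenset(include)
    unknown = include - {"transcriptional", "translational", "sigma"}
    if unknown:
        raise ValueError(f"unknown include class(es): {', '.join(sorted(unknown))}")
    net = GeneNetwork(includes=include)
    for g in model.genes:
        net.add_node(g)
    for reg_id in sorted(model.regulations):
        reg = model.regulations[reg_id]
        if reg.reg_class == ENZYME_ACTIVITY:
            continue
        if reg.reg_class in TRANSCRIPTIONAL_CLASSES and "transcriptional" not in include:
            continue
        if reg.reg_class in TRANSLATIONAL_CLASSES and "translational" not in include:
            continue
        sources = regulator_genes(reg, model)
        targets = regulated_genes(reg, model)
        label = MODE_TO_LABEL[reg.mode]
        for s in sources:
            for t in targets:
                net.add_edge(s, t, label, {reg.id})
    if "sigma" in include:
        for prom_id in sorted(model.promoters):
            prom = model.promoters[prom_id]
            if not prom.sigma_factor_id:
                continue
            tu = model.transcription_units.get(prom.tu_id)
            if tu is None:
                continue
            for s in product_genes(prom.sigma_factor_id, model):
                for t in tu.gene_ids:
                    net.add_edge(s, t, "activation", {f"sigma:{prom.id}"})
    return net


# ---------------------------------------------------------------------------
# clustering


def cluster_genes_by_regulators(network: GeneNetwork) -> list[list[str]]:
    """Partition non-regulator genes by their exact set of direct regulators.

    Two genes share a cluster iff their in-neighbor sets are identical.
    Genes that regulate others (out-degree > 0) are excluded.  Clusters are
    ordered by size descending, ties by lexicographically smallest member;
    members are sorted.  Genes with no regulators form one "unregulated"
    cluster (empty-set key).
    """
    regulators = network.regulator_nodes()
    buckets: dict[frozenset, list[str]] = {}
    for g in network.nodes():
        if g in regulators:
            continue
        buckets.setdefault(frozenset(network.regulators_of_gene(g)), []).append(g)
    clusters = [sorted(members) for members in buckets.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


# ---------------------------------------------------------------------------
# layouts


@dataclass
class LayoutResult:
    """Coordinates for one layout; ``assignment`` maps gene -> ring/layer."""

    kind: str
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)
    assignment: dict[str, int] = field(default_factory=dict)


# semi-minor radii of the three concentric ellipses (axes ratio 2:1)
_RING_RADII = (1.0, 2.0, 4.0)


def _ring3_order(network: GeneNetwork, ring3: set[str]) -> list[str]:
    """Cluster-contiguous angular order for the outer ring."""
    buckets: dict[frozenset, list[str]] = {}
    for g in ring3:
        buckets.setdefault(frozenset(network.regulators_of_gene(g)), []).append(g)
    clusters = [sorted(m) for m in buckets.values()]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return [g for c in clusters for g in c]


def elliptical_layout(network: GeneNetwork, model: RegulatoryModel) -> LayoutResult:
    """Concentric-ellipse layout of the global regulatory network.

    Ring 1 (innermost): sigma-factor genes.  Ring 2: all other regulator
    genes (out-degree > 0).  Ring 3: the remaining genes, grouped
    contiguously by regulator-set cluster.  A gene that is both sigma
    factor and transcription factor sits in ring 1 only.
    """
    nodes = network.nodes()
    if not nodes:
        raise ValueError("cannot lay out an empty network")
    sigma = sigma_factor_genes(model) & nodes
    regulators = network.regulator_nodes()
    ring1 = sorted(sigma)
    ring2 = sorted((regulators - sigma))
    ring3_set = nodes - sigma - set(ring2)
    ring3 = _ring3_order(network, ring3_set)
    result = LayoutResult(kind="elliptical")
    for ring_no, members in ((1, ring1), (2, ring2), (3, ring3)):
        r = _RING_RADII[ring_no - 1]
        n = len(members)
        for i, g in enumerate(members):
            theta = 2.0 * math.pi * i / n
            result.coordinates[g] = (2.0 * r * math.cos(theta), r * math.sin(theta))
            result.assignment[g] = ring_no
    return result


def layered_layout(network: GeneNetwork, model: Optional[RegulatoryModel] = None) -> LayoutResult:
    """Layered layout: regulators in the top layers, pure targets at bottom.

    A regulator's layer is 1 + the longest path from it within the
    regulator-induced subgraph, computed on the condensation so that all
    members of a strongly connected component share a layer.
    Non-regulators occupy layer 0 (drawn lowest), ordered
    cluster-contiguously; higher layers are ordered lexicographically.
    """
    nodes = network.nodes()
    if not nodes:
        raise ValueError("cannot lay out an empty network")
    regulators = network.regulator_nodes()
    sub = network.graph.subgraph(regulators)
    cond = nx.condensation(sub)
    layer_of_scc: dict[int, int] = {}
    for scc in reversed(list(nx.topological_sort(cond))):
        succs = [layer_of_scc[s] for s in cond.successors(scc)]
        layer_of_scc[scc] = 1 + (max(succs) if succs else 0)
    layer: dict[str, int] = {g: 0 for g in nodes}
    for scc, members in cond.nodes(data="members"):
        for g in members:
            layer[g] = layer_of_scc[scc]
    bottom = sorted(g for g in nodes if layer[g] == 0)
    order_by_layer: dict[int, list[str]] = {}
    for g in nodes:
        order_by_layer.setdefault(layer[g], []).append(g)
    result = LayoutResult(kind="layered")
    for lv, members in order_by_layer.items():
        if lv == 0:
            members = _ring3_order(network, set(members))
        else:
            members = sorted(members)
        n = len(members)
        for i, g in enumerate(members):
            result.coordinates[g] = (float(i) - (n - 1) / 2.0, float(lv))
            result.assignment[g] = lv
    return result


# ---------------------------------------------------------------------------
# subnetworks


def subnetwork(
    network: GeneNetwork,
    seed_genes: Iterable[str],
    direction: str = "regulatees",
    depth: Optional[int] = None,
) -> GeneNetwork:
    """Induced subnetwork of genes reachable from the seeds.

    ``direction`` chooses edge orientation: "regulatees" follows edges
    forward, "regulators" backward, "both" takes the union of the two
    traversals.  ``depth`` limits the number of hops (None = unbounded).
    Edge labels and provenance are preserved.
    """
    seeds = set(seed_genes)
    missing = seeds - network.nodes()
    if missing:
        raise ValueError(f"unknown seed gene(s): {', '.join(sorted(missing))}")
    if direction not in ("regulators", "regulatees", "both"):
        raise ValueError(f"unknown direction {direction!r}")

    def reach(graph: nx.DiGraph) -> set[str]:
        found = set(seeds)
        frontier = set(seeds)
        hops = 0
        while frontier and (depth is None or hops < depth):
            frontier = {v for u in frontier for v in graph.successors(u)} - found
            found |= frontier
            hops += 1
        return found

    keep: set[str] = set()
    if direction in ("regulatees", "both"):
        keep |= reach(network.graph)
    if direction in ("regulators", "both"):
        keep |= reach(network.graph.reverse(copy=False))
    keep |= seeds
    out = GeneNetwork(includes=network.includes)
    for g in keep:
        out.add_node(g)
    for u, v in network.edges():
        if u in keep and v in keep:
            mode, prov = network.edge_data(u, v)
            out.add_edge(u, v, mode, prov)
    return out
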