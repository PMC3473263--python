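"""Gene-group algebra and regulation-enrichment analysis.

A gene group is a named set of gene ids with an append-only history of the
operations that produced it.  Groups support retrieval of their direct or
indirect regulators and regulatees on the gene network, operon expansion,
set algebra, and transforms into the product/metabolite world (proteins
coded, substrate-level modulators, entities regulated by compounds).

Regulation enrichment asks whether a group is over-represented for targets
of particular regulators relative to the whole organism: for each candidate
regulator the overlap between its regulon (restricted to the universe) and
the group is scored with the one-sided hypergeometric upper tail, and the
resulting p-values are corrected for multiple testing across all candidate
regulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import ENZYME_ACTIVITY, RegulatoryModel, _modulated_enzymes
from .network import GeneNetwork

__all__ = [
    "GeneGroup",
    "EnrichmentOptions",
    "EnrichmentRow",
    "EnrichmentResult",
    "regulators_of",
    "regulatees_of",
    "expand_to_operons",
    "combine",
    "genes_to_products",
    "modulators_of",
    "entities_regulated_by_compounds",
    "regulation_enrichment",
    "hypergeom_upper_tail",
]


@dataclass
class GeneGroup:
    name: str
    members: set[str] = field(default_factory=set)
    history: list[str] = field(default_factory=list)

    def derive(self, name: str, members: set[str], op: str) -> "GeneGroup":
        return GeneGroup(name=name, members=set(members), history=self.history + [op])


def _neighbors_within(network: GeneNetwork, members: set[str], forward: bool, depth: Optional[int]) -> set[str]:
    """Union of nodes reachable from members within ``depth`` hops (>=1)."""
    graph = network.graph if forward else network.graph.reverse(copy=False)
    present = members & network.nodes()
    found: set[str] = set()
    frontier = set(present)
    hops = 0
    while frontier and (depth is None or hops < depth):
        nxt = {v for u in frontier for v in graph.successors(u)}
        frontier = nxt - found
        found |= nxt
        hops += 1
    return found


def regulators_of(
    group: GeneGroup, network: GeneNetwork, mode: str = "direct", depth: Optional[int] = None
) -> GeneGroup:
    """Regulators of any group member: direct in-neighbors, or reverse
    reachability within ``depth`` when ``mode`` = "direct+indirect".

    A member regulating another member is included.  Group members absent
    from the network contribute nothing.
    """
    d = 1 if mode == "direct" else depth
    found = _neighbors_within(network, set(group.members), forward=False, depth=d)
    return group.derive(f"regulators_of({group.name})", found, f"regulators_of mode={mode} depth={depth}")


def regulatees_of(
    group: GeneGroup, network: GeneNetwork, mode: str = "direct", depth: Optional[int] = None
) -> GeneGroup:
    """Mirror image of :func:`regulators_of`: forward reachability."""
    d = 1 if mode == "direct" else depth
    found = _neighbors_within(network, set(group.members), forward=True, depth=d)
    return group.derive(f"regulatees_of({group.name})", found, f"regulatees_of mode={mode} depth={depth}")


def expand_to_operons(group: GeneGroup, model: RegulatoryModel) -> GeneGroup:
    """Extend the group with all genes co-transcribed with a member."""
    members = set(group.members)
    for g in group.members:
        for tu_id in model.gene_to_tus.get(g, []):
            members.update(model.transcription_units[tu_id].gene_ids)
    return group.derive(f"operons({group.name})", members, "expand_to_operons")


def combine(a: GeneGroup, b: GeneGroup, op: str) -> GeneGroup:
    if op == "union":
        members = a.members | b.members
    elif op == "intersection":
        members = a.members & b.members
    elif op == "difference":
        members = a.members - b.members
    else:
        raise ValueError(f"unknown set operation {op!r}")
    return GeneGroup(
        name=f"({a.name} {op} {b.name})",
        members=members,
        history=a.history + b.history + [f"combine {op} with {b.name}"],
    )


def genes_to_products(group: GeneGroup, model: RegulatoryModel, include_complexes: bool = False) -> set[str]:
    """Products coded by group members; optionally also every complex or
    modified form whose component closure contains such a product."""
    direct = {
        pid
        for pid, prod in model.products.items()
        if prod.kind in ("polypeptide", "rna") and set(prod.gene_ids) & group.members
    }
    direct |= {
        model.genes[g].product_id for g in group.members
        if g in model.genes and model.genes[g].product_id
    }
    if not include_complexes:
        return direct
    out = set(direct)
    changed = True
    while changed:
        changed = False
        for pid, prod in model.products.items():
            if pid in out:
                continue
            closure = set(prod.component_ids)
            if prod.unmodified_form_id:
                closure.add(prod.unmodified_form_id)
            if closure & out:
                out.add(pid)
                changed = True
    return out


def modulators_of(
    products: set[str], model: RegulatoryModel, physiological_only: bool = False
) -> dict[str, set[str]]:
    """Substrate-level activators, inhibitors, and ligands of the products.

    Activators/inhibitors come from enzyme-activity regulations whose
    regulated entity is a product in the set (or a reaction it catalyzes),
    split by mode; ligands from the products' ligand lists.
    """
    out: dict[str, set[str]] = {"activators": set(), "inhibitors": set(), "ligands": set()}
    for reg in model.regulations.values():
        if reg.reg_class != ENZYME_ACTIVITY:
            continue
        if physiological_only and reg.physiologically_relevant is False:
            continue
        if not (_modulated_enzymes(reg, model) & products):
            continue
        if reg.mode == "+":
            out["activators"].add(reg.regulator_id)
        elif reg.mode == "-":
            out["inhibitors"].add(reg.regulator_id)
        elif reg.mode == "dual":
            out["activators"].add(reg.regulator_id)
            out["inhibitors"].add(reg.regulator_id)
    for pid in products:
        prod = model.products.get(pid)
        if prod is not None:
            out["ligands"].update(prod.ligand_ids)
    return out


def _complexes_containing(compound: str, model: RegulatoryModel) -> set[str]:
    """Products whose component closure contains the compound."""
    out: set[str] = set()
    changed = True
    while changed:
        changed = False
        for pid, prod in model.products.items():
            if pid in out:
                continue
            refs = set(prod.component_ids)
            if prod.unmodified_form_id:
                refs.add(prod.unmodified_form_id)
            if compound in refs or refs & out:
                out.add(pid)
                changed = True
    return out


def entities_regulated_by_compounds(compounds: set[str], model: RegulatoryModel) -> dict[str, set[str]]:
    """What a set of metabolites touches: enzymes they activate or inhibit,
    and proteins that bind them (as ligands, or as components of a
    regulating complex)."""
    out: dict[str, set[str]] = {
        "enzymes_activated": set(),
        "enzymes_inhibited": set(),
        "proteins_bound": set(),
    }
    for reg in model.regulations.values():
        if reg.reg_class == ENZYME_ACTIVITY and reg.regulator_id in compounds:
            targets = _modulated_enzymes(reg, model)
            if reg.mode in ("+", "dual"):
                out["enzymes_activated"] |= targets
            if reg.mode in ("-", "dual"):
                out["enzymes_inhibited"] |= targets
    binding_complexes: set[str] = set()
    for c in compounds:
        binding_complexes |= _complexes_containing(c, model)
    for pid, prod in model.products.items():
        if set(prod.ligand_ids) & compounds:
            out["proteins_bound"].add(pid)
    for reg in model.regulations.values():
        if reg.regulator_id in binding_complexes:
            out["proteins_bound"].add(reg.regulator_id)
    return out


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentOptions:
    mode: str = "direct"  # or "direct+indirect"
    universe: Optional[set[str]] = None  # default: all network genes
    alpha: float = 0.05
    correction: str = "BH"  # BH | bonferroni | none
    indirect_depth: Optional[int] = None  # None = unbounded


@dataclass
class EnrichmentRow:
    regulator: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class EnrichmentResult:
    rows: list[EnrichmentRow] = field(default_factory=list)
    n_tests: int = 0
    options: Optional[EnrichmentOptions] = None


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X hypergeometric with N items, K successes, n draws."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def regulation_enrichment(
    group: GeneGroup, network: GeneNetwork, opts: Optional[EnrichmentOptions] = None
) -> EnrichmentResult:
    """Test the group for over-representation of each regulator's targets.

    Candidate regulators are all genes with at least one regulatee inside
    the universe under the chosen mode/depth.  For each candidate, k =
    group members it regulates, K = universe members it regulates, n =
    group size, N = universe size; p_raw is the hypergeometric upper tail
    and p_adj the multiplicity-corrected value across all candidates.
    Rows are sorted by p_adj then regulator id.
    """
    opts = opts or EnrichmentOptions()
    universe = set(opts.universe) if opts.universe is not None else network.nodes()
    if not group.members <= universe:
        extra = sorted(group.members - universe)
        raise ValueError(f"group members outside the universe: {', '.join(extra)}")
    depth = 1 if opts.mode == "direct" else opts.indirect_depth
    N = len(universe)
    n = len(group.members)
    rows: list[EnrichmentRow] = []
    for regulator in sorted(network.regulator_nodes()):
        targets = _neighbors_within(network, {regulator}, forward=True, depth=depth) & universe
        K = len(targets)
        if K == 0:
            continue
        k = len(targets & group.members)
        rows.append(EnrichmentRow(regulator, k, K, n, N, hypergeom_upper_tail(k, N, K, n), 1.0, False))
    if rows:
        praw = [r.p_raw for r in rows]
        if opts.correction == "BH":
            _, padj, _, _ = multipletests(praw, alpha=opts.alpha, method="fdr_bh")
        elif opts.correction == "bonferroni":
            _, padj, _, _ = multipletests(praw, alpha=opts.alpha, method="bonferroni")
        elif opts.correction == "none":
            padj = praw
        else:
            raise ValueError(f"unknown correction {opts.correction!r}")
        for r, p in zip(rows, padj):
            r.p_adj = float(p)
            r.significant = r.p_adj < opts.alpha
    rows.sort(key=lambda r: (r.p_adj, r.regulator))
    return EnrichmentResult(rows=rows, n_tests=len(rows), options=opts)
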