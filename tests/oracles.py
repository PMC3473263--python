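"""Independent reference computations used to check the library.

Everything here is deliberately written against a different route than the
implementation under test: dense eigendecomposition instead of power
iteration, exhaustive simple-path enumeration instead of backward DFS,
subset enumeration instead of the hypergeometric closed form, and raw
TU-list arithmetic instead of the model's expansion helpers.
"""

from __future__ import annotations

import itertools
import math
import random

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# influence: dense eigendecomposition of the explicit iteration matrix


def influence_eig_oracle(nodes, edges, damping, normalization="regulator-count"):
    """Scores from the dominant eigenvector of B = (1-a)(M+I) + (a/n)*J."""
    nodes = sorted(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v in edges:
        A[index[u], index[v]] = 1.0
    if normalization == "regulator-count":
        r = A.sum(axis=0)
        r[r == 0] = 1.0
        A = A / r
    B = (1.0 - damping) * (A + np.eye(n)) + (damping / n) * np.ones((n, n))
    w, V = np.linalg.eig(B)
    i = int(np.argmax(np.abs(w)))
    v = np.real(V[:, i])
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return {g: float(100.0 * v[index[g]] / v.max()) for g in nodes}


def random_gene_network(seed, n_min=20, n_max=50, mean_out=2.5):
    """A random GeneNetwork-shaped graph for influence checks."""
    from regnet.network import GeneNetwork

    rng = random.Random(seed)
    n = rng.randint(n_min, n_max)
    genes = [f"g{i:03d}" for i in range(n)]
    net = GeneNetwork()
    for g in genes:
        net.add_node(g)
    n_edges = int(mean_out * n)
    modes = ["activation", "inhibition", "dual", "unknown"]
    for k in range(n_edges):
        u = rng.choice(genes)
        v = rng.choice(genes)
        net.add_edge(u, v, rng.choice(modes), {f"e{k}"})
    return net


# ---------------------------------------------------------------------------
# parity: exhaustive simple-path enumeration with iterative pruning


def parity_classify_oracle(graph: nx.DiGraph, target, depth):
    """Activator/inhibitor/unknown sets by brute-force path enumeration.

    Enumerates every simple path u -> target of length <= depth whose
    intermediate nodes are not (yet) ambiguous, multiplies edge sign sets
    along each path, and iterates: nodes collecting both net signs become
    unknown and are excluded as intermediates until nothing changes.
    """
    unknown: set = set()
    signs: dict = {}
    rounds = 0
    while True:
        rounds += 1
        assert rounds <= graph.number_of_nodes() + 1
        signs = {}
        for u in graph.nodes:
            if u == target:
                continue
            for path in nx.all_simple_paths(graph, u, target, cutoff=depth):
                if any(w in unknown for w in path[1:-1]):
                    continue
                prods = {1}
                for a, b in zip(path, path[1:]):
                    prods = {e * s for e in graph.edges[a, b]["signs"] for s in prods}
                signs.setdefault(u, set()).update(prods)
        new = {u for u, s in signs.items() if s >= {1, -1}}
        if new <= unknown:
            break
        unknown |= new
    activators = {u for u, s in signs.items() if u not in unknown and s == {1}}
    inhibitors = {u for u, s in signs.items() if u not in unknown and s == {-1}}
    # ambiguous nodes stay unknown only while some admissible path remains
    still_unknown = {u for u in signs if u in unknown}
    return activators, inhibitors, still_unknown


def random_signed_graph(seed, n_max=30, p_edge=None, p_dual=0.1, allow_cycles=True):
    """Random signed digraph shaped like a ParityGraph."""
    from regnet.parity import ParityGraph

    rng = random.Random(seed)
    n = rng.randint(6, n_max)
    if p_edge is None:
        p_edge = min(0.15, 3.0 / n)
    pg = ParityGraph()
    names = [f"n{i:02d}" for i in range(n)]
    for x in names:
        pg.add_node(x)
    for i, u in enumerate(names):
        for j, v in enumerate(names):
            if i == j:
                continue
            if not allow_cycles and j <= i:
                continue
            if rng.random() < p_edge:
                r = rng.random()
                signs = {1, -1} if r < p_dual else ({1} if r < 0.5 + p_dual / 2 else {-1})
                pg.add_edge(u, v, signs, f"e{i}-{j}")
    return pg


# ---------------------------------------------------------------------------
# enrichment: exhaustive subset enumeration


def hypergeom_tail_enum(k, N, K, n):
    """P(X >= k) by counting subsets: exact rational arithmetic."""
    total = math.comb(N, n)
    hits = 0
    for i in range(max(k, 0), min(K, n) + 1):
        hits += math.comb(K, i) * math.comb(N - K, n - i)
    return hits / total


def hypergeom_tail_enum_bruteforce(k, N, K, n):
    """Same tail by literally enumerating all C(N, n) subsets."""
    marked = set(range(K))
    total = 0
    atleast = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            atleast += 1
    return atleast / total


# ---------------------------------------------------------------------------
# expansion: re-derivation from raw TU lists


def expansion_oracle(doc: dict) -> dict:
    """Map regulation id -> regulated gene list, from the RegJSON document.

    Works on the serialized document only (raw dicts), re-deriving the
    promoter/terminator/TU/gene expansion rules from first principles.
    """
    tus = {t["id"]: t for t in doc["transcription_units"]}
    promoters = {p["id"]: p for p in doc["promoters"]}
    terminators = {t["id"]: t for t in doc["terminators"]}
    genes = {g["id"] for g in doc["genes"]}
    out = {}
    for reg in doc["regulations"]:
        eid = reg["regulated_entity_id"]
        if eid in promoters:
            out[reg["id"]] = list(tus[promoters[eid]["tu_id"]]["gene_ids"])
        elif eid in terminators:
            term = terminators[eid]
            gl = tus[term["tu_id"]]["gene_ids"]
            out[reg["id"]] = [g for idx, g in enumerate(gl) if idx >= term.get("site_index", 0)]
        elif eid in tus:
            out[reg["id"]] = list(tus[eid]["gene_ids"])
        elif eid in genes:
            out[reg["id"]] = [eid]
        else:
            out[reg["id"]] = []
    return out


def gene_network_edge_oracle(doc: dict) -> dict:
    """Expected merged gene-to-gene edges from the raw document.

    Returns {(src, tgt): label} for transcriptional + translational +
    sigma influence, re-deriving regulator gene resolution and the label
    merge lattice independently of the library.
    """
    products = {p["id"]: p for p in doc["products"]}
    compounds = {c["id"] for c in doc["compounds"]}
    tus = {t["id"]: t for t in doc["transcription_units"]}
    promoters = {p["id"]: p for p in doc["promoters"]}

    def genes_of(entity, seen=None):
        seen = seen or set()
        if entity in seen or entity in compounds:
            return set()
        seen = seen | {entity}
        p = products.get(entity)
        if p is None:
            return {entity}  # a bare gene id
        kind = p.get("kind", "polypeptide")
        if kind in ("polypeptide", "rna"):
            return set(p.get("gene_ids", []))
        if kind == "modified-form":
            return genes_of(p.get("unmodified_form_id"), seen) if p.get("unmodified_form_id") else set()
        out = set()
        for c in p.get("component_ids", []):
            out |= genes_of(c, seen)
        return out

    targets_of = expansion_oracle(doc)
    label_of = {"+": "activation", "-": "inhibition", "dual": "dual", "unknown": "unknown"}
    transcriptional = {
        "transcription-factor-binding",
        "allosteric-regulation-of-rnap",
        "transcriptional-attenuation",
    }
    edges: dict = {}

    def merge(a, b):
        if a == b:
            return a
        if a == "unknown":
            return b
        if b == "unknown":
            return a
        return "dual"

    for reg in doc["regulations"]:
        cls = reg["reg_class"]
        if cls not in transcriptional and cls != "regulation-of-translation":
            continue
        label = label_of[reg.get("mode", "unknown")]
        for s in genes_of(reg["regulator_id"]):
            for t in targets_of[reg["id"]]:
                key = (s, t)
                edges[key] = merge(edges[key], label) if key in edges else label
    for prom in doc["promoters"]:
        sf = prom.get("sigma_factor_id")
        if not sf:
            continue
        for s in genes_of(sf):
            for t in tus[prom["tu_id"]]["gene_ids"]:
                key = (s, t)
                edges[key] = merge(edges[key], "activation") if key in edges else "activation"
    return edges
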