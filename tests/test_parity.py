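"""Signed influence graph: edge rules, parity propagation, oracle equivalence."""

import pytest

from regnet.model import Compound, Gene, Product, Reaction, RegulatoryModel
from regnet.parity import (
    ParityGraph,
    ParityOptions,
    build_parity_graph,
    classify_influences,
    entity_node,
    influence_paths,
)
from regnet.synth import SynthParams, generate_model

from oracles import parity_classify_oracle, random_signed_graph


def _reaction_model(reversible=False):
    """A + B -> C catalyzed by enzyme gene ge."""
    m = RegulatoryModel()
    m.genes["ge"] = Gene(id="ge", product_id="p_ge")
    m.products["p_ge"] = Product(id="p_ge", kind="polypeptide", gene_ids=["ge"])
    for c in ("A", "B", "C"):
        m.compounds[c] = Compound(id=c)
    m.reactions["r1"] = Reaction(
        id="r1", reactant_ids=["A", "B"], product_ids=["C"],
        enzyme_ids=["p_ge"], reversible=reversible,
    )
    return m.reindex()


def _signed_edges(pg):
    return {(u, v): set(pg.edge_signs(u, v)) for u, v in pg.edges()}


class TestGraphConstruction:
    def test_irreversible_reaction_edge_rules(self):
        pg = build_parity_graph(_reaction_model())
        assert _signed_edges(pg) == {
            ("A", "C"): {1},
            ("B", "C"): {1},
            ("ge", "C"): {1},
            ("ge", "A"): {-1},
            ("ge", "B"): {-1},
            ("A", "B"): {-1},
            ("B", "A"): {-1},
        }

    def test_reversible_reaction_contributes_nothing(self):
        pg = build_parity_graph(_reaction_model(reversible=True))
        assert pg.edges() == set()

    def test_ligand_bound_tf_complex_structure(self, toy_model):
        """Components activate the complex; the complex carries the mode."""
        pg = build_parity_graph(toy_model)
        edges = _signed_edges(pg)
        assert edges[("trp", "holo_gt")] == {1}
        assert edges[("dim_gt", "holo_gt")] == {1}
        assert edges[("gt", "dim_gt")] == {1}  # polypeptide node is the gene
        assert edges[("holo_gt", "g1")] == {-1}

    def test_gene_and_primary_product_share_a_node(self, toy_model):
        assert entity_node("p_gt", toy_model) == "gt"
        assert entity_node("gt", toy_model) == "gt"
        assert entity_node("holo_gt", toy_model) == "holo_gt"

    def test_unknown_mode_regulations_are_omitted(self, toy_model):
        toy_model.regulations["reg_tl"].mode = "unknown"
        pg = build_parity_graph(toy_model)
        assert ("gr", "g3") not in pg.edges()

    def test_dual_mode_contributes_both_signs(self, toy_model):
        toy_model.regulations["reg_tl"].mode = "dual"
        pg = build_parity_graph(toy_model)
        assert set(pg.edge_signs("gr", "g3")) == {1, -1}

    def test_hub_compounds_are_excluded_entirely(self):
        params = SynthParams(seed=6, n_genes=60, n_tfs=6, n_sigma=2,
                             hub_compound_count=2, hub_degree=12)
        model, ledger = generate_model(params)
        pg = build_parity_graph(model, ParityOptions(hub_threshold=10))
        for hub in ledger.hub_compound_ids:
            assert hub not in pg.nodes()
        # raising the threshold re-admits them and only adds edges
        pg_hi = build_parity_graph(model, ParityOptions(hub_threshold=50))
        assert pg.edges() <= pg_hi.edges()

    def test_physiological_filter_drops_flagged_irrelevant_modulation(self, toy_model):
        toy_model.regulations["reg_enz"].physiologically_relevant = False
        pg = build_parity_graph(toy_model, ParityOptions(physiological_only=True))
        assert ("prod", "ge") not in pg.edges()
        pg_all = build_parity_graph(toy_model)
        assert ("prod", "ge") in pg_all.edges()

    def test_no_reactions_means_no_reaction_edges(self):
        model, _ = generate_model(SynthParams(seed=8, n_genes=50, n_tfs=5, n_sigma=2,
                                              n_reactions=0, hub_compound_count=0,
                                              n_enzyme_modulations=0))
        pg = build_parity_graph(model)
        for u, v in pg.edges():
            prov = pg.graph.edges[u, v]["provenance"]
            assert not any(p.startswith("rx") for p in prov)


def _chain(*signed_edges):
    pg = ParityGraph()
    seen = set()
    for u, v, s in signed_edges:
        seen |= {u, v}
        pg.add_edge(u, v, s, f"{u}->{v}")
    for n in seen:
        pg.add_node(n)
    return pg


class TestClassification:
    def test_double_negative_is_an_indirect_activator(self):
        pg = _chain(("C", "A", {-1}), ("A", "B", {-1}))
        cls = classify_influences(pg, "B", depth=6)
        assert "C" in cls.activators
        assert "A" in cls.inhibitors

    def test_conflicting_parity_node_is_unknown_and_prunes_upstream(self):
        pg = _chain(
            ("A", "B", {1}),
            ("A", "M", {1}),
            ("M", "B", {-1}),
            ("D", "A", {1}),
        )
        cls = classify_influences(pg, "B", depth=6)
        assert "A" in cls.unknown
        assert "D" not in cls.activators | cls.inhibitors | cls.unknown

    def test_target_absent_is_an_error(self):
        pg = _chain(("A", "B", {1}))
        with pytest.raises(ValueError):
            classify_influences(pg, "Z")

    @pytest.mark.parametrize("seed", range(1, 31))
    def test_matches_exhaustive_path_oracle(self, seed):
        pg = random_signed_graph(seed)
        target = sorted(pg.nodes())[0]
        cls = classify_influences(pg, target, depth=6)
        a, i, u = parity_classify_oracle(pg.graph, target, 6)
        assert (cls.activators, cls.inhibitors, cls.unknown) == (a, i, u)

    def test_negating_edges_into_target_swaps_activators_and_inhibitors(self):
        """Every path crosses exactly one edge into the target, so flipping
        those edges negates every path product: + and - swap, ambiguity is
        preserved."""
        for seed in (3, 14):
            pg = random_signed_graph(seed, p_dual=0.0, allow_cycles=False)
            target = sorted(pg.nodes())[-1]
            cls = classify_influences(pg, target, depth=6)
            flipped = ParityGraph()
            for n in pg.nodes():
                flipped.add_node(n)
            for u, v in pg.edges():
                signs = pg.edge_signs(u, v)
                if v == target:
                    signs = {-s for s in signs}
                flipped.add_edge(u, v, signs, "f")
            fcls = classify_influences(flipped, target, depth=6)
            assert fcls.activators == cls.inhibitors
            assert fcls.inhibitors == cls.activators
            assert fcls.unknown == cls.unknown

    def test_depth_increase_never_flips_a_determined_sign_directly(self):
        """A net activator can become unknown with more depth, never an
        inhibitor outright (sign sets only grow with new paths)."""
        for seed in range(1, 16):
            pg = random_signed_graph(seed)
            target = sorted(pg.nodes())[0]
            c1 = classify_influences(pg, target, depth=3)
            c2 = classify_influences(pg, target, depth=4)
            assert not (c1.activators & c2.inhibitors)
            assert not (c1.inhibitors & c2.activators)

    def test_fixpoint_terminates_within_node_budget_on_cycles(self):
        pg = _chain(("A", "B", {1}), ("B", "A", {-1}), ("A", "A", {1}), ("C", "A", {-1}))
        cls = classify_influences(pg, "B", depth=6)
        assert cls.fixpoint_rounds <= len(pg.nodes()) + 1


class TestMinPathLengths:
    def test_lengths_follow_admissible_paths_only(self):
        from regnet.parity import min_path_lengths

        pg = _chain(
            ("A", "B", {1}),
            ("A", "M", {1}),
            ("M", "B", {-1}),
            ("D", "A", {1}),
            ("D", "X", {1}),
            ("X", "B", {1}),
        )
        cls = classify_influences(pg, "B", depth=6)
        lengths = min_path_lengths(pg, cls)
        assert lengths["M"] == 1 and lengths["A"] == 1 and lengths["X"] == 1
        # D is determined via X only (A is unknown and cannot be crossed)
        assert lengths["D"] == 2


class TestPaths:
    def test_two_negative_edges_give_positive_product(self):
        pg = _chain(("C", "A", {-1}), ("A", "B", {-1}))
        paths = influence_paths(pg, "C", "B", depth=6)
        assert len(paths) == 1
        assert paths[0].sign_string() == "+"
        assert paths[0].nodes == ("C", "A", "B")

    def test_unreachable_pair_yields_no_paths(self):
        pg = _chain(("A", "B", {1}), ("C", "D", {1}))
        assert influence_paths(pg, "A", "D", depth=6) == []

    def test_paths_through_unknown_nodes_are_excluded(self):
        pg = _chain(
            ("A", "B", {1}),
            ("A", "M", {1}),
            ("M", "B", {-1}),
            ("D", "A", {1}),
            ("D", "X", {1}),
            ("X", "B", {1}),
        )
        # A is unknown; D reaches B legitimately only through X
        paths = influence_paths(pg, "D", "B", depth=6)
        assert [p.nodes for p in paths] == [("D", "X", "B")]

    def test_paths_sorted_by_length_then_lexicographic(self):
        pg = _chain(
            ("S", "B", {1}),
            ("S", "A", {1}),
            ("A", "B", {1}),
            ("S", "C", {1}),
            ("C", "B", {1}),
        )
        paths = influence_paths(pg, "S", "B", depth=6)
        assert [p.nodes for p in paths] == [
            ("S", "B"),
            ("S", "A", "B"),
            ("S", "C", "B"),
        ]
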