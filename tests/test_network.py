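"""Gene-network construction, label merging, clustering, layouts, subnetworks."""

import numpy as np
import pytest

from regnet.io import model_to_document
from regnet.model import Gene, Product, Promoter, Regulation, RegulatoryModel, TranscriptionUnit
from regnet.network import (
    GeneNetwork,
    build_gene_network,
    cluster_genes_by_regulators,
    elliptical_layout,
    layered_layout,
    merge_labels,
    subnetwork,
)
from regnet.synth import SynthParams, generate_model

from oracles import gene_network_edge_oracle


def _promoter_model(*regs, sigma=None):
    """Genes t, u plus TU [g1, g2] with promoter pm1 and TU [g1] with pm2."""
    m = RegulatoryModel()
    for gid in ("t", "u", "g1", "g2", "s"):
        m.genes[gid] = Gene(id=gid, product_id=f"p_{gid}")
        m.products[f"p_{gid}"] = Product(id=f"p_{gid}", kind="polypeptide", gene_ids=[gid])
    m.transcription_units["tu1"] = TranscriptionUnit(id="tu1", gene_ids=["g1", "g2"], promoter_id="pm1")
    m.transcription_units["tu2"] = TranscriptionUnit(id="tu2", gene_ids=["g1"], promoter_id="pm2")
    m.promoters["pm1"] = Promoter(id="pm1", tu_id="tu1", sigma_factor_id=sigma)
    m.promoters["pm2"] = Promoter(id="pm2", tu_id="tu2")
    for reg in regs:
        m.regulations[reg.id] = reg
    return m.reindex()


def _tfb(rid, regulator, promoter, mode):
    return Regulation(
        id=rid, reg_class="transcription-factor-binding",
        regulator_id=regulator, regulated_entity_id=promoter, mode=mode,
    )


class TestBuild:
    def test_promoter_regulation_fans_out_to_all_tu_genes(self):
        m = _promoter_model(_tfb("r1", "p_t", "pm1", "+"))
        net = build_gene_network(m, include={"transcriptional"})
        assert net.edges() == {("t", "g1"), ("t", "g2")}
        assert net.edge_data("t", "g1")[0] == "activation"

    def test_conflicting_signs_via_two_promoters_merge_to_dual(self):
        m = _promoter_model(_tfb("r1", "p_t", "pm1", "+"), _tfb("r2", "p_t", "pm2", "-"))
        net = build_gene_network(m, include={"transcriptional"})
        mode, prov = net.edge_data("t", "g1")
        assert mode == "dual"
        assert prov == {"r1", "r2"}
        assert net.edge_data("t", "g2")[0] == "activation"

    def test_unknown_absorbed_by_informative_label(self):
        m = _promoter_model(_tfb("r1", "p_t", "pm1", "unknown"), _tfb("r2", "p_t", "pm2", "-"))
        net = build_gene_network(m, include={"transcriptional"})
        assert net.edge_data("t", "g1")[0] == "inhibition"
        assert net.edge_data("t", "g2")[0] == "unknown"

    def test_sigma_edges_carry_promoter_provenance(self):
        m = _promoter_model(sigma="p_s")
        net = build_gene_network(m, include={"sigma"})
        assert net.edges() == {("s", "g1"), ("s", "g2")}
        mode, prov = net.edge_data("s", "g1")
        assert mode == "activation" and prov == {"sigma:pm1"}

    def test_enzyme_activity_never_contributes_edges(self, toy_model):
        net = build_gene_network(toy_model, include={"transcriptional", "translational", "sigma"})
        for _, _, prov in [
            (u, v, net.edge_data(u, v)[1]) for u, v in net.edges()
        ]:
            assert "reg_enz" not in prov

    def test_excluded_classes_are_absent(self, toy_model):
        net = build_gene_network(toy_model, include={"translational"})
        assert net.edges() == {("gr", "g3")}

    def test_merge_lattice_is_commutative_and_absorbing(self):
        labels = ["activation", "inhibition", "dual", "unknown"]
        for a in labels:
            for b in labels:
                assert merge_labels(a, b) == merge_labels(b, a)
            assert merge_labels(a, "dual") == "dual"
            assert merge_labels(a, a) == a

    def test_label_merge_is_order_independent_on_generated_model(self):
        model, _ = generate_model(SynthParams(seed=17, n_genes=60, n_tfs=6, n_sigma=2))
        net1 = build_gene_network(model)
        # rebuild with regulations inserted in reverse order
        shuffled = RegulatoryModel(
            genes=model.genes,
            transcription_units=model.transcription_units,
            promoters=model.promoters,
            terminators=model.terminators,
            products=model.products,
            compounds=model.compounds,
            reactions=model.reactions,
            regulations=dict(reversed(list(model.regulations.items()))),
        ).reindex()
        assert build_gene_network(shuffled) == net1

    @pytest.mark.parametrize("seed", [2, 8])
    def test_edges_match_raw_document_oracle(self, seed):
        """Edge set and merged labels equal a from-scratch re-derivation."""
        model, _ = generate_model(SynthParams(seed=seed, n_genes=70, n_tfs=7, n_sigma=2))
        net = build_gene_network(model)
        expected = gene_network_edge_oracle(model_to_document(model))
        assert {e: net.edge_data(*e)[0] for e in net.edges()} == expected


class TestClustering:
    def test_genes_cluster_by_identical_regulator_sets(self):
        m = _promoter_model(_tfb("r1", "p_t", "pm1", "+"))
        net = build_gene_network(m, include={"transcriptional"})
        clusters = cluster_genes_by_regulators(net)
        by_member = {g: tuple(c) for c in clusters for g in c}
        assert by_member["g1"] == by_member["g2"]  # both regulated by {t}
        assert by_member["u"] == by_member["s"]  # both unregulated
        assert by_member["g1"] != by_member["u"]

    def test_regulator_genes_are_excluded_from_clusters(self):
        m = _promoter_model(_tfb("r1", "p_t", "pm1", "+"))
        net = build_gene_network(m, include={"transcriptional"})
        clustered = {g for c in cluster_genes_by_regulators(net) for g in c}
        assert "t" not in clustered


class TestLayouts:
    def _net(self):
        model, _ = generate_model(SynthParams(seed=4, n_genes=40, n_tfs=5, n_sigma=2))
        return build_gene_network(model), model

    def test_elliptical_ring_sizes_on_fixture(self):
        # 1 sigma gene, 2 TFs, 5 pure targets
        m = RegulatoryModel()
        for gid in ("s", "t1", "t2", "a", "b", "c", "d", "e"):
            m.genes[gid] = Gene(id=gid, product_id=f"p_{gid}")
            m.products[f"p_{gid}"] = Product(id=f"p_{gid}", kind="polypeptide", gene_ids=[gid])
        for i, gid in enumerate(("a", "b", "c", "d", "e"), start=1):
            m.transcription_units[f"tu{i}"] = TranscriptionUnit(
                id=f"tu{i}", gene_ids=[gid], promoter_id=f"pm{i}"
            )
            m.promoters[f"pm{i}"] = Promoter(id=f"pm{i}", tu_id=f"tu{i}", sigma_factor_id="p_s")
        m.regulations["r1"] = _tfb("r1", "p_t1", "pm1", "+")
        m.regulations["r2"] = _tfb("r2", "p_t2", "pm2", "-")
        m.reindex()
        # restrict to the genes of interest: s regulates via sigma edges
        net = build_gene_network(m, include={"transcriptional", "sigma"})
        layout = elliptical_layout(net, m)
        rings = {1: set(), 2: set(), 3: set()}
        for g, ring in layout.assignment.items():
            rings[ring].add(g)
        assert rings[1] == {"s"}
        assert rings[2] == {"t1", "t2"}
        assert rings[3] == {"a", "b", "c", "d", "e"}

    def test_dual_role_sigma_and_tf_gene_sits_in_ring_one_only(self):
        m = _promoter_model(_tfb("r1", "p_s", "pm2", "+"), sigma="p_s")
        net = build_gene_network(m, include={"transcriptional", "sigma"})
        layout = elliptical_layout(net, m)
        assert layout.assignment["s"] == 1
        assert list(layout.assignment.values()).count(1) == 1

    def test_layouts_are_total_injective_and_deterministic(self):
        net, model = self._net()
        for fn in (elliptical_layout, layered_layout):
            l1, l2 = fn(net, model), fn(net, model)
            assert l1.coordinates == l2.coordinates
            assert set(l1.coordinates) == net.nodes()
            assert len(set(l1.coordinates.values())) == len(l1.coordinates)

    def test_layered_chain_orders_regulators_top_down(self):
        net = GeneNetwork()
        for g in ("t1", "t2", "g"):
            net.add_node(g)
        net.add_edge("t1", "t2", "activation", {"r1"})
        net.add_edge("t2", "g", "activation", {"r2"})
        layout = layered_layout(net)
        assert layout.assignment["t1"] > layout.assignment["t2"] > layout.assignment["g"]
        assert layout.assignment["g"] == 0

    def test_mutually_regulating_pair_shares_a_layer(self):
        net = GeneNetwork()
        for g in ("t1", "t2", "g"):
            net.add_node(g)
        net.add_edge("t1", "t2", "activation", {"r1"})
        net.add_edge("t2", "t1", "inhibition", {"r2"})
        net.add_edge("t1", "g", "activation", {"r3"})
        layout = layered_layout(net)
        assert layout.assignment["t1"] == layout.assignment["t2"]

    def test_edgeless_network_is_a_single_bottom_layer(self):
        net = GeneNetwork()
        for g in ("a", "b"):
            net.add_node(g)
        layout = layered_layout(net)
        assert set(layout.assignment.values()) == {0}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            layered_layout(GeneNetwork())
        with pytest.raises(ValueError):
            elliptical_layout(GeneNetwork(), RegulatoryModel())


class TestSubnetwork:
    def _chain(self):
        net = GeneNetwork()
        for g in ("a", "b", "c", "d"):
            net.add_node(g)
        net.add_edge("a", "b", "activation", {"r1"})
        net.add_edge("b", "c", "inhibition", {"r2"})
        net.add_edge("c", "a", "activation", {"r3"})  # cycle a->b->c->a
        net.add_edge("c", "d", "unknown", {"r4"})
        return net

    def test_depth_one_regulatees_are_direct_targets(self):
        net = self._chain()
        sub = subnetwork(net, {"a"}, "regulatees", depth=1)
        assert sub.nodes() == {"a", "b"}
        assert sub.edges() == {("a", "b")}

    def test_unbounded_depth_on_a_cycle_terminates_with_whole_cycle(self):
        net = self._chain()
        sub = subnetwork(net, {"a"}, "regulatees", depth=None)
        assert sub.nodes() == {"a", "b", "c", "d"}

    def test_all_seeds_identity(self):
        net = self._chain()
        assert subnetwork(net, net.nodes(), "both", depth=None) == net

    def test_unknown_seed_named_in_error(self):
        with pytest.raises(ValueError, match="ghost"):
            subnetwork(self._chain(), {"ghost"}, "regulatees", depth=1)

    def test_regulators_direction_follows_edges_backwards(self):
        net = self._chain()
        sub = subnetwork(net, {"d"}, "regulators", depth=1)
        assert sub.nodes() == {"c", "d"}

    @pytest.mark.parametrize("seed", [3, 12])
    def test_unbounded_reach_equals_matrix_power_closure(self, seed):
        """Transitive closure via boolean matrix powers agrees with BFS."""
        model, _ = generate_model(SynthParams(seed=seed, n_genes=30, n_tfs=4, n_sigma=1))
        net = build_gene_network(model)
        nodes = sorted(net.nodes())
        idx = {g: i for i, g in enumerate(nodes)}
        n = len(nodes)
        A = np.zeros((n, n), dtype=bool)
        for u, v in net.edges():
            A[idx[u], idx[v]] = True
        reach = A.copy()
        for _ in range(n):
            reach = reach | (reach @ A)
        seed_gene = nodes[0]
        expected = {nodes[j] for j in range(n) if reach[idx[seed_gene], j]} | {seed_gene}
        sub = subnetwork(net, {seed_gene}, "regulatees", depth=None)
        assert sub.nodes() == expected
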