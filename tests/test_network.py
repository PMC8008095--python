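"""Network expansion, knockouts, diffs, reachability and enzyme inference."""

import random

import pytest

from gangliosim import (GangliosimError, SimulationConfig, Structure,
                        UnreachableTargetError, downstream_products,
                        expand_network, infer_required_enzymes, knockout_scan,
                        network_diff, series_of)

GALA_ARM = {"LT", "[S3]LT", "[S8S3]LT", "[S8S8S3]LT"}


class TestExpansion:
    def test_full_network_counts(self, wild_type):
        assert wild_type.n_products == 41
        assert wild_type.n_reactions == 49
        assert wild_type.iterations_run == 11
        assert not wild_type.truncated

    def test_first_iteration(self):
        net = expand_network(SimulationConfig(max_iterations=1))
        assert set(net.products) == {"GT", "LT"}
        assert net.n_reactions == 2
        assert net.truncated  # the frontier was still productive at the cap

    def test_restricted_seed_and_knockouts(self):
        cfg = SimulationConfig(seed=Structure.parse("L4GT"),
                               knockouts=frozenset({4, 5, 6, 9, 10}))
        net = expand_network(cfg)
        assert set(net.products) == {"Vb4L4GT", "L3Vb4L4GT"}  # GA2, GA1
        assert net.n_reactions == 2

    def test_generations_increase_along_edges(self, wild_type):
        for ev in wild_type.events():
            gen_sub = wild_type.generation(ev.substrate.abbreviated)
            gen_prod = wild_type.generation(ev.product.abbreviated)
            assert gen_prod <= gen_sub + 1

    def test_every_product_has_a_producer(self, wild_type):
        for nid in wild_type.products:
            assert wild_type.graph.in_degree(nid) >= 1

    def test_rule_order_is_irrelevant(self, wild_type, ruleset):
        rules = list(ruleset)
        random.Random(20210323).shuffle(rules)
        net = expand_network(SimulationConfig(ruleset=tuple(rules)))
        assert set(net.graph.nodes) == set(wild_type.graph.nodes)
        assert net.edge_triples() == wild_type.edge_triples()
        assert net.iterations_run == wild_type.iterations_run

    def test_mass_balance_on_every_edge(self, wild_type):
        for ev in wild_type.events():
            assert len(ev.product) == len(ev.substrate) + 1
            added = ev.donor.split("-")[1]
            assert (ev.product.count_residues(added)
                    == ev.substrate.count_residues(added) + 1)

    def test_sialyl_chains_never_exceed_three(self, wild_type):
        assert all("S8S8S8" not in nid for nid in wild_type.node_ids())

    def test_invalid_config_rejected(self):
        with pytest.raises(GangliosimError):
            SimulationConfig(max_iterations=0)
        with pytest.raises(GangliosimError):
            SimulationConfig(knockouts=frozenset({12}))


class TestOracle:
    def test_engine_matches_closed_form_enumeration(self, wild_type, reference):
        assert set(wild_type.graph.nodes) == set(reference.graph.nodes)
        assert wild_type.edge_triples() == reference.edge_triples()

    def test_generations_match(self, wild_type, reference):
        for nid in reference.node_ids():
            assert wild_type.generation(nid) == reference.generation(nid)

    def test_reference_counts(self, reference):
        assert reference.n_products == 41
        assert reference.n_reactions == 49
        full_core = [n for n in reference.products
                     if series_of(n) not in (None, "Gala")]
        assert len(full_core) == 28

    def test_series_partition(self, wild_type):
        counts = {}
        for nid in wild_type.products:
            counts.setdefault(series_of(nid), []).append(nid)
        assert sorted(counts["Gala"]) == sorted(GALA_ARM)
        assert [len(counts[s]) for s in ("0", "a", "b", "c")] == [7, 7, 7, 7]
        assert len(counts[None]) == 9  # core intermediates on the Glc arm


class TestKnockouts:
    def test_severe_knockouts(self):
        nets = knockout_scan(SimulationConfig())
        # loss of ceramide glucosyltransferase leaves only the Gala arm
        assert set(nets[1].products) == GALA_ARM
        assert nets[1].n_reactions == 4
        assert nets[3].n_reactions == 5
        assert nets[7].n_reactions == 9

    def test_scan_includes_wild_type_reference(self, wild_type):
        nets = knockout_scan(SimulationConfig())
        assert nets[0].edge_triples() == wild_type.edge_triples()
        assert sorted(nets) == list(range(0, 11))

    def test_ko4_leaves_only_0_series_sialylated(self, wild_type):
        nets = knockout_scan(SimulationConfig())
        survivors = [nid for nid in nets[4].products
                     if Structure.parse(nid).count_residues("S")]
        assert survivors  # the 0-series route is intact
        assert all(series_of(nid) == "0" for nid in survivors)

    def test_ko6_eliminates_the_c_series(self, wild_type):
        nets = knockout_scan(SimulationConfig())
        diff = network_diff(wild_type, nets[6])
        c_series = {n for n in wild_type.products if series_of(n) == "c"}
        assert c_series <= diff.nodes_lost
        assert not any(series_of(n) == "c" for n in nets[6].products)

    def test_knockout_monotonicity(self, wild_type):
        nets = knockout_scan(SimulationConfig())
        for number in range(1, 11):
            ko = nets[number]
            assert set(ko.graph.nodes) <= set(wild_type.graph.nodes)
            assert ko.edge_triples() <= wild_type.edge_triples()

    def test_nested_knockouts_are_monotone(self):
        small = expand_network(SimulationConfig(knockouts=frozenset({4})))
        smaller = expand_network(SimulationConfig(knockouts=frozenset({4, 7})))
        assert set(smaller.graph.nodes) <= set(small.graph.nodes)
        assert smaller.edge_triples() <= small.edge_triples()


class TestDiff:
    def test_self_diff_is_empty(self, wild_type):
        assert network_diff(wild_type, wild_type).empty

    def test_diff_against_ko4(self, wild_type):
        nets = knockout_scan(SimulationConfig())
        diff = network_diff(wild_type, nets[4])
        assert not diff.nodes_gained and not diff.edges_gained
        # every a-, b-, c-series and sialylated Gala structure is lost
        for nid in wild_type.products:
            if (series_of(nid) in ("a", "b", "c")
                    or (series_of(nid) == "Gala"
                        and Structure.parse(nid).count_residues("S"))):
                assert nid in diff.nodes_lost


class TestReachability:
    def test_downstream_of_galcer(self, wild_type):
        assert downstream_products(wild_type, "LT") == GALA_ARM - {"LT"}

    def test_leaves_have_no_downstream(self, wild_type):
        gs1ca = "S8S8S3L3[S6]Vb4[S8S8S3]L4GT"
        assert downstream_products(wild_type, gs1ca) == set()

    def test_downstream_of_glccer(self, wild_type):
        assert len(downstream_products(wild_type, "GT")) == 36

    def test_unknown_node_rejected(self, wild_type):
        with pytest.raises(GangliosimError):
            downstream_products(wild_type, "S3L4GT")


class TestInference:
    def test_gm1a_requires_five_enzymes(self):
        result = infer_required_enzymes("L3Vb4[S3]L4GT")
        assert sorted(result.enzymes) == [1, 3, 4, 7, 8]
        assert [e.triple for e in result.path] == [
            ("T", 1, "GT"), ("GT", 3, "L4GT"), ("L4GT", 4, "[S3]L4GT"),
            ("[S3]L4GT", 7, "Vb4[S3]L4GT"),
            ("Vb4[S3]L4GT", 8, "L3Vb4[S3]L4GT")]

    def test_single_step(self):
        result = infer_required_enzymes("GT")
        assert result.enzymes == frozenset({1})

    def test_unbracketed_sialylation_is_unreachable(self):
        with pytest.raises(UnreachableTargetError) as err:
            infer_required_enzymes("S3L4GT")
        assert err.value.blocked == "S3L4GT"

    def test_every_network_node_is_inferable_and_regenerable(self, wild_type,
                                                             ruleset):
        all_numbers = {r.number for r in ruleset}
        for nid in wild_type.products:
            result = infer_required_enzymes(nid)
            # re-simulate with exactly the inferred enzymes
            cfg = SimulationConfig(
                knockouts=frozenset(all_numbers - result.enzymes))
            assert nid in expand_network(cfg)
            # the witness path starts at ceramide and ends at the target
            assert result.path[0].substrate.abbreviated == "T"
            assert result.path[-1].product.abbreviated == nid
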