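"""Graph parsing, validation and circuit decomposition."""

import numpy as np
import pytest

from pathcircuit import (
    ACTIVATION,
    INHIBITION,
    CircuitDecompositionError,
    PathwayGraph,
    PathwayNode,
    PathwayParseError,
    PathwayValidationError,
    SignedEdge,
    circuit_catalog,
    extract_all_circuits,
    extract_effector_circuit,
    extract_elementary_circuit,
    load_pathway,
    resolve_effectors,
    resolve_receptors,
    save_pathway,
)
from pathcircuit.studies import random_dag_circuit, simple_path_members

from conftest import make_graph


class TestLoading:
    def test_sif_parse(self, tmp_path):
        p = tmp_path / "toy.sif"
        p.write_text("A\tactivation\tB\nB\tactivation\tC\n")
        g = load_pathway(p)
        assert set(g.nodes) == {"A", "B", "C"}
        assert len(g.edges) == 2
        assert all(e.sign == ACTIVATION for e in g.edges)

    def test_sif_unknown_sign_rejected(self, tmp_path):
        p = tmp_path / "bad.sif"
        p.write_text("A\tactivates\tB\n")
        with pytest.raises(PathwayParseError, match="activates"):
            load_pathway(p)

    def test_sif_node_sidecar(self, tmp_path):
        (tmp_path / "toy.sif").write_text("A\tactivation\tB\n")
        (tmp_path / "toy.nodes.tsv").write_text(
            "A\tRecA\tg1,g2\t1\t0\nB\tEffB\tg3\t0\t1\n")
        g = load_pathway(tmp_path / "toy.sif")
        assert g.nodes["A"].genes == ("g1", "g2")
        assert g.nodes["A"].receptor is True
        assert g.nodes["B"].effector is True
        assert g.nodes["B"].label == "EffB"

    def test_json_round_trip(self, tmp_path, diamond_graph):
        path = tmp_path / "d.json"
        save_pathway(diamond_graph, path)
        g = load_pathway(path)
        assert g.to_dict() == diamond_graph.to_dict()

    def test_dangling_edge_rejected(self):
        with pytest.raises(PathwayValidationError, match="Z"):
            PathwayGraph("P", "P", {"A": PathwayNode("A")},
                         [SignedEdge("A", "Z", ACTIVATION)])

    def test_duplicate_edge_rejected(self):
        nodes = {n: PathwayNode(n) for n in "AB"}
        with pytest.raises(PathwayValidationError, match="duplicate"):
            PathwayGraph("P", "P", nodes, [
                SignedEdge("A", "B", ACTIVATION),
                SignedEdge("A", "B", INHIBITION),
            ])

    def test_self_loop_rejected_by_default(self):
        nodes = {"A": PathwayNode("A")}
        with pytest.raises(PathwayValidationError, match="self-loop"):
            PathwayGraph("P", "P", nodes, [SignedEdge("A", "A", ACTIVATION)])
        PathwayGraph("P", "P", nodes, [SignedEdge("A", "A", ACTIVATION)],
                     allow_self_loops=True)

    def test_duplicate_genes_rejected(self):
        with pytest.raises(PathwayValidationError, match="duplicate genes"):
            PathwayNode("A", genes=("g1", "g1"))


class TestRoleResolution:
    def test_topology_fallback(self, chain_graph):
        assert resolve_receptors(chain_graph) == {"A"}
        assert resolve_effectors(chain_graph) == {"C"}

    def test_annotation_wins_over_topology(self):
        g = make_graph([("A", ACTIVATION, "B"), ("B", ACTIVATION, "C")],
                       receptor_flags={"A": True, "B": True, "C": False})
        assert resolve_receptors(g) == {"A", "B"}

    def test_diamond_effector(self, diamond_graph):
        assert resolve_effectors(diamond_graph) == {"D"}

    def test_pure_cycle_has_no_roles(self):
        g = make_graph([("A", ACTIVATION, "B"), ("B", ACTIVATION, "A")])
        with pytest.raises(CircuitDecompositionError, match="receptor"):
            resolve_receptors(g)
        with pytest.raises(CircuitDecompositionError, match="effector"):
            resolve_effectors(g)


class TestExtraction:
    def test_diamond_full_membership(self, diamond_graph):
        c = extract_effector_circuit(diamond_graph, "D")
        assert c.member_nodes == frozenset("ABCD")
        assert len(c.member_edges) == 4
        assert c.receptors == frozenset("A")
        assert c.circuit_id == "P:D"

    def test_disconnected_stub_excluded(self):
        g = make_graph([("A", ACTIVATION, "B"), ("B", ACTIVATION, "C"),
                        ("D", ACTIVATION, "E")])
        c = extract_effector_circuit(g, "C")
        assert c.member_nodes == frozenset("ABC")

    def test_unreachable_effector_errors(self):
        g = make_graph([("A", ACTIVATION, "B"), ("C", ACTIVATION, "D")],
                       receptor_flags={"A": True},
                       effector_flags={"D": True})
        with pytest.raises(CircuitDecompositionError, match="reaches"):
            extract_effector_circuit(g, "D")

    def test_chain_yields_single_circuit(self, chain_graph):
        assert len(extract_all_circuits(chain_graph)) == 1

    def test_shared_upstream_duplicated_across_effectors(self):
        g = make_graph([("A", ACTIVATION, "B"), ("B", ACTIVATION, "C"),
                        ("B", ACTIVATION, "E")])
        circuits = extract_all_circuits(g)
        assert len(circuits) == 2
        for c in circuits:
            assert {"A", "B"} <= set(c.member_nodes)

    def test_elementary_excludes_private_branch(self):
        g = make_graph([("A1", ACTIVATION, "M"), ("A2", ACTIVATION, "N"),
                        ("M", ACTIVATION, "D"), ("N", ACTIVATION, "D")])
        c = extract_elementary_circuit(g, "A1", "D")
        assert c.member_nodes == frozenset({"A1", "M", "D"})
        assert "A2" not in c.member_nodes

    def test_inhibition_edges_carry_membership(self):
        g = make_graph([("A", ACTIVATION, "B"), ("B", INHIBITION, "C")])
        c = extract_effector_circuit(g, "C")
        assert c.member_nodes == frozenset("ABC")

    @pytest.mark.parametrize("seed", range(20))
    def test_membership_matches_simple_path_enumeration(self, seed):
        """Reachability-based membership equals exhaustive path enumeration
        on random DAGs."""
        rng = np.random.default_rng(seed)
        graph, circuit, _ = random_dag_circuit(rng, max_nodes=10)
        nodes, edges = simple_path_members(
            graph, set(circuit.receptors) | set(resolve_receptors(graph)),
            circuit.effector)
        assert circuit.member_nodes == frozenset(nodes)
        assert {(e.source, e.target) for e in circuit.member_edges} == edges

    @pytest.mark.parametrize("seed", range(10))
    def test_effector_circuit_is_union_of_elementary(self, seed):
        rng = np.random.default_rng(100 + seed)
        graph, circuit, _ = random_dag_circuit(rng, max_nodes=10)
        union_nodes: set = set()
        union_edges: set = set()
        for r in circuit.receptors:
            elem = extract_elementary_circuit(graph, r, circuit.effector)
            union_nodes |= set(elem.member_nodes)
            union_edges |= set(elem.member_edges)
        assert union_nodes == set(circuit.member_nodes)
        assert union_edges == set(circuit.member_edges)

    @pytest.mark.parametrize("seed", range(10))
    def test_extraction_idempotent(self, seed):
        rng = np.random.default_rng(200 + seed)
        graph, circuit, _ = random_dag_circuit(rng)
        sub = PathwayGraph(
            pathway_id=circuit.pathway_id, name="sub",
            nodes={n: graph.nodes[n] for n in sorted(circuit.member_nodes)},
            edges=list(circuit.member_edges),
        )
        again = extract_effector_circuit(sub, circuit.effector)
        assert again.member_nodes == circuit.member_nodes
        assert set(again.member_edges) == set(circuit.member_edges)

    @pytest.mark.parametrize("seed", range(10))
    def test_one_circuit_per_effector_with_receptor(self, seed):
        from pathcircuit.synthetic import PathwayShape, generate_pathway

        rng = np.random.default_rng(300 + seed)
        shape = PathwayShape(n_nodes=14, n_receptors=3, n_effectors=4)
        g = generate_pathway(shape, rng)
        circuits = extract_all_circuits(g)
        assert len(circuits) == len(resolve_effectors(g))
        assert all(len(c.receptors) >= 1 for c in circuits)
        assert [c.circuit_id for c in circuits] == \
            sorted(c.circuit_id for c in circuits)


def test_circuit_catalog_shape(diamond_graph):
    table = circuit_catalog(extract_all_circuits(diamond_graph))
    assert list(table.columns) == ["circuit_id", "pathway_id",
                                   "effector_label", "n_receptors",
                                   "n_nodes", "n_edges"]
    assert table.loc[0, "n_nodes"] == 4
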