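import numpy as np
import pandas as pd
import pytest

from pathcircuit import (
    ACTIVATION,
    INHIBITION,
    PathwayGraph,
    PathwayNode,
    SignedEdge,
    SyntheticSpec,
)


def make_graph(edges, pathway_id="P", genes=None, receptor_flags=None,
               effector_flags=None, allow_self_loops=False):
    """Build a PathwayGraph from (source, sign, target) triples."""
    node_ids = sorted({e[0] for e in edges} | {e[2] for e in edges})
    genes = genes or {}
    receptor_flags = receptor_flags or {}
    effector_flags = effector_flags or {}
    nodes = {
        n: PathwayNode(
            node_id=n,
            genes=tuple(genes.get(n, ())),
            receptor=receptor_flags.get(n),
            effector=effector_flags.get(n),
        )
        for n in node_ids
    }
    edge_list = [SignedEdge(s, t, sign) for s, sign, t in edges]
    return PathwayGraph(pathway_id=pathway_id, name=pathway_id, nodes=nodes,
                        edges=edge_list, allow_self_loops=allow_self_loops)


@pytest.fixture
def chain_graph():
    return make_graph([("A", ACTIVATION, "B"), ("B", ACTIVATION, "C")])


@pytest.fixture
def diamond_graph():
    return make_graph([
        ("A", ACTIVATION, "B"), ("A", ACTIVATION, "C"),
        ("B", ACTIVATION, "D"), ("C", ACTIVATION, "D"),
    ])


@pytest.fixture
def feedback_graph():
    # receptor A feeds a B<->C positive feedback loop; D is the effector
    return make_graph([
        ("A", ACTIVATION, "B"), ("B", ACTIVATION, "C"),
        ("C", ACTIVATION, "B"), ("C", ACTIVATION, "D"),
    ])


@pytest.fixture
def oscillator_graph():
    # negative feedback B<->C: undamped Jacobi cycles with period 4 at v=1
    return make_graph([
        ("A", ACTIVATION, "B"), ("B", ACTIVATION, "C"),
        ("C", INHIBITION, "B"), ("C", ACTIVATION, "D"),
    ])


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(seed=11, n_samples=40, n_case=20, n_pathways=3)


@pytest.fixture(scope="session")
def small_bundle(small_spec, tmp_path_factory):
    from pathcircuit import generate_dataset

    outdir = tmp_path_factory.mktemp("bundle")
    bundle = generate_dataset(small_spec, outdir)
    return bundle, outdir
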