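"""Signed pathway graphs and their decomposition into signaling circuits.

A pathway is a directed graph whose nodes house zero or more genes and whose
edges are signed (activation or inhibition).  Signal enters at *receptor*
nodes and is read out at *effector* nodes.  The unit of downstream analysis
is the **circuit**: the subgraph connecting receptor(s) to a single effector.

Two circuit flavors are exposed:

* an *effector circuit* joins one effector to **all** receptors that can
  transduce signal to it;
* an *elementary circuit* joins exactly one receptor to one effector.

Membership is sign-agnostic — inhibition edges transport (inhibitory) signal
and therefore belong to circuits.  On graphs with feedback loops membership
is defined by reachability (reachable from a receptor AND reaching the
effector), which coincides with simple-path membership on DAGs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

ACTIVATION = "activation"
INHIBITION = "inhibition"
_SIGNS = (ACTIVATION, INHIBITION)


class PathwayParseError(ValueError):
    """A pathway file could not be parsed (bad sign label, missing field...)."""


class PathwayValidationError(ValueError):
    """A structurally invalid pathway (dangling edge, duplicate id...)."""


class CircuitDecompositionError(ValueError):
    """Receptors/effectors cannot be resolved or do not connect."""


@dataclass(frozen=True)
class PathwayNode:
    """A pathway node: a protein (complex) backed by zero or more genes.

    ``receptor`` / ``effector`` are tri-state annotations: ``True``/``False``
    when the source asserts the role, ``None`` when it is silent (role then
    falls back to topology).
    """

    node_id: str
    label: str = ""
    genes: tuple[str, ...] = ()
    receptor: bool | None = None
    effector: bool | None = None

    def __post_init__(self) -> None:
        if not self.node_id:
            raise PathwayValidationError("node_id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.node_id)
        if len(set(self.genes)) != len(self.genes):
            raise PathwayValidationError(
                f"node {self.node_id!r}: duplicate genes in {self.genes}"
            )


@dataclass(frozen=True, order=True)
class SignedEdge:
    source: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in _SIGNS:
            raise PathwayParseError(
                f"edge {self.source}->{self.target}: unknown sign {self.sign!r} "
                f"(expected one of {_SIGNS})"
            )


@dataclass
class PathwayGraph:
    """A validated signed pathway graph."""

    pathway_id: str
    name: str
    nodes: dict[str, PathwayNode]
    edges: list[SignedEdge]
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise PathwayValidationError(
                        f"pathway {self.pathway_id!r}: edge {e.source}->{e.target} "
                        f"references undeclared node {endpoint!r}"
                    )
            if e.source == e.target and not self.allow_self_loops:
                raise PathwayValidationError(
                    f"pathway {self.pathway_id!r}: self-loop on {e.source!r} "
                    "(pass allow_self_loops=True to permit; self-loops are "
                    "ignored for circuit membership)"
                )
            key = (e.source, e.target)
            if key in seen:
                raise PathwayValidationError(
                    f"pathway {self.pathway_id!r}: duplicate edge {e.source}->{e.target}"
                )
            seen.add(key)

    # -- conversions ------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id, name=self.name)
        for n in self.nodes.values():
            g.add_node(n.node_id, label=n.label, genes=n.genes,
                       receptor=n.receptor, effector=n.effector)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "name": self.name,
            "nodes": [
                {
                    "id": n.node_id,
                    "label": n.label,
                    "genes": list(n.genes),
                    "receptor": n.receptor,
                    "effector": n.effector,
                }
                for n in self.nodes.values()
            ],
            "edges": [
                {"source": e.source, "target": e.target, "sign": e.sign}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping, allow_self_loops: bool = False) -> "PathwayGraph":
        try:
            nodes = {}
            for nd in data["nodes"]:
                node = PathwayNode(
                    node_id=str(nd["id"]),
                    label=str(nd.get("label") or nd["id"]),
                    genes=tuple(nd.get("genes") or ()),
                    receptor=nd.get("receptor"),
                    effector=nd.get("effector"),
                )
                if node.node_id in nodes:
                    raise PathwayValidationError(
                        f"duplicate node id {node.node_id!r}"
                    )
                nodes[node.node_id] = node
            edges = [
                SignedEdge(str(ed["source"]), str(ed["target"]), str(ed["sign"]))
                for ed in data["edges"]
            ]
            return cls(
                pathway_id=str(data["pathway_id"]),
                name=str(data.get("name", data["pathway_id"])),
                nodes=nodes,
                edges=edges,
                allow_self_loops=allow_self_loops,
            )
        except KeyError as exc:
            raise PathwayParseError(f"missing required field {exc}") from exc


@dataclass(frozen=True)
class Circuit:
    """A receptor→effector subgraph of one pathway; the unit of activity."""

    circuit_id: str
    pathway_id: str
    effector: str
    effector_label: str
    receptors: frozenset[str]
    member_nodes: frozenset[str]
    member_edges: tuple[SignedEdge, ...]

    def __post_init__(self) -> None:
        if self.effector not in self.member_nodes:
            raise PathwayValidationError("effector must be a member node")
        if not self.receptors:
            raise PathwayValidationError("circuit must have at least one receptor")
        if not self.receptors <= self.member_nodes:
            raise PathwayValidationError("receptors must be member nodes")

    def subgraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.member_nodes))
        for e in self.member_edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g


# ---------------------------------------------------------------------------
# loading


def _parse_sif(path: Path) -> list[SignedEdge]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PathwayParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            source, sign, target = (p.strip() for p in parts)
            if sign not in _SIGNS:
                raise PathwayParseError(
                    f"{path}:{lineno}: unknown sign label {sign!r} "
                    f"(expected one of {_SIGNS})"
                )
            edges.append(SignedEdge(source, target, sign))
    return edges


def _parse_node_sidecar(path: Path) -> dict[str, PathwayNode]:
    nodes: dict[str, PathwayNode] = {}

    def tristate(tok: str) -> bool | None:
        tok = tok.strip()
        if tok in ("", "NA", "na", "None"):
            return None
        if tok in ("0", "1"):
            return tok == "1"
        raise PathwayParseError(f"{path}: bad flag value {tok!r} (expected 0/1/NA)")

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise PathwayParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            node_id, label, genes_csv, recep, effec = parts
            genes = tuple(g for g in genes_csv.split(",") if g.strip())
            if node_id in nodes:
                raise PathwayValidationError(
                    f"{path}:{lineno}: duplicate node id {node_id!r}"
                )
            nodes[node_id] = PathwayNode(
                node_id=node_id, label=label or node_id, genes=genes,
                receptor=tristate(recep), effector=tristate(effec),
            )
    return nodes


def load_pathway(
    path: str | Path,
    format: str | None = None,
    nodes_path: str | Path | None = None,
    allow_self_loops: bool = False,
) -> PathwayGraph:
    """Load a pathway from JSON (canonical) or a SIF-like edge list.

    ``format`` is inferred from the suffix when not given.  For SIF inputs a
    node-metadata sidecar (``<stem>.nodes.tsv`` next to the edge file, or an
    explicit ``nodes_path``) supplies labels/genes/role flags; without it,
    bare gene-less nodes are derived from the edge list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sif"
    if format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise PathwayParseError(f"{path}: invalid JSON: {exc}") from exc
        return PathwayGraph.from_dict(data, allow_self_loops=allow_self_loops)
    if format == "sif":
        edges = _parse_sif(path)
        sidecar = Path(nodes_path) if nodes_path else path.with_suffix(".nodes.tsv")
        if sidecar.exists():
            nodes = _parse_node_sidecar(sidecar)
        else:
            ids = sorted({e.source for e in edges} | {e.target for e in edges})
            nodes = {i: PathwayNode(node_id=i) for i in ids}
        return PathwayGraph(
            pathway_id=path.stem, name=path.stem, nodes=nodes, edges=edges,
            allow_self_loops=allow_self_loops,
        )
    raise ValueError(f"unknown pathway format {format!r}")


def save_pathway(graph: PathwayGraph, path: str | Path) -> None:
    """Write the canonical JSON representation (round-trips via load_pathway)."""
    with open(path, "w") as fh:
        json.dump(graph.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# receptor / effector resolution

def _signless(graph: PathwayGraph) -> nx.DiGraph:
    """Directed connectivity graph, self-loops dropped."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(
        (e.source, e.target) for e in graph.edges if e.source != e.target
    )
    return g


def resolve_receptors(graph: PathwayGraph) -> set[str]:
    """Receptor nodes: annotated ones if any annotation is present anywhere,
    otherwise all nodes with in-degree zero."""
    flagged = {n.node_id for n in graph.nodes.values() if n.receptor}
    if any(n.receptor is not None for n in graph.nodes.values()):
        result = flagged
    else:
        g = _signless(graph)
        result = {n for n in g.nodes if g.in_degree(n) == 0}
    if not result:
        raise CircuitDecompositionError(
            f"pathway {graph.pathway_id!r}: no receptor resolvable "
            "(no annotated receptor and no in-degree-0 node)"
        )
    return result


def resolve_effectors(graph: PathwayGraph) -> set[str]:
    """Effector nodes: annotated ones when annotation is present, otherwise
    all nodes with out-degree zero."""
    flagged = {n.node_id for n in graph.nodes.values() if n.effector}
    if any(n.effector is not None for n in graph.nodes.values()):
        result = flagged
    else:
        g = _signless(graph)
        result = {n for n in g.nodes if g.out_degree(n) == 0}
    if not result:
        raise CircuitDecompositionError(
            f"pathway {graph.pathway_id!r}: no effector resolvable "
            "(no annotated effector and no out-degree-0 node)"
        )
    return result


# ---------------------------------------------------------------------------
# circuit extraction

def _extract(
    graph: PathwayGraph,
    receptors: set[str],
    effector: str,
    circuit_id: str,
) -> Circuit:
    g = _signless(graph)
    forward: set[str] = set()
    for r in receptors:
        if r in g:
            forward.add(r)
            forward |= nx.descendants(g, r)
    backward = {effector} | nx.ancestors(g, effector)
    members = forward & backward
    reaching = receptors & members
    if effector not in members or not reaching:
        raise CircuitDecompositionError(
            f"pathway {graph.pathway_id!r}: no receptor among {sorted(receptors)} "
            f"reaches effector {effector!r}"
        )
    edges = tuple(sorted(
        e for e in graph.edges
        if e.source != e.target and e.source in members and e.target in members
    ))
    return Circuit(
        circuit_id=circuit_id,
        pathway_id=graph.pathway_id,
        effector=effector,
        effector_label=graph.nodes[effector].label,
        receptors=frozenset(reaching),
        member_nodes=frozenset(members),
        member_edges=edges,
    )


def extract_effector_circuit(graph: PathwayGraph, effector: str) -> Circuit:
    """Circuit connecting ``effector`` to every receptor that reaches it."""
    if effector not in graph.nodes:
        raise CircuitDecompositionError(
            f"pathway {graph.pathway_id!r}: unknown effector node {effector!r}"
        )
    receptors = resolve_receptors(graph)
    label = graph.nodes[effector].label
    return _extract(graph, receptors, effector,
                    circuit_id=f"{graph.pathway_id}:{label}")


def extract_elementary_circuit(
    graph: PathwayGraph, receptor: str, effector: str
) -> Circuit:
    """Circuit connecting exactly one receptor to one effector."""
    for node in (receptor, effector):
        if node not in graph.nodes:
            raise CircuitDecompositionError(
                f"pathway {graph.pathway_id!r}: unknown node {node!r}"
            )
    cid = f"{graph.pathway_id}:{graph.nodes[receptor].label}->{graph.nodes[effector].label}"
    return _extract(graph, {receptor}, effector, circuit_id=cid)


def extract_all_circuits(
    graph: PathwayGraph, return_failures: bool = False
) -> list[Circuit] | tuple[list[Circuit], dict[str, str]]:
    """One effector circuit per resolvable effector, sorted by circuit id.

    Effectors no receptor reaches are collected into a failure report
    instead of aborting the whole decomposition; pass
    ``return_failures=True`` to receive it alongside the circuits.
    """
    receptors = resolve_receptors(graph)
    effectors = sorted(
        resolve_effectors(graph),
        key=lambda n: (graph.nodes[n].label, n),
    )
    circuits: list[Circuit] = []
    failures: dict[str, str] = {}
    label_counts: dict[str, int] = {}
    for eff in effectors:
        label = graph.nodes[eff].label
        label_counts[label] = label_counts.get(label, 0) + 1
        cid = f"{graph.pathway_id}:{label}"
        if label_counts[label] > 1:  # disambiguate colliding labels
            cid = f"{cid}#{label_counts[label]}"
        try:
            circuits.append(_extract(graph, receptors, eff, circuit_id=cid))
        except CircuitDecompositionError as exc:
            failures[eff] = str(exc)
    circuits.sort(key=lambda c: c.circuit_id)
    if return_failures:
        return circuits, failures
    return circuits


def circuit_catalog(circuits: Iterable[Circuit]):
    """Catalog table: one row per circuit with size summaries."""
    import pandas as pd

    rows = [
        {
            "circuit_id": c.circuit_id,
            "pathway_id": c.pathway_id,
            "effector_label": c.effector_label,
            "n_receptors": len(c.receptors),
            "n_nodes": len(c.member_nodes),
            "n_edges": len(c.member_edges),
        }
        for c in circuits
    ]
    return pd.DataFrame(rows, columns=[
        "circuit_id", "pathway_id", "effector_label",
        "n_receptors", "n_nodes", "n_edges",
    ])
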