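"""Synthetic pathway/expression/survival generator with known ground truth.

Every pipeline stage can be exercised without external data: the generator
emits random layered signed pathway graphs with designated receptors and
effectors, a gene × sample expression matrix on a log2(1 + FPKM)-like scale
with optional group-wise shifts planted on chosen circuits' member genes,
and survival outcomes whose hazard depends on the top activity decile of a
planted circuit — mirroring the stratification design of the survival
screen.

Effects are planted on genes, not on activities, so recovering them
genuinely exercises normalization, node summarization and propagation.
All randomness flows from a single integer seed; regeneration from the
written manifest reproduces a bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import expression_prep, propagation, survival as surv
from .pathway_model import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    PathwayGraph,
    PathwayNode,
    SignedEdge,
    extract_all_circuits,
    save_pathway,
)


@dataclass(frozen=True)
class PathwayShape:
    """Shape parameters of one random layered pathway graph."""

    n_nodes: int = 12
    n_receptors: int = 2
    n_effectors: int = 2
    n_layers: int = 4
    p_edge: float = 0.35
    inhibition_fraction: float = 0.25
    allow_cycles: bool = False
    back_edge_prob: float = 0.15
    genes_per_node: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.n_nodes < self.n_receptors + self.n_effectors:
            raise ValueError("n_nodes must cover receptors and effectors")
        if self.n_receptors < 1 or self.n_effectors < 1:
            raise ValueError("need at least one receptor and one effector")
        for p in (self.p_edge, self.inhibition_fraction, self.back_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.genes_per_node
        if not 1 <= lo <= hi:
            raise ValueError("genes_per_node must be a (lo, hi) range, lo >= 1")


@dataclass(frozen=True)
class PlantedShift:
    """A group-wise expression shift on one circuit's member genes.

    ``delta`` is the shift in units of each gene's between-sample range;
    applied to case samples only, in the given direction.
    """

    circuit: str | int
    delta: float = 0.3
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")


@dataclass(frozen=True)
class PlantedSurvival:
    """Hazard elevated by ``hazard_ratio`` for the top activity decile of
    one circuit; uniform censoring calibrated to ``censoring_rate``."""

    circuit: str | int = 0
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard ratio and baseline hazard must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic study; the seed fixes everything."""

    seed: int = 0
    n_samples: int = 120
    n_case: int = 60
    n_pathways: int = 10
    shape: PathwayShape = field(default_factory=PathwayShape)
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    planted_shifts: tuple[PlantedShift, ...] = ()
    planted_survival: PlantedSurvival | None = None

    def __post_init__(self) -> None:
        if not 2 <= self.n_case <= self.n_samples - 2:
            raise ValueError("each group needs at least 2 samples")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")

    # manifest round-trip ------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        shape = dict(d.pop("shape"))
        shape["genes_per_node"] = tuple(shape["genes_per_node"])
        shifts = tuple(PlantedShift(**s) for s in d.pop("planted_shifts"))
        ps = d.pop("planted_survival")
        return cls(
            shape=PathwayShape(**shape),
            planted_shifts=shifts,
            planted_survival=PlantedSurvival(**ps) if ps else None,
            **d,
        )


# ---------------------------------------------------------------------------
# graphs

def generate_pathway(
    shape: PathwayShape, rng: np.random.Generator, pathway_id: str = "P01"
) -> PathwayGraph:
    """One random layered signed pathway graph.

    Receptors fill the first layer, effectors the last; every non-receptor
    node is guaranteed an incoming edge from the previous layer and every
    non-effector an outgoing edge, so each effector is reachable from at
    least one receptor and decomposition always yields circuits.  With
    ``allow_cycles`` additional backward edges between middle layers create
    feedback loops.
    """
    nr, ne = shape.n_receptors, shape.n_effectors
    n_middle = shape.n_nodes - nr - ne
    node_ids = [f"{pathway_id}n{i:02d}" for i in range(shape.n_nodes)]
    receptors = node_ids[:nr]
    effectors = node_ids[nr:nr + ne]
    middles = node_ids[nr + ne:]

    n_mid_layers = max(1, shape.n_layers - 2) if n_middle else 0
    layers: list[list[str]] = [list(receptors)]
    mid_layers: list[list[str]] = [[] for _ in range(n_mid_layers)]
    for i, m in enumerate(middles):
        mid_layers[i % n_mid_layers].append(m)
    layers.extend(l for l in mid_layers if l)
    layers.append(list(effectors))

    layer_of = {n: i for i, layer in enumerate(layers) for n in layer}
    edges: dict[tuple[str, str], str] = {}

    def sign() -> str:
        return INHIBITION if rng.random() < shape.inhibition_fraction else ACTIVATION

    # random forward edges
    for u in node_ids:
        if u in effectors:
            continue
        for w in node_ids:
            if w in receptors or layer_of[w] <= layer_of[u]:
                continue
            if rng.random() < shape.p_edge:
                edges[(u, w)] = sign()
    # guarantee connectivity: one incoming from previous layer, one outgoing
    for li in range(1, len(layers)):
        for w in layers[li]:
            if not any(src for (src, tgt) in edges if tgt == w):
                u = layers[li - 1][rng.integers(len(layers[li - 1]))]
                edges[(u, w)] = sign()
    for li in range(len(layers) - 1):
        for u in layers[li]:
            if not any(tgt for (src, tgt) in edges if src == u):
                w = layers[li + 1][rng.integers(len(layers[li + 1]))]
                edges[(u, w)] = sign()
    # optional feedback among middle nodes
    if shape.allow_cycles and middles:
        for u in middles:
            for w in middles:
                if layer_of[w] >= layer_of[u] or (u, w) in edges:
                    continue
                if rng.random() < shape.back_edge_prob:
                    edges[(u, w)] = sign()

    nodes: dict[str, PathwayNode] = {}
    for n in node_ids:
        k = int(rng.integers(shape.genes_per_node[0],
                             shape.genes_per_node[1] + 1))
        genes = tuple(f"g_{n}_{j}" for j in range(k))
        nodes[n] = PathwayNode(
            node_id=n, label=n.upper(), genes=genes,
            receptor=n in receptors, effector=n in effectors,
        )
    edge_list = [SignedEdge(u, w, s) for (u, w), s in sorted(edges.items())]
    return PathwayGraph(pathway_id=pathway_id, name=f"synthetic {pathway_id}",
                        nodes=nodes, edges=edge_list)


def generate_pathways(spec: SyntheticSpec,
                      rng: np.random.Generator) -> list[PathwayGraph]:
    return [
        generate_pathway(spec.shape, rng, pathway_id=f"P{i + 1:02d}")
        for i in range(spec.n_pathways)
    ]


def _catalog(graphs: list[PathwayGraph]) -> tuple[list[Circuit], dict[str, PathwayGraph]]:
    circuits: list[Circuit] = []
    graph_of: dict[str, PathwayGraph] = {}
    for g in graphs:
        for c in extract_all_circuits(g):
            circuits.append(c)
            graph_of[c.circuit_id] = g
    circuits.sort(key=lambda c: c.circuit_id)
    return circuits, graph_of


def _select(circuits: list[Circuit], selector: str | int) -> Circuit:
    if isinstance(selector, int):
        if not 0 <= selector < len(circuits):
            raise ValueError(f"circuit index {selector} out of range "
                             f"(catalog has {len(circuits)})")
        return circuits[selector]
    for c in circuits:
        if c.circuit_id == selector:
            return c
    raise ValueError(f"planted selector {selector!r} matches no circuit")


# ---------------------------------------------------------------------------
# expression

def sample_labels(spec: SyntheticSpec) -> pd.Series:
    """Deterministic sample naming and case/reference assignment."""
    ids = [f"S{i:04d}" for i in range(spec.n_samples)]
    groups = ["case"] * spec.n_case + ["reference"] * (spec.n_samples - spec.n_case)
    return pd.Series(groups, index=pd.Index(ids, name="sample_id"), name="group")


def generate_expression(
    spec: SyntheticSpec,
    graphs: list[PathwayGraph],
    labels: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Expression matrix with planted group shifts; returns ground truth.

    Baseline values are i.i.d. Normal(baseline_mean, baseline_sd) truncated
    at zero.  For each planted shift, the member genes of the selected
    circuit are moved by ±delta · (gene's between-sample range) in case
    samples, then clipped at zero.
    """
    genes: list[str] = []
    for g in graphs:
        for node in g.nodes.values():
            genes.extend(node.genes)
    if len(set(genes)) != len(genes):
        raise ValueError("gene symbols collide across pathways")
    values = rng.normal(spec.baseline_mean, spec.baseline_sd,
                        size=(len(genes), len(labels)))
    np.clip(values, 0.0, None, out=values)
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=labels.index)

    case_cols = labels.index[labels == "case"]
    truth_shifts = []
    if spec.planted_shifts:
        circuits, graph_of = _catalog(graphs)
    for shift in spec.planted_shifts:
        c = _select(circuits, shift.circuit)
        graph = graph_of[c.circuit_id]
        member_genes = sorted(
            gene for n in c.member_nodes for gene in graph.nodes[n].genes
            if gene in expr.index
        )
        span = (expr.loc[member_genes].max(axis=1)
                - expr.loc[member_genes].min(axis=1))
        delta = shift.delta * span
        if shift.direction == "down":
            delta = -delta
        expr.loc[member_genes, case_cols] = (
            expr.loc[member_genes, case_cols].add(delta, axis=0).clip(lower=0.0)
        )
        truth_shifts.append({
            "circuit_id": c.circuit_id,
            "direction": shift.direction,
            "delta": shift.delta,
            "n_genes": len(member_genes),
        })
    truth = {"planted_shifts": truth_shifts}
    return expr, truth


# ---------------------------------------------------------------------------
# survival

def _censor_horizon(hazards: np.ndarray, rate: float) -> float:
    """Upper bound u of Uniform(0, u) censoring achieving the target rate.

    For T ~ Exp(h) and C ~ Uniform(0, u), P(censored) = P(C < T)
    = (1 − e^{−hu}) / (hu), averaged over samples; monotone decreasing in u.
    """

    def censored_frac(u: float) -> float:
        hu = hazards * u
        return float(np.mean((1.0 - np.exp(-hu)) / hu))

    lo, hi = 1e-9, 1.0
    while censored_frac(hi) > rate:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket censoring horizon")
    return float(optimize.brentq(lambda u: censored_frac(u) - rate, lo, hi,
                                 xtol=1e-12, rtol=1e-12))


def generate_survival(
    spec: SyntheticSpec,
    activity: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[surv.SurvivalData, dict]:
    """Exponential survival with the planted hazard structure.

    Every sample gets hazard ``baseline_hazard``; samples in the top
    ``fraction`` of the planted circuit's activity get it multiplied by
    ``hazard_ratio``.  With ``hazard_ratio == 1`` (or no planted effect)
    survival is independent of every circuit — the null screen.
    """
    ps = spec.planted_survival or PlantedSurvival(hazard_ratio=1.0)
    n = activity.shape[1]
    hazards = np.full(n, ps.baseline_hazard)
    truth: dict = {"hazard_ratio": ps.hazard_ratio,
                   "baseline_hazard": ps.baseline_hazard,
                   "circuit_id": None}
    if ps.hazard_ratio != 1.0:
        circuits = list(activity.index)
        if isinstance(ps.circuit, int):
            if not 0 <= ps.circuit < len(circuits):
                raise ValueError(f"circuit index {ps.circuit} out of range")
            cid = circuits[ps.circuit]
        else:
            if ps.circuit not in circuits:
                raise ValueError(f"planted selector {ps.circuit!r} matches "
                                 "no circuit in the activity matrix")
            cid = ps.circuit
        row = activity.loc[cid]
        tail = surv.stratify_by_activity(row, fraction=ps.fraction,
                                         tail=surv.HIGH)
        hazards[tail.to_numpy()] *= ps.hazard_ratio
        truth["circuit_id"] = cid
    event_times = rng.exponential(1.0 / hazards)
    if ps.censoring_rate > 0:
        horizon = _censor_horizon(hazards, ps.censoring_rate)
        censor_times = rng.uniform(0.0, horizon, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    table = pd.DataFrame(
        {"time": observed, "event": event},
        index=pd.Index(activity.columns, name="sample_id"),
    )
    return surv.SurvivalData(table), truth


# ---------------------------------------------------------------------------
# full bundle

@dataclass
class DatasetBundle:
    spec: SyntheticSpec
    graphs: list[PathwayGraph]
    circuits: list[Circuit]
    expression: pd.DataFrame
    labels: pd.Series
    survival: surv.SurvivalData
    annotation: pd.DataFrame
    ground_truth: dict


def _default_annotation(circuits: list[Circuit]) -> pd.DataFrame:
    """Synthetic effector→function table: effectors share terms round-robin
    so some functions aggregate several circuits."""
    labels = sorted({c.effector_label for c in circuits})
    n_terms = max(1, (len(labels) + 1) // 2)
    rows = [
        {"effector": lab,
         "term_id": f"F:{i % n_terms:04d}",
         "term_definition": f"synthetic cell function {i % n_terms}"}
        for i, lab in enumerate(labels)
    ]
    return pd.DataFrame(rows)


def generate_bundle(spec: SyntheticSpec) -> DatasetBundle:
    """Generate the full in-memory dataset for a spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    graphs = generate_pathways(spec, rng)
    labels = sample_labels(spec)
    expr, truth = generate_expression(spec, graphs, labels, rng)

    norm = expression_prep.normalize01(expr)
    circuits, _ = _catalog(graphs)
    acts = []
    for g in graphs:
        nv = expression_prep.node_values(norm, g)
        own = [c for c in circuits if c.pathway_id == g.pathway_id]
        acts.append(propagation.activity_matrix(own, nv))
    activity = pd.concat(acts).sort_index()

    surv_data, surv_truth = generate_survival(spec, activity, rng)
    truth["planted_survival"] = surv_truth
    annotation = _default_annotation(circuits)
    return DatasetBundle(
        spec=spec, graphs=graphs, circuits=circuits, expression=expr,
        labels=labels, survival=surv_data, annotation=annotation,
        ground_truth=truth,
    )


def generate_dataset(spec: SyntheticSpec, outdir: str | Path) -> DatasetBundle:
    """Generate a bundle and write it in the pipeline's input formats.

    Writes pathways/*.json, expression.tsv, clinical.tsv (sample_id, time,
    event, group), annotation.tsv, ground_truth.json and a manifest.json
    from which the identical bundle can be regenerated.
    """
    outdir = Path(outdir)
    bundle = generate_bundle(spec)
    (outdir / "pathways").mkdir(parents=True, exist_ok=True)
    for g in bundle.graphs:
        save_pathway(g, outdir / "pathways" / f"{g.pathway_id}.json")
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t",
                             float_format="%.10g")
    clinical = bundle.survival.table.copy()
    clinical["group"] = bundle.labels
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", float_format="%.10g")
    bundle.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"generator": "pathcircuit.synthetic",
                   "spec": spec.to_dict()}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return bundle


def regenerate_from_manifest(path: str | Path, outdir: str | Path) -> DatasetBundle:
    """Re-create a bundle exactly from its manifest."""
    with open(path) as fh:
        manifest = json.load(fh)
    spec = SyntheticSpec.from_dict(manifest["spec"])
    return generate_dataset(spec, outdir)
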