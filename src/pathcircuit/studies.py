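"""Reference oracles and seeded simulation studies.

This module plays the role a ``verification`` script plays in simulation
packages: it holds deliberately naive, independent re-implementations of
the core computations (memoized recursion instead of a topological pass,
brute-force fixed-point iteration, step-up FDR by hand, simple-path
enumeration) and the seeded studies that measure engine error, test
calibration, power and survival-screen recovery against them.

The naive implementations here exist to *check* the engine; none of them
is used by the pipeline itself.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import differential, expression_prep, propagation, synthetic
from . import survival as surv
from .pathway_model import ACTIVATION, Circuit, PathwayGraph, extract_all_circuits

# ---------------------------------------------------------------------------
# oracles


def recursive_signal_oracle(
    circuit: Circuit, values: Mapping[str, float]
) -> dict[str, float]:
    """Memoized recursive evaluation of the propagation rule (DAGs only)."""
    acts: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    inhs: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        (acts if e.sign == ACTIVATION else inhs)[e.target].append(e.source)
    memo: dict[str, float] = {}

    def signal(n: str) -> float:
        if n in memo:
            return memo[n]
        if n in circuit.receptors:
            act = 1.0
        elif acts[n]:
            prod = 1.0
            for p in sorted(acts[n]):
                prod *= 1.0 - signal(p)
            act = 1.0 - prod
        else:
            act = 1.0
        inh = 1.0
        for p in sorted(inhs[n]):
            inh *= 1.0 - signal(p)
        memo[n] = values[n] * act * inh
        return memo[n]

    return {n: signal(n) for n in sorted(circuit.member_nodes)}


def fixed_point_oracle(
    circuit: Circuit,
    values: Mapping[str, float],
    iterations: int = 1_000_000,
    damping: float = 1.0,
) -> tuple[dict[str, float], bool]:
    """Long-run brute-force iteration of the propagation map.

    Runs up to ``iterations`` synchronous sweeps in plain Python floats.
    Once a sweep moves no signal by more than 1e-15 — at the resolution of
    double precision, where rounding can sustain a one-ulp limit cycle —
    the state is treated as stationary: every remaining sweep would stay
    within that band, so the loop exits with the value the full run would
    report.  Returns the final state and whether it stabilized.
    """
    acts: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    inhs: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        (acts if e.sign == ACTIVATION else inhs)[e.target].append(e.source)
    for n in acts:
        acts[n].sort()
        inhs[n].sort()
    nodes = sorted(circuit.member_nodes)
    state = {n: float(values[n]) for n in nodes}
    stationary = False
    for _ in range(iterations):
        new = {}
        for n in nodes:
            if n in circuit.receptors:
                act = 1.0
            elif acts[n]:
                prod = 1.0
                for p in acts[n]:
                    prod *= 1.0 - state[p]
                act = 1.0 - prod
            else:
                act = 1.0
            inh = 1.0
            for p in inhs[n]:
                inh *= 1.0 - state[p]
            s = values[n] * act * inh
            if damping < 1.0:
                s = (1.0 - damping) * state[n] + damping * s
            new[n] = s
        if max(abs(new[n] - state[n]) for n in nodes) <= 1e-15:
            state = new
            stationary = True
            break
        state = new
    return state, stationary


def bh_oracle(pvalues) -> np.ndarray:
    """Brute-force Benjamini–Hochberg step-up, independent of statsmodels."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def simple_path_members(
    graph: PathwayGraph, receptors: set[str], effector: str
) -> tuple[set[str], set[tuple[str, str]]]:
    """Nodes/edges on at least one simple receptor→effector path (sign-
    agnostic), by exhaustive enumeration.  Exponential; fixtures only."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e.source, e.target) for e in graph.edges
                     if e.source != e.target)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for r in receptors:
        if r == effector:
            nodes.add(r)
            continue
        for path in nx.all_simple_paths(g, r, effector):
            nodes.update(path)
            edges.update(zip(path[:-1], path[1:]))
    return nodes, edges


# ---------------------------------------------------------------------------
# study fixtures


def _single_circuit_pathways(
    n: int, rng: np.random.Generator, **shape_kw
) -> tuple[list[PathwayGraph], list[Circuit]]:
    """n small independent pathways, each contributing exactly one circuit."""
    kw = dict(n_nodes=6, n_receptors=1, n_effectors=1, n_layers=3,
              p_edge=0.5, inhibition_fraction=0.25, genes_per_node=(1, 2))
    kw.update(shape_kw)
    shape = synthetic.PathwayShape(**kw)
    graphs = [synthetic.generate_pathway(shape, rng, pathway_id=f"P{i:03d}")
              for i in range(n)]
    circuits = []
    for g in graphs:
        own = extract_all_circuits(g)
        assert len(own) == 1
        circuits.extend(own)
    return graphs, circuits


def _null_activity(
    graphs: list[PathwayGraph],
    circuits: list[Circuit],
    n_samples: int,
    rng: np.random.Generator,
    planted: tuple[synthetic.PlantedShift, ...] = (),
    n_case: int | None = None,
) -> pd.DataFrame:
    """Activities of one synthetic cohort (optionally with planted shifts)."""
    spec = synthetic.SyntheticSpec(
        seed=0, n_samples=n_samples, n_case=n_case or n_samples // 2,
        n_pathways=len(graphs), planted_shifts=planted,
    )
    labels = synthetic.sample_labels(spec)
    expr, _ = synthetic.generate_expression(spec, graphs, labels, rng)
    norm = expression_prep.normalize01(expr)
    parts = []
    by_pathway: dict[str, list[Circuit]] = {}
    for c in circuits:
        by_pathway.setdefault(c.pathway_id, []).append(c)
    for g in graphs:
        nv = expression_prep.node_values(norm, g)
        parts.append(propagation.activity_matrix(by_pathway[g.pathway_id], nv))
    return pd.concat(parts).sort_index()


def random_dag_circuit(
    rng: np.random.Generator, max_nodes: int = 12
) -> tuple[PathwayGraph, Circuit, dict[str, float]]:
    """One random acyclic circuit with random node values."""
    shape = synthetic.PathwayShape(
        n_nodes=int(rng.integers(4, max_nodes + 1)),
        n_receptors=int(rng.integers(1, 3)),
        n_effectors=1, n_layers=int(rng.integers(3, 5)),
        p_edge=float(rng.uniform(0.3, 0.8)),
        inhibition_fraction=float(rng.uniform(0.0, 0.5)),
    )
    g = synthetic.generate_pathway(shape, rng, pathway_id="D")
    circuit = extract_all_circuits(g)[0]
    values = {n: float(rng.uniform(0, 1)) for n in g.nodes}
    return g, circuit, values


def random_cyclic_circuit(
    rng: np.random.Generator, max_nodes: int = 10
) -> tuple[PathwayGraph, Circuit, dict[str, float]] | None:
    """One random circuit containing a feedback loop, or None if the draw
    happened to stay acyclic."""
    import networkx as nx

    shape = synthetic.PathwayShape(
        n_nodes=int(rng.integers(6, max_nodes + 1)),
        n_receptors=1, n_effectors=1, n_layers=4,
        p_edge=float(rng.uniform(0.4, 0.8)),
        inhibition_fraction=float(rng.uniform(0.0, 0.5)),
        allow_cycles=True, back_edge_prob=0.6,
    )
    g = synthetic.generate_pathway(shape, rng, pathway_id="C")
    circuit = extract_all_circuits(g)[0]
    if nx.is_directed_acyclic_graph(circuit.subgraph()):
        return None
    values = {n: float(rng.uniform(0, 1)) for n in g.nodes}
    return g, circuit, values


# ---------------------------------------------------------------------------
# studies


def dag_engine_study(n_circuits: int = 200, seed: int = 0) -> dict:
    """Max |engine − memoized-recursion oracle| over random DAG circuits."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_circuits):
        _, circuit, values = random_dag_circuit(rng)
        state = propagation.propagate_circuit(circuit, values)
        oracle = recursive_signal_oracle(circuit, values)
        diff = max(abs(state.signals[n] - oracle[n]) for n in oracle)
        worst = max(worst, diff)
    return {"max_abs_error": worst, "n": n_circuits}


def cycle_engine_study(n_fixtures: int = 25, seed: int = 0,
                       oracle_iterations: int = 1_000_000) -> dict:
    """Jacobi engine vs long-run brute-force oracle on cyclic circuits.

    Fixtures where plain Jacobi oscillates are re-run with damping 0.5 —
    the documented remedy; the fixed point is invariant to damping.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_done = 0
    n_damped = 0
    while n_done < n_fixtures:
        drawn = random_cyclic_circuit(rng)
        if drawn is None:
            continue
        _, circuit, values = drawn
        damping = 1.0
        try:
            state = propagation.propagate_circuit(
                circuit, values, propagation.PropagationSettings())
        except propagation.ConvergenceError:
            damping = 0.5
            n_damped += 1
            state = propagation.propagate_circuit(
                circuit, values,
                propagation.PropagationSettings(damping=damping))
        oracle, stationary = fixed_point_oracle(
            circuit, values, iterations=oracle_iterations, damping=damping)
        assert stationary, "oracle did not stabilize"
        diff = max(abs(state.signals[n] - oracle[n]) for n in oracle)
        worst = max(worst, diff)
        n_done += 1
    return {"max_abs_error": worst, "n": n_fixtures, "n_damped": n_damped}


def differential_null_study(
    n_replicates: int = 100, n_circuits: int = 200,
    n_case: int = 60, n_reference: int = 60, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I calibration of the differential stage on null cohorts.

    Returns the KS uniformity p-value of all pooled raw Wilcoxon p-values
    and the mean fraction of circuits called significant at FDR ``alpha``.
    """
    rng = np.random.default_rng(seed)
    graphs, circuits = _single_circuit_pathways(n_circuits, rng)
    n = n_case + n_reference
    spec = synthetic.SyntheticSpec(seed=0, n_samples=n, n_case=n_case,
                                   n_pathways=len(graphs))
    labels = differential.GroupLabels.from_series(
        synthetic.sample_labels(spec), case="case")
    pooled = []
    fdr_fractions = []
    for _ in range(n_replicates):
        activity = _null_activity(graphs, circuits, n, rng)
        records = differential.differential_activity(activity, labels,
                                                     alpha=alpha)
        pooled.append(records["p_value"].to_numpy())
        fdr_fractions.append(records["significant"].mean())
    pooled = np.concatenate(pooled)
    ks = stats.kstest(pooled, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "mean_fdr_positive_fraction": float(np.mean(fdr_fractions)),
        "n_tests": int(pooled.size),
    }


def differential_power_study(
    n_replicates: int = 50, n_circuits: int = 200, n_planted: int = 5,
    delta: float = 0.3, n_case: int = 60, n_reference: int = 60,
    seed: int = 0, alpha: float = 0.05,
) -> dict:
    """Recovery of planted group shifts through the full pipeline.

    ``n_planted`` circuits receive a ±delta shift (alternating directions)
    on their member genes in case samples.  A replicate counts as recovered
    when every planted circuit is significant at FDR ``alpha`` with status
    matching the planted direction.
    """
    rng = np.random.default_rng(seed)
    graphs, circuits = _single_circuit_pathways(n_circuits, rng)
    # plant on activation-only circuits so the direction of the activity
    # response is structurally unambiguous
    coherent = [i for i, c in enumerate(circuits)
                if all(e.sign == ACTIVATION for e in c.member_edges)]
    if len(coherent) < n_planted:
        raise RuntimeError("not enough activation-only circuits to plant on")
    step = max(1, len(coherent) // n_planted)
    chosen = [coherent[i * step] for i in range(n_planted)]
    planted = tuple(
        synthetic.PlantedShift(circuit=circuits[idx].circuit_id, delta=delta,
                               direction="up" if k % 2 == 0 else "down")
        for k, idx in enumerate(chosen)
    )
    truth = {s.circuit: ("UP" if s.direction == "up" else "DOWN")
             for s in planted}
    n = n_case + n_reference
    spec = synthetic.SyntheticSpec(seed=0, n_samples=n, n_case=n_case,
                                   n_pathways=len(graphs))
    labels = differential.GroupLabels.from_series(
        synthetic.sample_labels(spec), case="case")
    hits = 0
    for _ in range(n_replicates):
        activity = _null_activity(graphs, circuits, n, rng, planted=planted)
        records = differential.differential_activity(activity, labels,
                                                     alpha=alpha)
        rec = records.set_index("circuit_id")
        ok = all(
            bool(rec.loc[cid, "significant"])
            and rec.loc[cid, "status"] == status
            for cid, status in truth.items()
        )
        hits += ok
    return {"recovery_rate": hits / n_replicates, "n": n_replicates,
            "n_planted": n_planted}


def survival_null_study(
    n_circuits: int = 100, n_samples: int = 500, censoring: float = 0.3,
    seed: int = 0,
) -> dict:
    """Calibration of the survival screen under a proportional-hazards null."""
    rng = np.random.default_rng(seed)
    graphs, circuits = _single_circuit_pathways(n_circuits, rng)
    activity = _null_activity(graphs, circuits, n_samples, rng)
    spec = synthetic.SyntheticSpec(
        seed=0, n_samples=n_samples, n_case=n_samples // 2,
        n_pathways=len(graphs),
        planted_survival=synthetic.PlantedSurvival(
            hazard_ratio=1.0, censoring_rate=censoring),
    )
    data, _ = synthetic.generate_survival(spec, activity, rng)
    screen = surv.survival_screen(activity, data)
    p = screen["p_value"].dropna().to_numpy()
    ks = stats.kstest(p, "uniform")
    return {
        "ks_p": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "frac_raw_p_below_0.05": float((p < 0.05).mean()),
        "observed_event_fraction": float(data.table["event"].mean()),
        "n_tests": int(p.size),
    }


def survival_recovery_study(
    n_replicates: int = 100, n_circuits: int = 100, n_samples: int = 500,
    hazard_ratio: float = 3.0, censoring: float = 0.3, seed: int = 0,
) -> dict:
    """How often the circuit carrying a planted top-decile hazard effect
    attains the smallest FDR-adjusted p in the screen."""
    rng = np.random.default_rng(seed)
    graphs, circuits = _single_circuit_pathways(n_circuits, rng)
    planted_id = circuits[0].circuit_id
    spec = synthetic.SyntheticSpec(
        seed=0, n_samples=n_samples, n_case=n_samples // 2,
        n_pathways=len(graphs),
        planted_survival=synthetic.PlantedSurvival(
            circuit=planted_id, hazard_ratio=hazard_ratio,
            censoring_rate=censoring),
    )
    hits = 0
    for _ in range(n_replicates):
        activity = _null_activity(graphs, circuits, n_samples, rng)
        data, _ = synthetic.generate_survival(spec, activity, rng)
        screen = surv.survival_screen(activity, data)
        tested = screen[screen["fdr_p"].notna()]
        best = tested["fdr_p"].min()
        planted_best = tested.loc[tested["circuit_id"] == planted_id,
                                  "fdr_p"].min()
        hits += bool(planted_best <= best)
    return {"recovery_rate": hits / n_replicates, "n": n_replicates}
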