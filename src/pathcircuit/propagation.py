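"""Signal propagation through signaling circuits.

Every node n holds a normalized expression proxy v_n ∈ [0, 1].  Signal
intensities obey the recursion

    S_n = v_n · (1 − ∏_{s_a ∈ A}(1 − s_a)) · ∏_{s_i ∈ I}(1 − s_i)

where A are the signals arriving over activation edges and I those arriving
over inhibition edges: activations combine as a noisy-OR, inhibitions
attenuate multiplicatively.  Receptors are seeded with an initial signal of
1, which enters the activation set, so a receptor transmits S = v.

Two conventions close the recursion where the formula alone is silent:

* **basal activation** — a non-receptor node with no incoming activation
  edges (only inhibitions, or nothing) gets activation factor 1 rather than
  the empty product's 0, which would silence it permanently;
* **cycles** — on acyclic circuits one pass in topological order is the
  exact fixed point; on circuits with feedback loops we run Jacobi
  fixed-point iteration from S⁰ = v until the update norm drops below a
  tolerance.  The map is continuous on [0,1]^N so a fixed point exists;
  non-convergence (possible for undamped negative feedback) raises, it is
  never papered over.  A damping factor < 1 averages successive iterates
  and resolves oscillatory cases.

Signals flow only along circuit-member edges; the parent pathway's other
edges are invisible to the circuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pathway_model import ACTIVATION, Circuit


class ConvergenceError(RuntimeError):
    """Jacobi iteration failed to reach the fixed point within max_iter."""


@dataclass(frozen=True)
class PropagationSettings:
    """Convergence controls for cyclic circuits.

    tol: max absolute per-node update considered converged (default 1e-10).
    max_iter: iteration cap before ConvergenceError (default 10_000).
    damping: fraction of the new iterate mixed in per step; 1.0 = plain
        Jacobi, values < 1 damp period-2 oscillations on negative feedback
        loops.
    """

    tol: float = 1e-10
    max_iter: int = 10_000
    damping: float = 1.0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must be in (0, 1]")


@dataclass
class SignalState:
    """Converged signal intensities for one circuit and one sample."""

    circuit_id: str
    signals: dict[str, float]
    converged: bool
    iterations_used: int


def node_update(
    v_n: float,
    activations: Sequence[float] = (),
    inhibitions: Sequence[float] = (),
    basal: float = 0.0,
) -> float:
    """One application of the propagation rule at a single node.

    ``basal`` is the initial signal injected at receptors (1 by convention);
    when positive it joins the activation set.  An empty activation set
    yields activation factor 1 (basal-activation convention).
    """
    inputs = [v_n, basal, *activations, *inhibitions]
    if any(not 0.0 <= x <= 1.0 for x in inputs):
        raise ValueError(f"propagation inputs must lie in [0, 1]: {inputs}")
    acts = list(activations)
    if basal > 0.0:
        acts.append(basal)
    if acts:
        act_factor = 1.0 - float(np.prod(np.sort(1.0 - np.asarray(acts))))
    else:
        act_factor = 1.0
    inh_factor = float(np.prod(np.sort(1.0 - np.asarray(inhibitions)))) \
        if inhibitions else 1.0
    return v_n * act_factor * inh_factor


def _preds_by_sign(circuit: Circuit) -> dict[str, tuple[list[str], list[str]]]:
    """node -> (activation predecessors, inhibition predecessors), sorted."""
    preds: dict[str, tuple[list[str], list[str]]] = {
        n: ([], []) for n in circuit.member_nodes
    }
    for e in sorted(circuit.member_edges):
        idx = 0 if e.sign == ACTIVATION else 1
        preds[e.target][idx].append(e.source)
    return preds


def _propagate_arrays(
    circuit: Circuit,
    values: Mapping[str, np.ndarray],
    settings: PropagationSettings,
) -> tuple[dict[str, np.ndarray], bool, int]:
    """Vectorized propagation: each node's value is an array over samples.

    Predecessor products are accumulated in sorted-node order so results are
    bit-identical across runs.
    """
    preds = _preds_by_sign(circuit)
    receptors = circuit.receptors
    nodes = sorted(circuit.member_nodes)
    v = {}
    for n in nodes:
        arr = np.asarray(values[n], dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"node {n!r}: values outside [0, 1]")
        v[n] = arr

    def update(state: Mapping[str, np.ndarray], n: str) -> np.ndarray:
        act_preds, inh_preds = preds[n]
        if n in receptors:
            act = np.ones_like(v[n])  # basal signal of 1 dominates the noisy-OR
        elif act_preds:
            prod = np.ones_like(v[n])
            for p in act_preds:
                prod = prod * (1.0 - state[p])
            act = 1.0 - prod
        else:
            act = np.ones_like(v[n])  # basal-activation convention
        inh = np.ones_like(v[n])
        for p in inh_preds:
            inh = inh * (1.0 - state[p])
        return v[n] * act * inh

    sub = circuit.subgraph()
    if nx.is_directed_acyclic_graph(sub):
        state: dict[str, np.ndarray] = {}
        for n in nx.lexicographical_topological_sort(sub):
            state[n] = update(state, n)
        return state, True, 1

    state = {n: v[n].copy() for n in nodes}
    d = settings.damping
    for it in range(1, settings.max_iter + 1):
        new = {n: update(state, n) for n in nodes}
        if d < 1.0:
            new = {n: (1.0 - d) * state[n] + d * new[n] for n in nodes}
        delta = max(np.max(np.abs(new[n] - state[n])) for n in nodes)
        state = new
        if delta < settings.tol:
            return state, True, it
    return state, False, settings.max_iter


def propagate_circuit(
    circuit: Circuit,
    values: Mapping[str, float] | pd.Series,
    settings: PropagationSettings | None = None,
    sample_id: str | None = None,
) -> SignalState:
    """Propagate one sample's node values through a circuit.

    ``values`` must cover every member node.  Raises ConvergenceError,
    naming the circuit (and sample when given), if a cyclic circuit does not
    reach its fixed point.
    """
    settings = settings or PropagationSettings()
    missing = sorted(n for n in circuit.member_nodes if n not in values)
    if missing:
        raise KeyError(
            f"circuit {circuit.circuit_id!r}: missing node values for {missing}"
        )
    arrays = {n: np.asarray([float(values[n])]) for n in circuit.member_nodes}
    state, converged, iters = _propagate_arrays(circuit, arrays, settings)
    if not converged:
        where = f", sample {sample_id!r}" if sample_id is not None else ""
        raise ConvergenceError(
            f"circuit {circuit.circuit_id!r}{where}: no fixed point within "
            f"{settings.max_iter} iterations (tol={settings.tol}); consider "
            f"damping < 1"
        )
    return SignalState(
        circuit_id=circuit.circuit_id,
        signals={n: float(state[n][0]) for n in sorted(state)},
        converged=converged,
        iterations_used=iters,
    )


def activity_matrix(
    circuits: Iterable[Circuit],
    node_values: pd.DataFrame,
    settings: PropagationSettings | None = None,
    return_convergence: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Circuit activities: the effector's signal per circuit per sample.

    Rows follow the circuit catalog order, columns the sample order of
    ``node_values``.  All samples of a circuit are propagated together.
    Convergence failures are aggregated into a single ConvergenceError that
    names every offending circuit.
    """
    settings = settings or PropagationSettings()
    circuits = list(circuits)
    rows = []
    report = []
    failures = []
    for c in circuits:
        missing = sorted(n for n in c.member_nodes if n not in node_values.index)
        if missing:
            raise KeyError(
                f"circuit {c.circuit_id!r}: node values missing for {missing}"
            )
        arrays = {n: node_values.loc[n].to_numpy(dtype=float)
                  for n in c.member_nodes}
        state, converged, iters = _propagate_arrays(c, arrays, settings)
        rows.append(state[c.effector])
        report.append({
            "circuit_id": c.circuit_id,
            "iterations": iters,
            "converged": converged,
        })
        if not converged:
            failures.append(c.circuit_id)
    if failures:
        raise ConvergenceError(
            f"{len(failures)} circuit(s) did not converge within "
            f"{settings.max_iter} iterations: {failures[:10]}"
        )
    result = pd.DataFrame(
        np.asarray(rows) if rows else np.empty((0, node_values.shape[1])),
        index=pd.Index([c.circuit_id for c in circuits], name="circuit_id"),
        columns=node_values.columns,
    )
    if return_convergence:
        return result, pd.DataFrame(report)
    return result
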