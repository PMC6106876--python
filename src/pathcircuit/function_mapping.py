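"""Mapping effector circuits to cell-function terms.

Effector proteins trigger cell functions described by GO-style terms.  A
flat annotation table (effector identifier → term id + definition) attaches
those terms to circuits, enabling (a) a function-level activity matrix — the
signal a cell function receives across all circuits ending in effectors
annotated with it — and (b) function-annotated differential result tables.

Annotation keys are matched against the circuit's effector label first,
then against the effector node's gene symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pathway_model import Circuit, PathwayGraph

_AGGREGATORS = {
    "mean": lambda m: np.mean(m, axis=0),
    "median": lambda m: np.median(m, axis=0),
    "max": lambda m: np.max(m, axis=0),
}


@dataclass
class FunctionAnnotation:
    """Many-to-many mapping: effector identifier -> {(term_id, definition)}."""

    terms: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, effector: str, term_id: str, definition: str = "") -> None:
        if not term_id:
            raise ValueError("term_id must be non-empty")
        self.terms.setdefault(effector, set()).add((term_id, definition))

    def lookup(self, keys: Sequence[str]) -> set[tuple[str, str]]:
        """Terms for the first key present in the annotation, else empty."""
        for key in keys:
            if key in self.terms:
                return self.terms[key]
        return set()

    def circuit_terms(self, circuit: Circuit,
                      graph: PathwayGraph | None = None) -> set[tuple[str, str]]:
        keys = [circuit.effector_label, circuit.effector]
        if graph is not None and circuit.effector in graph.nodes:
            keys.extend(graph.nodes[circuit.effector].genes)
        return self.lookup(keys)


def load_annotation(path: str | Path) -> FunctionAnnotation:
    """Read an effector→term TSV (columns effector, term_id, term_definition).

    Duplicate rows are de-duplicated; an effector may carry several terms
    and a term may annotate several effectors.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"effector", "term_id", "term_definition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: annotation file has no rows")
    ann = FunctionAnnotation()
    for row in df.itertuples(index=False):
        ann.add(row.effector, row.term_id, row.term_definition)
    return ann


def function_signal(
    activity: pd.DataFrame,
    circuits: Iterable[Circuit],
    annotation: FunctionAnnotation,
    aggregate: str = "mean",
    return_skipped: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, list[str]]:
    """Function-level signal: aggregate activity of each term's circuits.

    The value of a term in a sample is the ``aggregate`` (default arithmetic
    mean) of the activities of every circuit whose effector carries the
    term, so values stay in [0, 1].  Circuits without any annotation are
    skipped; ``return_skipped=True`` also returns their ids.  Raises if no
    circuit is annotated at all.
    """
    if aggregate not in _AGGREGATORS:
        raise ValueError(f"aggregate must be one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregate]
    by_term: dict[str, list[int]] = {}
    skipped: list[str] = []
    circuits = list(circuits)
    row_of = {cid: i for i, cid in enumerate(activity.index)}
    for c in circuits:
        if c.circuit_id not in row_of:
            raise ValueError(f"circuit {c.circuit_id!r} absent from activity matrix")
        terms = annotation.circuit_terms(c)
        if not terms:
            skipped.append(c.circuit_id)
            continue
        for term_id, _definition in terms:
            by_term.setdefault(term_id, []).append(row_of[c.circuit_id])
    if not by_term:
        raise ValueError("no circuit matched any annotation entry")
    values = activity.to_numpy(dtype=float)
    term_ids = sorted(by_term)
    out = np.vstack([agg(values[by_term[t], :]) for t in term_ids])
    result = pd.DataFrame(out, index=pd.Index(term_ids, name="term_id"),
                          columns=activity.columns)
    if return_skipped:
        return result, skipped
    return result


def annotate_differential(
    records: pd.DataFrame,
    annotation: FunctionAnnotation,
) -> pd.DataFrame:
    """Expand a differential result table with function terms.

    One output row per (circuit record, term) pair, in the classical
    reporting shape: circuit, status, FDR p-value, term id, term
    definition.  Records without a matching term keep empty term fields.
    """
    rows = []
    for rec in records.to_dict("records"):
        terms = sorted(annotation.lookup([rec.get("effector", ""),
                                          rec["circuit_id"]]))
        if not terms:
            terms = [("", "")]
        for term_id, definition in terms:
            out = dict(rec)
            out["term_id"] = term_id
            out["term_definition"] = definition
            rows.append(out)
    columns = list(records.columns) + ["term_id", "term_definition"]
    return pd.DataFrame(rows, columns=columns)
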