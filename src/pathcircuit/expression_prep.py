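"""Expression rescaling and gene→node summarization.

Input expression is a genes × samples matrix of nonnegative values on a
log2(1 + FPKM)-like scale.  Each gene row is min–max rescaled across samples
to [0, 1]; node values are then summaries of the member genes' rescaled
values and serve as proxies of protein activity for signal propagation.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .pathway_model import PathwayGraph

_SUMMARIES = {
    "median": lambda a: np.median(a, axis=0),
    "mean": lambda a: np.mean(a, axis=0),
    "percentile90": lambda a: np.percentile(a, 90, axis=0),
}


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples TSV (first column gene ids, header row required).

    Transparently handles gzip-compressed files. Validates uniqueness of gene
    and sample ids, and that all values are finite and nonnegative.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, comment="#")
    validate_expression(df)
    return df


def validate_expression(df: pd.DataFrame) -> None:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups[:5]}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")


def normalize01(
    expr: pd.DataFrame,
    winsorize: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-gene min–max rescaling to [0, 1] across samples.

    Each gene row x becomes (x − min) / (max − min); a constant row carries
    no between-sample information and maps to 0.5 everywhere.  Optional
    ``winsorize=(low, high)`` clips each row at those percentiles first
    (guards the range against single-sample outliers; off by default).
    The result is invariant under positive affine transforms of a row.
    """
    if expr.shape[1] < 2:
        raise ValueError("normalization requires at least 2 samples")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    if winsorize is not None:
        lo_p, hi_p = winsorize
        lo = np.percentile(values, lo_p, axis=1, keepdims=True)
        hi = np.percentile(values, hi_p, axis=1, keepdims=True)
        values = np.clip(values, lo, hi)
    row_min = values.min(axis=1, keepdims=True)
    row_max = values.max(axis=1, keepdims=True)
    span = row_max - row_min
    flat = (span == 0).ravel()
    span[span == 0] = 1.0
    out = (values - row_min) / span
    out[flat, :] = 0.5
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def node_values(
    norm: pd.DataFrame,
    graph: PathwayGraph,
    missing_default: float = 0.5,
    summary: str = "median",
    return_coverage: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Per-node activity proxies v_n in [0, 1] from normalized expression.

    A single-gene node takes that gene's value; a multi-gene node takes the
    ``summary`` (default median) of the member genes present in the matrix.
    Nodes whose genes are all unmeasured — and gene-less nodes — receive
    ``missing_default`` (0.5 = agnostic mid-activity; 0 would hard-silence
    circuits through the multiplicative propagation rule).

    With ``return_coverage=True`` also returns a per-node report of how many
    genes were measured and whether the default was used.
    """
    if not 0.0 <= missing_default <= 1.0:
        raise ValueError("missing_default must be in [0, 1]")
    if summary not in _SUMMARIES:
        raise ValueError(f"summary must be one of {sorted(_SUMMARIES)}")
    summarize = _SUMMARIES[summary]

    vals = norm.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("normalized matrix has values outside [0, 1]")
    gene_index = {g: i for i, g in enumerate(norm.index)}

    node_ids = list(graph.nodes)
    out = np.empty((len(node_ids), norm.shape[1]))
    coverage = []
    for i, nid in enumerate(node_ids):
        genes = graph.nodes[nid].genes
        rows = [gene_index[g] for g in genes if g in gene_index]
        if not rows:
            out[i, :] = missing_default
        elif len(rows) == 1:
            out[i, :] = vals[rows[0], :]
        else:
            out[i, :] = summarize(vals[rows, :])
        coverage.append({
            "node_id": nid,
            "n_genes": len(genes),
            "n_measured": len(rows),
            "used_default": not rows,
        })
    result = pd.DataFrame(out, index=pd.Index(node_ids, name="node_id"),
                          columns=norm.columns)
    if return_coverage:
        return result, pd.DataFrame(coverage)
    return result
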