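"""End-to-end orchestration: normalize → propagate → test → annotate → screen.

Stage outputs are plain TSV files with ``#``-prefixed metadata comment
lines (version, parameters), plus a machine-readable JSON run report.
Reruns with identical config, inputs and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import differential, expression_prep, function_mapping, propagation
from . import survival as surv
from .pathway_model import (
    PathwayGraph,
    circuit_catalog,
    extract_all_circuits,
    load_pathway,
)

logger = logging.getLogger("pathcircuit")


class ConfigError(ValueError):
    """Bad or incomplete pipeline configuration (exit code 2)."""


class DataError(ValueError):
    """Input files that parse but fail validation/consistency (exit code 3)."""


@dataclass
class PipelineConfig:
    pathways_dir: str = ""
    expression: str = ""
    clinical: str = ""
    annotation: str = ""
    out_dir: str = "pathcircuit_out"
    # expression prep
    winsorize: tuple[float, float] | None = None
    missing_default: float = 0.5
    node_summary: str = "median"
    # propagation
    tol: float = 1e-10
    max_iter: int = 10_000
    damping: float = 1.0
    # differential test
    case: str = "case"
    reference: str | None = None
    group_col: str = "group"
    alpha: float = 0.05
    # survival screen
    fraction: float = 0.10
    fdr_family: str = "joint"
    run_survival: bool = True
    # misc
    subset: str = ""  # "column=value" predicate on the clinical table
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if not 0 < self.fraction < 0.5:
            raise ConfigError("fraction must be in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if data.get("winsorize") is not None:
            data["winsorize"] = tuple(data["winsorize"])
        return cls(**data)

    def check_paths(self) -> None:
        for name in ("pathways_dir", "expression", "clinical"):
            p = getattr(self, name)
            if not p:
                raise ConfigError(f"config field {name!r} is required")
            if not Path(p).exists():
                raise ConfigError(f"{name}: path does not exist: {p}")
        if self.annotation and not Path(self.annotation).exists():
            raise ConfigError(f"annotation: path does not exist: {self.annotation}")


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               stage: str, index: bool = True) -> None:
    meta = [
        f"# producer: pathcircuit {__version__}",
        f"# stage: {stage}",
        f"# seed: {config.seed}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(meta) + "\n")
        df.to_csv(fh, sep="\t", float_format="%.12g", index=index)


def load_pathways_dir(path: str | Path) -> list[PathwayGraph]:
    path = Path(path)
    files = sorted(list(path.glob("*.json")) + list(path.glob("*.sif")))
    if not files:
        raise DataError(f"no pathway files (*.json, *.sif) in {path}")
    return [load_pathway(f) for f in files]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: missing column 'sample_id'")
    return df.set_index("sample_id")


def subset_samples(clinical: pd.DataFrame, predicate: str) -> pd.DataFrame:
    """Filter the clinical table by a ``column=value`` predicate."""
    if "=" not in predicate:
        raise ConfigError(f"subset predicate must be column=value: {predicate!r}")
    column, value = predicate.split("=", 1)
    if column not in clinical.columns:
        raise ConfigError(f"subset column {column!r} not in clinical table "
                          f"(have {list(clinical.columns)})")
    out = clinical[clinical[column].astype(str) == value]
    if out.empty:
        raise DataError(f"subset {predicate!r} matches no samples")
    return out


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write all stage outputs.

    Returns the run report (also written to ``run_report.json``).
    """
    logging.basicConfig(level=config.log_level)
    config.check_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    graphs = load_pathways_dir(config.pathways_dir)
    expr = expression_prep.read_expression(config.expression)
    clinical = read_clinical(config.clinical)
    if config.subset:
        clinical = subset_samples(clinical, config.subset)
        expr = expr[[s for s in expr.columns if s in clinical.index]]
        if expr.shape[1] < 4:
            raise DataError("subset leaves fewer than 4 samples")
    logger.info("loaded %d pathways, %d genes x %d samples",
                len(graphs), *expr.shape)

    norm = expression_prep.normalize01(expr, winsorize=config.winsorize)
    settings = propagation.PropagationSettings(
        tol=config.tol, max_iter=config.max_iter, damping=config.damping)

    circuits = []
    activities = []
    convergence = []
    for g in graphs:
        nv = expression_prep.node_values(
            norm, g, missing_default=config.missing_default,
            summary=config.node_summary)
        own = extract_all_circuits(g)
        act, conv = propagation.activity_matrix(
            own, nv, settings, return_convergence=True)
        circuits.extend(own)
        activities.append(act)
        convergence.append(conv)
    circuits.sort(key=lambda c: c.circuit_id)
    activity = pd.concat(activities).sort_index()
    convergence_df = pd.concat(convergence, ignore_index=True)

    catalog = circuit_catalog(circuits)
    _write_tsv(catalog, out / "circuits.tsv", config, "circuit_catalog",
               index=False)
    _write_tsv(activity, out / "activity.tsv", config, "activity_matrix")
    _write_tsv(convergence_df, out / "convergence.tsv", config,
               "convergence_report", index=False)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "n_pathways": len(graphs),
        "n_circuits": len(circuits),
        "n_genes": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
        "convergence": {
            "all_converged": bool(convergence_df["converged"].all()),
            "max_iterations": int(convergence_df["iterations"].max()),
        },
    }

    # differential stage
    if config.group_col in clinical.columns:
        labels = differential.GroupLabels.from_series(
            clinical[config.group_col].astype(str),
            case=config.case, reference=config.reference)
        records = differential.differential_activity(
            activity, labels, alpha=config.alpha)
        if config.annotation:
            ann = function_mapping.load_annotation(config.annotation)
            annotated = function_mapping.annotate_differential(records, ann)
            _write_tsv(annotated, out / "differential_annotated.tsv", config,
                       "differential_annotated", index=False)
            fsignal, skipped = function_mapping.function_signal(
                activity, circuits, ann, return_skipped=True)
            _write_tsv(fsignal, out / "function_activity.tsv", config,
                       "function_activity")
            report["n_unannotated_circuits"] = len(skipped)
        _write_tsv(records, out / "differential.tsv", config, "differential",
                   index=False)
        report["n_significant_circuits"] = int(records["significant"].sum())
    else:
        logger.warning("clinical table has no %r column; differential stage "
                       "skipped", config.group_col)

    # survival stage
    if config.run_survival:
        missing = {"time", "event"} - set(clinical.columns)
        if missing:
            raise ConfigError(
                f"survival stage requested but clinical table lacks columns "
                f"{sorted(missing)}")
        data = surv.SurvivalData(clinical[["time", "event"]]
                                 .astype({"time": float, "event": int}))
        screen = surv.survival_screen(
            activity, data, fraction=config.fraction, alpha=config.alpha,
            fdr_family=config.fdr_family)
        _write_tsv(screen, out / "survival.tsv", config, "survival_screen",
                   index=False)
        report["n_survival_hits"] = int(screen["significant"].sum())
        report["n_samples_without_survival"] = screen.attrs["n_samples_dropped"]

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
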