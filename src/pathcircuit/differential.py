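"""Two-group differential circuit-activity testing.

Circuit activities, like normalized expression, are comparative quantities:
they are tested between two conditions (case vs reference, e.g. a biomarker
present vs absent) with a two-sided Wilcoxon rank-sum test, and p-values are
adjusted across all circuits of a comparison with the Benjamini–Hochberg
step-up FDR procedure.  Each circuit is called UP when the case-group median
activity exceeds the reference median and DOWN when it is lower.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GroupLabels:
    """Binary sample grouping with a designated case level."""

    assignments: dict[str, str]  # sample_id -> level
    case: str
    reference: str

    def __post_init__(self) -> None:
        levels = set(self.assignments.values())
        if levels != {self.case, self.reference}:
            raise ValueError(
                f"labels contain levels {sorted(levels)}, expected exactly "
                f"{{{self.case!r}, {self.reference!r}}}"
            )
        for level in (self.case, self.reference):
            n = sum(1 for v in self.assignments.values() if v == level)
            if n < 2:
                raise ValueError(f"group {level!r} has {n} samples; need >= 2")

    @property
    def case_samples(self) -> list[str]:
        return [s for s, v in self.assignments.items() if v == self.case]

    @property
    def reference_samples(self) -> list[str]:
        return [s for s, v in self.assignments.items() if v == self.reference]

    def swapped(self) -> "GroupLabels":
        return GroupLabels(self.assignments, case=self.reference,
                           reference=self.case)

    @classmethod
    def from_series(cls, series: pd.Series, case: str,
                    reference: str | None = None) -> "GroupLabels":
        if reference is None:
            others = sorted(set(series) - {case})
            if len(others) != 1:
                raise ValueError(
                    f"cannot infer reference level from {sorted(set(series))}"
                )
            reference = others[0]
        return cls(dict(series.astype(str)), case=case, reference=reference)

    @classmethod
    def from_tsv(cls, path: str | Path, case: str,
                 sample_col: str = "sample_id", group_col: str = "group",
                 reference: str | None = None) -> "GroupLabels":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for col in (sample_col, group_col):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls.from_series(df.set_index(sample_col)[group_col],
                               case=case, reference=reference)


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float]:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Uses the exact null distribution when the pooled sample is small
    (n ≤ ``exact_max_n``) and tie-free; otherwise the normal approximation
    with tie and continuity corrections.  Returns (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_max_n and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_activity(
    activity: pd.DataFrame,
    labels: GroupLabels,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-circuit rank-sum test of case vs reference activities.

    Returns one row per circuit: statistic, raw and FDR-adjusted p-value,
    UP/DOWN status from group medians (ties are reported UP with
    ``tie=True``), per-group medians, and a significance call at ``alpha``
    on the adjusted p-value.  Sorted by adjusted p, then circuit id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    missing = [s for s in labels.assignments if s not in activity.columns]
    if missing:
        raise ValueError(f"labeled samples absent from activity matrix: "
                         f"{missing[:5]}")
    case_m = activity[labels.case_samples].to_numpy(dtype=float)
    ref_m = activity[labels.reference_samples].to_numpy(dtype=float)

    rows = []
    for i, circuit_id in enumerate(activity.index):
        stat, p = wilcoxon_rank_sum(case_m[i], ref_m[i])
        med_case = float(np.median(case_m[i]))
        med_ref = float(np.median(ref_m[i]))
        tie = med_case == med_ref
        status = "DOWN" if med_case < med_ref else "UP"
        effector = circuit_id.split(":", 1)[1] if ":" in circuit_id else circuit_id
        rows.append({
            "circuit_id": circuit_id,
            "effector": effector,
            "statistic": stat,
            "p_value": p,
            "status": status,
            "tie": tie,
            "median_case": med_case,
            "median_reference": med_ref,
        })
    out = pd.DataFrame(rows)
    out["fdr_p"] = adjust_fdr(out["p_value"].to_numpy())
    out["significant"] = out["fdr_p"] <= alpha
    out = out.sort_values(["fdr_p", "circuit_id"], kind="mergesort")
    columns = ["circuit_id", "effector", "statistic", "p_value", "fdr_p",
               "status", "tie", "median_case", "median_reference",
               "significant"]
    return out[columns].reset_index(drop=True)
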