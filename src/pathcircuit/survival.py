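"""Survival screening of circuit activities.

For each circuit, patients are split into the 10% with the highest (or
lowest) activity versus the rest; Kaplan–Meier curves are estimated per
stratum and the strata are compared with the standard (unweighted) log-rank
test, whose chi-square statistic (1 df) yields a p-value.  P-values are
FDR-adjusted jointly across all circuit × tail tests of a screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

from .differential import adjust_fdr

HIGH = "high10"
LOW = "low10"


class ConstantActivityError(ValueError):
    """Stratification is meaningless on a constant activity vector."""


@dataclass
class SurvivalData:
    """Follow-up times and event indicators, indexed by sample id."""

    table: pd.DataFrame  # columns: time, event; index: sample_id

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids in survival table")
        if (t["time"].to_numpy(dtype=float) < 0).any():
            raise ValueError("follow-up times must be nonnegative")
        if not set(np.unique(t["event"].to_numpy())) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @classmethod
    def from_tsv(cls, path: str | Path, sample_col: str = "sample_id",
                 time_col: str = "time", event_col: str = "event") -> "SurvivalData":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in (sample_col, time_col, event_col):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        table = df.set_index(sample_col)[[time_col, event_col]]
        table.columns = ["time", "event"]
        return cls(table.astype({"time": float, "event": int}))


def stratify_by_activity(
    activity: pd.Series,
    fraction: float = 0.10,
    tail: str = HIGH,
) -> pd.Series:
    """Boolean tail-membership labels for one circuit's activities.

    The tail group holds k = round(fraction·n) samples, floored at 2 (a
    warning is issued when the floor kicks in).  Membership is by activity
    rank; ties spanning the cutoff are broken by ascending sample id so the
    split is deterministic and has size exactly k.
    """
    if tail not in (HIGH, LOW):
        raise ValueError(f"tail must be {HIGH!r} or {LOW!r}")
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must be in (0, 0.5)")
    n = len(activity)
    if n < 4:
        raise ValueError(f"need at least 4 samples to stratify, got {n}")
    values = activity.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ConstantActivityError(
            "constant activity vector: stratification undefined"
        )
    k = int(np.floor(fraction * n + 0.5))
    if k < 2:
        warnings.warn(
            f"tail size round({fraction}*{n}) < 2; clamped to 2", stacklevel=2
        )
        k = 2
    order = sorted(
        activity.index,
        key=(lambda s: (-activity[s], s)) if tail == HIGH
        else (lambda s: (activity[s], s)),
    )
    members = set(order[:k])
    return pd.Series([s in members for s in activity.index],
                     index=activity.index, name="in_tail")


@dataclass
class KMEstimate:
    """Product-limit survival curve for one stratum."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) just after each event time


def km_estimate(labels: pd.Series, data: SurvivalData) -> dict[bool, KMEstimate]:
    """Kaplan–Meier estimate per stratum (True = tail group).

    Censored samples leave the risk set without stepping the curve down.
    """
    out: dict[bool, KMEstimate] = {}
    table = data.table.loc[labels.index]
    for group in (False, True):
        sub = table[labels == group]
        if sub.empty:
            raise ValueError(f"stratum {group} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        ev = kmf.event_table
        ev = ev[ev["observed"] > 0]
        times = ev.index.to_numpy(dtype=float)
        out[group] = KMEstimate(
            event_times=times,
            at_risk=ev["at_risk"].to_numpy(dtype=float),
            survival=kmf.survival_function_at_times(times).to_numpy(dtype=float),
        )
    return out


def logrank_test(labels: pd.Series, data: SurvivalData) -> tuple[float, float]:
    """Standard (rho = 0) two-group log-rank test.

    Returns (chi-square with 1 df, p).  Two groups with identical survival
    experience give chi-square 0, p = 1.  With no events at all the test is
    undefined and (0, nan) is returned.
    """
    table = data.table.loc[labels.index]
    a = table[labels.astype(bool)]
    b = table[~labels.astype(bool)]
    if a.empty or b.empty:
        raise ValueError("both groups must be non-empty")
    if table["event"].sum() == 0:
        return 0.0, float("nan")
    res = _lifelines_logrank(
        a["time"], b["time"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):  # zero-variance degenerate split
        return 0.0, 1.0
    return chi2, p


def survival_screen(
    activity: pd.DataFrame,
    data: SurvivalData,
    fraction: float = 0.10,
    alpha: float = 0.05,
    fdr_family: str = "joint",
) -> pd.DataFrame:
    """Screen every circuit for survival association in both tails.

    Samples missing survival data are dropped (their count is recorded in
    the returned frame's ``attrs``).  Circuits whose activity is constant,
    or tails with no events, are kept as rows with ``skip_reason`` set and
    excluded from the FDR family.  ``fdr_family`` is ``"joint"`` (all
    circuit × tail tests; default, conservative) or ``"per_tail"``.
    """
    if fdr_family not in ("joint", "per_tail"):
        raise ValueError("fdr_family must be 'joint' or 'per_tail'")
    common = [s for s in activity.columns if s in data.sample_ids]
    n_dropped = activity.shape[1] - len(common)
    if len(common) < 4:
        raise ValueError("fewer than 4 samples have survival data")
    sub_data = SurvivalData(data.table.loc[common])
    rows = []
    for circuit_id in activity.index:
        act = activity.loc[circuit_id, common]
        for tail in (HIGH, LOW):
            row = {"circuit_id": circuit_id, "tail": tail,
                   "n_tail": 0, "n_rest": 0,
                   "chi_square": np.nan, "p_value": np.nan,
                   "skip_reason": ""}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    labels = stratify_by_activity(act, fraction, tail)
                chi2, p = logrank_test(labels, sub_data)
                row["n_tail"] = int(labels.sum())
                row["n_rest"] = int((~labels).sum())
                if np.isnan(p):
                    row["skip_reason"] = "no events"
                else:
                    row["chi_square"] = chi2
                    row["p_value"] = p
            except ConstantActivityError:
                row["skip_reason"] = "constant activity"
            rows.append(row)
    out = pd.DataFrame(rows)
    out["fdr_p"] = np.nan
    tested = out["p_value"].notna()
    if fdr_family == "joint":
        if tested.any():
            out.loc[tested, "fdr_p"] = adjust_fdr(out.loc[tested, "p_value"])
    else:
        for tail in (HIGH, LOW):
            mask = tested & (out["tail"] == tail)
            if mask.any():
                out.loc[mask, "fdr_p"] = adjust_fdr(out.loc[mask, "p_value"])
    out["significant"] = out["fdr_p"] <= alpha
    out = out.sort_values(["fdr_p", "circuit_id", "tail"],
                          kind="mergesort", na_position="last")
    out = out.reset_index(drop=True)
    out.attrs["n_samples_dropped"] = n_dropped
    return out
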