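"""Tail stratification, Kaplan-Meier estimation and the log-rank screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathcircuit import (
    ConstantActivityError,
    SurvivalData,
    km_estimate,
    logrank_test,
    stratify_by_activity,
    survival_screen,
)
from pathcircuit.survival import HIGH, LOW


def surv_data(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalData(pd.DataFrame(
        {"time": np.asarray(times, dtype=float),
         "event": np.asarray(events, dtype=int)},
        index=pd.Index(ids, name="sample_id")))


def reference_logrank(times, events, group):
    """Independent hand-rolled log-rank chi-square (O−E with hypergeometric
    variance summed over distinct event times)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & group).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return chi2, stats.chi2.sf(chi2, df=1)


class TestStratify:
    def activity(self, values, ids=None):
        ids = ids or [f"s{i}" for i in range(len(values))]
        return pd.Series(np.asarray(values, float), index=ids)

    def test_ten_percent_of_twenty_is_two(self):
        act = self.activity(np.arange(20))
        labels = stratify_by_activity(act, 0.10, HIGH)
        assert labels.sum() == 2
        assert set(labels[labels].index) == {"s18", "s19"}

    def test_low_tail(self):
        act = self.activity(np.arange(20))
        labels = stratify_by_activity(act, 0.10, LOW)
        assert set(labels[labels].index) == {"s0", "s1"}

    def test_small_n_clamped_with_warning(self):
        act = self.activity(np.arange(10))
        with pytest.warns(UserWarning, match="clamped"):
            labels = stratify_by_activity(act, 0.10, HIGH)
        assert labels.sum() == 2

    def test_tie_broken_by_sample_id(self):
        act = self.activity([0.0] * 10 + [1.0] * 10)
        labels = stratify_by_activity(act, 0.10, HIGH)
        assert labels.sum() == 2
        assert set(labels[labels].index) == {"s10", "s11"}

    def test_constant_vector_flagged(self):
        with pytest.raises(ConstantActivityError):
            stratify_by_activity(self.activity([0.5] * 30), 0.10, HIGH)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="fraction"):
            stratify_by_activity(self.activity(np.arange(30)), 0.6, HIGH)


def km_one_group(times, events):
    """KM curve of the given samples, padding a disjoint dummy tail group."""
    n = len(times)
    data = surv_data(list(times) + [99.0, 99.0],
                     list(events) + [0, 0],
                     ids=[f"s{i}" for i in range(n)] + ["zz0", "zz1"])
    labels = pd.Series([False] * n + [True, True], index=data.sample_ids)
    return km_estimate(labels, data)[False]


class TestKaplanMeier:
    def test_no_censoring_steps(self):
        est = km_one_group([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(est.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat_curve(self):
        est = km_one_group([5, 6, 7], [0, 0, 0])
        assert est.event_times.size == 0  # no steps: S(t) stays at 1

    def test_empty_group_rejected(self):
        data = surv_data([1, 2], [1, 1])
        labels = pd.Series([False, False], index=data.sample_ids)
        with pytest.raises(ValueError, match="empty"):
            km_estimate(labels, data)

    def test_mixed_censoring_matches_hand_table(self):
        # times 1, 2+, 3, 4+, 5 -> S = 4/5, then 4/5*(2/3), then 0
        est = km_one_group([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        np.testing.assert_allclose(est.event_times, [1, 3, 5])
        np.testing.assert_allclose(est.at_risk, [5, 3, 1])
        np.testing.assert_allclose(est.survival,
                                   [4 / 5, 4 / 5 * 2 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(5, size=40)
        est = km_one_group(t, np.ones(40, int))
        empirical = [(t > ti).mean() for ti in est.event_times]
        np.testing.assert_allclose(est.survival, empirical, atol=1e-12)

    def test_survival_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(5, size=50)
        e = rng.integers(0, 2, size=50)
        e[0] = 1
        est = km_one_group(t, e)
        assert (np.diff(est.survival) <= 1e-12).all()
        assert ((est.survival >= 0) & (est.survival <= 1)).all()

    def test_sample_order_invariance(self):
        t = [3, 1, 4, 1.5, 5.0]
        e = [1, 0, 1, 1, 0]
        a = km_one_group(t, e)
        order = [4, 2, 0, 3, 1]
        b = km_one_group([t[i] for i in order], [e[i] for i in order])
        np.testing.assert_allclose(a.survival, b.survival)


class TestLogrank:
    def test_identical_groups_zero_chi_square(self):
        times = [1, 2, 3, 4, 5.0] * 2
        events = [1, 1, 0, 1, 1] * 2
        data = surv_data(times, events)
        labels = pd.Series([True] * 5 + [False] * 5, index=data.sample_ids)
        chi2, p = logrank_test(labels, data)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_event_closed_form(self):
        # one event in the tail group at t=1 among 3 at risk (1 vs 2):
        # O−E = 1 − 1/3, V = (1/3)(2/3) -> chi2 = (2/3)^2/(2/9) = 2
        data = surv_data([1, 5, 5], [1, 0, 0])
        labels = pd.Series([True, False, False], index=data.sample_ids)
        chi2, p = logrank_test(labels, data)
        assert chi2 == pytest.approx(2.0)
        assert p == pytest.approx(stats.chi2.sf(2.0, 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        t = rng.exponential(5, size=n)
        e = rng.integers(0, 2, size=n)
        e[:3] = 1
        g = rng.integers(0, 2, size=n).astype(bool)
        g[:2] = [True, False]
        data = surv_data(t, e)
        labels = pd.Series(g, index=data.sample_ids)
        chi2, p = logrank_test(labels, data)
        ref_chi2, ref_p = reference_logrank(t, e, g)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-8)
        assert p == pytest.approx(ref_p, rel=1e-8)

    def test_group_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(5, size=20)
        e = np.ones(20, int)
        g = np.array([True] * 5 + [False] * 15)
        data = surv_data(t, e)
        a = logrank_test(pd.Series(g, index=data.sample_ids), data)
        b = logrank_test(pd.Series(~g, index=data.sample_ids), data)
        assert a[0] == pytest.approx(b[0])

    def test_no_events_flagged(self):
        data = surv_data([1, 2, 3, 4], [0, 0, 0, 0])
        labels = pd.Series([True, True, False, False], index=data.sample_ids)
        chi2, p = logrank_test(labels, data)
        assert np.isnan(p)


class TestScreen:
    def _screen_inputs(self, rng, n=60, n_circuits=5, planted=False):
        ids = [f"s{i:03d}" for i in range(n)]
        act = pd.DataFrame(rng.uniform(size=(n_circuits, n)),
                           index=[f"P{i}:E{i}" for i in range(n_circuits)],
                           columns=ids)
        hazard = np.full(n, 0.2)
        if planted:
            top = act.iloc[0].to_numpy().argsort()[-6:]
            hazard[top] *= 8.0
        t = rng.exponential(1 / hazard)
        data = surv_data(t, np.ones(n), ids=ids)
        return act, data

    def test_null_screen_not_significant(self):
        rng = np.random.default_rng(10)
        act, data = self._screen_inputs(rng)
        out = survival_screen(act, data)
        assert len(out) == 10  # both tails per circuit
        assert not out["significant"].any()

    def test_planted_effect_ranks_first(self):
        rng = np.random.default_rng(11)
        act, data = self._screen_inputs(rng, planted=True)
        out = survival_screen(act, data)
        top = out.iloc[0]
        assert top["circuit_id"] == "P0:E0"
        assert top["tail"] == HIGH
        assert top["significant"]

    def test_constant_circuit_skipped(self):
        rng = np.random.default_rng(12)
        act, data = self._screen_inputs(rng)
        act.iloc[2, :] = 0.5
        out = survival_screen(act, data)
        skipped = out[out["circuit_id"] == "P2:E2"]
        assert (skipped["skip_reason"] == "constant activity").all()
        assert skipped["fdr_p"].isna().all()

    def test_missing_survival_samples_dropped(self):
        rng = np.random.default_rng(13)
        act, data = self._screen_inputs(rng)
        short = SurvivalData(data.table.iloc[:-5])
        out = survival_screen(act, short)
        assert out.attrs["n_samples_dropped"] == 5
        assert (out["n_tail"] + out["n_rest"] == 55).all()

    def test_per_tail_family_option(self):
        rng = np.random.default_rng(14)
        act, data = self._screen_inputs(rng)
        from pathcircuit import adjust_fdr

        joint = survival_screen(act, data, fdr_family="joint")
        per = survival_screen(act, data, fdr_family="per_tail")
        merged = joint.merge(per, on=["circuit_id", "tail"],
                             suffixes=("_j", "_p"))
        np.testing.assert_allclose(merged["p_value_j"], merged["p_value_p"])
        for tail in (HIGH, LOW):
            sub = merged[merged["tail"] == tail]
            np.testing.assert_allclose(
                sub["fdr_p_p"], adjust_fdr(sub["p_value_p"]), atol=1e-12)
        np.testing.assert_allclose(
            merged["fdr_p_j"], adjust_fdr(merged["p_value_j"]), atol=1e-12)
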