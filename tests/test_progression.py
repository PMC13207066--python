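"""Stratification, survival testing, stage association, and the final call."""

import numpy as np
import pandas as pd
import pytest

from cpcellsub import (
    ClinicalCohort,
    call_progression,
    stage_association,
    stratify_by_score,
    survival_association,
)
from cpcellsub.progression import AssociationResult, AxisResult


def make_cohort(os_time, os_event, **stages):
    n = len(os_time)
    table = pd.DataFrame({
        "os_time": os_time,
        "os_event": os_event,
        "t_stage": stages.get("t", [np.nan] * n),
        "n_stage": stages.get("n", [np.nan] * n),
        "m_stage": stages.get("m", [np.nan] * n),
        "tnm_stage": stages.get("tnm", [np.nan] * n),
    }, index=[f"S{i}" for i in range(n)])
    return ClinicalCohort(table)


class TestStratify:
    def test_median_split(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = stratify_by_score(s)
        assert list(groups[groups == "low"].index) == ["a", "b"]
        assert list(groups[groups == "high"].index) == ["c", "d"]

    def test_upper_quartile(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups = stratify_by_score(s, quantile=0.75)
        assert list(groups[groups == "high"].index) == ["d"]

    def test_constant_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            stratify_by_score(pd.Series([2.0, 2.0, 2.0]))


class TestLogRank:
    def hand_logrank_chi2(self, times_a, times_b):
        """Independent oracle: the O-E/V table over distinct event times,
        all events observed, no censoring."""
        all_times = sorted(set(times_a) | set(times_b))
        o_minus_e = 0.0
        v = 0.0
        for t in all_times:
            n_a = sum(1 for x in times_a if x >= t)
            n_b = sum(1 for x in times_b if x >= t)
            n = n_a + n_b
            d = sum(1 for x in times_a if x == t) + sum(1 for x in times_b if x == t)
            o_a = sum(1 for x in times_a if x == t)
            e_a = d * n_a / n
            o_minus_e += o_a - e_a
            if n > 1:
                v += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
        return o_minus_e**2 / v

    def test_matches_hand_enumeration(self):
        times_a, times_b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        cohort = make_cohort(times_a + times_b, [1] * 6)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=cohort.sample_ids)
        p, direction, fits = survival_association(groups, cohort)
        from lifelines.statistics import logrank_test

        res = logrank_test(times_a, times_b, event_observed_A=[1] * 3,
                           event_observed_B=[1] * 3)
        expected = self.hand_logrank_chi2(times_a, times_b)
        assert res.test_statistic == pytest.approx(expected, abs=1e-10)
        import scipy.stats
        assert p == pytest.approx(scipy.stats.chi2.sf(expected, 1), abs=1e-10)
        assert direction == "high_worse"

    def test_identical_groups_p_one(self):
        times = [2.0, 4.0, 6.0, 2.0, 4.0, 6.0]
        cohort = make_cohort(times, [1] * 6)
        groups = pd.Series(["high", "high", "high", "low", "low", "low"],
                           index=cohort.sample_ids)
        p, _, _ = survival_association(groups, cohort)
        assert p == pytest.approx(1.0)

    def test_degenerate_risk_sets_error(self):
        # one arm entirely censored before any event: no overlapping risk sets
        cohort = make_cohort([1.0, 2.0, 3.0, 0.5, 0.5, 0.5], [1, 1, 1, 0, 0, 0])
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=cohort.sample_ids)
        with pytest.raises(ValueError, match="degenerate"):
            survival_association(groups, cohort)

    def test_no_events_error(self):
        cohort = make_cohort([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        groups = pd.Series(["high", "high", "low", "low"], index=cohort.sample_ids)
        with pytest.raises(ValueError, match="events"):
            survival_association(groups, cohort)


class TestStageAssociation:
    def _cohort_with_t(self, t_codes):
        n = len(t_codes)
        return make_cohort([10.0] * n, [1] * n, t=t_codes)

    def test_monotone_increase_gives_rho_one(self):
        # scores constant within each stage level: identical tie structure,
        # so the tie-corrected correlation is exactly 1
        t = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        scores = pd.Series([10.0] * 3 + [20.0] * 3 + [30.0] * 3,
                           index=[f"S{i}" for i in range(9)])
        res = stage_association(scores, self._cohort_with_t(t), "T")
        assert res.spearman_r == pytest.approx(1.0)
        assert res.group_test == "kruskal_wallis"
        assert res.group_test_p < 0.05

    def test_monotone_decrease_symmetric(self):
        t = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        scores = pd.Series([30.0] * 3 + [20.0] * 3 + [10.0] * 3,
                           index=[f"S{i}" for i in range(9)])
        res = stage_association(scores, self._cohort_with_t(t), "T")
        assert res.spearman_r == pytest.approx(-1.0)
        assert res.group_test_p < 0.05

    def test_binary_axis_uses_wilcoxon(self):
        cohort = make_cohort([10.0] * 10, [1] * 10, m=[0] * 5 + [1] * 5)
        scores = pd.Series(np.arange(10, dtype=float), index=cohort.sample_ids)
        res = stage_association(scores, cohort, "M")
        assert res.group_test == "wilcoxon"
        assert res.group_test_p < 0.05

    def test_single_level_not_evaluable(self):
        cohort = make_cohort([10.0] * 6, [1] * 6, t=[2] * 6)
        scores = pd.Series(np.arange(6, dtype=float), index=cohort.sample_ids)
        res = stage_association(scores, cohort, "T")
        assert not res.evaluable

    def test_monotone_rescaling_invariance(self):
        t = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        cohort = self._cohort_with_t(t)
        rng = np.random.default_rng(2)
        base = pd.Series(rng.normal(size=9), index=cohort.sample_ids)
        res1 = stage_association(base, cohort, "T")
        res2 = stage_association(np.exp(base * 3.0), cohort, "T")
        assert res1.group_test_p == pytest.approx(res2.group_test_p, abs=1e-12)
        assert res1.spearman_r == pytest.approx(res2.spearman_r, abs=1e-12)


class TestCallPolicy:
    def _result(self, os_p, axis_ps, rhos=None):
        rhos = rhos or {a: 0.3 for a in "T N M TNM".split()}
        res = AssociationResult("sp", os_logrank_p=os_p, os_direction="high_worse")
        for axis, p in axis_ps.items():
            res.axes[axis] = AxisResult(
                axis=axis, group_test_p=p, spearman_r=rhos[axis], spearman_p=p,
                n_used=100,
            )
        return res

    def test_all_axes_and_os_significant(self):
        res = self._result(0.01, {a: 0.001 for a in "T N M TNM".split()})
        call = call_progression(res)
        assert call.called and set(call.axes_significant) == {"T", "N", "M", "TNM"}

    def test_os_not_significant_blocks_call(self):
        res = self._result(0.2, {a: 0.001 for a in "T N M TNM".split()})
        assert not call_progression(res).called

    def test_min_axes_one_with_single_axis(self):
        res = self._result(0.01, {"T": 0.001, "N": 0.9, "M": 0.9, "TNM": 0.9})
        call = call_progression(res, min_axes=1)
        assert call.called and call.axes_significant == ["T"]
        assert not call_progression(res, min_axes=4).called

    def test_direction_consistency_blocks_mixed_signs(self):
        rhos = {"T": 0.3, "N": -0.3, "M": 0.3, "TNM": 0.3}
        res = self._result(0.01, {a: 0.001 for a in "T N M TNM".split()}, rhos)
        assert not call_progression(res, min_axes=1).called
        assert call_progression(res, min_axes=1, direction_consistent=False).called
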