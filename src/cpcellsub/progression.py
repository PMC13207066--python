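"""Progression-association calling for scored cell subpopulations.

Given per-sample abundance scores for a subpopulation and a clinically
annotated cohort, this module (1) stratifies samples into high/low
infiltration groups at a score quantile, (2) tests overall survival between
the groups with the log-rank test, (3) tests abundance differences across
each staging axis (Wilcoxon rank-sum for the binary N and M axes,
Kruskal-Wallis for the multi-level T and overall-stage axes) together with
a Spearman correlation of abundance against the ordinal stage code, and
(4) emits the final call: a subpopulation is progression-associated when
its infiltration predicts prognosis (log-rank p < alpha) and is
significantly associated with at least ``min_axes`` staging axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time

from .data_model import ClinicalCohort
from .stats import kruskal_wallis, spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "AxisResult",
    "AssociationResult",
    "ProgressionCall",
    "stratify_by_score",
    "survival_association",
    "stage_association",
    "call_progression",
    "associate_subpopulation",
]

AXES = ("T", "N", "M", "TNM")
BINARY_AXES = frozenset({"N", "M"})


@dataclass
class AxisResult:
    """Association of one score vector with one staging axis."""

    axis: str
    group_test_p: float = float("nan")
    group_test: str = ""
    spearman_r: float = float("nan")
    spearman_p: float = float("nan")
    n_used: int = 0
    evaluable: bool = True


@dataclass
class AssociationResult:
    """All survival and staging statistics for one subpopulation."""

    subpopulation: str
    os_logrank_p: float = float("nan")
    os_direction: str = ""  # high_worse | high_better
    n_os: int = 0
    axes: dict[str, AxisResult] = field(default_factory=dict)


@dataclass
class ProgressionCall:
    """Final progression-association decision for one subpopulation."""

    subpopulation: str
    called: bool
    axes_significant: list[str]
    policy: dict


def stratify_by_score(scores: pd.Series, quantile: float = 0.5) -> pd.Series:
    """Split samples into high (score > quantile cutpoint) and low groups.

    Returns a Series of {"high", "low"} labels. Constant scores cannot be
    stratified and raise.
    """
    vals = scores.to_numpy(dtype=float)
    if len(np.unique(vals)) < 2:
        raise ValueError("degenerate stratification: constant score vector")
    cut = np.quantile(vals, quantile)
    labels = np.where(vals > cut, "high", "low")
    if (labels == "high").all() or (labels == "low").all():
        # quantile landed on an extreme; fall back to median of distinct values
        cut = np.median(np.unique(vals))
        labels = np.where(vals > cut, "high", "low")
    return pd.Series(labels, index=scores.index, name="group")


def survival_association(
    groups: pd.Series, cohort: ClinicalCohort
) -> tuple[float, str, dict[str, KaplanMeierFitter]]:
    """Two-group log-rank test of overall survival.

    Returns ``(p_value, direction, km_fits)`` where direction is
    ``high_worse`` if the high group has the shorter restricted mean
    survival. Samples with missing survival are dropped and counted.
    """
    common = [s for s in groups.index if s in set(cohort.sample_ids)]
    clin = cohort.table.loc[common, ["os_time", "os_event"]]
    ok = clin["os_time"].notna() & clin["os_event"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d sample(s) with missing survival", n_dropped)
    clin = clin[ok]
    grp = groups.loc[clin.index]

    hi = clin[grp == "high"]
    lo = clin[grp == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("a stratum is empty after missing-data removal")
    if clin["os_event"].sum() == 0:
        raise ValueError("no events observed in the pooled data")

    # the comparison is informative only if both groups are at risk at
    # some event time; otherwise O-E = V = 0 identically
    event_times = clin.loc[clin["os_event"] == 1, "os_time"]
    overlap = any(
        (hi["os_time"] >= t).any() and (lo["os_time"] >= t).any()
        for t in event_times
    )
    if not overlap:
        raise ValueError(
            "degenerate log-rank comparison (no overlapping risk sets)"
        )
    res = logrank_test(
        hi["os_time"], lo["os_time"],
        event_observed_A=hi["os_event"], event_observed_B=lo["os_event"],
    )
    fits: dict[str, KaplanMeierFitter] = {}
    rmst: dict[str, float] = {}
    horizon = float(clin["os_time"].max())
    for label, sub in (("high", hi), ("low", lo)):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"], label=label)
        fits[label] = kmf
        rmst[label] = float(restricted_mean_survival_time(kmf, t=horizon))
    direction = "high_worse" if rmst["high"] < rmst["low"] else "high_better"
    return float(res.p_value), direction, fits


def stage_association(
    scores: pd.Series,
    cohort: ClinicalCohort,
    axis: str,
    *,
    min_per_group: int = 3,
) -> AxisResult:
    """Test one staging axis against the score vector.

    Binary axes (N, M) use the two-sided Wilcoxon rank-sum test; multi-level
    axes (T, TNM) use Kruskal-Wallis. The Spearman correlation is computed
    against the ordinal stage codes with average ranks for ties. An axis
    with fewer than two adequately sized stage levels is marked
    non-evaluable rather than erroring.
    """
    if axis not in AXES:
        raise ValueError(f"unknown staging axis {axis!r}")
    stage = cohort.stage(axis)
    common = [s for s in scores.index if s in stage.index]
    stage = stage.loc[common]
    sc = scores.loc[common]
    ok = stage.notna()
    stage, sc = stage[ok], sc[ok]

    res = AxisResult(axis=axis, n_used=int(len(sc)))
    levels = sorted(stage.unique())
    big_levels = [lv for lv in levels if (stage == lv).sum() >= min_per_group]
    if len(big_levels) < 2:
        res.evaluable = False
        return res

    groups = [sc[stage == lv].to_numpy() for lv in big_levels]
    if axis in BINARY_AXES or len(big_levels) == 2:
        stat, p = wilcoxon_rank_sum(groups[0], groups[1])
        res.group_test = "wilcoxon"
    else:
        stat, p = kruskal_wallis(groups)
        res.group_test = "kruskal_wallis"
    res.group_test_p = p
    res.spearman_r, res.spearman_p = spearman(sc.to_numpy(), stage.to_numpy())
    return res


def call_progression(
    result: AssociationResult,
    alpha: float = 0.05,
    min_axes: int = 4,
    direction_consistent: bool = True,
) -> ProgressionCall:
    """Apply the final progression-association rule.

    An axis is significant iff its Spearman p < alpha, |rho| > 0, and the
    group test p < alpha. The subpopulation is called iff the log-rank
    p < alpha and at least ``min_axes`` axes are significant (and, if
    ``direction_consistent``, all significant axes correlate in the same
    direction).
    """
    sig: list[str] = []
    signs: list[float] = []
    for axis in AXES:
        ar = result.axes.get(axis)
        if ar is None or not ar.evaluable:
            continue
        if (
            ar.spearman_p < alpha
            and abs(ar.spearman_r) > 0
            and ar.group_test_p < alpha
        ):
            sig.append(axis)
            signs.append(np.sign(ar.spearman_r))
    called = (
        np.isfinite(result.os_logrank_p)
        and result.os_logrank_p < alpha
        and len(sig) >= min_axes
    )
    if called and direction_consistent and len(set(signs)) > 1:
        called = False
    policy = {
        "alpha": alpha,
        "min_axes": min_axes,
        "direction_consistent": direction_consistent,
    }
    return ProgressionCall(
        subpopulation=result.subpopulation,
        called=bool(called),
        axes_significant=sig,
        policy=policy,
    )


def associate_subpopulation(
    scores: pd.Series,
    cohort: ClinicalCohort,
    subpopulation: str,
    *,
    quantile: float = 0.5,
    min_per_group: int = 3,
) -> AssociationResult:
    """Run survival and all four staging-axis tests for one score vector."""
    common = [s for s in scores.index if s in set(cohort.sample_ids)]
    sc = scores.loc[common]
    result = AssociationResult(subpopulation=subpopulation)
    groups = stratify_by_score(sc, quantile=quantile)
    p, direction, _ = survival_association(groups, cohort)
    result.os_logrank_p = p
    result.os_direction = direction
    result.n_os = int(cohort.table.loc[common, "os_time"].notna().sum())
    for axis in AXES:
        result.axes[axis] = stage_association(
            sc, cohort, axis, min_per_group=min_per_group
        )
    return result


def association_table(
    results: list[AssociationResult],
    calls: list[ProgressionCall],
) -> pd.DataFrame:
    """Flatten results + calls into one row per subpopulation.

    A BH-adjusted log-rank p column across subpopulations is included for
    transparency; the call itself uses the unadjusted per-subpopulation p.
    """
    from .stats import bh_adjust

    rows = []
    for res, call in zip(results, calls):
        row: dict = {
            "subpopulation": res.subpopulation,
            "os_logrank_p": res.os_logrank_p,
            "os_direction": res.os_direction,
            "called": call.called,
            "axes_significant": ",".join(call.axes_significant),
        }
        for axis in AXES:
            ar = res.axes.get(axis, AxisResult(axis=axis, evaluable=False))
            row[f"{axis}_group_p"] = ar.group_test_p
            row[f"{axis}_spearman_r"] = ar.spearman_r
            row[f"{axis}_spearman_p"] = ar.spearman_p
            row[f"{axis}_n"] = ar.n_used
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subpopulation")
    p = df["os_logrank_p"].to_numpy(dtype=float)
    finite = np.isfinite(p)
    adj = np.full(len(p), np.nan)
    if finite.any():
        adj[finite] = bh_adjust(p[finite])
    df.insert(1, "os_logrank_p_bh", adj)
    return df
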