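"""Survival screening of gene pairs.

For each gene pair, tumor samples are split into group 1 (ΔPCC strictly
above the empirical 75th percentile across the cohort, i.e. the top 25%)
and group 2 (the rest). Pairs where either group has fewer than
``min_group`` patients are excluded. Surviving pairs are tested with the
two-sample log-rank test; raw p-values are Benjamini-Hochberg adjusted over
the pairs actually tested. A pair is called prognostic when its adjusted
log-rank p-value and the p-value of its whole-tumor-cohort correlation are
both below their thresholds (default 0.05 each).

Tie handling in the group split: values exactly at the percentile cut fall
into group 2, so heavily tied ΔPCC distributions degrade safely towards
exclusion rather than an arbitrary split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from statsmodels.stats.multitest import multipletests

from .network import ConstantInputError, pcc_pvalue, pearson_cc, spearman_cc
from .types import (
    ExpressionMatrix,
    PairScreenResult,
    SurvivalTable,
    ValidationError,
    split_pair,
)


@dataclass
class GroupAssignment:
    """Two-group split of tumor samples by a pair's ΔPCC values."""

    pair_id: str
    group1: set[str]
    group2: set[str]
    threshold_value: float
    excluded: bool

    @property
    def n1(self) -> int:
        return len(self.group1)

    @property
    def n2(self) -> int:
        return len(self.group2)


def assign_groups(delta_values: Mapping[str, float], fraction: float = 0.25,
                  min_group: int = 10, pair_id: str = "") -> GroupAssignment:
    """Split samples into top-``fraction`` ΔPCC (group 1) vs the rest.

    Group 1 contains the samples strictly above the (1 - fraction) empirical
    percentile (linear interpolation); the assignment is flagged ``excluded``
    when either group has fewer than ``min_group`` members.
    """
    if not delta_values:
        raise ValidationError("no ΔPCC values to group")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    samples = list(delta_values)
    values = np.asarray([delta_values[s] for s in samples], dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValidationError("non-finite ΔPCC value")
    threshold = float(np.quantile(values, 1.0 - fraction))
    in_top = values > threshold
    group1 = {s for s, t in zip(samples, in_top) if t}
    group2 = {s for s, t in zip(samples, in_top) if not t}
    excluded = min(len(group1), len(group2)) < min_group
    return GroupAssignment(pair_id=pair_id, group1=group1, group2=group2,
                           threshold_value=threshold, excluded=excluded)


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 labels: Sequence[int]) -> tuple[float, float]:
    """Unweighted (Mantel-Haenszel) two-sample log-rank test.

    ``labels`` marks group membership (two distinct values). Returns the
    chi-square statistic (1 df) and its p-value.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValidationError(f"expected exactly 2 groups, got {groups.size}")
    if events.sum() == 0:
        raise ValidationError("log-rank test undefined with zero events")
    a = labels == groups[0]
    res = _lifelines_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, each p_j maps to min(1, p_j * m / j) with monotonicity
    enforced by a cumulative minimum from the largest rank down.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times, "survival": self.survival,
            "at_risk": self.at_risk, "n_events": self.n_events,
        })


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("no survival records")
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    table = fitter.event_table
    mask = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[mask]
    surv = fitter.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMEstimate(
        event_times=event_times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float)[mask].astype(int),
        n_events=table["observed"].to_numpy(dtype=float)[mask].astype(int),
    )


def km_by_group(survival: SurvivalTable, group1: set[str]) -> dict[str, KMEstimate]:
    """KM estimates for group 1 and group 2 of a pair's split."""
    mask = np.asarray([s in group1 for s in survival.sample_ids])
    out = {}
    for name, sel in (("group1", mask), ("group2", ~mask)):
        if sel.any():
            out[name] = kaplan_meier(survival.time[sel], survival.event[sel])
    return out


def _tumor_pcc(tumor_expr: ExpressionMatrix, gene_a: str, gene_b: str,
               samples: Sequence[str], method: str) -> tuple[float, float]:
    idx = [tumor_expr.sample_ids.index(s) for s in samples]
    x = tumor_expr.gene_values(gene_a)[idx]
    y = tumor_expr.gene_values(gene_b)[idx]
    corr = pearson_cc if method == "pearson" else spearman_cc
    try:
        r = corr(x, y)
    except ConstantInputError:
        return 0.0, 1.0
    return r, pcc_pvalue(r, len(samples))


def screen_pairs(delta: pd.DataFrame, survival: SurvivalTable,
                 tumor_expr: ExpressionMatrix, fraction: float = 0.25,
                 min_group: int = 10, method: str = "pearson",
                 ) -> list[PairScreenResult]:
    """Log-rank screen of every pair in a ΔPCC tensor.

    ``delta`` is indexed by canonical pair id with one column per tumor
    sample. Groups are formed over all samples in the tensor; the log-rank
    test runs on the samples that also have survival records. Excluded
    pairs (either group under ``min_group``) produce no p-value and do not
    count towards the BH adjustment's number of tests.
    """
    surv_ids = [s for s in delta.columns if s in set(survival.sample_ids)]
    if not surv_ids:
        raise ValidationError("no tumor sample in the ΔPCC tensor has survival data")
    if len(surv_ids) < len(delta.columns):
        warnings.warn(
            f"{len(delta.columns) - len(surv_ids)} tumor samples lack survival "
            "records and are ignored in the log-rank test",
            stacklevel=2,
        )
    surv = survival.subset(surv_ids)
    tested: list[PairScreenResult] = []
    raw_p: list[float] = []
    for pair_id, row in delta.iterrows():
        assignment = assign_groups(row.to_dict(), fraction=fraction,
                                   min_group=min_group, pair_id=pair_id)
        if assignment.excluded:
            continue
        labels = np.asarray([1 if s in assignment.group1 else 2 for s in surv_ids])
        if len(set(labels)) < 2 or surv.n_events == 0:
            continue
        stat, p = logrank_test(surv.time, surv.event, labels)
        gene_a, gene_b = split_pair(pair_id)
        pcc_t, pcc_t_p = _tumor_pcc(tumor_expr, gene_a, gene_b, surv_ids, method)
        tested.append(PairScreenResult(
            gene_a=gene_a, gene_b=gene_b,
            n_group1=int((labels == 1).sum()), n_group2=int((labels == 2).sum()),
            logrank_stat=stat, p_raw=p, p_adj=np.nan,
            pcc_tumor=pcc_t, pcc_tumor_p=pcc_t_p,
        ))
        raw_p.append(p)
    if not tested:
        warnings.warn("no gene pair survived the group-size exclusion", stacklevel=2)
        return []
    adjusted = bh_adjust(raw_p)
    for result, p_adj in zip(tested, adjusted):
        result.p_adj = float(p_adj)
    return tested


def select_prognostic(results: Sequence[PairScreenResult], alpha_adj: float = 0.05,
                      alpha_pcc: float = 0.05) -> list[PairScreenResult]:
    """Prognostic pairs: adjusted log-rank p and tumor-PCC p both below threshold.

    Sets the ``selected`` flag on every result and returns the selected
    subset sorted by adjusted p-value ascending.
    """
    for r in results:
        r.selected = bool(r.p_adj < alpha_adj and r.pcc_tumor_p < alpha_pcc)
    chosen = [r for r in results if r.selected]
    chosen.sort(key=lambda r: (r.p_adj, r.p_raw, r.pair_id))
    return chosen
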