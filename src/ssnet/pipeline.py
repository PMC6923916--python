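"""End-to-end orchestration: reference network → per-patient ΔPCC →
pair screening → selection → Cox → exports.

``run_pipeline`` reads the four inputs (normal and tumor expression, an
optional gene set restricting the universe, the survival table), computes
the ΔPCC tensor for every pair and tumor sample, screens the pairs that
pass the dual-significance edge filter in at least one patient network,
selects prognostic pairs, attaches Cox hazard ratios, and writes results
plus a machine-readable summary to the run directory. Outputs are
deterministic for a fixed config; the summary contains no timestamps so
reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .cox import confounder_check, group_hazard_ratio
from .io import (
    read_expression,
    read_gene_set,
    read_survival,
    write_results,
    write_results_json,
)
from .network import build_network, count_delta_pccs, delta_pcc_tensor
from .prognostic import assign_groups, bh_adjust, logrank_test, screen_pairs, select_prognostic
from .types import ExpressionMatrix, PairScreenResult, SurvivalTable, ValidationError

PathLike = Union[str, Path]
logger = logging.getLogger("ssnet")

_SEMANTIC_FIELDS = (
    "normal_expression", "tumor_expression", "gene_set", "survival",
    "alpha_edge", "fraction", "min_group", "alpha_adj", "alpha_pcc",
    "correlation_kind", "seed",
)


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one pipeline run."""

    normal_expression: str
    tumor_expression: str
    survival: str
    gene_set: Optional[str] = None
    alpha_edge: float = 0.05
    fraction: float = 0.25
    min_group: int = 10
    alpha_adj: float = 0.05
    alpha_pcc: float = 0.05
    correlation_kind: str = "pearson"
    output_dir: str = "ssnet_run"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_edge", "alpha_adj", "alpha_pcc", "fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.min_group < 1:
            raise ValidationError("min_group must be >= 1")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValidationError(f"unknown correlation kind {self.correlation_kind!r}")

    @classmethod
    def from_json(cls, path: PathLike) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")

    def config_hash(self) -> str:
        """Hash over the semantically meaningful fields (not output_dir)."""
        payload = {k: getattr(self, k) for k in _SEMANTIC_FIELDS}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _restrict_to_gene_set(expr: ExpressionMatrix, symbols: Sequence[str],
                          label: str) -> ExpressionMatrix:
    keep = [g for g in expr.gene_ids if g in set(symbols)]
    if len(keep) < 2:
        raise ValidationError(f"fewer than 2 gene-set genes present in {label} matrix")
    return expr.subset_genes(keep)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen; returns the summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    normal = read_expression(config.normal_expression)
    tumor = read_expression(config.tumor_expression)
    survival = read_survival(config.survival)

    if config.gene_set is not None:
        gene_set = read_gene_set(config.gene_set)
        normal = _restrict_to_gene_set(normal, gene_set.symbols, "normal")
        tumor = _restrict_to_gene_set(tumor, gene_set.symbols, "tumor")

    diff = set(normal.gene_ids) ^ set(tumor.gene_ids)
    if diff:
        raise ValidationError(
            f"normal and tumor matrices disagree on genes: {sorted(diff)}")
    if not set(tumor.sample_ids) & set(survival.sample_ids):
        raise ValidationError("no tumor sample has survival data")

    k = normal.n_genes
    n_tumor = tumor.n_samples
    logger.info("computing ΔPCC tensor: %d pairs x %d patients "
                "(%d ΔPCC values)", k * (k - 1) // 2, n_tumor,
                count_delta_pccs(n_tumor, k))
    delta, edge = delta_pcc_tensor(normal, tumor, alpha_edge=config.alpha_edge,
                                   method=config.correlation_kind)
    cache = out / f"delta_cache_{config.config_hash()}.npz"
    np.savez_compressed(cache, delta=delta.to_numpy(), edge=edge.to_numpy(),
                        pairs=np.array(delta.index), samples=np.array(delta.columns))
    logger.info("ΔPCC tensor done in %.2fs", time.perf_counter() - t0)

    edge_any = edge.any(axis=1)
    candidates = delta.loc[edge_any]
    logger.info("%d / %d pairs pass the dual-significance edge filter "
                "in at least one patient network", len(candidates), len(delta))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = screen_pairs(candidates, survival, tumor,
                               fraction=config.fraction,
                               min_group=config.min_group,
                               method=config.correlation_kind)
    selected = select_prognostic(results, alpha_adj=config.alpha_adj,
                                 alpha_pcc=config.alpha_pcc)

    surv_ids = [s for s in delta.columns if s in set(survival.sample_ids)]
    surv = survival.subset(surv_ids)
    for r in selected:
        assignment = assign_groups(candidates.loc[r.pair_id].to_dict(),
                                   fraction=config.fraction,
                                   min_group=config.min_group,
                                   pair_id=r.pair_id)
        fit = group_hazard_ratio(surv, assignment.group1)
        entry = fit.for_covariate("group1")
        r.hr = entry["hazard_ratio"]
        r.hr_p = entry["p"]
        r.hr_ci_low, r.hr_ci_high = entry["ci95"]

    write_results(results, out / "screen_results.tsv")
    write_results_json(results, out / "screen_results.json")
    write_results(selected, out / "prognostic_pairs.tsv")

    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_genes": k,
        "n_normal_samples": normal.n_samples,
        "n_tumor_samples": n_tumor,
        "n_delta_pccs": count_delta_pccs(n_tumor, k),
        "pairs_candidate": k * (k - 1) // 2,
        "pairs_edge_filtered": int(edge_any.sum()),
        "pairs_tested": len(results),
        "pairs_selected": len(selected),
        "selected_pairs": [r.pair_id for r in selected],
    }
    if not results:
        summary["warning"] = "no gene pair survived the group-size exclusion"
        logger.warning("zero pairs tested: every candidate pair was excluded "
                       "by the <%d-patient rule", config.min_group)
    (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return summary


def single_gene_screen(tumor_expr: ExpressionMatrix, survival: SurvivalTable,
                       alpha_adj: float = 0.05) -> pd.DataFrame:
    """Gene-level survival screen: dichotomize at mean expression, log-rank, BH.

    For every gene, samples above the gene's mean log2 expression form the
    high group. Constant genes are skipped (flagged in the returned frame
    with ``tested=False``). Returns one row per gene with group sizes,
    log-rank statistic, raw and adjusted p, and the selection flag at
    ``alpha_adj``.
    """
    ids = [s for s in tumor_expr.sample_ids if s in set(survival.sample_ids)]
    if not ids:
        raise ValidationError("no tumor sample has survival data")
    surv = survival.subset(ids)
    cols = [tumor_expr.sample_ids.index(s) for s in ids]
    rows = []
    tested_idx, raw_p = [], []
    for gi, gene in enumerate(tumor_expr.gene_ids):
        x = tumor_expr.values[gi, cols]
        row = {"gene": gene, "n_high": 0, "n_low": 0, "logrank_stat": np.nan,
               "p_value": np.nan, "adj_p_value": np.nan, "tested": False,
               "selected": False}
        if np.ptp(x) > 0 and surv.n_events > 0:
            high = x > x.mean()
            if high.any() and (~high).any():
                stat, p = logrank_test(surv.time, surv.event, high.astype(int))
                row.update(n_high=int(high.sum()), n_low=int((~high).sum()),
                           logrank_stat=stat, p_value=p, tested=True)
                tested_idx.append(len(rows))
                raw_p.append(p)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if raw_p:
        adj = bh_adjust(raw_p)
        frame.loc[tested_idx, "adj_p_value"] = adj
        frame.loc[tested_idx, "selected"] = adj < alpha_adj
    return frame


def intersect_pairs(*pair_lists: Sequence[str]) -> list[str]:
    """Pairs common to every cohort's selected list (convenience)."""
    if not pair_lists:
        return []
    common = set(pair_lists[0])
    for other in pair_lists[1:]:
        common &= set(other)
    return sorted(common)
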