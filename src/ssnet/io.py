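"""Readers and writers for the package's plain-text file formats.

Formats:

* expression matrix — TSV, genes in rows, header row of sample ids,
  first column of gene symbols, cells = log2 expression;
* gene set — CSV with header ``symbol,tier`` (tier: elite|related);
* survival table — TSV with header ``sample_id  time  event [age] [gender]``;
* screen results — TSV mirroring the published table layout (pair, group
  sizes, log-rank statistic, p, adjusted p, HR, Cox p, CI bounds), plus a
  JSON form for programmatic use.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GeneSet,
    PairScreenResult,
    SurvivalTable,
    ValidationError,
)

PathLike = Union[str, Path]

RESULT_COLUMNS = [
    "pair", "gene_a", "gene_b", "n_group1", "n_group2",
    "logrank_stat", "p_value", "adj_p_value",
    "pcc_tumor", "pcc_tumor_p",
    "hazard_ratio", "cox_p_value", "ci95_low", "ci95_high", "selected",
]


def read_expression(path: PathLike, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV into an :class:`ExpressionMatrix`.

    Values are taken as-is (assumed log2-transformed upstream); set
    ``log2_transform`` to apply ``log2(x + 1)`` to raw values.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene rows in {path}: {dupes}")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise ValidationError(
                f"non-numeric cell in {path} at gene {row!r}, sample {col!r}"
            )
        frame[col] = coerced
    values = frame.to_numpy(dtype=float)
    if log2_transform:
        if np.any(values < 0):
            raise ValidationError("negative values cannot be log2(x+1)-transformed")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(list(frame.index), list(frame.columns), values)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path: PathLike, cancer_type: str = "") -> GeneSet:
    """Read a ``symbol,tier`` CSV; unknown tiers and duplicates are errors."""
    frame = pd.read_csv(path, dtype=str)
    missing = {"symbol", "tier"} - set(frame.columns)
    if missing:
        raise ValidationError(f"gene set {path} lacks columns: {sorted(missing)}")
    genes = [(str(r.symbol), str(r.tier)) for r in frame.itertuples(index=False)]
    return GeneSet(cancer_type=cancer_type, genes=genes)


def write_gene_set(gene_set: GeneSet, path: PathLike) -> None:
    pd.DataFrame(gene_set.genes, columns=["symbol", "tier"]).to_csv(path, index=False)


def read_survival(path: PathLike) -> SurvivalTable:
    """Read a survival TSV with required sample_id/time/event columns."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "time", "event"} - set(frame.columns)
    if missing:
        raise ValidationError(f"survival table {path} lacks columns: {sorted(missing)}")
    if frame["event"].isna().any():
        raise ValidationError("missing event indicator")
    event = _parse_event(frame["event"])
    age = frame["age"].to_numpy(dtype=float) if "age" in frame.columns else None
    gender = None
    if "gender" in frame.columns:
        gender = [None if (isinstance(g, float) and math.isnan(g)) or g == ""
                  else str(g) for g in frame["gender"]]
    return SurvivalTable(
        list(frame["sample_id"]),
        frame["time"].to_numpy(dtype=float),
        event,
        age,
        gender,
    )


def _parse_event(col: pd.Series) -> np.ndarray:
    mapping = {"0": False, "1": True, "false": False, "true": True}
    out = []
    for v in col:
        key = str(v).strip().lower()
        if key.endswith(".0"):
            key = key[:-2]
        if key not in mapping:
            raise ValidationError(f"cannot parse event indicator {v!r}")
        out.append(mapping[key])
    return np.asarray(out, dtype=bool)


def write_survival(table: SurvivalTable, path: PathLike) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def results_to_frame(results: Sequence[PairScreenResult]) -> pd.DataFrame:
    """Results as a DataFrame in the published column order, sorted by adjusted p."""
    rows = [
        {
            "pair": r.pair_id, "gene_a": r.gene_a, "gene_b": r.gene_b,
            "n_group1": r.n_group1, "n_group2": r.n_group2,
            "logrank_stat": r.logrank_stat, "p_value": r.p_raw,
            "adj_p_value": r.p_adj, "pcc_tumor": r.pcc_tumor,
            "pcc_tumor_p": r.pcc_tumor_p, "hazard_ratio": r.hr,
            "cox_p_value": r.hr_p, "ci95_low": r.hr_ci_low,
            "ci95_high": r.hr_ci_high, "selected": r.selected,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return frame.sort_values("adj_p_value", kind="stable").reset_index(drop=True)


def write_results(results: Sequence[PairScreenResult], path: PathLike) -> None:
    """Write a TSV of screen results, one row per pair, adjusted-p ascending."""
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def read_results(path: PathLike) -> list[PairScreenResult]:
    frame = pd.read_csv(path, sep="\t")
    out = []
    for r in frame.itertuples(index=False):
        out.append(PairScreenResult(
            gene_a=str(r.gene_a), gene_b=str(r.gene_b),
            n_group1=int(r.n_group1), n_group2=int(r.n_group2),
            logrank_stat=float(r.logrank_stat), p_raw=float(r.p_value),
            p_adj=float(r.adj_p_value), pcc_tumor=float(r.pcc_tumor),
            pcc_tumor_p=float(r.pcc_tumor_p), hr=float(r.hazard_ratio),
            hr_p=float(r.cox_p_value), hr_ci_low=float(r.ci95_low),
            hr_ci_high=float(r.ci95_high), selected=bool(r.selected),
        ))
    return out


def write_results_json(results: Sequence[PairScreenResult], path: PathLike) -> None:
    frame = results_to_frame(results)
    records = json.loads(frame.to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=1) + "\n")
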