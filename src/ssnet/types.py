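"""Shared domain types: expression matrices, gene sets, survival tables, screen results.

All gene pairs are identified by a canonical key: the two symbols in
lexicographic order joined by an underscore (``canonical_pair``), so joins
and deduplication across modules are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VALID_TIERS = ("elite", "related")
VALID_GENDERS = ("male", "female")


class ValidationError(ValueError):
    """An input violated a domain-type invariant."""


def canonical_pair(gene_a: str, gene_b: str) -> str:
    """Canonical pair key: lexicographically ordered symbols joined by '_'."""
    if gene_a == gene_b:
        raise ValidationError(f"self-pair not allowed: {gene_a!r}")
    a, b = sorted((gene_a, gene_b))
    return f"{a}_{b}"


def split_pair(pair_id: str) -> tuple[str, str]:
    """Inverse of :func:`canonical_pair` for keys without '_' inside symbols."""
    a, _, b = pair_id.partition("_")
    if not a or not b:
        raise ValidationError(f"malformed pair id: {pair_id!r}")
    return a, b


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression values.

    Rows are genes, columns are samples. Values are assumed to be already
    log2-transformed; no transformation happens here.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def sample_vector(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        return self.values[:, j]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))


@dataclass
class GeneSet:
    """Disease-associated genes for one cancer type, tiered elite/related."""

    cancer_type: str
    genes: list[tuple[str, str]]  # (symbol, tier)

    def __post_init__(self) -> None:
        symbols = [s for s, _ in self.genes]
        if len(set(symbols)) != len(symbols):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise ValidationError(f"duplicate gene symbols: {dupes}")
        for symbol, tier in self.genes:
            if tier not in VALID_TIERS:
                raise ValidationError(
                    f"unknown tier {tier!r} for {symbol!r}; expected one of {VALID_TIERS}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.genes]

    @property
    def n_elite(self) -> int:
        return sum(1 for _, t in self.genes if t == "elite")

    @property
    def n_related(self) -> int:
        return sum(1 for _, t in self.genes if t == "related")


@dataclass
class SurvivalTable:
    """Per-sample follow-up: duration, event indicator, optional age/gender.

    ``time`` is an opaque non-negative duration (the unit is whatever the
    clinical source used, typically days); ``event`` is True when death was
    observed and False for censoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    age: Optional[np.ndarray] = None       # NaN where missing
    gender: Optional[list[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids in survival table")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length mismatch with sample ids")
        if np.any(~np.isfinite(self.time)) or np.any(self.time < 0):
            raise ValidationError("survival times must be finite and >= 0")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != (n,):
                raise ValidationError("age length mismatch")
            with np.errstate(invalid="ignore"):
                if np.any(self.age < 0):
                    raise ValidationError("ages must be >= 0")
        if self.gender is not None:
            if len(self.gender) != n:
                raise ValidationError("gender length mismatch")
            for g in self.gender:
                if g is not None and g not in VALID_GENDERS:
                    raise ValidationError(f"unknown gender {g!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        data = {"sample_id": self.sample_ids,
                "time": self.time,
                "event": self.event.astype(int)}
        if self.age is not None:
            data["age"] = self.age
        if self.gender is not None:
            data["gender"] = ["" if g is None else g for g in self.gender]
        return pd.DataFrame(data)

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return SurvivalTable(
            [self.sample_ids[i] for i in idx],
            self.time[idx],
            self.event[idx],
            None if self.age is None else self.age[idx],
            None if self.gender is None else [self.gender[i] for i in idx],
        )


@dataclass
class PairScreenResult:
    """Screening outcome for one gene pair (one row of the results table)."""

    gene_a: str
    gene_b: str
    n_group1: int
    n_group2: int
    logrank_stat: float
    p_raw: float
    p_adj: float
    pcc_tumor: float
    pcc_tumor_p: float
    hr: float = math.nan
    hr_p: float = math.nan
    hr_ci_low: float = math.nan
    hr_ci_high: float = math.nan
    selected: bool = False

    def __post_init__(self) -> None:
        self.gene_a, self.gene_b = sorted((str(self.gene_a), str(self.gene_b)))

    @property
    def pair_id(self) -> str:
        return canonical_pair(self.gene_a, self.gene_b)
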