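"""Correlation networks and single-sample perturbation (ΔPCC).

The reference network is the all-pairs Pearson correlation matrix of the
normal samples together with two-sided significance p-values. A perturbed
network is the same computation after appending one patient's tumor sample
to the normal cohort; the patient-specific network keeps, for every gene
pair significant in *both* networks (p < alpha_edge), the absolute change
in correlation

    dPCC(g_i, g_j) = | PCC_perturbed(g_i, g_j) - PCC_reference(g_i, g_j) |,

which lies in [0, 2] and acts as the patient-specific edge weight.

Significance of a correlation r over n samples uses the standard two-sided
t-test, t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom. Genes
with zero variance have undefined correlations; their pairs are assigned
pcc = 0 and p-value = 1 so they can never pass the edge filter, and the
gene is recorded in ``degenerate_genes``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, ValidationError, canonical_pair

PathLike = Union[str, Path]

EDGE_COLUMNS = ["gene_a", "gene_b", "delta_pcc", "pcc_ref", "pcc_pert", "p_ref", "p_pert"]


class ConstantInputError(ValueError):
    """A correlation was requested for a zero-variance vector."""


def _check_vectors(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("expected 1-D vectors")
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector: correlation undefined")
    return x, y


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient, clipped to [-1, 1]."""
    x, y = _check_vectors(np.asarray(x), np.asarray(y))
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))


def spearman_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson on mean ranks (ties averaged)."""
    x, y = _check_vectors(np.asarray(x), np.asarray(y))
    return pearson_cc(stats.rankdata(x), stats.rankdata(y))


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a correlation r over n samples (t-test, df=n-2)."""
    if n < 3:
        raise ValueError("significance requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass
class CorrelationNetwork:
    """All-pairs correlation matrix with significance p-values."""

    gene_ids: list[str]
    n_samples: int
    pcc: np.ndarray
    pvalue: np.ndarray
    degenerate_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.gene_ids)
        self.pcc = np.asarray(self.pcc, dtype=float)
        self.pvalue = np.asarray(self.pvalue, dtype=float)
        if self.n_samples < 3:
            raise ValidationError("a correlation network needs >= 3 samples")
        if self.pcc.shape != (k, k) or self.pvalue.shape != (k, k):
            raise ValidationError("matrix shape does not match gene count")
        if not np.allclose(self.pcc, self.pcc.T, atol=1e-12):
            raise ValidationError("pcc matrix not symmetric")
        if np.any(np.abs(self.pcc) > 1 + 1e-12):
            raise ValidationError("pcc out of [-1, 1]")

    def pair_value(self, gene_a: str, gene_b: str) -> tuple[float, float]:
        i = self.gene_ids.index(gene_a)
        j = self.gene_ids.index(gene_b)
        return float(self.pcc[i, j]), float(self.pvalue[i, j])


def _correlation_matrix(values: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """(pcc, degenerate-row mask) for a genes x samples value matrix."""
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    degenerate = np.ptp(values, axis=1) == 0
    safe = values.copy()
    # stop corrcoef warnings on zero-variance rows; results overwritten below
    safe[degenerate] = np.random.default_rng(0).normal(size=(degenerate.sum(), values.shape[1]))
    with np.errstate(invalid="ignore"):
        pcc = np.corrcoef(safe)
    pcc = np.clip(pcc, -1.0, 1.0)
    pcc[degenerate, :] = 0.0
    pcc[:, degenerate] = 0.0
    np.fill_diagonal(pcc, 1.0)
    return pcc, degenerate


def _pvalue_matrix(pcc: np.ndarray, n: int, degenerate: np.ndarray) -> np.ndarray:
    r = np.clip(pcc, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[degenerate, :] = 1.0
    p[:, degenerate] = 1.0
    np.fill_diagonal(p, 0.0)
    return p


def build_network(expr: ExpressionMatrix, method: str = "pearson") -> CorrelationNetwork:
    """All-pairs correlation network from a sample cohort."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation kind {method!r}")
    if expr.n_samples < 3:
        raise ValidationError("need >= 3 samples to build a network")
    if expr.n_genes < 2:
        raise ValidationError("need >= 2 genes to build a network")
    pcc, degenerate = _correlation_matrix(expr.values, method)
    pvalue = _pvalue_matrix(pcc, expr.n_samples, degenerate)
    return CorrelationNetwork(
        gene_ids=list(expr.gene_ids),
        n_samples=expr.n_samples,
        pcc=pcc,
        pvalue=pvalue,
        degenerate_genes=[g for g, d in zip(expr.gene_ids, degenerate) if d],
    )


def _augment(normal: ExpressionMatrix, tumor_sample: Sequence[float],
             sample_id: str = "__patient__") -> ExpressionMatrix:
    vec = np.asarray(tumor_sample, dtype=float)
    if vec.shape != (normal.n_genes,):
        raise ValidationError(
            f"tumor sample has {vec.shape[0] if vec.ndim == 1 else '?'} genes, "
            f"expected {normal.n_genes}"
        )
    return ExpressionMatrix(
        list(normal.gene_ids),
        list(normal.sample_ids) + [sample_id],
        np.column_stack([normal.values, vec]),
    )


def align_tumor_sample(normal: ExpressionMatrix, tumor: ExpressionMatrix,
                       sample_id: str) -> np.ndarray:
    """Tumor sample vector reordered to the normal matrix's gene order."""
    missing = sorted(set(normal.gene_ids) - set(tumor.gene_ids))
    if missing:
        raise ValidationError(f"tumor matrix lacks genes: {missing}")
    vec = tumor.sample_vector(sample_id)
    idx = [tumor.gene_index(g) for g in normal.gene_ids]
    return vec[idx]


def build_perturbed_network(normal: ExpressionMatrix,
                            tumor_sample: Sequence[float],
                            method: str = "pearson") -> CorrelationNetwork:
    """Network over the N normal samples plus one tumor sample (N+1 total)."""
    return build_network(_augment(normal, tumor_sample), method=method)


def delta_pcc(ref: CorrelationNetwork, pert: CorrelationNetwork) -> np.ndarray:
    """Elementwise |PCC_perturbed - PCC_reference|; entries in [0, 2], diagonal 0."""
    if ref.gene_ids != pert.gene_ids:
        raise ValidationError("gene sets differ between reference and perturbed networks")
    d = np.abs(pert.pcc - ref.pcc)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class PatientSpecificNetwork:
    """Edges significant in both reference and perturbed networks, ΔPCC-weighted."""

    patient_id: str
    edges: list[tuple]  # (gene_a, gene_b, delta_pcc, pcc_ref, pcc_pert, p_ref, p_pert)
    alpha_edge: float = 0.05

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def pair_ids(self) -> list[str]:
        return [canonical_pair(a, b) for a, b, *_ in self.edges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=EDGE_COLUMNS)

    def to_graph(self):
        import networkx as nx

        graph = nx.Graph(patient_id=self.patient_id, alpha_edge=self.alpha_edge)
        for a, b, d, r_ref, r_pert, p_ref, p_pert in self.edges:
            graph.add_edge(a, b, delta_pcc=float(d), pcc_ref=float(r_ref),
                           pcc_pert=float(r_pert), p_ref=float(p_ref),
                           p_pert=float(p_pert))
        return graph

    def write_tsv(self, path: PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: PathLike) -> None:
        import networkx as nx

        nx.write_graphml(self.to_graph(), str(path))

    def write_json(self, path: PathLike) -> None:
        nodes = sorted({g for a, b, *_ in self.edges for g in (a, b)})
        doc = {
            "patient_id": self.patient_id,
            "alpha_edge": self.alpha_edge,
            "nodes": [{"id": g} for g in nodes],
            "edges": [
                {"source": a, "target": b, "delta_pcc": d, "pcc_ref": r_ref,
                 "pcc_pert": r_pert, "p_ref": p_ref, "p_pert": p_pert}
                for a, b, d, r_ref, r_pert, p_ref, p_pert in self.edges
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def _edges_from_matrices(gene_ids: Sequence[str], dmat: np.ndarray,
                         ref: CorrelationNetwork, pert: CorrelationNetwork,
                         mask: np.ndarray) -> list[tuple]:
    iu, ju = np.where(np.triu(mask, k=1))
    edges = []
    for i, j in zip(iu, ju):
        a, b = sorted((gene_ids[i], gene_ids[j]))
        edges.append((a, b, float(dmat[i, j]), float(ref.pcc[i, j]),
                      float(pert.pcc[i, j]), float(ref.pvalue[i, j]),
                      float(pert.pvalue[i, j])))
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def build_patient_network(normal: ExpressionMatrix, tumor_sample: Sequence[float],
                          patient_id: str, alpha_edge: float = 0.05,
                          method: str = "pearson",
                          reference: Optional[CorrelationNetwork] = None,
                          ) -> PatientSpecificNetwork:
    """Patient-specific network: dual-significance filter plus ΔPCC weights.

    ``reference`` may be passed to avoid recomputing the normal-cohort
    network per patient; it must come from the same matrix and method.
    """
    ref = reference if reference is not None else build_network(normal, method=method)
    pert = build_perturbed_network(normal, tumor_sample, method=method)
    dmat = delta_pcc(ref, pert)
    mask = (ref.pvalue < alpha_edge) & (pert.pvalue < alpha_edge)
    np.fill_diagonal(mask, False)
    edges = _edges_from_matrices(normal.gene_ids, dmat, ref, pert, mask)
    return PatientSpecificNetwork(patient_id=patient_id, edges=edges,
                                  alpha_edge=alpha_edge)


def count_delta_pccs(n_tumor: int, k_genes: int) -> int:
    """Number of ΔPCC values over a cohort: n_tumor * C(k_genes, 2)."""
    if n_tumor < 0:
        raise ValueError("n_tumor must be >= 0")
    if k_genes < 2:
        raise ValueError("k_genes must be >= 2")
    return n_tumor * math.comb(k_genes, 2)


def pair_index(gene_ids: Sequence[str]) -> list[str]:
    """Canonical pair ids for the upper triangle of a gene list, row-major."""
    ids = list(gene_ids)
    return [canonical_pair(ids[i], ids[j])
            for i in range(len(ids)) for j in range(i + 1, len(ids))]


def delta_pcc_tensor(normal: ExpressionMatrix, tumor: ExpressionMatrix,
                     alpha_edge: float = 0.05, method: str = "pearson",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ΔPCC values and dual-significance flags for every (pair, tumor sample).

    Returns ``(delta, edge)`` DataFrames indexed by canonical pair id with
    one column per tumor sample: ``delta`` holds ΔPCC for every pair whether
    or not it passes the filter, ``edge`` holds booleans marking pairs
    significant (p < alpha_edge) in both the reference and that patient's
    perturbed network.
    """
    missing = sorted(set(normal.gene_ids) - set(tumor.gene_ids))
    if missing:
        raise ValidationError(f"tumor matrix lacks genes: {missing}")
    tumor = tumor.subset_genes(normal.gene_ids)
    ref = build_network(normal, method=method)
    k = normal.n_genes
    iu, ju = np.triu_indices(k, k=1)
    pairs = pair_index(normal.gene_ids)
    delta = np.empty((len(pairs), tumor.n_samples))
    edge = np.empty((len(pairs), tumor.n_samples), dtype=bool)
    ref_sig = ref.pvalue[iu, ju] < alpha_edge
    for s in range(tumor.n_samples):
        pert = build_perturbed_network(normal, tumor.values[:, s], method=method)
        delta[:, s] = np.abs(pert.pcc - ref.pcc)[iu, ju]
        edge[:, s] = ref_sig & (pert.pvalue[iu, ju] < alpha_edge)
    cols = list(tumor.sample_ids)
    return (pd.DataFrame(delta, index=pairs, columns=cols),
            pd.DataFrame(edge, index=pairs, columns=cols))
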