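"""Quantitative evaluation: candidate-set retrieval accuracy, Pearson
correlations at spot and gene level, MSE/MAE, and correlation histograms.

Alignment accuracy asks, for each query image, whether its true expression
partner has the strictly highest cosine similarity within a candidate pool —
the true partner plus either its k spatially nearest spots or k random
spots.  Chance level is therefore 1 / (k + 1).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoders import l2_normalize

__all__ = [
    "CandidateSet",
    "EvalReport",
    "adjacent_candidates",
    "random_candidates",
    "alignment_accuracy",
    "pearson",
    "pearson_per_gene",
    "pearson_per_spot",
    "mse_mae",
    "correlation_histogram",
]


@dataclass
class CandidateSet:
    query_index: int
    candidate_indices: list
    kind: str  # "adjacent" | "random"
    k: int

    def __post_init__(self):
        if self.query_index not in self.candidate_indices:
            raise ValueError("the true pair must be among the candidates")
        if len(set(self.candidate_indices)) != len(self.candidate_indices):
            raise ValueError("candidate indices must be unique")


def adjacent_candidates(coords: np.ndarray, query: int, k: int) -> CandidateSet:
    """True pair plus the query's k nearest spots by Euclidean distance
    (ties by index)."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the {n} available spots")
    d = np.linalg.norm(coords - coords[query], axis=1)
    order = sorted((i for i in range(n) if i != query), key=lambda i: (d[i], i))
    return CandidateSet(query, [query] + order[:k], "adjacent", k)


def random_candidates(n: int, query: int, k: int, rng_seed: int) -> CandidateSet:
    """True pair plus k spots drawn uniformly without replacement."""
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    rng = np.random.default_rng(rng_seed)
    others = np.array([i for i in range(n) if i != query])
    picked = rng.choice(others, size=k, replace=False)
    return CandidateSet(query, [query] + picked.tolist(), "random", k)


def alignment_accuracy(V: np.ndarray, E: np.ndarray, candidate_sets) -> float:
    """Fraction of queries whose true partner is the strict cosine argmax
    within its candidate pool (ties count as incorrect)."""
    V_n = l2_normalize(np.asarray(V, dtype=float))
    E_n = l2_normalize(np.asarray(E, dtype=float))
    candidate_sets = list(candidate_sets)
    if not candidate_sets:
        raise ValueError("no candidate sets supplied")
    n_correct = 0
    for cs in candidate_sets:
        if not cs.candidate_indices:
            raise ValueError("empty candidate set")
        sims = E_n[cs.candidate_indices] @ V_n[cs.query_index]
        true_pos = cs.candidate_indices.index(cs.query_index)
        best = sims.max()
        if sims[true_pos] == best and (sims == best).sum() == 1:
            n_correct += 1
    return n_correct / len(candidate_sets)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0.0:
        warnings.warn("Pearson undefined for constant vector; returning NaN")
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([pearson(a, b) for a, b in zip(A, B)])


def pearson_per_gene(X: np.ndarray, X_p: np.ndarray) -> np.ndarray:
    """Correlation of each gene (column) across spots; NaN where undefined."""
    X, X_p = np.asarray(X, float), np.asarray(X_p, float)
    if X.shape != X_p.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_p.shape}")
    return _rowwise_pearson(X.T, X_p.T)


def pearson_per_spot(X: np.ndarray, X_p: np.ndarray) -> np.ndarray:
    """Correlation of each spot (row) across the gene panel."""
    X, X_p = np.asarray(X, float), np.asarray(X_p, float)
    if X.shape != X_p.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_p.shape}")
    return _rowwise_pearson(X, X_p)


def mse_mae(X: np.ndarray, X_p: np.ndarray) -> tuple:
    X, X_p = np.asarray(X, float), np.asarray(X_p, float)
    if X.shape != X_p.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_p.shape}")
    diff = X - X_p
    return float(np.mean(diff ** 2)), float(np.mean(np.abs(diff)))


def correlation_histogram(pcc_gene: np.ndarray, bin_edges) -> np.ndarray:
    """Counts of correlation values per half-open bin [lo, hi); the last bin
    is unbounded above so every value >= the first edge is counted once."""
    values = np.asarray(pcc_gene, dtype=float)
    values = values[np.isfinite(values)]
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for v in values:
        if v < edges[0]:
            continue
        idx = int(np.searchsorted(edges, v, side="right")) - 1
        counts[min(idx, len(counts) - 1)] += 1
    return counts


@dataclass
class EvalReport:
    alignment_accuracy: dict = field(default_factory=dict)  # key -> fraction
    pcc_spot: np.ndarray | None = None
    pcc_gene: np.ndarray | None = None
    mse: float | None = None
    mae: float | None = None

    def summary(self) -> dict:
        def _nanmean(v):
            if v is None:
                return None
            v = np.asarray(v, dtype=float)
            finite = v[np.isfinite(v)]
            return float(finite.mean()) if finite.size else None

        return {
            "alignment_accuracy": {k: float(v) for k, v in self.alignment_accuracy.items()},
            "mean_pcc_spot": _nanmean(self.pcc_spot),
            "mean_pcc_gene": _nanmean(self.pcc_gene),
            "mse": self.mse,
            "mae": self.mae,
        }

    def save(self, out_dir, gene_names=None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "eval_report.json").write_text(json.dumps(self.summary(), indent=2))
        if self.pcc_gene is not None:
            idx = gene_names if gene_names is not None else range(len(self.pcc_gene))
            pd.Series(self.pcc_gene, index=idx, name="pcc").to_csv(
                out_dir / "pcc_gene.tsv", sep="\t")
        if self.pcc_spot is not None:
            pd.Series(self.pcc_spot, name="pcc").to_csv(out_dir / "pcc_spot.tsv", sep="\t")
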