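"""Expression-state discovery by NMF and rank-based meta-analysis.

Tumour (or culture) expression profiles are clustered by non-negative matrix
factorization into k states (default k = 3: proliferative, invasive and an
immune-like confounder), after restricting to genes whose expression standard
deviation across samples exceeds 1. Cluster-specific gene rankings contrast
each cluster against the rest and score genes by sign(log2FC) * -log10(padj);
rankings from several datasets are merged with the uniform-order-statistics Q
used for the motif/track rank aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import CountMatrix, nb_differential
from .enrichment import combine_rankings_orderstat

P_FLOOR = 1e-300


def sd_filter(expr_matrix: pd.DataFrame, sd_min: float = 1.0) -> pd.DataFrame:
    """Genes with sample standard deviation strictly above ``sd_min``."""
    if expr_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sd = expr_matrix.std(axis=1, ddof=1)
    return expr_matrix[sd > sd_min]


@dataclass
class NMFModel:
    """Frobenius NMF fit: X (genes x samples) ~ W @ H, all entries >= 0."""

    w: np.ndarray
    h: np.ndarray
    k: int
    seed: int
    n_iter: int
    error: float
    error_trace: np.ndarray = field(repr=False, default=None)

    def cluster_map(self, samples) -> pd.Series:
        """Sample -> cluster by the dominant H component."""
        return pd.Series(self.h.argmax(axis=0), index=samples, name="cluster")


def _mu_nmf(x: np.ndarray, k: int, rng: np.random.Generator,
            max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    eps = 1e-12
    n, m = x.shape
    scale = np.sqrt(x.mean() / k)
    w = scale * rng.random((n, k)) + eps
    h = scale * rng.random((k, m)) + eps
    norm_x = np.linalg.norm(x)
    errors = []
    prev = None
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + eps)
        w *= (x @ h.T) / (w @ h @ h.T + eps)
        err = np.linalg.norm(x - w @ h) / (norm_x + eps)
        errors.append(err)
        if prev is not None and abs(prev - err) < tol:
            break
        prev = err
    return w, h, np.array(errors)


def nmf_cluster(expr_matrix: pd.DataFrame, k: int = 3, seed: int = 0,
                n_restarts: int = 10, max_iter: int = 2000,
                tol: float = 1e-6) -> tuple[NMFModel, pd.Series]:
    """Multiplicative-update Frobenius NMF, best of ``n_restarts`` by error.

    The input must be non-negative (log-transformed normalised counts).
    Samples are assigned to the cluster with the largest H coefficient.
    """
    x = expr_matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("NMF input must be non-negative")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        w, h, errs = _mu_nmf(x, k, rng, max_iter, tol)
        if best is None or errs[-1] < best[2][-1]:
            best = (w, h, errs)
    w, h, errs = best
    model = NMFModel(w=w, h=h, k=k, seed=seed, n_iter=len(errs),
                     error=float(errs[-1]), error_trace=errs)
    return model, model.cluster_map(expr_matrix.columns)


def cluster_gene_ranking(expr_counts: CountMatrix, cluster_map: pd.Series,
                         cluster) -> pd.Series:
    """Signed -log10(padj) scores contrasting one cluster against the rest.

    Positive scores mark genes higher in the cluster; p-values are floored at
    1e-300 so scores stay finite.
    """
    samples = list(expr_counts.counts.columns)
    in_cluster = [s for s in samples if cluster_map.loc[s] == cluster]
    if not in_cluster or len(in_cluster) == len(samples):
        raise ValueError("cluster must be a proper non-empty subset of samples")
    design = pd.Series({s: "cluster" if s in in_cluster else "rest" for s in samples})
    cm = CountMatrix(expr_counts.counts, design)
    res = nb_differential(cm, state_a="rest", state_b="cluster")
    score = np.sign(res["log2fc"]) * (-np.log10(np.maximum(res["padj"], P_FLOOR)))
    return pd.Series(score.to_numpy(), index=res["id"], name=f"cluster_{cluster}")


def meta_rank(rankings: list[pd.Series]) -> pd.Series:
    """Combine per-dataset gene rankings with order statistics.

    Each input maps gene -> score (higher = more state-specific). Scores are
    turned into rank ratios within each dataset; a gene absent from a dataset
    gets the worst ratio 1. The combined ordering is by ascending Q.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings")
    universe = sorted(set().union(*[set(r.index) for r in rankings]))
    ratios = np.ones((len(universe), len(rankings)))
    for j, r in enumerate(rankings):
        order = r.sort_values(ascending=False, kind="mergesort")
        rr = pd.Series(np.arange(1, len(order) + 1) / len(order), index=order.index)
        idx = [i for i, g in enumerate(universe) if g in rr.index]
        ratios[idx, j] = rr.loc[[universe[i] for i in idx]].to_numpy()
    q = combine_rankings_orderstat(ratios)
    return pd.Series(q, index=universe, name="q").sort_values(kind="mergesort")
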