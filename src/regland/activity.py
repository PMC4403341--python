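"""Differential activity of regions and genes between two cell states.

Count matrices (regions x samples or genes x samples) are normalised by
median-of-ratios size factors, log-transformed, and tested per row with a
negative-binomial Wald test (moment dispersion estimate shrunk toward the
matrix-wide mean). State signatures and state-specific region sets are then
thresholded at |log2FC| >= 1 and BH-adjusted p <= 0.05, with an additional
pooled-count binomial support filter for regions.

The NB Wald test and the binomial support test are documented stand-ins for
external callers (DESeq2, MACS2 differential peaks): the pipeline's substance
is the thresholds and the intersection logic, and both interfaces accept
externally produced result tables as drop-in replacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["id", "base_mean", "log2fc", "pvalue", "padj"]


@dataclass
class CountMatrix:
    """Integer counts with a sample -> state design.

    ``counts`` rows are feature IDs (regions or genes), columns are samples.
    ``design`` maps every column to a state label; exactly two states are
    required for differential operations.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        self.design = pd.Series(self.design)
        if self.counts.isna().any().any():
            raise ValueError("count matrix has missing cells")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.design.index]
        if missing:
            raise ValueError(f"samples without a state label: {missing}")
        self.design = self.design.loc[self.counts.columns]

    @property
    def states(self) -> list[str]:
        return sorted(self.design.unique())

    def state_samples(self, state: str) -> list[str]:
        return list(self.design.index[self.design == state])

    def to_tsv(self, counts_path, design_path) -> None:
        self.counts.rename_axis("id").to_csv(counts_path, sep="\t")
        self.design.rename_axis("sample").rename("state").to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0)["state"]
        return cls(counts, design)


@dataclass
class GeneSignature:
    state: str
    genes: list[str]
    lfc_min: float
    padj_max: float

    def __len__(self):
        return len(self.genes)


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean pseudo-reference).

    Rows with any zero are excluded from the reference, as in the DESeq
    estimator. Factors are strictly positive; every sample must have at least
    one nonzero count in a reference row.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no row with all-positive counts for the reference")
    logs = np.log(x[positive])
    ref = logs.mean(axis=1)
    factors = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def log_transform(counts: pd.DataFrame | CountMatrix,
                  factors: pd.Series | None = None,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), monotone in counts."""
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if factors is None:
        factors = size_factors(counts)
    return np.log2(counts / factors + pseudocount)


def _moment_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-row method-of-moments NB dispersion from within-group residuals."""
    n_total = sum(g.size for g in groups)
    ss = np.zeros(norm.shape[0])
    mu_sq = np.zeros(norm.shape[0])
    for g in groups:
        sub = norm[:, g]
        m = sub.mean(axis=1)
        ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        mu_sq += sub.shape[1] * m ** 2
    df = n_total - len(groups)
    var = ss / max(df, 1)
    mean_all = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean_all) / np.where(mu_sq > 0, mu_sq / n_total, np.inf)
    return np.clip(np.nan_to_num(alpha, nan=0.0), 0.0, 50.0)


def nb_differential(counts: CountMatrix,
                    state_a: str | None = None,
                    state_b: str | None = None,
                    prior_weight: float = 10.0) -> pd.DataFrame:
    """Per-row NB Wald test of state B over state A.

    Dispersion is a per-row moment estimate shrunk toward the matrix-wide mean
    dispersion with weight ``df / (df + prior_weight)``; the Wald statistic on
    the log fold change of shrunken group means (normalised mean + 0.5) is
    referred to a t distribution with ``n_A + n_B - 2`` degrees of freedom and
    p-values are BH-adjusted across rows. Rows that are all zero get p = 1 and
    log2fc = 0.

    Returns a DataFrame with columns ``id, base_mean, log2fc, pvalue, padj``
    where log2fc > 0 means higher in ``state_b``.
    """
    states = counts.states
    if state_a is None or state_b is None:
        if len(states) != 2:
            raise ValueError(f"need exactly two states, got {states}")
        state_a, state_b = states
    cols = list(counts.counts.columns)
    idx_a = np.array([cols.index(s) for s in counts.state_samples(state_a)])
    idx_b = np.array([cols.index(s) for s in counts.state_samples(state_b)])
    if idx_a.size < 1 or idx_b.size < 1:
        raise ValueError("each state needs at least one sample")
    factors = size_factors(counts).to_numpy()
    norm = counts.counts.to_numpy(dtype=float) / factors

    alpha_row = _moment_dispersion(norm, [idx_a, idx_b])
    df_resid = idx_a.size + idx_b.size - 2
    w = df_resid / (df_resid + prior_weight)
    alpha = w * alpha_row + (1 - w) * alpha_row.mean()

    mu_a = norm[:, idx_a].mean(axis=1)
    mu_b = norm[:, idx_b].mean(axis=1)
    sm_a, sm_b = mu_a + 0.5, mu_b + 0.5
    log2fc = np.log2(sm_b / sm_a)
    # delta method on ln(mu + 0.5): Var(mean) = (mu + alpha mu^2)/n
    var_a = (mu_a + alpha * mu_a ** 2) / idx_a.size / sm_a ** 2
    var_b = (mu_b + alpha * mu_b ** 2) / idx_b.size / sm_b ** 2
    se = np.sqrt(var_a + var_b) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    dfree = max(df_resid, 1)
    pvalue = 2 * stats.t.sf(np.abs(z), dfree)
    allzero = counts.counts.to_numpy().sum(axis=1) == 0
    pvalue = np.where(allzero, 1.0, pvalue)
    log2fc = np.where(allzero, 0.0, log2fc)
    padj = bh_adjust(pvalue)
    return pd.DataFrame({"id": counts.counts.index,
                         "base_mean": norm.mean(axis=1),
                         "log2fc": log2fc,
                         "pvalue": pvalue,
                         "padj": padj}).set_index("id", drop=False)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def define_signature(results: pd.DataFrame,
                     state_a: str, state_b: str,
                     lfc_min: float = 1.0,
                     padj_max: float = 0.05) -> tuple[GeneSignature, GeneSignature]:
    """Split differential results into two disjoint state signatures.

    Membership requires |log2fc| >= lfc_min and padj <= padj_max; the sign of
    log2fc (B over A) sets the state.
    """
    passing = results[(results["log2fc"].abs() >= lfc_min) & (results["padj"] <= padj_max)]
    up_b = passing[passing["log2fc"] > 0]["id"].tolist()
    up_a = passing[passing["log2fc"] < 0]["id"].tolist()
    return (GeneSignature(state_a, up_a, lfc_min, padj_max),
            GeneSignature(state_b, up_b, lfc_min, padj_max))


def binomial_support(counts: CountMatrix,
                     state_a: str, state_b: str,
                     support_q: float = 0.05) -> pd.DataFrame:
    """Pooled-count binomial support test (differential-peak stand-in).

    Counts are pooled within each state; under no difference the state-B pool
    of a region is Binomial(total, S_B/(S_A+S_B)) where S_g is the summed size
    factor of group g. Two-sided p-values are BH-adjusted; the result carries
    the direction (sign of the pooled log-ratio relative to expectation).
    """
    factors = size_factors(counts)
    a_cols = counts.state_samples(state_a)
    b_cols = counts.state_samples(state_b)
    s_a, s_b = factors[a_cols].sum(), factors[b_cols].sum()
    p0 = s_b / (s_a + s_b)
    k_b = counts.counts[b_cols].sum(axis=1).to_numpy()
    n = counts.counts[a_cols + b_cols].sum(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = np.array([stats.binomtest(int(k), int(t), p0).pvalue if t > 0 else 1.0
                          for k, t in zip(k_b, n)])
    qvals = bh_adjust(pvals)
    direction = np.sign(np.where(n > 0, k_b / np.maximum(n, 1) - p0, 0.0))
    return pd.DataFrame({"id": counts.counts.index, "support_q": qvals,
                         "direction": direction,
                         "supported": qvals < support_q}).set_index("id", drop=False)


def differential_regions(region_counts: CountMatrix,
                         state_a: str | None = None,
                         state_b: str | None = None,
                         lfc_min: float = 1.0,
                         padj_max: float = 0.05,
                         support_q: float = 0.05) -> dict:
    """Two-stage state-specific region calling.

    Stage 1: NB Wald differential at (padj <= 0.05, |log2FC| >= 1).
    Stage 2: pooled binomial support at BH q < ``support_q``, required to be
    direction-concordant with stage 1. The final sets are the intersection;
    ``support_q=1`` disables stage 2 exactly.
    """
    states = region_counts.states
    if state_a is None or state_b is None:
        state_a, state_b = states
    res = nb_differential(region_counts, state_a, state_b)
    stage1 = res[(res["log2fc"].abs() >= lfc_min) & (res["padj"] <= padj_max)]
    if support_q >= 1.0:
        final = stage1
    else:
        supp = binomial_support(region_counts, state_a, state_b, support_q=support_q)
        ok = supp.loc[stage1.index]
        concordant = ok["supported"] & (ok["direction"] == np.sign(stage1["log2fc"]))
        final = stage1[concordant.to_numpy()]
    return {
        state_a: final[final["log2fc"] < 0]["id"].tolist(),
        state_b: final[final["log2fc"] > 0]["id"].tolist(),
        "results": res,
    }


def methylation_region_stats(beta: pd.DataFrame,
                             design: pd.Series,
                             cpg_regions: pd.Series,
                             cpg_alpha: float = 1e-10,
                             region_alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate CpG methylation evidence per regulatory region.

    Per-CpG Welch t-tests between the two states select significant probes at
    ``cpg_alpha``; regions covered by at least two significant probes are
    scored by a two-sample t-test on per-sample medians of their probes'
    beta values. Regions with fewer than two probes are excluded and reported
    with ``n_probes`` but NaN statistics. ``delta_beta`` is the second state's
    mean region median minus the first (states in sorted label order).
    """
    if ((beta < 0) | (beta > 1)).any().any():
        raise ValueError("beta values must lie in [0, 1]")
    design = design.loc[beta.columns]
    states = sorted(design.unique())
    if len(states) != 2:
        raise ValueError("need exactly two states")
    a_cols = design.index[design == states[0]]
    b_cols = design.index[design == states[1]]
    t, p = stats.ttest_ind(beta[a_cols], beta[b_cols], axis=1, equal_var=False)
    sig = pd.Series(p < cpg_alpha, index=beta.index)
    rows = []
    for region, probes in cpg_regions.groupby(cpg_regions):
        probe_ids = [i for i in probes.index if i in beta.index and sig.get(i, False)]
        if len(probe_ids) < 2:
            rows.append((region, len(probe_ids), np.nan, np.nan, np.nan, False))
            continue
        med_a = beta.loc[probe_ids, a_cols].median(axis=0)
        med_b = beta.loc[probe_ids, b_cols].median(axis=0)
        tt, pp = stats.ttest_ind(med_a, med_b, equal_var=False)
        delta = float(med_b.mean() - med_a.mean())
        rows.append((region, len(probe_ids), delta, float(tt), float(pp), pp < region_alpha))
    return pd.DataFrame(rows, columns=["region_id", "n_probes", "delta_beta",
                                       "t", "pvalue", "significant"]).set_index("region_id", drop=False)
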