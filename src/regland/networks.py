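"""TF -> enhancer -> gene network assembly and validation.

Differential regions are assigned to candidate target genes under three
jointly applied filters: the gene's TSS lies within a distance window of the
region, the gene is itself differentially expressed between the two states,
and the region's activity profile correlates with the gene's expression
profile across the sample panel. Restricting the resulting links to a TF's
predicted target regions yields that TF's regulatory network, which is
validated by target-set overlap (hypergeometric) and by pre-ranked GSEA of
the target genes in an external co-expression ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

# the parameter grid explored for the assignment
DISTANCE_GRID = (10_000, 20_000, 100_000, 1_000_000, 2_000_000)
GE_ALPHA_GRID = (0.05, 0.1, 1.0)
CORR_GRID = (0.0, 0.1, 0.3, 0.5, 0.7)


@dataclass(frozen=True)
class AssignmentParams:
    """Filters of the region-to-gene assignment.

    Defaults are the settings used to build the final networks: a 1 Mb TSS
    window, differential expression at adjusted p <= 0.1 with |log2FC| >= 1,
    and |Pearson r| >= 0.3 between region activity and gene expression.
    """

    max_dist: int = 1_000_000
    ge_alpha: float = 0.1
    lfc_min: float = 1.0
    corr_min: float = 0.3
    corr_mode: str = "absolute"  # "absolute" | "positive"
    closest_only: bool = False
    distance_anchor: str = "edge"  # "edge" | "midpoint"

    def __post_init__(self):
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")
        if not 0 <= self.corr_min <= 1:
            raise ValueError("corr_min must be in [0, 1]")
        if self.corr_mode not in ("absolute", "positive"):
            raise ValueError("corr_mode must be 'absolute' or 'positive'")


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def assign_regions_to_genes(regions: pd.DataFrame,
                            tss_table: pd.DataFrame,
                            expr_results: pd.DataFrame,
                            activity_matrix: pd.DataFrame,
                            expr_matrix: pd.DataFrame,
                            params: AssignmentParams = AssignmentParams()) -> pd.DataFrame:
    """Link regions to genes passing distance, expression and correlation filters.

    ``regions`` needs chrom/start/end/id columns; ``tss_table`` gene_id/chrom/
    tss; ``expr_results`` the differential table (id, log2fc, padj);
    ``activity_matrix`` and ``expr_matrix`` real-valued profiles over the
    same sample panel (region rows / gene rows). Genes failing the expression
    filter are ignored entirely. Returns a link table with columns
    region_id, gene_id, distance, corr.
    """
    if list(activity_matrix.columns) != list(expr_matrix.columns):
        raise ValueError("activity and expression matrices must share the sample panel")
    de = expr_results[(expr_results["log2fc"].abs() >= params.lfc_min)
                      & (expr_results["padj"] <= params.ge_alpha)]
    genes = tss_table[tss_table["gene_id"].isin(de["id"])]
    rows = []
    for chrom, reg_grp in regions.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        tss = g["tss"].to_numpy()
        gids = g["gene_id"].to_numpy()
        for _, r in reg_grp.iterrows():
            if params.distance_anchor == "midpoint":
                mid = (int(r["start"]) + int(r["end"])) // 2
                dist = np.abs(tss - mid)
            else:
                dist = np.maximum.reduce([int(r["start"]) - tss,
                                          tss - int(r["end"]) + 1,
                                          np.zeros_like(tss)])
            hit = dist <= params.max_dist
            for gid, d in zip(gids[hit], dist[hit]):
                rows.append((r["id"], gid, int(d)))
    if not rows:
        return pd.DataFrame(columns=["region_id", "gene_id", "distance", "corr"])
    links = pd.DataFrame(rows, columns=["region_id", "gene_id", "distance"])
    act = activity_matrix.loc[links["region_id"]].to_numpy(dtype=float)
    expr = expr_matrix.loc[links["gene_id"]].to_numpy(dtype=float)
    links["corr"] = _pearson_rows(act, expr)
    if params.corr_mode == "absolute":
        ok = links["corr"].abs() >= params.corr_min
    else:
        ok = links["corr"] >= params.corr_min
    links = links[ok].reset_index(drop=True)
    if params.closest_only and len(links):
        links = (links.sort_values(["region_id", "distance", "gene_id"])
                 .groupby("region_id", as_index=False).first())
    return links.reset_index(drop=True)


def assignment_coverage(links: pd.DataFrame, n_regions_total: int) -> float:
    """Percentage of regions with at least one link (0-100 scale)."""
    n_linked = links["region_id"].nunique() if len(links) else 0
    if n_regions_total < n_linked:
        raise ValueError("total region count below linked region count")
    if n_regions_total == 0:
        return 0.0
    return 100.0 * n_linked / n_regions_total


def fraction_report(k: int, n: int, decimals: int | None = None) -> float:
    """A printed percentage: nearest integer by default, or fixed decimals."""
    pct = 100.0 * k / n
    return round(pct) if decimals is None else round(pct, decimals)


@dataclass
class TFNetwork:
    """A TF's predicted regulatory network: its target regions' gene links."""

    tf_name: str
    links: pd.DataFrame
    params: AssignmentParams = field(default_factory=AssignmentParams)

    @property
    def target_genes(self) -> set:
        return set(self.links["gene_id"]) if len(self.links) else set()

    @property
    def regions(self) -> set:
        return set(self.links["region_id"]) if len(self.links) else set()

    def edges(self) -> set:
        return set(zip(self.links["region_id"], self.links["gene_id"])) if len(self.links) else set()


def build_tf_network(tf_name: str, tf_leading_targets, links: pd.DataFrame,
                     params: AssignmentParams = AssignmentParams()) -> TFNetwork:
    """Restrict the link table to the TF's predicted target regions."""
    targets = set(tf_leading_targets)
    sub = links[links["region_id"].isin(targets)].reset_index(drop=True) if len(links) \
        else links
    return TFNetwork(tf_name, sub, params)


def target_overlap(net_a: TFNetwork, net_b: TFNetwork, universe: int) -> tuple[int, float]:
    """Shared target genes of two networks with an upper hypergeometric tail p."""
    a, b = net_a.target_genes, net_b.target_genes
    if universe < len(a | b):
        raise ValueError("universe smaller than the union of target sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b))) if a and b else 1.0
    return k, p


def enrichment_score(scores: np.ndarray, in_set: np.ndarray, weight_p: float = 1.0) -> tuple[float, np.ndarray]:
    """GSEA running-sum enrichment score for a ranked list.

    ``scores`` must be sorted descending; hits step up proportionally to
    |score|^p, misses step down by 1/(N - |S|); ES is the maximum deviation
    from zero (signed).
    """
    n = scores.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a proper non-empty subset of the ranking")
    w = np.abs(scores) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero scores inside the set: fall back to equal steps
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def gsea_preranked(ranking: pd.Series, gene_set, weight_p: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> dict:
    """Pre-ranked GSEA with gene-set permutation.

    ``ranking`` maps gene -> score (any order; sorted internally, ties kept
    stable). The null is built from ``n_perm`` random gene sets of the same
    size; NES divides ES by the mean |null ES| of the same sign and the FDR
    q-value is the fraction of same-signed null ES at least as extreme.
    """
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    scores = ranking.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    genes = ranking.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    es, running = enrichment_score(scores, in_set, weight_p)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = scores.size
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hit, replace=False)] = True
        null[i], _ = enrichment_score(scores, perm, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if same_sign.size else 1.0
    nes_val = es / denom if denom > 0 else 0.0
    extreme = (np.abs(same_sign) >= abs(es)).sum() if same_sign.size else 0
    fdr = (1 + extreme) / (1 + same_sign.size) if same_sign.size else 1.0
    leading = genes[:int(np.argmax(np.abs(running))) + 1][in_set[:int(np.argmax(np.abs(running))) + 1]]
    return {"es": es, "nes": nes_val, "fdr": float(fdr),
            "leading_edge": list(leading), "n_hit": n_hit}


def signature_score_correlation(expr_matrix: pd.DataFrame, signature,
                                phenotype: pd.Series) -> tuple[float, float]:
    """Pearson r (and two-sided p) of mean-signature expression vs a phenotype."""
    sig = [g for g in signature if g in expr_matrix.index]
    if not sig:
        raise ValueError("no signature gene present in the expression matrix")
    phenotype = phenotype.loc[expr_matrix.columns]
    if phenotype.nunique() <= 1:
        raise ValueError("constant phenotype")
    if len(phenotype) < 3:
        raise ValueError("need at least 3 samples")
    score = expr_matrix.loc[sig].mean(axis=0)
    r, p = stats.pearsonr(score, phenotype)
    return float(r), float(p)


def correlation_arcs(region_activity: pd.DataFrame, regions: pd.DataFrame,
                     gene_expr: pd.Series, gene_tss: int, gene_chrom: str,
                     window: int = 1_000_000) -> pd.DataFrame:
    """Pearson r between each nearby region's activity and one gene's expression.

    Regions within ``window`` of the gene's TSS (edge distance) are reported
    with their distance and correlation — the data behind interaction-arc
    plots comparing activity-expression coupling with 3D-contact calls.
    """
    if len(gene_expr) < 3:
        raise ValueError("need at least 3 samples")
    sub = regions[regions["chrom"] == gene_chrom]
    dist = np.maximum.reduce([sub["start"].to_numpy() - gene_tss,
                              gene_tss - sub["end"].to_numpy() + 1,
                              np.zeros(len(sub), dtype=np.int64)])
    sub = sub[dist <= window]
    dist = dist[dist <= window]
    act = region_activity.loc[sub["id"]].to_numpy(dtype=float)
    expr = gene_expr.loc[region_activity.columns].to_numpy(dtype=float)[None, :]
    corr = _pearson_rows(act, np.repeat(expr, len(sub), axis=0)) if len(sub) else np.array([])
    return pd.DataFrame({"region_id": sub["id"].to_numpy(), "distance": dist,
                         "corr": corr})
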