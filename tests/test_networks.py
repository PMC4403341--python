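"""Region-to-gene assignment, TF networks, overlap tests and pre-ranked GSEA."""

import math

import numpy as np
import pandas as pd
import pytest

from regland import activity, networks as net
from regland.networks import AssignmentParams
from regland.simulate import simulate_linked_study


def tiny_setup(tss_pos, padj, corr_sign=1.0, lfc=1.5, n_samples=6, seed=0):
    """One region + one gene with controllable distance/padj/correlation."""
    rng = np.random.default_rng(seed)
    regions = pd.DataFrame({"chrom": ["c"], "start": [1_000_000],
                            "end": [1_001_000], "id": ["r1"]})
    tss = pd.DataFrame({"gene_id": ["g1"], "chrom": ["c"], "tss": [tss_pos]})
    res = pd.DataFrame({"id": ["g1"], "log2fc": [lfc], "padj": [padj]})
    base = rng.normal(0, 1, n_samples)
    act = pd.DataFrame([base], index=["r1"],
                       columns=[f"s{i}" for i in range(n_samples)])
    expr = pd.DataFrame([corr_sign * base], index=["g1"], columns=act.columns)
    return regions, tss, res, act, expr


class TestAssignment:
    def test_passing_link(self):
        args = tiny_setup(tss_pos=1_500_000, padj=0.05)
        links = net.assign_regions_to_genes(*args, AssignmentParams())
        assert len(links) == 1 and links.iloc[0]["gene_id"] == "g1"

    def test_distance_filter(self):
        args = tiny_setup(tss_pos=2_600_000, padj=0.05)  # 1.6 Mb away
        assert net.assign_regions_to_genes(*args, AssignmentParams()).empty

    def test_corr_mode_positive_vs_absolute(self):
        args = tiny_setup(tss_pos=1_200_000, padj=0.05, corr_sign=-1.0)
        absolute = net.assign_regions_to_genes(*args, AssignmentParams(corr_mode="absolute"))
        positive = net.assign_regions_to_genes(*args, AssignmentParams(corr_mode="positive"))
        assert len(absolute) == 1 and positive.empty

    def test_expression_filter_ignores_gene(self):
        args = tiny_setup(tss_pos=1_200_000, padj=0.5)
        assert net.assign_regions_to_genes(*args, AssignmentParams(ge_alpha=0.1)).empty

    def test_mismatched_sample_panels_rejected(self):
        regions, tss, res, act, expr = tiny_setup(1_200_000, 0.05)
        expr.columns = [f"x{i}" for i in range(expr.shape[1])]
        with pytest.raises(ValueError):
            net.assign_regions_to_genes(regions, tss, res, act, expr)

    def test_relaxing_thresholds_never_removes_links(self):
        study = simulate_linked_study(seed=3, n_links=20)
        sets = activity.differential_regions(study.region_counts)
        res = activity.nb_differential(study.expr_counts)
        ids = sorted(set(sets["proliferative"]) | set(sets["invasive"]))
        regions = study.catalog.regions[study.catalog.regions["id"].isin(ids)]
        act_m = activity.log_transform(study.region_counts)
        expr_m = activity.log_transform(study.expr_counts)
        prev_edges = None
        # tighten along the printed grids: links must be nested
        for dist, alpha, corr in [(2_000_000, 1.0, 0.0), (1_000_000, 0.1, 0.3),
                                  (100_000, 0.05, 0.5), (10_000, 0.05, 0.7)]:
            links = net.assign_regions_to_genes(
                regions, study.annotation, res, act_m, expr_m,
                AssignmentParams(max_dist=dist, ge_alpha=alpha, corr_min=corr))
            edges = set(zip(links["region_id"], links["gene_id"]))
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_closest_only_subset(self):
        study = simulate_linked_study(seed=4, n_links=12)
        res = activity.nb_differential(study.expr_counts)
        regions = study.catalog.regions
        act_m = activity.log_transform(study.region_counts)
        expr_m = activity.log_transform(study.expr_counts)
        all_links = net.assign_regions_to_genes(regions, study.annotation, res,
                                                act_m, expr_m, AssignmentParams())
        closest = net.assign_regions_to_genes(regions, study.annotation, res,
                                              act_m, expr_m,
                                              AssignmentParams(closest_only=True))
        assert set(zip(closest["region_id"], closest["gene_id"])) <= \
            set(zip(all_links["region_id"], all_links["gene_id"]))
        assert closest.groupby("region_id").size().max() == 1


class TestCoverage:
    @pytest.mark.parametrize("k, n, expected", [
        (1404, 20122, 7), (4599, 20122, 23), (0, 100, 0)])
    def test_rounded_percentages(self, k, n, expected):
        assert net.fraction_report(k, n) == expected

    @pytest.mark.parametrize("k, n, expected", [
        (2437, 6669, 36.5), (1520, 6669, 22.8)])
    def test_one_decimal_percentages(self, k, n, expected):
        assert net.fraction_report(k, n, decimals=1) == expected

    def test_assignment_coverage_counts_distinct_regions(self):
        links = pd.DataFrame({"region_id": ["r1", "r1", "r2"],
                              "gene_id": ["g1", "g2", "g1"]})
        assert net.assignment_coverage(links, 10) == 20.0
        with pytest.raises(ValueError):
            net.assignment_coverage(links, 1)


class TestTFNetwork:
    def test_no_targets_empty_network(self):
        links = pd.DataFrame({"region_id": ["r1"], "gene_id": ["g1"],
                              "distance": [5], "corr": [0.9]})
        network = net.build_tf_network("TF", [], links)
        assert network.target_genes == set() and len(network.links) == 0

    def test_shared_regions_identical_gene_sets(self):
        links = pd.DataFrame({"region_id": ["r1", "r2"], "gene_id": ["g1", "g2"],
                              "distance": [5, 6], "corr": [0.9, 0.8]})
        n1 = net.build_tf_network("TF_a", ["r1", "r2"], links)
        n2 = net.build_tf_network("TF_b", ["r1", "r2"], links)
        assert n1.target_genes == n2.target_genes

    def test_planted_network_recovery_at_default_parameters(self):
        study = simulate_linked_study(seed=2)
        sets = activity.differential_regions(study.region_counts)
        res = activity.nb_differential(study.expr_counts)
        ids = sorted(set(sets["proliferative"]) | set(sets["invasive"]))
        regions = study.catalog.regions[study.catalog.regions["id"].isin(ids)]
        links = net.assign_regions_to_genes(
            regions, study.annotation, res,
            activity.log_transform(study.region_counts),
            activity.log_transform(study.expr_counts), AssignmentParams())
        network = net.build_tf_network("TF1", study.truth.tf_target_regions["TF1"],
                                       links)
        planted = set(study.truth.region_gene_links)
        edges = network.edges()
        recall = len(edges & planted) / len(planted)
        precision = len(edges & planted) / max(len(edges), 1)
        assert recall >= 0.9
        assert precision >= 0.8


class TestOverlap:
    def n(self, genes):
        links = pd.DataFrame({"region_id": [f"r{i}" for i in range(len(genes))],
                              "gene_id": genes, "distance": 0, "corr": 1.0})
        return net.build_tf_network("t", links["region_id"], links)

    def test_disjoint_sets(self):
        k, p = net.target_overlap(self.n(["a", "b"]), self.n(["c", "d"]), 100)
        assert k == 0 and p > 0.9

    def test_enumeration_value(self):
        k, p = net.target_overlap(self.n(list("abcde")), self.n(list("abcde")), 20)
        assert k == 5 and np.isclose(p, 1 / math.comb(20, 5))


def brute_force_es(scores, in_set, p):
    """Explicit running-sum maximum-deviation re-computation."""
    n = len(scores)
    w = np.abs(scores) ** p
    nr = w[in_set].sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if in_set[i]:
            running += w[i] / nr
        else:
            running -= 1 / (n - in_set.sum())
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def ranked(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_es_equals_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(3)
        for seed in range(10):
            ranking = self.ranked(seed=seed)
            genes = list(rng.choice(ranking.index, size=8, replace=False))
            res = net.gsea_preranked(ranking, genes, weight_p=weight_p,
                                     n_perm=10, seed=0)
            in_set = np.isin(ranking.index, genes)
            oracle = brute_force_es(ranking.to_numpy(), in_set, weight_p)
            assert np.isclose(res["es"], oracle)

    def test_top_loaded_set_significant(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(np.sort(rng.normal(0, 1, 2000))[::-1],
                           index=[f"g{i}" for i in range(2000)])
        res = net.gsea_preranked(scores, [f"g{i}" for i in range(50)],
                                 n_perm=500, seed=2)
        assert res["fdr"] < 0.01 and res["es"] > 0.9

    def test_null_set_not_significant(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.normal(0, 1, 500),
                           index=[f"g{i}" for i in range(500)])
        genes = list(rng.choice(scores.index, 30, replace=False))
        res = net.gsea_preranked(scores, genes, n_perm=300, seed=5)
        assert res["fdr"] > 0.05

    def test_degenerate_sets_rejected(self):
        ranking = self.ranked()
        with pytest.raises(ValueError):
            net.gsea_preranked(ranking, list(ranking.index))  # all genes
        with pytest.raises(ValueError):
            net.gsea_preranked(ranking, ["absent"])


class TestSignatureScore:
    def expr(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(5, 1, (20, n)),
                            index=[f"g{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(n)])

    def test_phenotype_equal_to_score_r_one(self):
        expr = self.expr()
        sig = ["g0", "g1", "g2"]
        phenotype = expr.loc[sig].mean(axis=0)
        r, p = net.signature_score_correlation(expr, sig, phenotype)
        assert np.isclose(r, 1.0)

    def test_sign_flip_negates_r(self):
        expr = self.expr(seed=2)
        sig = ["g0", "g1"]
        phenotype = pd.Series(np.arange(expr.shape[1], dtype=float),
                              index=expr.columns)
        r1, _ = net.signature_score_correlation(expr, sig, phenotype)
        r2, _ = net.signature_score_correlation(expr, sig, -phenotype)
        assert np.isclose(r1, -r2)

    def test_constant_phenotype_rejected(self):
        expr = self.expr()
        with pytest.raises(ValueError):
            net.signature_score_correlation(expr, ["g0"],
                                            pd.Series(1.0, index=expr.columns))


class TestCorrelationArcs:
    def test_proportional_and_anticorrelated(self):
        samples = [f"s{i}" for i in range(6)]
        regions = pd.DataFrame({"chrom": ["c", "c"], "start": [1000, 5000],
                                "end": [2000, 6000], "id": ["r1", "r2"]})
        base = np.arange(6, dtype=float)
        act_m = pd.DataFrame([base * 2, -base], index=["r1", "r2"], columns=samples)
        gene = pd.Series(base, index=samples)
        arcs = net.correlation_arcs(act_m, regions, gene, gene_tss=3000,
                                    gene_chrom="c", window=10_000)
        arcs = arcs.set_index("region_id")
        assert np.isclose(arcs.loc["r1", "corr"], 1.0)
        assert np.isclose(arcs.loc["r2", "corr"], -1.0)

    def test_planted_link_beats_unlinked_background(self):
        study = simulate_linked_study(seed=6, n_links=10)
        act_m = activity.log_transform(study.region_counts)
        rid, gid = study.truth.region_gene_links[0]
        gene_row = study.annotation.set_index("gene_id").loc[gid]
        expr_m = activity.log_transform(study.expr_counts)
        arcs = net.correlation_arcs(act_m, study.catalog.regions,
                                    expr_m.loc[gid], int(gene_row["tss"]),
                                    gene_row["chrom"], window=2_000_000)
        arcs = arcs.set_index("region_id")
        linked_r = abs(arcs.loc[rid, "corr"])
        others = arcs.drop(index=[rid])["corr"].abs()
        unlinked = others[~others.index.isin(
            study.truth.active_regions_by_state["invasive"]
            | study.truth.active_regions_by_state["proliferative"])]
        if len(unlinked) >= 5:
            assert linked_r > np.quantile(unlinked, 0.95)
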