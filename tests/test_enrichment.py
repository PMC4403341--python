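"""Motif scanning, rankings, recovery AUC/NES, order statistics and the
hypergeometric significance test, each against an independent oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from regland import enrichment as en
from regland.enrichment import PWM, FeatureRanking


def sharp_pwm(consensus="ACGTACGT", w=0.97):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), (1 - w) / 3)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = w
    return PWM("sharp", m)


def brute_force_scan(seq, pwm, background=None):
    """Per-window, per-strand re-computation with explicit loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    q = np.full(4, 0.25) if background is None else np.asarray(background)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def site(s):
        total = 0.0
        for j, b in enumerate(s):
            if b == "N":
                total += float((q * np.log2(pwm.matrix[j] / q)).sum())
            else:
                total += math.log2(pwm.matrix[j, idx[b]] / q[idx[b]])
        return total

    best = float("-inf")
    rc = "".join(comp[b] for b in reversed(seq))
    for strand_seq in (seq, rc):
        for i in range(len(strand_seq) - pwm.length + 1):
            best = max(best, site(strand_seq[i:i + pwm.length]))
    return best


class TestScan:
    def test_consensus_scores_closed_form(self):
        pwm = sharp_pwm()
        expected = float(np.log2(4 * pwm.matrix.max(axis=1)).sum())
        score = en.scan_pwm({"r": pwm.consensus()}, pwm)["r"]
        assert np.isclose(score, expected)

    def test_reverse_complement_same_score(self):
        pwm = sharp_pwm("ACGGTTAC")
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = "TTTT" + pwm.consensus() + "GGGG"
        rc = "".join(comp[b] for b in reversed(seq))
        s1 = en.scan_pwm({"r": seq}, pwm)["r"]
        s2 = en.scan_pwm({"r": rc}, pwm)["r"]
        assert np.isclose(s1, s2)

    def test_short_or_empty_sequence_sentinel(self):
        pwm = sharp_pwm()
        out = en.scan_pwm({"a": "ACG", "b": ""}, pwm)
        assert np.isneginf(out["a"]) and np.isneginf(out["b"])

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(12)
        pwm = sharp_pwm("ACGTTGCA", w=0.7)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                     size=300))
            fast = en.scan_pwm({"r": seq}, pwm)["r"]
            assert np.isclose(fast, brute_force_scan(seq, pwm), atol=1e-9)


class TestRanking:
    def test_strictly_decreasing_scores_identity(self):
        scores = pd.Series([9.0, 5.0, 1.0], index=["a", "b", "c"])
        r = en.rank_regions(scores, "f")
        assert r.order == ["a", "b", "c"]

    def test_tied_scores_differ_by_seed_but_valid(self):
        scores = pd.Series(np.zeros(50), index=[f"r{i}" for i in range(50)])
        r1 = en.rank_regions(scores, "f", tie_seed=1)
        r2 = en.rank_regions(scores, "f", tie_seed=2)
        assert sorted(r1.order) == sorted(r2.order)
        assert r1.order != r2.order

    def test_tied_block_ranks_uniform_over_seeds(self):
        scores = pd.Series([1.0, 0.0, 0.0, 0.0, 0.0], index=list("abcde"))
        positions = {k: [] for k in "bcde"}
        for seed in range(400):
            r = en.rank_regions(scores, "f", tie_seed=seed)
            for k in "bcde":
                positions[k].append(r.order.index(k))
        for k in "bcde":
            assert 1.9 < np.mean(positions[k]) < 3.1  # uniform over ranks 1..4

    def test_wrong_length_rejected(self):
        scores = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            en.rank_regions(scores, "f", catalog_ids=["a", "b"])


class TestTrackRanking:
    class Cat:
        regions = pd.DataFrame({
            "chrom": ["c", "c", "c"], "start": [0, 100, 200],
            "end": [50, 150, 250], "id": ["r1", "r2", "r3"]})

    def test_max_peak_score_and_zero_default(self):
        peaks = pd.DataFrame({"chrom": ["c", "c"], "start": [10, 30],
                              "end": [40, 60], "score": [3.0, 7.0]})
        r = en.track_ranking(peaks, self.Cat(), "t")
        assert r.scores["r1"] == 7.0 and r.scores["r2"] == 0.0

    def test_one_bp_overlap_counts(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [149], "end": [201],
                              "score": [5.0]})
        r = en.track_ranking(peaks, self.Cat(), "t")
        assert r.scores["r2"] == 5.0 and r.scores["r3"] == 5.0 and r.scores["r1"] == 0.0


class TestOrderStatistics:
    def test_single_source_is_identity(self):
        assert np.isclose(en.combine_rankings_orderstat([0.3]), 0.3)

    def test_certain_event(self):
        assert np.isclose(en.combine_rankings_orderstat([1.0, 1.0]), 1.0)

    def test_analytic_two_source_value(self):
        assert np.isclose(en.combine_rankings_orderstat([0.1, 0.2]), 0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            en.combine_rankings_orderstat([0.0, 0.5])

    def test_matches_monte_carlo_for_small_n(self):
        rng = np.random.default_rng(17)
        n_draws = 200_000
        for n in range(1, 6):
            u = np.sort(rng.random((n_draws, n)), axis=1)
            for _ in range(4):
                s = np.sort(rng.random(n))
                q = en.combine_rankings_orderstat(s)
                hits = (u <= s).all(axis=1)
                p_hat = hits.mean()
                se = math.sqrt(max(p_hat * (1 - p_hat), 1e-12) / n_draws)
                assert abs(q - p_hat) <= max(3 * se, 5e-4)


class TestRecovery:
    def ranking(self, order):
        return FeatureRanking("f", "motif", order)

    def test_no_foreground_in_top_auc_zero(self):
        order = [f"r{i}" for i in range(1000)]
        assert en.recovery_auc(self.ranking(order), ["r999"]) == 0.0

    def test_closed_form_top_ranked_foreground(self):
        order = [f"r{i}" for i in range(10_000)]
        fg = [f"r{i}" for i in range(5)]  # ranks 1..5, T = 25
        auc = en.recovery_auc(self.ranking(order), fg)
        assert np.isclose(auc, 0.92)

    def test_equals_step_function_oracle(self):
        rng = np.random.default_rng(5)
        order = [f"r{i}" for i in range(2000)]
        for _ in range(20):
            fg = list(rng.choice(order, size=50, replace=False))
            t = math.ceil(0.0025 * 2000)
            ranks = {rid: i + 1 for i, rid in enumerate(order)}
            oracle = np.mean([sum(1 for f in fg if ranks[f] <= x) / len(fg)
                              for x in range(1, t + 1)])
            assert np.isclose(en.recovery_auc(self.ranking(order), fg), oracle)

    def test_random_ranking_mean_matches_expectation(self):
        rng = np.random.default_rng(8)
        m, f = 1000, 100
        t = math.ceil(0.0025 * m)
        ids = [f"r{i}" for i in range(m)]
        fg = ids[:f]
        aucs = []
        for _ in range(2000):
            order = list(rng.permutation(ids))
            aucs.append(en.recovery_auc(self.ranking(order), fg))
        expected = (t + 1) / (2 * m)  # uniform placement
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - expected) < 4 * se

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            en.recovery_auc(self.ranking(["a", "b"]), [])


class TestNES:
    def test_mean_feature_zero_and_hand_values(self):
        aucs = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        out = en.nes(aucs)  # population sd = sqrt(2/300)
        assert np.isclose(out["b"], 0.0)
        assert np.allclose(out[["a", "c"]], [-np.sqrt(1.5), np.sqrt(1.5)])
        out_s = en.nes(aucs, population_sd=False)  # sample sd = 0.1
        assert np.allclose(out_s[["a", "c"]], [-1.0, 1.0])

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        aucs = pd.Series(rng.random(10))
        assert np.allclose(en.nes(aucs), en.nes(aucs * 3 + 0.7))

    def test_degenerate_collection_rejected(self):
        with pytest.raises(ValueError):
            en.nes(pd.Series([0.1, 0.1, 0.1]))


class TestHypergeometric:
    def test_full_catalog_foreground_p_one(self):
        order = [f"r{i}" for i in range(100)]
        p, _ = en.hypergeom_enrichment(FeatureRanking("f", "motif", order), order)
        assert np.isclose(p, 1.0)

    def test_enumeration_value(self):
        # M=20, F=5, T=5 (cutoff 0.25), all 5 in top 5 -> 1/C(20,5)
        order = [f"r{i}" for i in range(20)]
        fg = order[:5]
        p, padj = en.hypergeom_enrichment(FeatureRanking("f", "motif", order), fg,
                                          cutoff_frac=0.25, n_features=10)
        assert np.isclose(p, 1 / math.comb(20, 5))
        assert np.isclose(padj, 10 * p)

    def test_monotone_in_hit_count(self):
        order = [f"r{i}" for i in range(100)]
        ranking = FeatureRanking("f", "motif", order)
        p_vals = []
        for k in range(4):
            fg = order[:k] + order[50:50 + (3 - k)] + order[90:95]
            p, _ = en.hypergeom_enrichment(ranking, fg, cutoff_frac=0.05)
            p_vals.append(p)
        assert all(a >= b for a, b in zip(p_vals, p_vals[1:]))


class TestTargets:
    def test_leading_targets_subset_and_order(self):
        order = [f"r{i}" for i in range(1000)]
        fg = ["r500", "r1", "r0"]
        targets = en.leading_targets(FeatureRanking("f", "motif", order), fg,
                                     cutoff_frac=0.01)
        assert targets == ["r0", "r1"]
        assert set(targets) <= set(fg)

    def test_intersect_motif_track(self):
        order = ["a", "b", "c", "d"]
        ranking = FeatureRanking("m", "motif", order)
        assert en.intersect_motif_track(["a", "c"], ["c", "d"], ranking) == ["c"]
        assert en.intersect_motif_track(["a"], ["b"]) == []
        both = en.intersect_motif_track(["a", "b"], ["a", "b"])
        assert both == ["a", "b"]
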